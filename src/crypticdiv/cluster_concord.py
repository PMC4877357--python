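"""Cluster detection and cross-dataset partition concordance.

The cluster-detection procedure reduces the data to the ordination axes
retained by the broken-stick rule (covariance PCA for coordinate data,
Gower-centered PCoA for distance matrices) and then selects the number
of clusters and covariance structure of a Gaussian mixture by BIC, with
EM initialized deterministically from Ward agglomerative cuts.

Partition agreement between datasets is measured with the adjusted Rand
index (ARI) on the overlapping observations, with significance from a
permutation null that shuffles one partition's labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb
from sklearn.cluster import AgglomerativeClustering
from sklearn.mixture import GaussianMixture

__all__ = [
    "Partition", "PCAReduction", "ConcordanceResult", "broken_stick_reduce",
    "gmm_cluster", "adjusted_rand", "ari_permutation_test",
    "concordance_matrix",
]

#: GaussianMixture covariance structures searched during model selection
COVARIANCE_STRUCTURES = ("spherical", "diag", "tied", "full")
DEFAULT_K_MAX = 9


@dataclass
class Partition:
    """Hard cluster labels (1..k) over a set of specimen IDs."""

    ids: list
    labels: np.ndarray
    k: int
    source: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids/labels length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate specimen IDs")
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or uniq.max() > self.k:
            raise ValueError("labels must lie in 1..k")


@dataclass
class PCAReduction:
    scores: np.ndarray          # n x retained
    eigenvalues: np.ndarray     # full (positive) spectrum
    retained: list              # indices of retained axes (prefix)
    broken_stick: np.ndarray    # expected proportions b_k
    mode: str = "pca"


@dataclass
class ConcordanceResult:
    ari: float
    p_value: float
    n_common: int
    n_perm: int = 0


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected relative eigenvalues b_k = (1/p) sum_{i=k}^p 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_reduce(data, mode: str = "pca") -> PCAReduction:
    """Ordinate and keep the leading axes passing the broken-stick rule.

    ``mode='pca'``: eigendecomposition of the covariance matrix (scores
    centered). ``mode='pcoa'``: Gower-centered principal coordinates of a
    symmetric zero-diagonal distance matrix; negative eigenvalues are
    dropped and proportions taken over the positive part. Axes are
    retained while their relative eigenvalue exceeds the broken-stick
    expectation, stopping at the first failure; if the first axis
    already fails, axis 1 alone is retained so clustering has at least
    one dimension to work with.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need n >= 3")
    if mode == "pca":
        Xc = X - X.mean(0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        lam = s ** 2 / (X.shape[0] - 1)
        scores = u * s
    elif mode == "pcoa":
        if X.shape[0] != X.shape[1] or not np.allclose(X, X.T):
            raise ValueError("pcoa mode needs a symmetric distance matrix")
        if not np.allclose(np.diag(X), 0):
            raise ValueError("distance matrix must have zero diagonal")
        n = X.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (X ** 2) @ J
        lam, vec = np.linalg.eigh(B)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        pos = lam > max(1e-10 * abs(lam).max(), 0)
        lam, vec = lam[pos], vec[:, pos]
        if lam.size == 0:
            raise ValueError("no positive eigenvalues (all-zero distances?)")
        scores = vec * np.sqrt(lam)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero variance")
    rel = lam / total
    bk = broken_stick(len(lam))
    n_keep = 0
    for i in range(len(lam)):
        if rel[i] > bk[i]:
            n_keep += 1
        else:
            break
    if n_keep == 0:
        n_keep = 1  # fallback: clustering needs at least one axis
    return PCAReduction(scores=scores[:, :n_keep], eigenvalues=lam,
                        retained=list(range(n_keep)), broken_stick=bk,
                        mode=mode)


def gmm_cluster(reduced, k_max: int = DEFAULT_K_MAX, seed: int = 0,
                ids=None, source: str = "") -> Partition:
    """BIC-selected Gaussian-mixture partition of reduced scores.

    Fits mixtures for K = 1..k_max across the covariance structures in
    :data:`COVARIANCE_STRUCTURES`, each initialized from the K-cluster
    Ward agglomerative cut (deterministic given the data), and returns
    the hard assignment of the (structure, K) pair with the lowest BIC.
    Candidates within 2 BIC units of the optimum count as ties and
    resolve toward the smallest K (the conventional "barely worth
    mentioning" band for BIC differences). Degenerate candidates (EM
    failure, vanishing covariance) are discarded.
    """
    X = reduced.scores if isinstance(reduced, PCAReduction) else np.asarray(reduced, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n <= k_max:
        k_max = n - 1
    if ids is None:
        ids = list(range(n))
    candidates = []  # (bic, K, structure, labels)
    for K in range(1, k_max + 1):
        if K == 1:
            means = X.mean(0, keepdims=True)
        else:
            ward = AgglomerativeClustering(n_clusters=K, linkage="ward")
            init_labels = ward.fit_predict(X)
            means = np.stack([X[init_labels == j].mean(0) for j in range(K)])
        for structure in COVARIANCE_STRUCTURES:
            try:
                gm = GaussianMixture(
                    n_components=K, covariance_type=structure,
                    means_init=means, n_init=1, max_iter=500,
                    reg_covar=1e-9, random_state=seed)
                gm.fit(X)
                if not gm.converged_ and K > 1:
                    continue
                bic = gm.bic(X)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.isfinite(bic):
                continue
            candidates.append((bic, K, structure, gm.predict(X)))
    if not candidates:
        # total degeneracy (e.g., identical points): a single cluster
        return Partition(ids=list(ids), labels=np.ones(n, dtype=int), k=1,
                         source=source)
    best_bic = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_bic + 2.0]
    _, K, structure, labels = min(tied, key=lambda c: (c[1], c[0]))
    # relabel to 1..k in order of first appearance, dropping empty comps
    uniq = []
    remap = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(uniq) + 1
            uniq.append(lab)
    labels = np.array([remap[lab] for lab in labels])
    return Partition(ids=list(ids), labels=labels, k=len(uniq), source=source)


def _common_labels(a: Partition, b: Partition):
    common = [i for i in a.ids if i in set(b.ids)]
    if len(common) < 2:
        raise ValueError("fewer than 2 overlapping observations")
    pa = {s: l for s, l in zip(a.ids, a.labels)}
    pb = {s: l for s, l in zip(b.ids, b.labels)}
    la = np.array([pa[s] for s in common])
    lb = np.array([pb[s] for s in common])
    return la, lb, len(common)


def _ari_from_labels(la: np.ndarray, lb: np.ndarray) -> float:
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    n = len(la)
    cont = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(cont, (ia, ib), 1)
    sum_ij = comb(cont, 2).sum()
    sum_a = comb(cont.sum(1), 2).sum()
    sum_b = comb(cont.sum(0), 2).sum()
    n2 = comb(n, 2)
    expected = sum_a * sum_b / n2
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # degenerate (e.g., all-singleton partition): chance-level agreement
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


def adjusted_rand(a: Partition, b: Partition) -> float:
    """Adjusted Rand index on the observations shared by both partitions."""
    la, lb, _ = _common_labels(a, b)
    return _ari_from_labels(la, lb)


def ari_permutation_test(a: Partition, b: Partition, n_perm: int = 1000,
                         seed: int | None = None) -> ConcordanceResult:
    """Permutation significance of the ARI between two partitions.

    The null shuffles one partition's labels over the common
    observations; p = (count{ARI_perm >= ARI_obs} + 1) / (n_perm + 1).
    """
    la, lb, n_common = _common_labels(a, b)
    ari_obs = _ari_from_labels(la, lb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _ari_from_labels(la, rng.permutation(lb)) >= ari_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ConcordanceResult(ari=ari_obs, p_value=p, n_common=n_common,
                             n_perm=n_perm)


def concordance_matrix(partitions: dict, n_perm: int = 1000,
                       seed: int | None = None):
    """Pairwise ARI + permutation p over all dataset pairs.

    ``partitions`` maps dataset name -> Partition. Returns a dict of
    (name_i, name_j) -> ConcordanceResult for i < j.
    """
    names = list(partitions)
    rng = np.random.default_rng(seed)
    out = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            sub = int(rng.integers(0, 2 ** 31 - 1))
            out[(na, nb)] = ari_permutation_test(
                partitions[na], partitions[nb], n_perm=n_perm, seed=sub)
    return out
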