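"""Shape-level statistics with resampling nulls.

Operates on flattened shape-variable matrices (rows = specimens), e.g.
``ShapeResiduals.residuals`` from :mod:`crypticdiv.morpho_geometry`:

* permutation test on the Procrustes distance between two group means;
* leave-one-out cross-validated linear discriminant classification;
* between-group PCA ordination;
* morphological integration as the scaled variance of eigenvalues (SVE)
  with bootstrap;
* three disparity (morphospace occupation) estimators with rarefaction,
  and a bootstrap tail test for between-group disparity differences;
* Escoufier's RV coefficient between two shape blocks with its
  permutation test, rarefied RV, and a two-group RV-difference test.

All permutation p-values use (count + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .morpho_geometry import ShapeResiduals

__all__ = [
    "procrustes_distance_test", "loo_cv_classification", "between_group_pca",
    "integration_sve", "disparity_rarefied", "btail_test", "rv_and_tests",
    "rv_coefficient", "ProcTestResult", "DisparityResult", "RVResult",
    "IntegrationResult",
]


def _as_matrix(x):
    if isinstance(x, ShapeResiduals):
        return np.asarray(x.residuals, dtype=float)
    return np.asarray(x, dtype=float)


def _two_groups(labels):
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    a = np.flatnonzero(labels == groups[0])
    b = np.flatnonzero(labels == groups[1])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    return groups, a, b


@dataclass
class ProcTestResult:
    proc_distance: float
    p_value: float
    n_perm: int


@dataclass
class DisparityResult:
    estimator: str
    group: str
    rarefied_n: int
    mean: float
    sd: float
    boot_reps: int
    boot_distribution: np.ndarray


@dataclass
class RVResult:
    rv: float
    p_value: float | None = None
    rarefied: dict | None = None  # group -> (mean, sd, draws)
    diff_p: float | None = None


@dataclass
class IntegrationResult:
    sve: float
    boot_distribution: np.ndarray


def procrustes_distance_test(x, labels, n_perm: int = 1000,
                             seed: int | None = None) -> ProcTestResult:
    """Permutation test on the distance between two group mean shapes.

    In tangent space the Procrustes distance between group means is the
    Euclidean distance between the mean shape-variable vectors; the null
    is built by permuting group labels.
    """
    X = _as_matrix(x)
    labels = np.asarray(labels)
    _, ia, ib = _two_groups(labels)
    d_obs = float(np.linalg.norm(X[ia].mean(0) - X[ib].mean(0)))
    rng = np.random.default_rng(seed)
    n = len(labels)
    na = len(ia)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa, pb = perm[:na], perm[na:]
        d = np.linalg.norm(X[pa].mean(0) - X[pb].mean(0))
        if d >= d_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ProcTestResult(d_obs, p, n_perm)


def loo_cv_classification(x, labels, var_explained: float = 0.95):
    """Leave-one-out cross-validated linear discriminant classification.

    When the pooled covariance is singular (p >= n - 2, typical for
    shape data) the discriminant is trained on the leading principal
    components explaining ``var_explained`` of the variance. Returns
    per-group and overall percent correct plus the number of PCs used.
    """
    X = _as_matrix(x)
    labels = np.asarray(labels)
    groups, ia, ib = _two_groups(labels)
    n, p = X.shape
    n_components = None
    if p >= n - 2:
        Xc = X - X.mean(0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        lam = s ** 2
        lam = lam / lam.sum()
        n_components = int(np.searchsorted(np.cumsum(lam), var_explained) + 1)
        n_components = min(n_components, n - 3)
        X = Xc @ vt[:n_components].T
    correct = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(X[mask], labels[mask])
        correct[i] = lda.predict(X[i:i + 1])[0] == labels[i]
    per_group = {str(g): 100.0 * correct[labels == g].mean() for g in groups}
    return {"per_group": per_group,
            "overall": 100.0 * correct.mean(),
            "n_components": n_components}


def between_group_pca(x, labels):
    """Between-group PCA: eigenvectors of the covariance of group means.

    All specimens are projected onto the between-group axes; with two
    groups there is exactly one axis, parallel to the difference between
    the group means.
    """
    X = _as_matrix(x)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    means = np.stack([X[labels == g].mean(0) for g in groups])
    gm = means - means.mean(0)
    cov = gm.T @ gm / (len(groups) - 1)
    u, s, vt = np.linalg.svd(gm, full_matrices=False)
    n_axes = len(groups) - 1
    axes = vt[:n_axes]
    scores = (X - means.mean(0)) @ axes.T
    mean_scores = gm @ axes.T
    return {"axes": axes, "scores": scores, "group_means": means,
            "group_mean_scores": mean_scores, "groups": list(groups)}


def scaled_variance_of_eigenvalues(X: np.ndarray) -> float:
    """SVE = Var(lambda) / (sum lambda)^2 with the population (1/p) variance."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        return 0.0
    return float(lam.var() / total ** 2)


def integration_sve(x, n_boot: int = 1000, seed: int | None = None) -> IntegrationResult:
    """Morphological integration: scaled variance of eigenvalues + bootstrap."""
    X = _as_matrix(x)
    if X.shape[0] < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    sve = scaled_variance_of_eigenvalues(X)
    boot = np.empty(n_boot)
    n = X.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b] = scaled_variance_of_eigenvalues(X[idx])
    return IntegrationResult(sve, boot)


_ESTIMATORS = ("multivariate_variance", "mean_pairwise_dist",
               "mean_dist_centroid")


def _disparity_stat(X: np.ndarray, estimator: str) -> float:
    Xc = X - X.mean(0)
    if estimator == "multivariate_variance":
        return float((Xc ** 2).sum() / (X.shape[0] - 1))
    if estimator == "mean_pairwise_dist":
        from scipy.spatial.distance import pdist
        return float(pdist(X).mean())
    if estimator == "mean_dist_centroid":
        return float(np.sqrt((Xc ** 2).sum(1)).mean())
    raise ValueError(f"unknown disparity estimator {estimator!r}")


def disparity_rarefied(x, labels, estimator: str, rarefied_n: int | None = None,
                       n_boot: int = 1000, seed: int | None = None):
    """Rarefied disparity per group via with-replacement bootstrap.

    Each bootstrap replicate draws ``rarefied_n`` specimens with
    replacement within the group and computes the estimator
    (multivariate variance = trace of the covariance matrix); reported
    as mean +/- sd over replicates. Defaults to rarefaction at the
    smallest group size.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown disparity estimator {estimator!r}; "
                         f"choose from {_ESTIMATORS}")
    X = _as_matrix(x)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    sizes = {g: int((labels == g).sum()) for g in groups}
    if rarefied_n is None:
        rarefied_n = min(sizes.values())
    if rarefied_n > min(sizes.values()):
        raise ValueError("rarefied_n exceeds smallest group size")
    if rarefied_n < 2:
        raise ValueError("rarefied_n must be >= 2")
    rng = np.random.default_rng(seed)
    out = {}
    for g in groups:
        Xg = X[labels == g]
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, Xg.shape[0], rarefied_n)
            boot[b] = _disparity_stat(Xg[idx], estimator)
        out[str(g)] = DisparityResult(estimator, str(g), rarefied_n,
                                      float(boot.mean()), float(boot.std(ddof=1)),
                                      n_boot, boot)
    return out


def btail_test(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """Two-sided bootstrap tail test between two bootstrap distributions.

    Locates each group's point estimate (bootstrap mean) in the other
    group's bootstrap distribution, takes the doubled smaller tail in
    each direction and averages the two directions; capped at 1.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty bootstrap vector")

    def one_way(dist, point):
        hi = (dist >= point).mean()
        lo = (dist <= point).mean()
        return 2.0 * min(hi, lo)

    p = 0.5 * (one_way(a, b.mean()) + one_way(b, a.mean()))
    # never exactly 0: resolution limited by the bootstrap sample sizes
    p = max(p, 2.0 / (min(a.size, b.size) + 1))
    return float(min(p, 1.0))


def rv_coefficient(X1: np.ndarray, X2: np.ndarray) -> float:
    """Escoufier's RV between two blocks of variables (rows matched)."""
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    a = X1 - X1.mean(0)
    b = X2 - X2.mean(0)
    s12 = a.T @ b
    s11 = a.T @ a
    s22 = b.T @ b
    num = (s12 ** 2).sum()
    den = np.sqrt((s11 ** 2).sum() * (s22 ** 2).sum())
    if den <= 0:
        raise ValueError("zero variance in a block")
    return float(num / den)


def rv_and_tests(block1, block2, labels=None, ids1=None, ids2=None,
                 rarefied_n: int | None = None, n_perm: int = 1000,
                 n_rare: int = 100, seed: int | None = None) -> RVResult:
    """RV coefficient, its permutation test, and between-group comparison.

    The independence test permutes specimen correspondence between
    blocks. When ``labels`` (two groups) and ``rarefied_n`` are given,
    the rarefied RV (mean/sd over without-replacement subsamples of size
    ``rarefied_n``) is computed per group and the group difference in
    rarefied RV is tested by permuting group labels.
    """
    if isinstance(block1, ShapeResiduals) and ids1 is None:
        ids1 = block1.specimen_ids
    if isinstance(block2, ShapeResiduals) and ids2 is None:
        ids2 = block2.specimen_ids
    X1 = _as_matrix(block1)
    X2 = _as_matrix(block2)
    if ids1 is not None and ids2 is not None and list(ids1) != list(ids2):
        common = [i for i in ids1 if i in set(ids2)]
        orphans = sorted(set(ids1).symmetric_difference(ids2))
        if not common:
            raise ValueError(f"no shared specimen IDs; orphans: {orphans}")
        pos1 = {s: i for i, s in enumerate(ids1)}
        pos2 = {s: i for i, s in enumerate(ids2)}
        X1 = X1[[pos1[s] for s in common]]
        X2 = X2[[pos2[s] for s in common]]
        if labels is not None:
            labels = np.asarray(labels)[[pos1[s] for s in common]]
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("blocks must share specimens (pass ids to match)")
    rng = np.random.default_rng(seed)
    n = X1.shape[0]
    rv_obs = rv_coefficient(X1, X2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rv_coefficient(X1, X2[perm]) >= rv_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    result = RVResult(rv=rv_obs, p_value=p)

    if labels is None or rarefied_n is None:
        return result
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("two groups required for the RV difference test")

    def rarefied_rv(idx):
        draws = np.empty(n_rare)
        for r in range(n_rare):
            sub = rng.choice(idx, size=rarefied_n, replace=False)
            draws[r] = rv_coefficient(X1[sub], X2[sub])
        return draws

    rare = {}
    means = {}
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if rarefied_n > len(idx):
            raise ValueError("rarefied_n exceeds group size")
        draws = rarefied_rv(idx)
        rare[str(g)] = (float(draws.mean()), float(draws.std(ddof=1)), draws)
        means[g] = draws.mean()
    d_obs = abs(means[groups[0]] - means[groups[1]])
    na = int((labels == groups[0]).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ia, ib = perm[:na], perm[na:]
        d = abs(rarefied_rv(ia).mean() - rarefied_rv(ib).mean())
        if d >= d_obs:
            count += 1
    result.rarefied = rare
    result.diff_p = (count + 1) / (n_perm + 1)
    return result
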