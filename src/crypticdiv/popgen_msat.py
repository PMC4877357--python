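"""Microsatellite statistics.

Weir-Cockerham (1984) theta (F_ST) with a permutation test, the
codominant genotype distance of Smouse & Peakall with Gower-centered
principal coordinates, and frequency-based population assignment with
Monte-Carlo exclusion probabilities (GeneClass-style).

Genotypes are unordered pairs of integer allele sizes; 0 codes a missing
allele (the Genepop convention). Missing genotypes are excluded
locus-wise: pairwise for distances, listwise per locus for allele
frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenotypeTable", "MsatFstResult", "AssignmentResult", "read_genepop",
    "wc_fst_permutation", "codominant_distance_matrix",
    "codominant_distance_pcoa", "frequency_assignment", "write_genepop",
]

MISSING = 0


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes; alleles shape (n, n_loci, 2)."""

    ids: list
    pop_labels: list
    loci: list
    alleles: np.ndarray
    missing_code: int = MISSING

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L, two = self.alleles.shape
        assert two == 2
        if len(self.ids) != n or len(self.pop_labels) != n:
            raise ValueError("ids/pop_labels length mismatch")
        if len(self.loci) != L:
            raise ValueError("loci names length mismatch")
        # store allele pairs in sorted (unordered) form
        self.alleles = np.sort(self.alleles, axis=2)

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def genotyped(self, locus: int) -> np.ndarray:
        """Boolean mask of individuals fully genotyped at a locus."""
        return (self.alleles[:, locus, :] != self.missing_code).all(axis=1)


@dataclass
class MsatFstResult:
    theta: float
    per_locus: np.ndarray
    p_value: float
    n_perm: int


@dataclass
class AssignmentResult:
    ids: list
    populations: list
    log_likelihood: np.ndarray  # n x n_pops (log10)
    assigned: list
    exclusion_p: np.ndarray     # n x n_pops
    alpha: float


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeTable:
    """Read a Genepop file with 2- or 3-digit allele codes.

    Populations are named pop1, pop2, ... in order of the Pop blocks;
    allele code 0 (00/000) means missing.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty genepop file")
    lines = lines[1:]  # title
    loci = []
    i = 0
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [x.strip() for x in lines[i].split(",") if x.strip()]
        loci.extend(chunk)
        i += 1
    ids, pops, rows = [], [], []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        name, _, geno = line.partition(",")
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(f"individual {name.strip()!r}: "
                             f"{len(codes)} genotypes for {len(loci)} loci")
        width = len(codes[0]) // 2
        row = [(int(c[:width]), int(c[width:])) for c in codes]
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    if not rows:
        raise ValueError("no individuals found")
    return GenotypeTable(ids, pops, loci, np.asarray(rows))


def write_genepop(gt: GenotypeTable, path, title="crypticdiv export",
                  digits: int = 3):
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in gt.loci:
            fh.write(loc + "\n")
        pops = list(dict.fromkeys(gt.pop_labels))
        for pop in pops:
            fh.write("Pop\n")
            for i in range(gt.n):
                if gt.pop_labels[i] != pop:
                    continue
                codes = " ".join(
                    f"{a:0{digits}d}{b:0{digits}d}"
                    for a, b in gt.alleles[i])
                fh.write(f"{gt.ids[i]} , {codes}\n")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(gt: GenotypeTable, labels: np.ndarray):
    """Summed variance components (a, b, c) per locus over alleles."""
    pops = np.unique(labels)
    r = len(pops)
    per_locus = np.full(gt.n_loci, np.nan)
    A = B = C = 0.0
    for loc in range(gt.n_loci):
        ok = gt.genotyped(loc)
        sizes = np.array([float((ok & (labels == p)).sum()) for p in pops])
        if (sizes < 1).any() or sizes.sum() < 2:
            continue
        als = gt.alleles[:, loc, :]
        alleles = np.unique(als[ok])
        alleles = alleles[alleles != gt.missing_code]
        if len(alleles) < 2:
            continue
        nbar = sizes.mean()
        nc = (sizes.sum() - (sizes ** 2).sum() / sizes.sum()) / (r - 1)
        la = lb = lc = 0.0
        for allele in alleles:
            p_i = np.empty(r)
            h_i = np.empty(r)
            for j, p in enumerate(pops):
                sel = ok & (labels == p)
                pair = als[sel]
                p_i[j] = (pair == allele).sum() / (2.0 * sizes[j])
                h_i[j] = ((pair == allele).sum(axis=1) == 1).mean()
            pbar = (sizes * p_i).sum() / sizes.sum()
            s2 = (sizes * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (sizes * h_i).sum() / sizes.sum()
            if nbar <= 1:
                continue
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1) / r * s2
                                     - hbar / 4.0) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                       - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2.0
            la, lb, lc = la + a, lb + b, lc + c
        if la + lb + lc != 0:
            per_locus[loc] = la / (la + lb + lc)
        A, B, C = A + la, B + lb, C + lc
    return A, B, C, per_locus


def wc_fst_permutation(gt: GenotypeTable, n_perm: int = 1000,
                       seed: int | None = None) -> MsatFstResult:
    """Multi-locus Weir-Cockerham theta with a permutation test.

    theta = sum(a) / sum(a + b + c) over alleles and loci; the null
    permutes individuals among populations.
    """
    labels = np.asarray(gt.pop_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two populations")
    A, B, C, per_locus = _wc_components(gt, labels)
    if A + B + C == 0:
        raise ValueError("monomorphic table: theta undefined")
    theta = A / (A + B + C)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        Ap, Bp, Cp, _ = _wc_components(gt, perm)
        tp = Ap / (Ap + Bp + Cp) if (Ap + Bp + Cp) != 0 else 0.0
        if tp >= theta:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MsatFstResult(float(theta), per_locus, p, n_perm)


# ---------------------------------------------------------------------------
# Codominant genotype distance + PCoA
# ---------------------------------------------------------------------------

def _geno_sqdist(g1, g2, missing) -> float | None:
    """Single-locus squared codominant distance (Smouse & Peakall 1999).

    AA-AA / AB-AB: 0; AA-AB: 1; AB-AC: 1; AB-CD: 2; AA-BC: 3; AA-BB: 4.
    """
    if missing in g1 or missing in g2:
        return None
    a, b = g1
    c, d = g2
    het1, het2 = a != b, c != d
    shared = len(set(g1) & set(g2))
    if set(g1) == set(g2) and het1 == het2:
        return 0.0
    if het1 and het2:
        return 1.0 if shared else 2.0
    if het1 != het2:
        return 1.0 if shared else 3.0
    return 4.0  # two different homozygotes


def codominant_distance_matrix(gt: GenotypeTable) -> np.ndarray:
    """Pairwise squared codominant distances summed over loci.

    Pairs missing at a locus skip it; the sum is rescaled to the full
    locus count. Individuals missing at all loci are excluded upstream.
    """
    n, L = gt.n, gt.n_loci
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        tot, used = 0.0, 0
        for loc in range(L):
            d = _geno_sqdist(gt.alleles[i, loc], gt.alleles[j, loc],
                             gt.missing_code)
            if d is not None:
                tot += d
                used += 1
        if used == 0:
            raise ValueError(
                f"individuals {gt.ids[i]}, {gt.ids[j]} share no typed loci")
        D[i, j] = D[j, i] = tot * L / used
    return D


def codominant_distance_pcoa(gt: GenotypeTable):
    """PCoA of the codominant distance matrix.

    Returns scores on all positive axes and percent variance per axis
    (over the positive eigenvalues). Individuals untyped at every locus
    are dropped with a warning.
    """
    import warnings
    if gt.n < 3:
        raise ValueError("need at least 3 individuals")
    typed = np.array([(gt.alleles[i] != gt.missing_code).any() for i in range(gt.n)])
    if not typed.all():
        dropped = [gt.ids[i] for i in np.flatnonzero(~typed)]
        warnings.warn(f"dropping individuals with no typed loci: {dropped}")
        keep = np.flatnonzero(typed)
        gt = GenotypeTable([gt.ids[i] for i in keep],
                           [gt.pop_labels[i] for i in keep], gt.loci,
                           gt.alleles[keep], gt.missing_code)
    D2 = codominant_distance_matrix(gt)
    n = gt.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos = lam > 1e-10 * max(abs(lam).max(), 1.0)
    lam, vec = lam[pos], vec[:, pos]
    scores = vec * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    return {"ids": list(gt.ids), "pop_labels": list(gt.pop_labels),
            "scores": scores, "percent_variance": pct}


# ---------------------------------------------------------------------------
# Frequency-based assignment
# ---------------------------------------------------------------------------

def _allele_freqs(gt: GenotypeTable, labels: np.ndarray, exclude: int | None = None):
    """Per-pop per-locus allele frequency dicts and sample sizes."""
    pops = list(dict.fromkeys(labels))
    freqs = {p: [] for p in pops}
    sizes = {p: [] for p in pops}
    for loc in range(gt.n_loci):
        ok = gt.genotyped(loc)
        for p in pops:
            sel = ok & (labels == p)
            if exclude is not None:
                sel = sel & (np.arange(gt.n) != exclude)
            pair = gt.alleles[sel, loc, :].ravel()
            n2 = len(pair)
            if n2 == 0:
                freqs[p].append(None)
                sizes[p].append(0)
                continue
            vals, counts = np.unique(pair, return_counts=True)
            freqs[p].append(dict(zip(vals.tolist(),
                                     (counts / n2).tolist())))
            sizes[p].append(n2 // 2)
    return pops, freqs, sizes


def _geno_loglik(geno, freq: dict, n_ref: int) -> float | None:
    """log10 Hardy-Weinberg genotype probability under reference freqs.

    Alleles unobserved in the reference get frequency 1/(2n+1).
    """
    if freq is None:
        return None
    a, b = geno
    sub = 1.0 / (2 * n_ref + 1)
    pa = freq.get(int(a), sub)
    pb = freq.get(int(b), sub)
    prob = pa * pb if a == b else 2 * pa * pb
    return float(np.log10(prob))


def frequency_assignment(gt: GenotypeTable, n_sim: int = 10000,
                         alpha: float = 0.05,
                         seed: int | None = None) -> AssignmentResult:
    """Frequency-method assignment with Monte-Carlo exclusion test.

    Each individual's multilocus genotype likelihood under each
    reference population's allele frequencies is computed with
    leave-one-out when the individual belongs to that reference;
    assignment is to the highest-likelihood population. The exclusion p
    for a population is the share of ``n_sim`` genotypes simulated from
    its (HW) frequencies whose likelihood is <= the individual's.
    """
    labels = np.asarray(gt.pop_labels)
    pops = list(dict.fromkeys(labels))
    counts = {p: int((labels == p).sum()) for p in pops}
    if min(counts.values()) < 5:
        raise ValueError("each reference population needs n >= 5")
    rng = np.random.default_rng(seed)
    n = gt.n
    ll = np.zeros((n, len(pops)))
    for i in range(n):
        for j, p in enumerate(pops):
            excl = i if labels[i] == p else None
            _, freqs, sizes = _allele_freqs(gt, labels, exclude=excl)
            tot = 0.0
            for loc in range(gt.n_loci):
                if gt.missing_code in gt.alleles[i, loc]:
                    continue
                v = _geno_loglik(gt.alleles[i, loc], freqs[p][loc],
                                 sizes[p][loc])
                if v is not None:
                    tot += v
            ll[i, j] = tot
    assigned = [pops[int(np.argmax(ll[i]))] for i in range(n)]

    # simulated likelihood distributions per reference population
    _, freqs, sizes = _allele_freqs(gt, labels)
    sim_ll = {}
    for j, p in enumerate(pops):
        sims = np.zeros(n_sim)
        for loc in range(gt.n_loci):
            f = freqs[p][loc]
            if f is None:
                continue
            alleles = np.array(list(f))
            probs = np.array([f[a] for a in alleles])
            probs = probs / probs.sum()
            g1 = rng.choice(alleles, size=n_sim, p=probs)
            g2 = rng.choice(alleles, size=n_sim, p=probs)
            pa = np.array([f[a] for a in g1])
            pb = np.array([f[a] for a in g2])
            prob = np.where(g1 == g2, pa * pb, 2 * pa * pb)
            sims += np.log10(prob)
        sim_ll[p] = np.sort(sims)
    excl_p = np.zeros((n, len(pops)))
    for i in range(n):
        for j, p in enumerate(pops):
            # fraction of simulated genotypes at least as unlikely
            k = np.searchsorted(sim_ll[p], ll[i, j], side="right")
            excl_p[i, j] = (k + 1) / (n_sim + 1)
    return AssignmentResult(list(gt.ids), pops, ll, assigned, excl_p, alpha)
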