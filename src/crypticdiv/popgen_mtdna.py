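"""Mitochondrial sequence statistics.

Diversity summaries, the Fu's Fs and Ramos-Onsins & Rozas R2 neutrality
tests with coalescent-simulation nulls, AMOVA-based Phi_ST with a
permutation test, Tamura-Nei (TN93) distances, and a median-joining
haplotype network with transversions weighted more heavily than
transitions (default 3x, as recommended for mitochondrial data).

Gap/ambiguity handling follows common DNAsp/Arlequin defaults: complete
deletion (sites with any gap/N dropped) for S, theta_W, singletons and
haplotype counts; pairwise-complete sites for the mean pairwise
differences pi and for distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import msprime
import networkx as nx
import numpy as np

__all__ = [
    "SeqAlignment", "SeqStats", "FstResult", "HaploNetwork",
    "read_fasta_alignment", "seq_stats", "fu_fs", "r2_test",
    "phi_st_permutation", "tamura_nei_matrix", "median_joining_network",
    "ewens_log_pk", "fs_from_ewens",
]

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class UndefinedStatisticError(ValueError):
    """Statistic undefined for this input (e.g., no segregating sites)."""


@dataclass
class SeqAlignment:
    """Equal-length aligned DNA sequences with population labels."""

    ids: list
    sequences: list
    pop_labels: list
    length: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        for sid, s in zip(self.ids, self.sequences):
            if len(s) != L:
                raise ValueError(f"sequence {sid} has length {len(s)} != {L}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence IDs")
        self.length = L
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    def subset(self, pop) -> "SeqAlignment":
        idx = [i for i, p in enumerate(self.pop_labels) if p == pop]
        return SeqAlignment([self.ids[i] for i in idx],
                            [self.sequences[i] for i in idx],
                            [pop] * len(idx))

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


def read_fasta_alignment(fasta_path, popmap=None) -> SeqAlignment:
    """Read a pre-aligned FASTA; popmap maps id -> population.

    ``popmap`` may be a dict or a two-column CSV path (id, population).
    """
    from Bio import SeqIO
    ids, seqs = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if isinstance(popmap, (str, bytes)) or hasattr(popmap, "read_text"):
        import csv
        mapping = {}
        with open(popmap, newline="") as fh:
            for row in csv.reader(fh):
                if len(row) >= 2 and row[0].lower() not in ("id", "specimen"):
                    mapping[row[0]] = row[1]
        popmap = mapping
    if popmap is None:
        pops = ["pop1"] * len(ids)
    else:
        pops = [popmap[i] for i in ids]
    return SeqAlignment(ids, seqs, pops)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SeqStats:
    n: int
    S: int
    pi: float
    theta_w: float
    singletons: np.ndarray  # U_i per sequence
    k_obs: int
    complete_sites: int = 0


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def seq_stats(aln: SeqAlignment) -> SeqStats:
    """Segregating sites, pi, Watterson's theta, singletons, haplotypes."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = aln.to_array()
    valid = np.isin(arr, list("ACGT"))
    complete = valid.all(axis=0)
    sub = arr[:, complete]
    seg = np.array([len(set(col)) > 1 for col in sub.T], dtype=bool)
    S = int(seg.sum())
    n = aln.n
    U = np.zeros(n, dtype=int)
    for col in sub[:, seg].T:
        states, counts = np.unique(col, return_counts=True)
        for st, ct in zip(states, counts):
            if ct == 1:
                U[np.flatnonzero(col == st)[0]] += 1
    # pi with pairwise-complete sites
    tot = 0.0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        tot += float((arr[i, both] != arr[j, both]).sum())
    pi = tot / (n * (n - 1) / 2)
    theta_w = S / _harmonic(n) if n > 1 else 0.0
    haps = {tuple(row) for row in sub}
    return SeqStats(n=n, S=S, pi=pi, theta_w=theta_w, singletons=U,
                    k_obs=len(haps), complete_sites=int(complete.sum()))


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def _log_stirling_row(n: int) -> np.ndarray:
    """log unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # s(0,0) = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # s(m,k) = (m-1)*s(m-1,k) + s(m-1,k-1)
        with np.errstate(divide="ignore"):
            a = row + np.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(a[1:], row[:-1])
        if m == 1:
            new[1] = 0.0
        row = new
    return row


def ewens_log_pk(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling_row(n)[1:]  # k = 1..n
    k = np.arange(1, n + 1)
    log_denom = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * np.log(theta) - log_denom


def fs_from_ewens(n: int, theta: float, k_obs: int) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta)."""
    logp = ewens_log_pk(n, theta)
    p = np.exp(logp)
    p = p / p.sum()  # guard against tiny normalisation drift
    sp = float(p[k_obs - 1:].sum())
    if sp >= 1.0 - 1e-12:
        return np.inf
    if sp <= 1e-300:
        return -np.inf
    return float(np.log(sp / (1.0 - sp)))


def _sim_neutral_sample(n: int, theta: float, rng) -> tuple:
    """One neutral coalescent sample; returns (k_hap, pi, S, singletons)."""
    anc_seed = int(rng.integers(1, 2 ** 31 - 1))
    mut_seed = int(rng.integers(1, 2 ** 31 - 1))
    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                              random_seed=anc_seed)
    mts = msprime.sim_mutations(ts, rate=theta / 2.0, discrete_genome=False,
                                random_seed=mut_seed)
    gm = mts.genotype_matrix()  # sites x samples
    if gm.shape[0] == 0:
        return 1, 0.0, 0, np.zeros(n, dtype=int)
    k = len({tuple(col) for col in gm.T})
    counts = gm.astype(bool).sum(axis=1)
    npairs = n * (n - 1) / 2
    pi = float((counts * (n - counts)).sum() / npairs)
    U = np.zeros(n, dtype=int)
    for row, d in zip(gm, counts):
        if d == 1:
            U[np.flatnonzero(row)[0]] += 1
        elif d == n - 1:
            U[np.flatnonzero(row == 0)[0]] += 1
    return k, pi, int(gm.shape[0]), U


def fu_fs(stats: SeqStats, n_sims: int = 1000, seed: int | None = None):
    """Fu's Fs and its one-tailed coalescent p-value.

    Fs is computed from the Ewens distribution with theta = pi; the null
    distribution comes from neutral constant-size coalescent samples
    simulated with the same theta, and p = Pr(Fs_sim <= Fs_obs) -- small
    p flags an excess of haplotypes (negative Fs), as expected after a
    demographic expansion.
    """
    if stats.S == 0 or stats.pi <= 0:
        raise UndefinedStatisticError("Fs undefined: no variation (S = 0)")
    fs_obs = fs_from_ewens(stats.n, stats.pi, stats.k_obs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sims):
        k_sim, pi_sim, _, _ = _sim_neutral_sample(stats.n, stats.pi, rng)
        if pi_sim <= 0 or k_sim == 1:
            fs_sim = np.inf
        else:
            fs_sim = fs_from_ewens(stats.n, pi_sim, k_sim)
        if fs_sim <= fs_obs:
            count += 1
    p = (count + 1) / (n_sims + 1)
    return fs_obs, p


# ---------------------------------------------------------------------------
# Ramos-Onsins & Rozas R2
# ---------------------------------------------------------------------------

def r2_statistic(n: int, S: int, pi: float, U: np.ndarray) -> float:
    return float(np.sqrt(np.mean((U - pi / 2.0) ** 2)) / S)


def _sim_fixed_s(n: int, S: int, rng) -> tuple:
    """Neutral genealogy with exactly S mutations placed by branch length."""
    seed = int(rng.integers(1, 2 ** 31 - 1))
    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                              random_seed=seed)
    tree = ts.first()
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lengths = np.array([tree.branch_length(u) for u in nodes])
    probs = lengths / lengths.sum()
    picks = rng.choice(len(nodes), size=S, p=probs)
    npairs = n * (n - 1) / 2
    pi = 0.0
    U = np.zeros(n, dtype=int)
    for ix in picks:
        node = nodes[ix]
        below = list(tree.samples(node))
        d = len(below)
        pi += d * (n - d) / npairs
        if d == 1:
            U[below[0]] += 1
        elif d == n - 1:
            others = set(range(n)) - set(below)
            U[others.pop()] += 1
    return pi, U


def r2_test(stats: SeqStats, n_sims: int = 1000, seed: int | None = None):
    """Ramos-Onsins & Rozas R2 and its coalescent p-value.

    R2 contrasts singleton counts with pi; the null conditions on the
    observed number of segregating sites S (mutations dropped on neutral
    genealogies in proportion to branch length). One-tailed toward small
    R2 (recent expansion).
    """
    if stats.S == 0:
        raise UndefinedStatisticError("R2 undefined: S = 0")
    r2_obs = r2_statistic(stats.n, stats.S, stats.pi, stats.singletons)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sims):
        pi_sim, U_sim = _sim_fixed_s(stats.n, stats.S, rng)
        if r2_statistic(stats.n, stats.S, pi_sim, U_sim) <= r2_obs:
            count += 1
    p = (count + 1) / (n_sims + 1)
    return r2_obs, p


# ---------------------------------------------------------------------------
# Phi_ST (AMOVA) with permutation
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    phi_st: float
    p_value: float
    n_perm: int
    undefined: bool = False


def pairwise_diff_matrix(aln: SeqAlignment) -> np.ndarray:
    """Pairwise nucleotide differences (pairwise-complete sites)."""
    arr = aln.to_array()
    valid = np.isin(arr, list("ACGT"))
    n = aln.n
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        d[i, j] = d[j, i] = float((arr[i, both] != arr[j, both]).sum())
    return d


def _phi_from_sqd(d2: np.ndarray, labels: np.ndarray):
    pops = np.unique(labels)
    N = len(labels)
    K = len(pops)
    ssd_total = d2[np.triu_indices(N, 1)].sum() / N
    ssd_within = 0.0
    sizes = []
    for p in pops:
        idx = np.flatnonzero(labels == p)
        sizes.append(len(idx))
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    df_a, df_w = K - 1, N - K
    sigma_w = ssd_within / df_w if df_w > 0 else 0.0
    sizes = np.asarray(sizes, dtype=float)
    n_c = (N - (sizes ** 2).sum() / N) / (K - 1)
    sigma_a = (ssd_among / df_a - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if abs(denom) < 1e-15:
        return 0.0, True
    return float(sigma_a / denom), False


def phi_st_permutation(aln: SeqAlignment, n_perm: int = 1000,
                       seed: int | None = None,
                       distance: str = "pairwise_diff") -> FstResult:
    """AMOVA Phi_ST between populations with a permutation test.

    Variance components follow the squared-distance AMOVA; with the
    default ``pairwise_diff`` the matrix of nucleotide differences plays
    the role of squared distances (the Arlequin convention); with
    ``tamura_nei`` TN93 distances are used the same way. The null
    permutes individuals among populations.
    """
    labels = np.asarray(aln.pop_labels)
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if counts.min() < 2:
        raise ValueError("each population needs n >= 2")
    if distance == "pairwise_diff":
        d2 = pairwise_diff_matrix(aln)
    elif distance == "tamura_nei":
        d2 = tamura_nei_matrix(aln)
        d2 = np.nan_to_num(d2, nan=np.nanmax(d2[np.isfinite(d2)]) if
                           np.isfinite(d2).any() else 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    phi_obs, undef = _phi_from_sqd(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        phi_p, _ = _phi_from_sqd(d2, perm)
        if phi_p >= phi_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return FstResult(phi_obs, p, n_perm, undefined=undef)


# ---------------------------------------------------------------------------
# Tamura-Nei (TN93) distances
# ---------------------------------------------------------------------------

def tamura_nei_matrix(aln: SeqAlignment) -> np.ndarray:
    """TN93 distances among individuals with alignment-wide base frequencies.

    Saturated pairs (a logarithm argument <= 0) get NaN.
    """
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    arr = aln.to_array()
    valid = np.isin(arr, list("ACGT"))
    flat = arr[valid]
    freqs = {b: (flat == b).mean() for b in "ACGT"}
    gA, gC, gG, gT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gR, gY = gA + gG, gC + gT
    n = aln.n
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        a, b = arr[i, both], arr[j, both]
        L = both.sum()
        if L == 0:
            D[i, j] = D[j, i] = np.nan
            continue
        diff = a != b
        pur = np.isin(a, ["A", "G"]) & np.isin(b, ["A", "G"])
        pyr = np.isin(a, ["C", "T"]) & np.isin(b, ["C", "T"])
        P1 = float((diff & pur).sum()) / L   # A<->G
        P2 = float((diff & pyr).sum()) / L   # C<->T
        Q = float((diff & ~pur & ~pyr).sum()) / L
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = 1 - P1 * gR / (2 * gA * gG) - Q / (2 * gR)
            t2 = 1 - P2 * gY / (2 * gC * gT) - Q / (2 * gY)
            t3 = 1 - Q / (2 * gR * gY)
            if t1 <= 0 or t2 <= 0 or t3 <= 0:
                D[i, j] = D[j, i] = np.nan
                continue
            d = (-(2 * gA * gG / gR) * np.log(t1)
                 - (2 * gC * gT / gY) * np.log(t2)
                 - 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
                 * np.log(t3))
        D[i, j] = D[j, i] = d if np.isfinite(d) else np.nan
    return D


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

@dataclass
class HaploNetwork:
    graph: nx.Graph
    haplotypes: dict            # node -> sequence string
    multiplicity: dict          # node -> {pop: count} ({} for medians)
    epsilon: int = 0
    tv_weight: int = 3

    @property
    def median_nodes(self):
        return [u for u, m in self.multiplicity.items() if not m]

    def total_cost(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def write_edgelist_csv(self, path):
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node1", "node2", "weight", "n_changes"])
            for u, v, d in self.graph.edges(data=True):
                w.writerow([u, v, d["weight"], d["n_changes"]])

    def write_gml(self, path):
        g = self.graph.copy()
        for u in g.nodes:
            g.nodes[u]["is_median"] = not self.multiplicity[u]
            for pop, c in self.multiplicity[u].items():
                g.nodes[u][f"n_{pop}"] = c
        nx.write_gml(g, str(path))


def _site_cost(x: str, y: str, tv_weight: int) -> float:
    if x == y:
        return 0.0
    if x not in _NUC or y not in _NUC:
        return 0.0  # skip gaps/ambiguities
    if (x in _PURINES) == (y in _PURINES):
        return 1.0  # transition (within purines or within pyrimidines)
    return float(tv_weight)


def _weighted_dist(a: str, b: str, tv_weight: int):
    w = 0.0
    nmut = 0
    for x, y in zip(a, b):
        c = _site_cost(x, y, tv_weight)
        if c > 0:
            w += c
            nmut += 1
    return w, nmut


def _msn_edges(nodes, seqs, tv_weight, epsilon):
    """Epsilon-relaxed minimum spanning network over the node set."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    dist = {}
    full = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        w, nm = _weighted_dist(seqs[u], seqs[v], tv_weight)
        dist[(u, v)] = (w, nm)
        full.add_edge(u, v, weight=w)
    if len(nodes) < 2:
        return g
    mst = nx.minimum_spanning_tree(full, weight="weight")
    for u, v in itertools.combinations(nodes, 2):
        # connection cost = minimax path weight, read off the MST
        path = nx.shortest_path(mst, u, v)
        dconn = max(full[a][b]["weight"]
                    for a, b in zip(path, path[1:]))
        w, nm = dist[(u, v)]
        if w <= dconn + epsilon:
            g.add_edge(u, v, weight=w, n_changes=nm)
    return g


def _median_seq(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)  # majority where it exists, else first sequence
    return "".join(out)


def median_joining_network(aln: SeqAlignment, epsilon: int = 0,
                           tv_weight: int = 3,
                           max_rounds: int = 10) -> HaploNetwork:
    """Median-joining haplotype network (Bandelt et al. 1999 scheme).

    Identical sequences are collapsed into haplotypes with per-population
    multiplicities. Each round builds the epsilon-relaxed minimum
    spanning network under weighted Hamming distance (transitions 1,
    transversions ``tv_weight``), proposes majority-consensus median
    (Steiner) vectors for triples that are mutually linked in the
    network, keeps those that shorten the triple's connection, and
    prunes medians that end up unused; rounds repeat until stable.
    """
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    seqs: dict = {}
    mult: dict = {}
    order = []
    for sid, s, pop in zip(aln.ids, aln.sequences, aln.pop_labels):
        node = None
        for h, hs in seqs.items():
            if hs == s:
                node = h
                break
        if node is None:
            node = f"H{len(seqs) + 1}"
            seqs[node] = s
            mult[node] = {}
            order.append(node)
        mult[node][pop] = mult[node].get(pop, 0) + 1

    n_medians = 0
    for _ in range(max_rounds):
        nodes = list(seqs)
        g = _msn_edges(nodes, seqs, tv_weight, epsilon)
        new = []
        for u, v, w in itertools.combinations(nodes, 3):
            links = sum(g.has_edge(a, b)
                        for a, b in ((u, v), (u, w), (v, w)))
            if links < 2:
                continue
            for first, o1, o2 in ((u, v, w), (v, u, w), (w, u, v)):
                m = _median_seq(seqs[first], seqs[o1], seqs[o2])
                if m in seqs.values() or m in (x[1] for x in new):
                    continue
                dm = sum(_weighted_dist(m, seqs[x], tv_weight)[0]
                         for x in (u, v, w))
                duv = _weighted_dist(seqs[u], seqs[v], tv_weight)[0]
                duw = _weighted_dist(seqs[u], seqs[w], tv_weight)[0]
                dvw = _weighted_dist(seqs[v], seqs[w], tv_weight)[0]
                steiner_free = duv + duw + dvw - max(duv, duw, dvw)
                if dm < steiner_free:
                    new.append(((u, v, w), m))
        if not new:
            break
        for _, m in new:
            n_medians += 1
            node = f"mv{n_medians}"
            seqs[node] = m
            mult[node] = {}
        # prune medians that are leaves (or isolated) in the new network
        while True:
            nodes = list(seqs)
            g = _msn_edges(nodes, seqs, tv_weight, epsilon)
            drop = [u for u in nodes
                    if not mult[u] and g.degree(u) <= 1]
            if not drop:
                break
            for u in drop:
                del seqs[u], mult[u]
    nodes = list(seqs)
    g = _msn_edges(nodes, seqs, tv_weight, epsilon)
    return HaploNetwork(graph=g, haplotypes=dict(seqs),
                        multiplicity=dict(mult), epsilon=epsilon,
                        tv_weight=tv_weight)
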