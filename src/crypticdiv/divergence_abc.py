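"""Hierarchical ABC test of simultaneous divergence across taxon pairs.

Two co-distributed taxon pairs span the same source -> crater-lake
colonization. The hyperparameter Psi counts the distinct divergence
times among the pairs: Psi = 1 means a single shared colonization time,
Psi = 2 two independent times. Rejection ABC on per-pair coalescent
summary statistics yields the posterior over Psi and the dispersion of
the accepted divergence times.

The per-pair model is an isolation-with-migration coalescent (two
populations of scaled sizes theta_1, theta_2 exchanging migrants at rate
m until they merge at time tau, in coalescent units) with infinite-sites
mutation, simulated with msprime. Mutation rates are scaled so that the
expected within-population mean pairwise difference equals theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .popgen_mtdna import SeqAlignment

__all__ = [
    "ABCModel", "ABCResult", "coalescent_sim_pair", "summary_stats_pair",
    "simulate_reference_table", "abc_from_table", "abc_psi",
]

SUMMARY_NAMES = ("pi_1", "pi_2", "theta_w_1", "theta_w_2",
                 "pi_between", "pi_net")


@dataclass
class ABCModel:
    """Priors and design of the two-pair hierarchical model.

    theta_j ~ U(0, theta_max) independently per population; tau ~
    U(0, tau_max); migration m ~ U(0, m_max) per pair (m_max = 0 turns
    migration off); Psi in {1, 2} with equal prior probability. Sample
    sizes are (n_source, n_derived) per pair; L is the sequence length
    in bp.
    """

    n_pairs: int = 2
    theta_max: float = 20.0
    tau_max: float = 5.0
    m_max: float = 0.0
    L: int = 711
    sample_sizes: tuple = ((20, 20), (20, 20))
    psi_values: tuple = (1, 2)

    def __post_init__(self):
        if self.n_pairs != 2:
            raise ValueError("this design supports exactly two taxon pairs")
        if min(self.theta_max, self.tau_max) <= 0 or self.m_max < 0:
            raise ValueError("prior bounds must be positive (m_max >= 0)")


@dataclass
class ABCResult:
    posterior_psi: dict          # psi -> probability
    accepted_tau: np.ndarray     # n_accept x 2
    omega: np.ndarray            # dispersion Var(tau)/E(tau) per accepted draw
    n_sims: int
    tolerance: float
    accepted_idx: np.ndarray = field(default=None, repr=False)


def _pair_demography(theta1: float, theta2: float, tau: float, m: float):
    """Standard coalescent scaling: time in units of the pair's reference
    population; theta enters through the mutation rate, so population
    sizes are O(1) ratios theta_j / theta_bar and tau is genuinely in
    coalescent units regardless of theta."""
    theta_bar = max((theta1 + theta2) / 2.0, 1e-9)
    dem = msprime.Demography()
    dem.add_population(name="source",
                       initial_size=max(theta1 / theta_bar, 1e-6))
    dem.add_population(name="derived",
                       initial_size=max(theta2 / theta_bar, 1e-6))
    dem.add_population(name="anc", initial_size=1.0)
    if m > 0:
        dem.set_symmetric_migration_rate(["source", "derived"], m)
    dem.add_population_split(time=max(tau, 1e-9),
                             derived=["source", "derived"], ancestral="anc")
    return dem


def coalescent_sim_pair(theta1: float, theta2: float, tau: float, m: float,
                        n1: int, n2: int, L: int,
                        seed: int | None = None,
                        as_alignment: bool = True):
    """Simulate one taxon pair under isolation-with-migration.

    Uses the standard coalescent scaling: time is measured in units of
    the pair's reference population (size theta_bar = (theta_1 +
    theta_2)/2 on the mutation scale), population sizes are the ratios
    theta_j / theta_bar, and the per-sequence mutation rate is
    theta_bar / 2 — so the expected pairwise difference within
    population j is theta_j and tau is in coalescent units. Returns a
    SeqAlignment (populations ``source`` and ``derived``) or, with
    ``as_alignment=False``, the 0/1 site matrix used by the summary
    statistics.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per population")
    if seed is None:
        anc_seed = mut_seed = None
    else:
        # independent streams for genealogy and mutations
        ss = np.random.SeedSequence(int(seed)).spawn(2)
        anc_seed = int(ss[0].generate_state(1)[0] % (2 ** 31 - 2)) + 1
        mut_seed = int(ss[1].generate_state(1)[0] % (2 ** 31 - 2)) + 1
    dem = _pair_demography(theta1, theta2, tau, m)
    ts = msprime.sim_ancestry(samples={"source": n1, "derived": n2},
                              demography=dem, ploidy=1,
                              sequence_length=L, random_seed=anc_seed)
    theta_bar = (theta1 + theta2) / 2.0
    rate = (theta_bar / 2.0) / L if theta_bar > 0 else 0.0
    mts = msprime.sim_mutations(ts, rate=rate, discrete_genome=False,
                                random_seed=mut_seed)
    gm = mts.genotype_matrix()  # sites x samples, 0 = ancestral
    gm = (gm > 0).astype(np.int8)
    positions = [s.position for s in mts.sites()]
    pops = ["source"] * n1 + ["derived"] * n2
    if not as_alignment:
        return gm, np.array(pops)
    # place variants on distinct integer columns of a random background
    # with a control-region-like composition and transition-biased changes
    cols = []
    used = set()
    for pos in positions:
        c = int(pos)
        while c in used or c >= L:
            c = (c + 1) % L
        used.add(c)
        cols.append(c)
    base_rng = np.random.default_rng(
        np.random.SeedSequence([mut_seed or 0, 12345]))
    background = base_rng.choice(list("ACGT"), size=L,
                                 p=[0.33, 0.22, 0.13, 0.32])
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    seqs = np.tile(background, (n1 + n2, 1))
    for row, c in zip(gm, cols):
        anc = background[c]
        if base_rng.random() < 0.85:
            der = transition[anc]
        else:
            der = base_rng.choice(list(transversions[anc]))
        seqs[row.astype(bool), c] = der
    ids = [f"pair_{p}_{i}" for i, p in enumerate(pops)]
    return SeqAlignment(ids, ["".join(s) for s in seqs], pops)


def _stats_from_matrix(gm: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """(pi_1, pi_2, theta_w_1, theta_w_2, pi_between, pi_net) from 0/1 sites."""
    i1 = pops == "source"
    i2 = pops == "derived"
    n1, n2 = int(i1.sum()), int(i2.sum())

    def within(mask, n):
        if gm.shape[0] == 0:
            return 0.0, 0.0
        counts = gm[:, mask].sum(axis=1)
        npairs = n * (n - 1) / 2
        pi = float((counts * (n - counts)).sum() / npairs)
        seg = int(((counts > 0) & (counts < n)).sum())
        a1 = np.sum(1.0 / np.arange(1, n))
        return pi, seg / a1

    pi1, tw1 = within(i1, n1)
    pi2, tw2 = within(i2, n2)
    if gm.shape[0] == 0:
        pib = 0.0
    else:
        c1 = gm[:, i1].sum(axis=1)
        c2 = gm[:, i2].sum(axis=1)
        pib = float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum() / (n1 * n2))
    return np.array([pi1, pi2, tw1, tw2, pib, pib - (pi1 + pi2) / 2.0])


def summary_stats_pair(aln_or_matrix, pops=None) -> np.ndarray:
    """msBayes-style summary vector for one taxon pair.

    Accepts a SeqAlignment with two populations or a (site-matrix, pops)
    pair from :func:`coalescent_sim_pair`.
    """
    if isinstance(aln_or_matrix, SeqAlignment):
        aln = aln_or_matrix
        pops_arr = np.asarray(aln.pop_labels)
        uniq = list(dict.fromkeys(pops_arr))
        if len(uniq) != 2:
            raise ValueError("need exactly two populations")
        arr = aln.to_array()
        valid = np.isin(arr, list("ACGT")).all(axis=0)
        sub = arr[:, valid]
        seg = np.array([len(set(c)) > 1 for c in sub.T], dtype=bool)
        segsub = sub[:, seg]
        # binarise each segregating site against its first-row state
        gm = (segsub != segsub[0]).astype(np.int8).T
        relabel = np.where(pops_arr == uniq[0], "source", "derived")
        return _stats_from_matrix(gm, relabel)
    gm = np.asarray(aln_or_matrix)
    return _stats_from_matrix(gm, np.asarray(pops))


def _draw_params(model: ABCModel, psi: int, rng):
    taus = np.empty(2)
    if psi == 1:
        taus[:] = rng.uniform(0, model.tau_max)
    else:
        taus[:] = rng.uniform(0, model.tau_max, size=2)
    thetas = rng.uniform(0, model.theta_max, size=(2, 2))
    ms = (rng.uniform(0, model.m_max, size=2) if model.m_max > 0
          else np.zeros(2))
    return taus, thetas, ms


def simulate_reference_table(model: ABCModel, n_sims: int,
                             seed: int | None = None):
    """Prior-predictive reference table for rejection ABC.

    Psi is stratified (half the draws per value) so the accept-all limit
    reproduces the uniform hyperprior exactly. Returns a dict with the
    drawn psi, tau matrix, and the (n_sims x 12) summary matrix (both
    pairs concatenated).
    """
    rng = np.random.default_rng(seed)
    psis = np.repeat(model.psi_values, n_sims // len(model.psi_values))
    if len(psis) < n_sims:
        psis = np.concatenate([psis, model.psi_values[:n_sims - len(psis)]])
    psis = np.array(psis)
    rng.shuffle(psis)
    taus = np.empty((n_sims, 2))
    stats = np.empty((n_sims, 12))
    for s in range(n_sims):
        tau, theta, m = _draw_params(model, psis[s], rng)
        taus[s] = tau
        row = []
        for pair in range(2):
            n1, n2 = model.sample_sizes[pair]
            gm, pops = coalescent_sim_pair(
                theta[pair, 0], theta[pair, 1], tau[pair], m[pair],
                n1, n2, model.L,
                seed=int(rng.integers(1, 2 ** 31 - 1)),
                as_alignment=False)
            row.append(_stats_from_matrix(gm, pops))
        stats[s] = np.concatenate(row)
    return {"psi": psis, "tau": taus, "stats": stats, "model": model}


def divergence_features(stats: np.ndarray) -> np.ndarray:
    """Hyperparameter-targeted features from the raw summary vector(s).

    Per pair: a pooled theta estimate (mean of the two pi and two
    Watterson values) and the scaled divergence-time estimate
    tau_hat = pi_net / theta_hat; plus the across-pair contrast
    |tau_hat_1 - tau_hat_2|, the moment that separates one shared
    divergence time from two independent ones. The theta floor guards
    the ratio for (near-)monomorphic pairs.
    """
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    thetas, taus = [], []
    for base in (0, 6):
        th = 0.25 * (stats[:, base] + stats[:, base + 1]
                     + stats[:, base + 2] + stats[:, base + 3])
        taus.append(stats[:, base + 5] / np.maximum(th, 0.5))
        thetas.append(th)
    t1, t2 = taus
    return np.column_stack([thetas[0], thetas[1], t1, t2, np.abs(t1 - t2)])


def abc_from_table(observed: np.ndarray, table: dict,
                   tolerance_frac: float) -> ABCResult:
    """Rejection step: accept the closest tolerance_frac of the table.

    The raw 12-long summary vectors are mapped to the divergence-scaled
    features of :func:`divergence_features`, standardized by the
    across-simulation median absolute deviation (zero-MAD dimensions are
    dropped), and compared by Euclidean distance.
    """
    if not 0 < tolerance_frac <= 1:
        raise ValueError("tolerance_frac must be in (0, 1]")
    raw = table["stats"]
    obs_raw = np.asarray(observed, dtype=float).ravel()
    if obs_raw.shape[0] != raw.shape[1]:
        raise ValueError("observed summary length mismatch")
    stats = divergence_features(raw)
    obs = divergence_features(obs_raw)[0]
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    keep = mad > 0
    if not keep.any():
        raise ValueError("all summary statistics are degenerate")
    z = (stats[:, keep] - med[keep]) / mad[keep]
    zo = (obs[keep] - med[keep]) / mad[keep]
    dist = np.sqrt(((z - zo) ** 2).sum(axis=1))
    n_accept = max(int(round(tolerance_frac * raw.shape[0])), 1)
    idx = np.argsort(dist, kind="stable")[:n_accept]
    psi_acc = table["psi"][idx]
    post = {int(v): float((psi_acc == v).mean())
            for v in table["model"].psi_values}
    tau_acc = table["tau"][idx]
    mean_tau = tau_acc.mean(axis=1)
    var_tau = tau_acc.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(mean_tau > 0, var_tau / mean_tau, 0.0)
    return ABCResult(posterior_psi=post, accepted_tau=tau_acc, omega=omega,
                     n_sims=stats.shape[0], tolerance=tolerance_frac,
                     accepted_idx=idx)


def abc_psi(observed, model: ABCModel, n_sims: int = 10000,
            tolerance_frac: float = 0.01, seed: int | None = None,
            table: dict | None = None) -> ABCResult:
    """Full hierarchical ABC run for the divergence-time hyperparameter.

    ``observed`` is the concatenated 12-long summary vector of the two
    taxon pairs (see :func:`summary_stats_pair`). A precomputed
    reference table may be passed to amortize simulation cost across
    several observed datasets drawn against the same priors.
    """
    if table is None:
        table = simulate_reference_table(model, n_sims, seed=seed)
    return abc_from_table(observed, table, tolerance_frac)
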