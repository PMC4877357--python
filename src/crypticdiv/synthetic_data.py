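"""Synthetic landmark, sequence, and microsatellite data with known truth.

Emulates the study design the pipeline targets: two lake populations
(source "Managua", crater "Xiloa") measured for body shape, pharyngeal
jaw shape, a mitochondrial control-region alignment, and a 12-locus
microsatellite panel. Defaults mirror that design: sample sizes 17/44
(body), 22/30 (jaw), 22/40 (mtDNA), 25/32 (microsatellites), a 974-bp
sequence scaled to roughly 50 segregating sites at n = 62, and 12 loci
at a target F_ST of 0.07.

Landmark specimens are built as mean shape + group shift + allometric
component x centroid size + correlated within-group noise, then pushed
back to "digitised" pixel coordinates by random similarity transforms.
An optional latent cluster map shared across datasets lets concordance
tests contrast linked structure (ARI -> 1) against independent structure
(ARI -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divergence_abc import coalescent_sim_pair
from .morpho_geometry import LandmarkDataset
from .popgen_msat import GenotypeTable
from .popgen_mtdna import SeqAlignment

__all__ = ["SynthSpec", "gen_landmarks", "gen_sequences", "gen_microsats",
           "write_fasta", "DEFAULT_GROUPS"]

DEFAULT_GROUPS = ("Managua", "Xiloa")


@dataclass
class SynthSpec:
    """Parameters of the synthetic study; defaults follow the emulated design."""

    seed: int = 0
    groups: tuple = DEFAULT_GROUPS
    # landmarks
    n_per_group: tuple = (17, 44)
    n_points: int = 9
    shift_magnitude: float = 0.0       # Procrustes units between group means
    allometry_slope: float = 0.0       # shape change per unit centroid size
    noise_sd: float = 0.01             # Procrustes units
    spectrum_decay: float = 0.7        # geometric decay of noise eigenvalues
    symmetric: bool = False
    n_missing: int = 0                 # side points deleted (imputation path)
    # sequences
    seq_n: tuple = (22, 40)
    seq_L: int = 974
    theta: float = 10.6                # E[S] ~ 50 at n = 62 (Watterson)
    tau: float = 1.0
    migration: float = 0.0
    # microsatellites
    msat_n: tuple = (25, 32)
    n_loci: int = 12
    n_alleles: int = 8
    target_fst: float = 0.07
    # latent clusters (shared across datasets when set)
    cluster_labels: dict = field(default_factory=dict)  # id -> int


def _rng(spec: SynthSpec, salt: int):
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def _mean_shape(k: int, symmetric: bool):
    """A fish-ish template: points on an ellipse (symmetric about y-axis)."""
    if symmetric:
        n_side = (k - 1) // 2
        t = np.linspace(0.3, np.pi - 0.3, n_side)
        left = np.column_stack([-np.abs(np.cos(t)) - 0.2, np.sin(t) - 0.3])
        right = left * np.array([-1.0, 1.0])
        mid = np.array([[0.0, 0.8]] + [[0.0, -0.6]] * (k - 2 * n_side - 1))
        pts = np.vstack([mid, left, right])
        pairing = [(len(mid) + i, len(mid) + n_side + i) for i in range(n_side)]
        midline = list(range(len(mid)))
        return pts, pairing, midline
    t = np.linspace(0, 2 * np.pi, k, endpoint=False)
    pts = np.column_stack([1.5 * np.cos(t), np.sin(t)])
    return pts, [], []


def gen_landmarks(spec: SynthSpec) -> LandmarkDataset:
    """Two-group landmark data with known shift, allometry, and noise."""
    rng = _rng(spec, 1)
    k = spec.n_points
    mean, pairing, midline = _mean_shape(k, spec.symmetric)
    mean = mean - mean.mean(0)
    mean = mean / np.linalg.norm(mean)
    p = 2 * k
    # group shift along a fixed normalized direction in shape space
    shift_dir = rng.standard_normal(p)
    shift_dir -= shift_dir @ mean.ravel() * mean.ravel()
    shift_dir /= np.linalg.norm(shift_dir)
    allo_dir = rng.standard_normal(p)
    allo_dir -= allo_dir @ mean.ravel() * mean.ravel()
    allo_dir /= np.linalg.norm(allo_dir)
    # correlated noise spectrum (geometric decay)
    lam = spec.spectrum_decay ** np.arange(p)
    basis = np.linalg.qr(rng.standard_normal((p, p)))[0]
    noise_cov_root = basis * np.sqrt(lam / lam.sum() * p)

    ids, coords, groups = [], [], []
    cluster_of = spec.cluster_labels
    for g, (gname, n) in enumerate(zip(spec.groups, spec.n_per_group)):
        for i in range(n):
            sid = f"{gname}_{i + 1}"
            cs = rng.uniform(80.0, 160.0)  # "pixels"
            shape = mean.ravel().copy()
            shape += (g - 0.5) * spec.shift_magnitude * shift_dir
            shape += spec.allometry_slope * (cs - 120.0) * allo_dir
            if sid in cluster_of:
                cl_rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 77, cluster_of[sid]]))
                cl_dir = cl_rng.standard_normal(p)
                cl_dir /= np.linalg.norm(cl_dir)
                shape += 6.0 * spec.noise_sd * cl_dir
            shape += spec.noise_sd * (noise_cov_root @ rng.standard_normal(p))
            cfg = shape.reshape(k, 2)
            if spec.symmetric:
                # symmetrise the mean structure but keep small asymmetry
                refl = cfg.copy()
                refl[:, 0] = -refl[:, 0]
                perm = np.arange(k)
                for l, r in pairing:
                    perm[l], perm[r] = r, l
                cfg = 0.5 * (cfg + refl[perm]) \
                    + 0.25 * (cfg - refl[perm])
            # back to "digitised" raw coordinates
            ang = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])
            cfg = cfg @ R.T * cs + rng.uniform(200, 800, size=2)
            ids.append(sid)
            coords.append(cfg)
            groups.append(gname)
    coords = np.stack(coords)
    missing = np.zeros((len(ids), k), dtype=bool)
    if spec.n_missing > 0:
        if not pairing:
            raise ValueError("missing points require a symmetric template")
        sides = [l for l, _ in pairing]
        for s in rng.choice(len(ids), size=spec.n_missing, replace=False):
            pt = int(rng.choice(sides))
            coords[s, pt] = np.nan
            missing[s, pt] = True
    roles = ["landmark"] * k
    return LandmarkDataset(specimen_ids=ids, coords=coords,
                           point_roles=roles, pairing=pairing,
                           midline=midline, missing_mask=missing,
                           group_labels=groups)


def gen_sequences(spec: SynthSpec, fasta_path=None) -> SeqAlignment:
    """Two-population coalescent control-region alignment.

    Wraps the isolation-with-migration simulator; the two simulated
    populations are renamed to the study's lakes. Optionally writes a
    FASTA file.
    """
    n1, n2 = spec.seq_n
    rng = _rng(spec, 2)
    aln = coalescent_sim_pair(spec.theta, spec.theta, spec.tau,
                              spec.migration, n1, n2, spec.seq_L,
                              seed=int(rng.integers(1, 2 ** 31 - 1)))
    name = {"source": spec.groups[0], "derived": spec.groups[1]}
    pops = [name[p] for p in aln.pop_labels]
    ids = [f"{p}_{i + 1}" for i, p in enumerate(pops)]
    out = SeqAlignment(ids, aln.sequences, pops)
    if fasta_path is not None:
        write_fasta(out, fasta_path)
    return out


def write_fasta(aln: SeqAlignment, path):
    with open(path, "w") as fh:
        for sid, s in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")


def gen_microsats(spec: SynthSpec) -> GenotypeTable:
    """Balding-Nichols microsatellite genotypes at a target F_ST.

    Ancestral allele frequencies are symmetric-Dirichlet; each
    population's frequencies are Dirichlet with concentration
    p_anc * (1 - F) / F, giving E[F_ST] = target_fst; diploid genotypes
    are drawn by binomial (HW) sampling. With ``cluster_labels`` set,
    latent clusters (instead of lakes) act as the Balding-Nichols
    subpopulations.
    """
    if not 0 <= spec.target_fst < 0.5:
        raise ValueError("target F_ST must be in [0, 0.5)")
    rng = _rng(spec, 3)
    ids, pops = [], []
    for gname, n in zip(spec.groups, spec.msat_n):
        ids += [f"{gname}_{i + 1}" for i in range(n)]
        pops += [gname] * n
    if spec.cluster_labels:
        units = [spec.cluster_labels[i] for i in ids]
    else:
        units = pops
    uniq = list(dict.fromkeys(units))
    n_ind = len(ids)
    alleles = np.zeros((n_ind, spec.n_loci, 2), dtype=int)
    F = spec.target_fst
    for loc in range(spec.n_loci):
        p_anc = rng.dirichlet(np.ones(spec.n_alleles))
        for u in uniq:
            if F > 0:
                p_u = rng.dirichlet(p_anc * (1 - F) / F)
            else:
                p_u = p_anc
            sel = [i for i, x in enumerate(units) if x == u]
            draws = rng.choice(spec.n_alleles, size=(len(sel), 2), p=p_u)
            alleles[sel, loc, :] = draws + 101  # allele sizes 101..
    loci = [f"loc{j + 1}" for j in range(spec.n_loci)]
    return GenotypeTable(ids, pops, loci, alleles)
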