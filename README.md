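# crypticdiv

Integrated geometric-morphometric and population-genetic testing for
**cryptic divergence** — the situation where a nominal species may hide
unrecognized sympatric or allopatric differentiation. The package was
built around a classic study design from Nicaraguan crater-lake cichlids
(a source-lake population and a crater-lake population scored for body
shape, lower-pharyngeal-jaw shape, mitochondrial control-region
sequences, and 12 microsatellite loci), but every component is generic.

The reasoning the toolkit operationalizes: adaptive divergence should
leave *concordant* signals — morphological clusters that coincide with
genetic clusters — whereas drift and noise produce partitions that agree
no better than chance. The pipeline therefore runs, per dataset:

* **Shape**: generalized Procrustes analysis with bending-energy sliding
  of semilandmarks, reflection-based repair of missing bilateral points,
  the symmetric component for object-symmetric structures, allometry
  correction by regression on centroid size; then a Procrustes-distance
  permutation test for mean differences, leave-one-out cross-validated
  discrimination, between-group PCA, the scaled variance of eigenvalues
  (integration, SVE = Var(λ)/T²), three rarefied disparity estimators
  with a bootstrap tail test, and Escoufier's RV (covariation) with
  permutation and rarefaction tests.
* **mtDNA**: S, π, Watterson's θ, Fu's *F*s (exact Ewens computation,
  coalescent null), Ramos-Onsins & Rozas *R*², AMOVA Φ_ST with
  permutation, Tamura–Nei distances, and a median-joining haplotype
  network with transversions weighted 3×.
* **Microsatellites**: Weir–Cockerham θ (F_ST) with permutation,
  codominant genotype distances with PCoA, and frequency-based
  population assignment with Monte-Carlo exclusion probabilities.
* **Clustering & concordance**: broken-stick-limited PCA/PCoA followed by
  BIC-selected Gaussian mixtures (Ward-initialized EM) on any dataset;
  adjusted Rand index between partitions with a permutation test.
* **Timing of colonization**: a hierarchical ABC test of whether two
  co-distributed taxon pairs crossed the same barrier simultaneously
  (hyperparameter Ψ ∈ {1, 2} counting distinct divergence times), with
  an isolation-with-migration coalescent simulator.

A synthetic-data module generates landmark, sequence, and genotype
datasets with known ground truth (group shifts, allometry, divergence
time, target F_ST, linked latent clusters) so the whole pipeline is
exercisable and testable without any downloads.

## Worked example

Simulate a study-shaped bundle and run the pieces from Python:

```python
import numpy as np
from crypticdiv import (SynthSpec, gen_landmarks, gen_sequences,
                        gen_microsats, gpa_with_sliding, allometry_correct,
                        procrustes_distance_test, wc_fst_permutation,
                        phi_st_permutation, seq_stats, fu_fs)

spec = SynthSpec(seed=1)              # defaults mirror the study design
ds   = gen_landmarks(spec)            # 17 + 44 specimens, 9 points
shapes = allometry_correct(gpa_with_sliding(ds))
res = procrustes_distance_test(shapes, np.asarray(ds.group_labels),
                               n_perm=999, seed=1)
print(f"Procrustes distance {res.proc_distance:.4f}  P = {res.p_value:.3f}")

aln = gen_sequences(spec)             # two-population coalescent, 974 bp
print("Phi_ST =", round(phi_st_permutation(aln, seed=1).phi_st, 3))

gt = gen_microsats(spec)              # 12 loci, Balding-Nichols F_ST 0.07
print("WC theta =", round(wc_fst_permutation(gt, seed=1).theta, 3))
```

Output (seed 1):

```
Procrustes distance 0.0089  P = 0.569
Phi_ST = 0.45
WC theta = 0.077
```

The landmark generator used no group shift, so the mean-shape test is
non-significant (a between-mean distance of 0.009 Procrustes units is
pure sampling noise at these sample sizes). The sequence generator's
default divergence time (τ = 1 coalescent unit) produces a clear
mitochondrial Φ_ST — single-locus Φ_ST is highly variable around its
expectation — and the Weir–Cockerham estimate recovers the generator's
target F_ST of 0.07 up to single-panel noise.

The same workflow is available from a shell:

```bash
crypticdiv simulate --seed 1 --out bundle/
crypticdiv gpa bundle/landmarks.tps --out aligned.csv
crypticdiv msat bundle/msat.gen --n-perm 999
crypticdiv run config.yaml --out results/
```

`crypticdiv run` executes the full dependency-ordered pipeline
(geometry → shape statistics and clustering; sequences → mtDNA
statistics and clustering; genotypes → microsatellite statistics and
clustering; partitions → concordance; optional ABC) and writes a JSON
results tree plus CSV tables (disparity per trait and lake, the
pairwise concordance matrix, one partition CSV per dataset).

See `docs/methods.md` for the models, conventions, numerical choices,
and known limitations.

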