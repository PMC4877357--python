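# Methods

`crypticdiv` tests whether a nominal species shows cryptic divergence —
between populations (allopatric) or within them (sympatric) — by running
the same battery of analyses on four kinds of data from the same
specimens: body shape, a second morphological trait (here the lower
pharyngeal jaw), a mitochondrial sequence alignment, and a multi-locus
microsatellite panel. The logic is concordance: real adaptive divergence
should produce clusters that agree across morphology and genetics, while
drift or noise produces partitions that agree no better than chance.

## Geometric morphometrics

**Superimposition.** Configurations of 2-D points are aligned by
generalized Procrustes analysis: center, scale to unit centroid size
(CS = sqrt of summed squared distances to the centroid), rotate to the
evolving consensus, iterate until the RMS change of the consensus falls
below `tol` (default 1e-8, max 100 iterations; non-convergence returns
the last iterate with a flag). Rotations are proper (no reflections).
After convergence, configurations are orthogonally projected onto the
tangent space at the consensus, so Euclidean geometry on the flattened
coordinates approximates Procrustes geometry.

**Sliding semilandmarks.** Points on curves without one-to-one anatomical
correspondence slide along their local tangent (the chord through their
curve neighbours) to minimise the thin-plate-spline bending energy
against the consensus; the minimisation is a small linear solve per
specimen per iteration, and a unit test checks it against a brute-force
grid search. The alternative Procrustes-distance sliding criterion is
deliberately not implemented; bending energy is the default of the
standard relative-warps tools. "Helper" points participate in the
alignment as fixed anchors (they are not slid, an explicit choice where
practice varies) and are removed from the shape variables afterwards.

**Missing points.** Specimens with a damaged side of a bilaterally
symmetric structure are repaired by reflecting the intact partner across
the specimen's symmetry axis, fit as the principal axis of its midline
points plus the midpoints of its complete pairs. Both members of a pair
missing is unrecoverable and raises an error.

**Symmetric component.** For object-symmetric structures each
configuration is paired with its reflected-and-relabeled copy, all
copies enter one joint GPA, and the symmetric component is the average
of the two aligned copies of each specimen. The operation is idempotent
(property-tested).

**Allometry.** Shape variables are regressed on centroid size in a
single pooled multivariate regression (pooling rather than within-group
regression is the simplest reading of regressing shape on size when the
groups are not assumed to differ); residuals, with the mean shape added
back, feed all downstream analyses. Size may be the structure's own CS
or an external vector (e.g., body CS for jaw shape, supporting the
design in which jaw allometry is controlled by body size); a log-size
option exists but the default is untransformed CS. Residuals are exactly
orthogonal to centered size (tested to 1e-8).

## Shape statistics and their nulls

All permutation p-values are computed as (count + 1)/(n_perm + 1) and
can never be exactly zero. Defaults are 1000 permutations / 1000
bootstraps.

* **Mean difference**: Euclidean (= tangent-space Procrustes) distance
  between two group mean shapes; labels permuted.
* **Discrimination**: leave-one-out cross-validated LDA; when the pooled
  covariance is singular (nearly always for shape data) the discriminant
  is trained on the leading PCs explaining 95% of variance.
* **Ordination**: between-group PCA (eigenvectors of the covariance of
  group means, all specimens projected); with two groups exactly one
  axis, parallel to the mean difference — chosen over canonical variates
  because it does not exaggerate separation.
* **Integration**: scaled variance of eigenvalues, SVE =
  Var(lambda)/T^2 with the population (1/p) variance convention over the
  full spectrum and T the total variance, bootstrapped over specimens.
  Closed-form anchor: rank-1 variation in p dimensions with T = 1 gives
  (p-1)/p^2.
* **Disparity**: multivariate variance (trace of the covariance), mean
  pairwise distance, and mean distance from the group centroid, each
  rarefied to the smallest group by with-replacement bootstrap
  (mean +/- sd over replicates). Group differences are tested with a
  symmetric bootstrap tail comparison: each group's point estimate is
  located in the other group's bootstrap distribution, the doubled
  smaller tail is taken, and the two directions are averaged (the tail
  procedure of the morphometric-disparity tools is unpublished; this is
  its documented behaviour).
* **Covariation**: Escoufier's RV between two blocks;
  independence tested by permuting the specimen correspondence; rarefied
  RV uses without-replacement subsamples (with-replacement resampling
  biases RV upward); the two-group difference in rarefied RV is tested
  by permuting group labels.

## Cluster detection and concordance

Any dataset is reduced to the ordination axes that pass the broken-stick
rule — covariance PCA for coordinate data (standard, not robust PCA, a
deliberate choice), Gower-centered PCoA for distance matrices (negative
eigenvalues dropped; proportions over the positive part). Axes are kept
while the relative eigenvalue exceeds b_k = (1/p) sum_{i=k..p} 1/i,
stopping at the first failure; if even the first axis fails, axis 1 is
retained so clustering has a dimension to work with.

Gaussian mixtures are fitted for K = 1..9 across four covariance
structures (spherical, diagonal, shared full, free full), each EM run
initialized deterministically from the K-cluster Ward cut, and the
(structure, K) pair with the lowest BIC wins; candidates within 2 BIC
units of the optimum (differences "barely worth mentioning" on the
conventional evidence scale) count as ties and resolve toward the
smallest K, so near-tie draws do not split real clusters.
A fifth family (shared spherical variance) is not available in the
mixture backend and is omitted; the four families span the same
sphere-to-ellipsoid range.

Partition agreement uses the adjusted Rand index on the specimens shared
by the two datasets, with significance from permuting one partition's
labels. ARI anchors: identical partitions give 1, the crossed pairs
(1,1,2,2) vs (1,2,1,2) give -0.5, an all-singleton partition gives 0.

## Mitochondrial statistics

Sites with gaps or ambiguity codes are dropped alignment-wide (complete
deletion) for S, Watterson's theta, singleton counts and haplotype
counts; pi and distances use pairwise-complete sites.

**Fu's Fs** is computed exactly from the Ewens sampling distribution:
S' = P(K >= k_obs | theta = pi) with unsigned Stirling numbers of the
first kind evaluated by recurrence in log space, and Fs = ln(S'/(1-S')).
Significance comes from neutral constant-size coalescent samples
simulated at theta = pi (p = share of simulated Fs <= observed).
Calibration note: under neutrality the realised size at the nominal 0.05
cut is about 9%, while the classical 0.02 threshold gives ~5% — the
long-known behaviour of this p-value, which is why raw p-values are
reported and the test suite checks calibration at 0.02.

**R2** (Ramos-Onsins & Rozas) contrasts singleton counts with pi/2,
normalised by S; its null conditions on the observed S by dropping
exactly S mutations on simulated neutral genealogies in proportion to
branch length. Both tests are one-tailed toward expansion.

**Phi_ST** comes from AMOVA variance components computed on the matrix
of pairwise differences treated as squared distances (the convention of
the standard AMOVA software; TN93 distances are an option), with
individuals permuted among populations for the null. A fully
monomorphic comparison reports 0 with an `undefined` flag.

**TN93 distances** use alignment-wide empirical base frequencies and the
two transition classes plus transversions; saturated pairs (log argument
<= 0) are flagged NaN rather than truncated.

**Median-joining network**: haplotypes are collapsed with per-population
multiplicities; each round builds the epsilon-relaxed minimum spanning
network under weighted Hamming distance (transitions 1, transversions 3
by default), proposes majority-consensus median vectors for triples
mutually linked in the network, keeps those that shorten the triple's
connection, and prunes unused medians until stable. With epsilon = 0 and
chain-like data the network equals the minimum spanning tree
(property-tested); a triangle of pairwise-2-step haplotypes recovers the
unobserved central haplotype as its single median. Star contraction is
display post-processing and is intentionally not implemented.

## Microsatellite statistics

**F_ST** is the Weir–Cockerham (1984) theta: variance components a, b, c
summed over alleles and loci, theta = sum(a)/sum(a+b+c), permutation
null over individuals. Mean recovery from Balding–Nichols simulations at
F in {0.02, 0.07, 0.15} is within +/-0.01 (acceptance-tested).

**Codominant distances** follow the squared single-locus scheme
(identical 0; one shared allele 1; two heterozygotes sharing none 2;
homozygote vs non-matching heterozygote 3; two different homozygotes 4),
summed over comparable loci and rescaled to the panel size, then
Gower-centered PCoA.

**Assignment** uses the frequency method: leave-one-out Hardy–Weinberg
likelihood of each genotype under each reference population's allele
frequencies, unobserved alleles substituted at 1/(2n+1); exclusion
p-values locate the individual's likelihood in the distribution of
genotypes simulated from the reference frequencies (default 10,000).

## Hierarchical ABC for the timing of colonization

Two taxon pairs span the same source-to-crater-lake colonization. The
hyperparameter Psi in {1, 2} counts distinct divergence times (Psi = 1:
simultaneous colonization), with a uniform hyperprior sampled in
stratified halves so the accept-everything limit reproduces the prior
exactly. Per pair, theta per population ~ U(0, 20), tau ~ U(0, 5) in
coalescent units, migration ~ U(0, m_max) with m_max in {0, 0.5}.

The simulator is a two-population isolation-with-migration coalescent
under the standard scaling: time in units of the pair's reference
population, population sizes the ratios theta_j/theta_bar, and the
per-sequence mutation rate theta_bar/2, with infinite-sites mutations
(a deliberate simplification of the finite-sites machinery of the full
pipelines; acceptance here is property-based self-consistency, not the
reproduction of published posterior curves). Expected within-population
diversity equals theta_j (simulation-tested to 3 SE).

Rejection ABC compares divergence-scaled features rather than the raw
summary vector: per pair a pooled theta-hat (mean of both pi and both
Watterson estimates) and tau-hat = pi_net/theta-hat, plus the contrast
|tau-hat_1 − tau-hat_2| — the moment that separates one shared
divergence time from two. Features are standardized by across-simulation
median absolute deviations and the closest tolerance fraction (default
1%) of draws is accepted; the posterior of Psi is the acceptance
proportion and Omega = Var(tau)/E(tau) over each accepted draw's pair of
taus summarizes divergence-time dispersion. No regression adjustment is
applied.

**Identifiability.** With a single locus the ancestral coalescent
contributes irreducible Exp(1)-scale noise to tau-hat, so equal-time
data yield posteriors near 0.55–0.6 rather than near 1 under these
priors; the self-consistency experiments (P(correct Psi) > 0.5 in >= 80%
of replicates) sit close to this single-locus ceiling. The discordant
design uses tau_1 ~ U(0.2, 0.5) with tau_2 = 10 tau_1, keeping the older
divergence in the resolvable 2–5 range: a ten-fold contrast between two
near-zero times is not resolvable at one locus. Raising m_max to 0.5
blurs the signal of isolation and degrades discrimination, which the
suite asserts directionally.

## Synthetic data

The generators emulate the study design: two lake populations with the
study's sample sizes per dataset (body 17/44, jaw 22/30, mtDNA 22/40,
microsatellites 25/32), a ~974-bp control-region-scale alignment whose
default theta (10.6) is set by the Watterson expectation E[S] ~ 50 at
n = 62, and 12 microsatellite loci at a target F_ST of 0.07 via the
Balding–Nichols model (population frequencies Dirichlet-distributed
around ancestral frequencies with concentration (1-F)/F). Landmark
specimens are mean shape + group shift + allometric component x CS +
correlated noise with a geometrically decaying spectrum, pushed back to
pixel-like coordinates by random similarity transforms; options add
bilateral symmetry, deleted side points (to exercise imputation), and a
latent cluster map shared across datasets so concordance has a positive
control. Everything is reproducible bit-for-bit from the generator seed.

What the generators do not emulate: digitization error structure,
mutation-rate heterogeneity along the sequence, microsatellite stepwise
mutation and null alleles, and selection. Passing tests therefore
demonstrate statistical correctness of the machinery under idealized
conditions, not robustness to those real-data features.

## Problem sizes in the validation suite

Calibration experiments use 600–800 null replicates of 99-permutation
tests; Weir–Cockerham recovery uses 200 replicates per F_ST level; the
ABC experiments use a 20,000-draw reference table with 50 pseudo-observed
replicates per scenario (4,000 draws and 30 replicates for the migration
contrast). These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances while keeping the whole suite desk-scale.

## Known limitations

* 2-D landmarks only; no outline (curve) records.
* The GMM family set omits a shared-spherical structure.
* Single-locus ABC cannot approach certainty about Psi; multiple loci
  would be needed for sharp posteriors.
* Phi_ST treats the supplied distance as the squared AMOVA distance;
  saturated TN93 pairs are imputed with the matrix maximum in the
  pipeline path.
* The haplotype-network median search enumerates triples linked in the
  current network, which is adequate for control-region-scale data but
  not optimized for thousands of haplotypes.
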