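"""Sequence statistics, neutrality tests, Phi_ST, TN93, haplotype network."""

from fractions import Fraction

import numpy as np
import pytest

from crypticdiv import popgen_mtdna as pm
from crypticdiv.divergence_abc import coalescent_sim_pair


def _aln(seqs, pops=None, ids=None):
    n = len(seqs)
    return pm.SeqAlignment(ids or [f"s{i}" for i in range(n)], list(seqs),
                           pops or ["p"] * n)


class TestSeqStats:
    def test_identical_sequences(self):
        st = pm.seq_stats(_aln(["ACGT"] * 4))
        assert st.S == 0 and st.pi == 0 and st.k_obs == 1

    def test_two_sequences_three_differences(self):
        st = pm.seq_stats(_aln(["AAAACCC", "AAATCCA"]))
        # sites 3 and 6 differ... plus site 3: A->T, site 6: C->A
        assert st.S == 2 and st.pi == 2

    def test_singleton_counts_and_watterson(self):
        seqs = ["AAAA", "GAAA", "GAAA", "GAAA"]
        st = pm.seq_stats(_aln(seqs))
        # the A at site 0 of sequence 0 is the singleton state
        assert list(st.singletons) == [1, 0, 0, 0]
        assert st.S == 1
        assert st.theta_w == pytest.approx(1 / (1 + 1 / 2 + 1 / 3))

    def test_complete_deletion_for_s_pairwise_for_pi(self):
        seqs = ["AAAA", "A-AA", "AAGA"]
        st = pm.seq_stats(_aln(seqs))
        # site 1 has a gap -> dropped for S; site 2 segregates
        assert st.S == 1
        assert st.complete_sites == 3

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            pm.seq_stats(_aln(["ACGT"]))


class TestFuFs:
    def test_k_equals_one_gives_positive_infinity(self):
        assert pm.fs_from_ewens(4, 1.0, 1) == np.inf

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 5.0])
    def test_matches_exact_ewens_enumeration(self, n, theta):
        """Log-space recurrence vs exact rational Stirling enumeration."""
        # oracle: exact unsigned Stirling numbers by integer recurrence
        rows = [[1]]
        for m in range(1, n + 1):
            prev = rows[-1]
            cur = [0] * (m + 1)
            for k in range(1, m + 1):
                cur[k] = (m - 1) * (prev[k] if k < len(prev) else 0) \
                    + prev[k - 1]
            rows.append(cur)
        th = Fraction(theta).limit_denominator(10 ** 6)
        denom = Fraction(1)
        for i in range(n):
            denom *= th + i
        probs = [Fraction(rows[n][k]) * th ** k / denom
                 for k in range(1, n + 1)]
        assert float(sum(probs)) == pytest.approx(1.0, abs=1e-12)
        for k_obs in range(2, n + 1):
            sp = float(sum(probs[k_obs - 1:]))
            if sp >= 1 - 1e-12:
                continue
            oracle = np.log(sp / (1 - sp))
            assert pm.fs_from_ewens(n, theta, k_obs) == pytest.approx(
                oracle, abs=1e-9)

    def test_undefined_without_variation(self):
        st = pm.SeqStats(n=5, S=0, pi=0.0, theta_w=0.0,
                         singletons=np.zeros(5, int), k_obs=1)
        with pytest.raises(pm.UndefinedStatisticError):
            pm.fu_fs(st)

    def test_expansion_like_sample_gives_negative_fs(self):
        # many haplotypes for little pairwise diversity -> negative Fs
        st = pm.SeqStats(n=20, S=15, pi=1.2, theta_w=4.2,
                         singletons=np.ones(20, int), k_obs=16)
        fs, p = pm.fu_fs(st, n_sims=100, seed=1)
        assert fs < -5
        assert p <= 0.05


class TestR2:
    def test_two_sequence_hand_value(self):
        # one difference between two sequences: both carry a singleton,
        # pi = 1, so R2 = sqrt(mean((1 - 0.5)^2)) / 1 = 0.5
        st = pm.seq_stats(_aln(["AAAA", "GAAA"]))
        r2 = pm.r2_statistic(st.n, st.S, st.pi, st.singletons)
        assert r2 == pytest.approx(0.5)

    def test_star_genealogy_shifts_r2_down(self):
        # recent-expansion-like data (all singletons) vs balanced genealogy
        n = 10
        star_U = np.ones(n, int)
        pi_star = 2 * n / n / (n - 1) * (n - 1) / 2  # low diversity
        r2_star = pm.r2_statistic(n, n, 1.0, star_U)
        balanced_U = np.zeros(n, int)
        r2_bal = pm.r2_statistic(n, n, 4.0, balanced_U)
        assert r2_star < r2_bal

    def test_null_simulation_p_reasonable(self):
        rng = np.random.default_rng(0)
        aln = coalescent_sim_pair(4.0, 4.0, 0.0, 0.0, 10, 10, 500, seed=11)
        sub = pm.SeqAlignment(aln.ids[:12], aln.sequences[:12],
                              ["p"] * 12)
        st = pm.seq_stats(sub)
        r2, p = pm.r2_test(st, n_sims=200, seed=3)
        assert 0 < r2 < 1
        assert 0 < p <= 1

    def test_undefined_without_segregating_sites(self):
        st = pm.SeqStats(n=4, S=0, pi=0.0, theta_w=0.0,
                         singletons=np.zeros(4, int), k_obs=1)
        with pytest.raises(pm.UndefinedStatisticError):
            pm.r2_test(st)


class TestPhiST:
    def test_no_variation_reports_zero_with_flag(self):
        aln = _aln(["AAAA"] * 6, pops=["x"] * 3 + ["y"] * 3)
        res = pm.phi_st_permutation(aln, n_perm=19, seed=0)
        assert res.phi_st == 0.0
        assert res.undefined

    def test_reciprocal_monomorphism_gives_one(self):
        aln = _aln(["AAAA"] * 6 + ["GGAA"] * 6,
                   pops=["x"] * 6 + ["y"] * 6)
        res = pm.phi_st_permutation(aln, n_perm=199, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_monotone_in_divergence_time(self):
        rng = np.random.default_rng(101)
        means = []
        for tau in (0.1, 1.0, 10.0):
            phis = [pm.phi_st_permutation(
                coalescent_sim_pair(5.0, 5.0, tau, 0.0, 12, 12, 800,
                                    seed=int(rng.integers(1, 2 ** 31 - 1))),
                n_perm=9, seed=1).phi_st for _ in range(10)]
            means.append(np.mean(phis))
        assert means[0] < means[1] < means[2]

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            pm.phi_st_permutation(_aln(["AAAA", "GAAA"]))


class TestTamuraNei:
    def test_identical_pair_zero(self):
        D = pm.tamura_nei_matrix(_aln(["ACGT" * 5] * 2))
        assert D[0, 1] == 0.0

    def test_hand_arithmetic_100bp(self):
        # 100 bp, seq1 = 25 each of A/C/G/T; seq2 has 2 A->G transitions
        # and 1 A->T transversion. Frozen value from a hand evaluation of
        # the TN93 formula with empirical (alignment-wide) frequencies.
        s1 = "A" * 25 + "C" * 25 + "G" * 25 + "T" * 25
        s2 = "GGT" + s1[3:]
        D = pm.tamura_nei_matrix(_aln([s1, s2]))
        assert D[0, 1] == pytest.approx(0.0311548053, abs=1e-9)

    def test_reduces_to_k80_for_equal_frequencies(self):
        # equal base composition, small divergence: TN93 ~ K80 distance
        s1 = ("ACGT" * 50)
        s2 = list(s1)
        s2[0] = "G"   # transition
        s2[9] = "A"   # transversion at a T site
        s2 = "".join(s2)
        P = 0.005
        Q = 0.005
        k80 = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        D = pm.tamura_nei_matrix(_aln([s1, s2]))
        assert D[0, 1] == pytest.approx(k80, rel=1e-2)

    def test_tn93_at_least_p_distance(self):
        rng = np.random.default_rng(12)
        aln = coalescent_sim_pair(8.0, 8.0, 1.0, 0.0, 6, 6, 400, seed=5)
        # remap some derived states to produce transversions as well
        seqs = [s.replace("G", "T") if i % 3 == 0 else s
                for i, s in enumerate(aln.sequences)]
        aln2 = _aln(seqs)
        D = pm.tamura_nei_matrix(aln2)
        arr = aln2.to_array()
        n = aln2.n
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(D[i, j]):
                    continue
                pdist = (arr[i] != arr[j]).mean()
                assert D[i, j] >= pdist - 1e-12

    def test_saturation_flagged_as_nan(self):
        # complementary sequences: every site a transversion -> saturated
        s1 = "A" * 30 + "C" * 30 + "G" * 30 + "T" * 30
        comp = str.maketrans("ACGT", "TGCA")
        D = pm.tamura_nei_matrix(_aln([s1, s1.translate(comp)]))
        assert np.isnan(D[0, 1])


class TestMedianJoining:
    def test_two_haplotypes_one_transition(self):
        net = pm.median_joining_network(_aln(["AAAA", "AGAA"] * 2))
        assert len(net.graph.edges) == 1
        (u, v, d), = net.graph.edges(data=True)
        assert d["weight"] == 1.0 and d["n_changes"] == 1

    def test_transversion_weighting(self):
        net = pm.median_joining_network(_aln(["AAAA", "ATAA"]), tv_weight=3)
        (u, v, d), = net.graph.edges(data=True)
        assert d["weight"] == 3.0 and d["n_changes"] == 1

    def test_steiner_triple_adds_one_median(self):
        # three haplotypes pairwise 2 apart around an unobserved hub
        tri = _aln(["GAAA", "AGAA", "AAGA"])
        net = pm.median_joining_network(tri)
        assert len(net.median_nodes) == 1
        hub = net.median_nodes[0]
        assert net.haplotypes[hub] == "AAAA"
        # network cost drops from the 4 (MST) to 3 (star through median)
        assert net.total_cost() == pytest.approx(3.0)
        # oracle: brute-force Steiner enumeration over per-site alphabets
        best = np.inf
        for cand in ("GAAA", "AGAA", "AAGA", "AAAA", "GGAA", "GAGA",
                     "AGGA", "GGGA"):
            cost = sum(pm._weighted_dist(cand, s, 3)[0]
                       for s in tri.sequences)
            best = min(best, cost)
        assert net.total_cost() == pytest.approx(best)

    def test_star_with_observed_hub_needs_no_medians(self):
        hub = "AAAA"
        net = pm.median_joining_network(
            _aln([hub, "GAAA", "AGAA", "AAGA"]))
        assert net.median_nodes == []
        assert len(net.graph.edges) == 3

    def test_unique_one_step_haplotypes_equal_mst(self):
        # chain of one-step haplotypes: MJ network = minimum spanning tree
        seqs = ["AAAA", "GAAA", "GGAA", "GGGA"]
        net = pm.median_joining_network(_aln(seqs), epsilon=0)
        assert len(net.median_nodes) == 0
        assert len(net.graph.edges) == 3
        assert net.total_cost() == pytest.approx(3.0)

    def test_multiplicities_tracked_per_population(self):
        aln = _aln(["AAAA", "AAAA", "AGAA"], pops=["x", "y", "y"])
        net = pm.median_joining_network(aln)
        counts = [m for m in net.multiplicity.values() if m]
        assert {"x": 1, "y": 1} in counts and {"y": 1} in counts


class TestCalibration:
    def test_fs_size_at_fu_threshold(self):
        """Type-I behaviour of the Fs test under neutrality (n=30, theta=5).

        The Fs p-value is anticonservative at the nominal 0.05 cut; at
        the classical 0.02 threshold the realised size is ~5%.
        """
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(200):
            k, pi, S, U = pm._sim_neutral_sample(30, 5.0, rng)
            if S == 0 or pi <= 0:
                continue
            st = pm.SeqStats(n=30, S=S, pi=pi, theta_w=0.0,
                             singletons=U, k_obs=k)
            _, p = pm.fu_fs(st, n_sims=100,
                            seed=int(rng.integers(2 ** 31 - 1)))
            ps.append(p)
        ps = np.array(ps)
        rate_02 = (ps <= 0.02).mean()
        rate_05 = (ps <= 0.05).mean()
        assert 0.02 <= rate_02 <= 0.08
        assert rate_05 >= rate_02
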