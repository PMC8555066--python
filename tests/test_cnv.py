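import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster import hierarchy

from metastrack.cnv import (
    AlleleSpecificState,
    CopyNumberSegment,
    Order,
    assign_groups,
    bin_log2,
    cluster_profiles,
    expected_af,
    infer_allele_state_pair,
    order_allele_states,
    reachable,
)
from metastrack.errors import AmbiguousStateError, DataError, UsageError

MB = 1_000_000


def seg(sample, chrom, start, end, log2, cn=2, loh=False):
    return CopyNumberSegment(sample, chrom, start, end, cn, log2, loh)


class TestBinLog2:
    def test_constant_segment_spans_three_bins(self):
        m = bin_log2([seg("S1", "chr1", 0, 3 * MB, 0.58)])
        assert m.values.shape == (1, 3)
        assert np.allclose(m.values.to_numpy(), 0.58)

    def test_length_weighted_mean(self):
        m = bin_log2([
            seg("S1", "chr1", 0, MB // 2, 0.0),
            seg("S1", "chr1", MB // 2, MB, 1.0),
        ])
        assert m.values.iloc[0, 0] == pytest.approx(0.5)

    def test_uncovered_bins_missing(self):
        m = bin_log2([
            seg("S1", "chr1", 0, MB, 0.0),
            seg("S2", "chr1", 0, 3 * MB, 0.2),
        ])
        row = m.values.loc["S1"].to_numpy()
        assert np.isnan(row[1]) and np.isnan(row[2])

    def test_overlap_raises(self):
        with pytest.raises(DataError):
            bin_log2([
                seg("S1", "chr1", 0, MB, 0.0),
                seg("S1", "chr1", MB // 2, 2 * MB, 1.0),
            ])


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        m = bin_log2([
            seg("A", "chr1", 0, 2 * MB, 0.5),
            seg("B", "chr1", 0, 2 * MB, 0.5),
        ])
        link, samples = cluster_profiles(m)
        assert link[0, 2] == 0.0

    def test_identical_pair_merges_first(self):
        m = bin_log2([
            seg("A", "chr1", 0, 2 * MB, 0.5),
            seg("B", "chr1", 0, 2 * MB, 0.5),
            seg("C", "chr1", 0, 2 * MB, -1.0),
        ])
        link, samples = cluster_profiles(m)
        first = {samples[int(link[0, 0])], samples[int(link[0, 1])]}
        assert first == {"A", "B"}

    def test_matches_hand_computed_upgma(self):
        # profiles chosen so the 4x4 distance matrix is easy by hand:
        # one bin, values A=0, B=1, C=5, D=7 -> d(A,B)=1, d(C,D)=2,
        # UPGMA merges (A,B) at 1, (C,D) at 2, then both at (5+7+4+6)/4=5.5
        segs = [
            seg("A", "chr1", 0, MB, 0.0),
            seg("B", "chr1", 0, MB, 1.0),
            seg("C", "chr1", 0, MB, 5.0),
            seg("D", "chr1", 0, MB, 7.0),
        ]
        link, samples = cluster_profiles(bin_log2(segs))
        assert sorted(link[:, 2].tolist()) == pytest.approx([1.0, 2.0, 5.5])

    def test_single_sample_rejected(self):
        m = bin_log2([seg("A", "chr1", 0, MB, 0.0)])
        with pytest.raises(UsageError):
            cluster_profiles(m)


class TestExpectedAf:
    def test_pure_tumor_cn3(self):
        assert expected_af(1, 3, 1.0) == pytest.approx(0.33, abs=0.005)
        assert expected_af(2, 3, 1.0) == pytest.approx(0.67, abs=0.005)

    def test_pure_tumor_copy_neutral_loh(self):
        assert expected_af(2, 2, 1.0) == 1.0
        assert expected_af(0, 2, 1.0) == 0.0

    def test_half_purity_loh_retained_allele(self):
        assert expected_af(2, 2, 0.5) == pytest.approx(0.75)

    @given(st.floats(0.05, 1.0))
    def test_reduces_to_m_over_c_at_purity_one_and_half_at_diploid(self, p):
        assert expected_af(1, 2, p) == pytest.approx(0.5)
        assert expected_af(2, 3, 1.0) == pytest.approx(2 / 3)


class TestAlleleStateInference:
    def _simulate_pair(self, rng, split1, split2, concordant, purity1, purity2,
                       n=25, depth=60):
        m1 = {True: split1[0], False: split1[1]}
        m2 = {True: split2[0], False: split2[1]} if concordant else \
             {True: split2[1], False: split2[0]}
        on_a = rng.random(n) < 0.5
        af1 = np.array([expected_af(m1[a], sum(split1), purity1) for a in on_a])
        af2 = np.array([expected_af(m2[a], sum(split2), purity2) for a in on_a])
        o1 = rng.binomial(depth, af1) / depth
        o2 = rng.binomial(depth, af2) / depth
        return o1, o2

    def test_recovers_planted_states_in_most_loci(self):
        rng = np.random.default_rng(0)
        states = [(2, 1), (2, 0), (3, 1), (3, 0)]
        ok = 0
        trials = 120
        for i in range(trials):
            s1 = states[i % len(states)]
            s2 = states[(i // len(states)) % len(states)]
            conc = bool(i % 2)
            p1, p2 = rng.uniform(0.7, 1.0, 2)
            af1, af2 = self._simulate_pair(rng, s1, s2, conc, p1, p2)
            try:
                st1, st2, got_conc, vote = infer_allele_state_pair(
                    af1, af2, sum(s1), sum(s2), p1, p2
                )
            except AmbiguousStateError:
                continue
            recovered = (
                (st1.count_a, st1.count_b) == s1
                and {st2.count_a, st2.count_b} == set(s2)
                and got_conc == conc
            )
            ok += recovered
        assert ok / trials >= 0.99

    def test_ambiguous_vote_raises(self):
        rng = np.random.default_rng(1)
        # both samples balanced (1,1): no allele is distinguishable
        af1 = rng.binomial(60, 0.5, 30) / 60
        af2 = rng.binomial(60, 0.5, 30) / 60
        with pytest.raises(AmbiguousStateError):
            infer_allele_state_pair(af1, af2, 2, 2, 1.0, 1.0)

    def test_too_few_variants_rejected(self):
        with pytest.raises(UsageError):
            infer_allele_state_pair(np.ones(3), np.ones(3), 2, 2)


class TestOrderAlleleStates:
    def mk(self, a, b):
        return AlleleSpecificState("s", ("chr3", 0, 100), a, b)

    def test_amplified_then_lost(self):
        # one allele amplified while retaining the second, versus the
        # second allele lost: the former must precede the latter
        assert order_allele_states(self.mk(2, 1), self.mk(2, 0)) is Order.PRECEDES

    def test_no_resurrection(self):
        assert order_allele_states(self.mk(1, 0), self.mk(1, 1)) is Order.FOLLOWS

    def test_reflexive(self):
        assert order_allele_states(self.mk(2, 1), self.mk(2, 1)) is Order.EQUAL

    def test_different_locus_rejected(self):
        other = AlleleSpecificState("s", ("chr5", 0, 100), 1, 1)
        with pytest.raises(UsageError):
            order_allele_states(self.mk(1, 1), other)

    @given(st.tuples(st.integers(0, 3), st.integers(0, 3)),
           st.tuples(st.integers(0, 3), st.integers(0, 3)),
           st.tuples(st.integers(0, 3), st.integers(0, 3)))
    def test_reachability_is_a_preorder(self, x, y, z):
        sx, sy, sz = (self.mk(*t) for t in (x, y, z))
        assert reachable(sx, sx)
        if reachable(sx, sy) and reachable(sy, sz):
            assert reachable(sx, sz)


class TestAssignGroups:
    def _group_segs(self, sample, chrom, amp):
        v = 0.58 if amp else -1.0
        return [
            seg(sample, chrom, 0, 2 * MB, v),
            seg(sample, chrom, 2 * MB, 3 * MB, 0.0),
            seg(sample, chrom, 3 * MB, 5 * MB, v),
        ]

    def test_planted_groups_recovered_and_flat_samples_ungrouped(self):
        segs = []
        for s in ("A1", "A2"):
            segs += self._group_segs(s, "chr1", True)
            segs += [seg(s, "chr2", 0, 5 * MB, 0.0)]
        for s in ("B1", "B2"):
            segs += [seg(s, "chr1", 0, 5 * MB, 0.0)]
            segs += self._group_segs(s, "chr2", False)
        segs += [seg("M1", "chr1", 0, 5 * MB, 0.0), seg("M1", "chr2", 0, 5 * MB, 0.0)]
        groups = assign_groups(bin_log2(segs))
        assert groups["A1"] == groups["A2"] != "ungrouped"
        assert groups["B1"] == groups["B2"] != "ungrouped"
        assert groups["A1"] != groups["B1"]
        assert groups["M1"] == "ungrouped"

    def test_all_identical_profiles_single_group(self):
        segs = []
        for s in ("A", "B", "C"):
            segs += self._group_segs(s, "chr1", True)
        groups = assign_groups(bin_log2(segs))
        assert set(groups.values()) == {"G1"}

    def test_no_shared_events_all_ungrouped(self):
        segs = [
            seg("A", "chr1", 0, 5 * MB, 0.0),
            seg("B", "chr1", 0, 5 * MB, 0.0),
            seg("C", "chr1", 0, 5 * MB, 0.0),
        ]
        groups = assign_groups(bin_log2(segs))
        assert set(groups.values()) == {"ungrouped"}
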