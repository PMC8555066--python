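import numpy as np
import pytest

from metastrack import phylogeny as ph
from metastrack import simulate as sim
from metastrack.errors import UsageError
from metastrack.pipeline import sample_phylogeny_from_table
from metastrack.variant_io import call_somatic, filter_variants


def make_matrix(rows, samples=None):
    rows = np.asarray(rows, dtype=np.uint8)
    samples = samples or [f"S{i+1}" for i in range(rows.shape[1])]
    return ph.BinaryOccurrenceMatrix(
        variants=[f"v{i}" for i in range(len(rows))],
        samples=samples,
        v=rows,
    )


def cluster(vid, *samples):
    return ph.VariantCluster(vid, frozenset({vid}), frozenset(samples))


class TestEncodeBinary:
    def test_threshold_strictly_greater(self, small_cohort):
        t = call_somatic(small_cohort.table)
        mat = ph.encode_binary(t, chroms=["chr14"])
        # noiseless AFs are purity*prev/2 >= 0.25 where present, 0 elsewhere
        af = t.af
        assert mat.v.max() == 1
        # boundary handled strictly: exactly 0.1 encodes absent
        row = np.array([[0.1, 0.11]])
        assert (row > 0.1).tolist() == [[False, True]]

    def test_hand_encoded_fixture(self, small_cohort):
        t = call_somatic(small_cohort.table)
        mat = ph.encode_binary(t, chroms=["chr14"])
        # every somatic variant of the truncal clone is present everywhere
        truncal = [i for i, v in enumerate(mat.variants)
                   if v in {f"{c}:{p}:C>T" for c, p in small_cohort.tree.clone_variants[0]}]
        assert (mat.v[truncal] == 1).all()

    def test_empty_chrom_selection_rejected(self, small_cohort):
        t = call_somatic(small_cohort.table)
        with pytest.raises(UsageError):
            ph.encode_binary(t, chroms=[])

    def test_all_zero_rows_dropped(self):
        from tests.test_variant_io import make_table

        t = make_table([60], [[40, 40, 40]], [[0, 0, 0]], normals=("N1",))
        t = call_somatic(t)
        mat = ph.encode_binary(t)
        assert len(mat.variants) == 0


class TestClusterVariants:
    def test_forced_partition(self):
        mat = make_matrix([[1, 1, 0], [1, 1, 0], [0, 1, 1]])
        clusters = ph.cluster_variants(mat)
        assert sorted(c.size for c in clusters) == [1, 2]

    def test_all_identical_rows(self):
        mat = make_matrix([[1, 0]] * 4)
        assert len(ph.cluster_variants(mat)) == 1

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 2, size=(6, 4))
        rows[rows.sum(axis=1) == 0, 0] = 1
        mat = make_matrix(rows)
        clusters = ph.cluster_variants(mat)
        brute = {}
        for vid, row in zip(mat.variants, rows):
            brute.setdefault(tuple(row), set()).add(vid)
        assert {c.member_variants for c in clusters} == {
            frozenset(v) for v in brute.values()
        }

    def test_ids_ordered_by_sample_set_size(self):
        mat = make_matrix([[1, 0, 0], [1, 1, 1], [1, 1, 0]])
        clusters = ph.cluster_variants(mat)
        sizes = [len(c.sample_set) for c in clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert clusters[0].id == "K1"


class TestCompatibility:
    @pytest.mark.parametrize("a, b, want", [
        (("S1", "S2"), ("S1",), ph.NESTED),
        (("S1",), ("S2",), ph.DISJOINT),
        (("S1", "S2"), ("S2", "S3"), ph.CONFLICT),
    ])
    def test_three_gamete_cases(self, a, b, want):
        assert ph.check_compatibility(cluster("a", *a), cluster("b", *b)) == want


class TestMixtureFlagging:
    def test_conflict_free_matrix_flags_nothing(self):
        clusters = [cluster("a", "S1", "S2"), cluster("b", "S1"), cluster("c", "S3")]
        mixtures, pruned = ph.flag_mixture_samples(clusters)
        assert mixtures == set()
        assert len(pruned) == 3

    def test_single_conflict_resolved_by_one_sample(self):
        # S2 sits in the intersection of the two conflicting clusters;
        # exhaustive search over single removals confirms it is the only fix
        clusters = [
            cluster("a", "S1", "S2"),
            cluster("b", "S2", "S3"),
            cluster("c", "S1"),
            cluster("d", "S3"),
        ]
        mixtures, pruned = ph.flag_mixture_samples(clusters)
        assert mixtures == {"S2"}
        assert not any(
            ph.check_compatibility(x, y) == ph.CONFLICT
            for i, x in enumerate(pruned)
            for y in pruned[i + 1:]
        )

    def test_planted_mixture_sites_flagged_exactly(self):
        cfg = sim.SimulationConfig(
            seed=3, n_subclones=6, n_sites=8, depth_mean=None,
            purity_range=(1.0, 1.0), germline_het_spacing=None,
        )
        cohort = sim.simulate_cohort(cfg, n_mixture_sites=3)
        t = call_somatic(filter_variants(cohort.table))
        mat = ph.encode_binary(t, chroms=["chr14"])
        mixtures, pruned = ph.flag_mixture_samples(ph.cluster_variants(mat))
        assert mixtures == set(cohort.mixture_sites)


class TestPerfectPhylogeny:
    def test_three_cluster_example(self):
        clusters = [
            cluster("a", "S1", "S2", "S3"),
            cluster("b", "S1", "S2"),
            cluster("c", "S3"),
        ]
        phylo = ph.build_perfect_phylogeny(clusters)
        tree = phylo.tree
        assert phylo.root == "a"
        assert set(tree.successors("a")) == {"b", "c"}
        assert set(tree.successors("b")) == {"S1", "S2"}
        assert set(tree.successors("c")) == {"S3"}

    def test_single_sample_tree(self):
        phylo = ph.build_perfect_phylogeny([cluster("a", "S1")])
        assert phylo.leaves() == ["S1"]
        assert phylo.tree.nodes["a"]["branch_length"] == 1

    def test_residual_conflict_rejected(self):
        with pytest.raises(UsageError):
            ph.build_perfect_phylogeny(
                [cluster("a", "S1", "S2"), cluster("b", "S2", "S3")]
            )

    def test_cluster_sample_sets_equal_leaf_sets(self, small_cohort):
        t = call_somatic(small_cohort.table)
        phylo = sample_phylogeny_from_table(t, chroms=["chr14"])
        for node, data in phylo.tree.nodes(data=True):
            if "sample_set" not in data:
                continue
            leaves = {
                n for n in phylo.tree if phylo.tree.out_degree(n) == 0
                and node in __import__("networkx").ancestors(phylo.tree, n) | {n}
            }
            assert leaves == set(data["sample_set"])

    def test_noiseless_simulated_topology_recovered(self, small_cohort):
        t = call_somatic(small_cohort.table)
        mat = ph.encode_binary(t, chroms=["chr14"])
        clusters = ph.cluster_variants(mat)
        got = {c.sample_set for c in clusters}
        assert got == small_cohort.truth_sample_sets()

    def test_newick_round_trip_leaf_set(self, small_cohort):
        t = call_somatic(small_cohort.table)
        phylo = sample_phylogeny_from_table(t, chroms=["chr14"])
        nwk = phylo.to_newick()
        assert nwk.endswith(";")
        for leaf in phylo.leaves():
            assert leaf in nwk


class TestUpgmaHamming:
    def test_identical_columns_merge_at_zero(self):
        link, samples = ph.upgma_hamming(make_matrix([[1, 1, 0], [0, 0, 1]]))
        merged = {samples[int(link[0, 0])], samples[int(link[0, 1])]}
        assert merged == {"S1", "S2"}
        assert link[0, 2] == 0.0

    def test_hand_computed_four_samples(self):
        # columns: S1=(1,0,0,0) S2=(1,1,0,0) S3=(0,0,1,1) S4=(0,0,1,0)
        # Hamming fractions: d12=0.25, d34=0.25, cross pairs 0.75 except
        # d13=1.0 -> UPGMA heights 0.25, 0.25, (1+.75+.75+.5)/4=0.75
        mat = make_matrix([
            [1, 1, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 0],
        ])
        link, samples = ph.upgma_hamming(mat)
        assert sorted(link[:, 2].tolist()) == pytest.approx([0.25, 0.25, 0.75])

    def test_single_sample_rejected(self):
        with pytest.raises(UsageError):
            ph.upgma_hamming(make_matrix([[1]]))


class TestSharingStats:
    def test_identical_to_primary(self):
        from tests.test_variant_io import make_table

        depth = np.full((3, 4), 60)
        alt = np.array([[30, 30, 30, 0], [30, 30, 0, 0], [30, 30, 0, 0]])
        t = call_somatic(make_table([60] * 3, depth, alt, normals=("N1",)))
        stats = ph.sharing_stats(t, "T1")
        assert stats["T2"] == pytest.approx((1.0, 0.0, 0.0))

    def test_hand_computed_fractions(self):
        from tests.test_variant_io import make_table

        # T2 carries 4 variants: 2 truncal (in T1), 1 shared with T3 only,
        # 1 private
        depth = np.full((5, 4), 60)
        alt = np.array([
            [30, 30, 0, 0],   # truncal (T1+T2)
            [30, 30, 30, 0],  # truncal (everyone)
            [0, 30, 30, 0],   # shared (T2+T3)
            [0, 30, 0, 0],    # private to T2
            [30, 0, 0, 0],    # T1 only
        ])
        t = call_somatic(make_table([60] * 5, depth, alt, normals=("N1",)))
        stats = ph.sharing_stats(t, "T1")
        assert stats["T2"] == pytest.approx((0.5, 0.25, 0.25))

    def test_unknown_primary_rejected(self, small_cohort):
        t = call_somatic(small_cohort.table)
        with pytest.raises(UsageError):
            ph.sharing_stats(t, "nope")
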