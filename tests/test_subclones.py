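import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metastrack import subclones as sc
from metastrack.errors import UsageError


def make_clusters(prev_rows, samples=("S1",)):
    """Clusters with fixed prevalences (bypassing AF estimation)."""
    out = []
    for i, row in enumerate(prev_rows):
        c = sc.VAFCluster(
            id=f"C{i+1}",
            member_variants=tuple(f"v{i}_{j}" for j in range(3)),
            samples=tuple(samples),
            mean_af=np.asarray(row, dtype=float) / 2,
        )
        c.prevalence = np.asarray(row, dtype=float)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# independent oracle: every labeled tree via Pruefer sequences
# ---------------------------------------------------------------------------

def pruefer_to_parents(seq, n, root):
    """Decode a Pruefer sequence into a parent array rooted at ``root``."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for x in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, x))
        degree[leaf] -= 1
        degree[x] -= 1
        if degree[x] == 1:
            import bisect

            bisect.insort(leaves, x)
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    # orient away from root
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parents = [-2] * n
    parents[root] = -1
    stack = [root]
    seen = {root}
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                parents[nb] = node
                seen.add(nb)
                stack.append(nb)
    return tuple(parents)


def all_rooted_trees(n, root):
    if n == 1:
        return {(-1,)}
    if n == 2:
        return {tuple(-1 if i == root else root for i in range(2))}
    return {
        pruefer_to_parents(seq, n, root)
        for seq in itertools.product(range(n), repeat=n - 2)
    }


def oracle_valid_trees(P, root, tol):
    """Brute-force: keep trees satisfying the edge and sum constraints."""
    n = len(P)
    valid = []
    for parents in sorted(all_rooted_trees(n, root)):
        ok = True
        for child, par in enumerate(parents):
            if par < 0:
                continue
            if (P[par] < P[child] - tol).any():
                ok = False
                break
        if ok:
            for node in range(n):
                kids = [c for c, p in enumerate(parents) if p == node]
                if kids and (P[kids].sum(axis=0) > P[node] + tol).any():
                    ok = False
                    break
        if ok:
            valid.append(parents)
    return sorted(valid)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterVafs:
    def test_within_tolerance_merged(self):
        af = np.array([[0.48, 0.25], [0.50, 0.27]])
        clusters = sc.cluster_vafs(af, ["a", "b"], ["S1", "S2"])
        assert len(clusters) == 1
        assert clusters[0].size == 2

    def test_different_presence_patterns_separate(self):
        af = np.array([[0.5, 0.0], [0.0, 0.5]])
        clusters = sc.cluster_vafs(af, ["a", "b"], ["S1", "S2"])
        assert len(clusters) == 2

    def test_simulated_cluster_count_matches_planted_clones(self, noisy_cohort):
        from metastrack.pipeline import somatic_af_matrix
        from metastrack.variant_io import call_somatic

        t = call_somatic(noisy_cohort.table)
        af, ids, depth = somatic_af_matrix(t, t.tumor_samples, ["chr14"])
        clusters = sc.cluster_vafs(af, ids, t.tumor_samples, depth=depth)
        clusters = sc.consolidate_clusters(clusters)
        assert len(clusters) == noisy_cohort.tree.n_clones

    def test_empty_input_warns_and_returns_empty(self):
        assert sc.cluster_vafs(np.zeros((0, 2)), [], ["S1", "S2"]) == []


class TestPrevalence:
    def test_founding_clone_pure_tumor(self):
        assert sc.prevalence(0.5, 1.0) == pytest.approx(1.0)

    def test_purity_correction(self):
        assert sc.prevalence(0.2, 0.8) == pytest.approx(0.5)

    def test_capped_at_one(self):
        assert sc.prevalence(0.4, 0.5) == 1.0  # raw 1.6

    def test_deleted_region_single_copy(self):
        # variants inside a one-copy deletion: prevalence = af at purity 1
        assert sc.prevalence(0.3, 1.0, copies_total=1, copies_variant=1) == \
            pytest.approx(0.3)

    def test_zero_purity_rejected(self):
        with pytest.raises(UsageError):
            sc.prevalence(0.1, 0.0)

    @given(st.floats(0.01, 0.45), st.floats(0.3, 1.0), st.floats(0.01, 0.1))
    def test_monotone_in_af_and_purity(self, af, purity, eps):
        lo = sc.prevalence(af, purity)
        assert sc.prevalence(min(af + eps, 0.5), purity) >= lo
        if purity - eps > 0:
            assert sc.prevalence(af, purity - eps) >= lo


class TestEnumerateTrees:
    def test_single_sample_three_clusters_two_trees(self):
        clusters = make_clusters([[1.0], [0.6], [0.3]])
        sol = sc.enumerate_trees(clusters)
        # brute force over the 3 shapes rooted at the founder gives exactly
        # the chain and the star; the chain with C3 above C2 violates AF order
        assert sorted(sol.trees) == [(-1, 0, 0), (-1, 0, 1)]

    def test_two_samples_unique_tree(self):
        clusters = make_clusters(
            [[1.0, 1.0], [0.6, 0.0], [0.3, 1.0]], samples=("S1", "S2")
        )
        sol = sc.enumerate_trees(clusters)
        assert sol.trees == [(-1, 0, 0)]
        assert sol.violations == [0.0]

    def test_single_cluster(self):
        sol = sc.enumerate_trees(make_clusters([[1.0]]))
        assert sol.trees == [(-1,)]
        assert sol.chosen == 0

    def test_guard_on_cluster_count(self):
        clusters = make_clusters([[1.0]] + [[0.01]] * 12)
        with pytest.raises(UsageError):
            sc.enumerate_trees(clusters)

    def test_infeasible_constraints_reported(self):
        # two children each needing nearly all of an absent parent
        clusters = make_clusters([[1.0, 0.0], [0.0, 1.0]], samples=("S1", "S2"))
        sol = sc.enumerate_trees(clusters)
        assert sol.chosen is None
        assert sol.diagnostics

    def test_matches_pruefer_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 6))
            s = int(rng.integers(1, 4))
            P = np.round(rng.uniform(0, 1, size=(n, s)), 2)
            P[0] = 1.0  # founder
            clusters = make_clusters(P, samples=[f"S{j}" for j in range(s)])
            sol = sc.enumerate_trees(clusters, tolerance=0.1)
            want = oracle_valid_trees(P, sol.root, 0.1)
            assert sorted(tuple(int(x) for x in t) for t in sol.trees) == want

    def test_sum_constraint_holds_for_every_reported_tree(self):
        rng = np.random.default_rng(12)
        P = np.round(rng.uniform(0, 1, size=(4, 2)), 2)
        P[0] = 1.0
        clusters = make_clusters(P, samples=["S1", "S2"])
        sol = sc.enumerate_trees(clusters)
        for t in sol.trees:
            for node in range(len(P)):
                kids = [c for c, p in enumerate(t) if p == node]
                if kids:
                    assert (P[kids].sum(axis=0) <= P[node] + 0.1 + 1e-12).all()


class TestAssembly:
    def _solution(self, prev_rows, samples, tree):
        clusters = make_clusters(prev_rows, samples)
        return sc.SolutionSet(
            clusters=clusters, root=0, trees=[tree],
            violations=[0.0], tolerance=0.1, chosen=0,
        )

    def test_identical_solutions_join_to_same_tree(self):
        a = self._solution([[1.0], [0.5]], ("S1",), (-1, 0))
        b = self._solution([[1.0], [0.5]], ("S2",), (-1, 0))
        joint = sc.assemble_multi_sample({"g1": a, "g2": b})
        assert set(joint.graph.edges) == {("C1", "C2")}

    def test_disjoint_sets_star_join_at_founder(self):
        a = sc.SolutionSet(
            clusters=make_clusters([[1.0], [0.5]], ("S1",)),
            root=0, trees=[(-1, 0)], violations=[0.0], tolerance=0.1, chosen=0,
        )
        c3 = make_clusters([[1.0], [0.4]], ("S2",))
        c3[1].id = "C3"
        b = sc.SolutionSet(clusters=c3, root=0, trees=[(-1, 0)],
                           violations=[0.0], tolerance=0.1, chosen=0)
        joint = sc.assemble_multi_sample({"g1": a, "g2": b})
        assert set(joint.graph.edges) == {("C1", "C2"), ("C1", "C3")}

    def test_conflicting_parentage_reported_not_silent(self):
        a = self._solution([[1.0], [0.6], [0.3]], ("S1",), (-1, 0, 1))
        b = self._solution([[1.0], [0.6], [0.3]], ("S2",), (-1, 0, 0))
        joint = sc.assemble_multi_sample({"g1": a, "g2": b})
        assert joint.conflicts
        assert "C3" in joint.conflicts[0]
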