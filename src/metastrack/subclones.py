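"""Subclonal reconstruction from variant allele fractions.

Somatic variants restricted to copy-number-neutral regions are clustered by
their AF levels across samples; each cluster is a candidate subclone.  AFs
convert to cellular prevalence with purity and copy-state correction (for a
heterozygous variant in a diploid region, prevalence = 2*AF/purity).  All
rooted trees over the clusters are enumerated; a tree is kept when, in every
sample, each node's prevalence (+/- a tolerance absorbing AF measurement
error) can accommodate the summed prevalence of its children.  Among valid
trees, the one using the least total constraint slack is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from metastrack.errors import UsageError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class VAFCluster:
    """A set of variants sharing AF level across all samples."""

    id: str
    member_variants: tuple[str, ...]
    samples: tuple[str, ...]
    mean_af: np.ndarray                  # (s,) mean AF per sample
    prevalence: np.ndarray | None = None  # (s,) cellular prevalence, set later

    @property
    def size(self) -> int:
        return len(self.member_variants)


@dataclass
class SolutionSet:
    """All enumerated subclone trees for one cluster set.

    Trees are parent arrays over cluster indices (root has parent -1);
    ``chosen`` indexes the minimal-violation tree, ties broken by the
    deterministic serialization order in which trees are stored.
    """

    clusters: list[VAFCluster]
    root: int
    trees: list[tuple[int, ...]]
    violations: list[float]
    tolerance: float
    chosen: int | None = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def chosen_tree(self) -> tuple[int, ...] | None:
        return None if self.chosen is None else self.trees[self.chosen]

    def chosen_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        parents = self.chosen_tree
        if parents is None:
            return g
        for i, c in enumerate(self.clusters):
            g.add_node(c.id, prevalence=c.prevalence, samples=c.samples)
        for i, p in enumerate(parents):
            if p >= 0:
                g.add_edge(self.clusters[p].id, self.clusters[i].id)
        return g


# ---------------------------------------------------------------------------
# VAF clustering
# ---------------------------------------------------------------------------

def _em_components(
    block: np.ndarray,
    sd: np.ndarray,
    max_k: int = 8,
    n_iter: int = 60,
) -> list[list[int]]:
    """Cluster AF vectors by a Gaussian mixture with known per-observation
    noise (binomial read-sampling error), selecting the component count by
    AIC.

    Greedy distance-threshold merging is path-dependent: a single clone's
    variants can end up in two blobs whose selection-biased centroids sit
    just beyond any fixed tolerance.  Likelihood-based assignment with the
    known noise scale has no such failure mode and is deterministic
    (farthest-point initialization).
    """
    n, s = block.shape
    if n == 1:
        return [[0]]
    prec = 1.0 / np.maximum(sd, 0.02) ** 2          # (n, s)
    max_k = min(max_k, n)

    def init_farthest(k: int) -> np.ndarray:
        centers = [block.mean(axis=0)]
        for _ in range(1, k):
            d = np.stack([(((block - c) ** 2) * prec).sum(axis=1) for c in centers])
            centers.append(block[int(d.min(axis=0).argmax())])
        return np.vstack(centers)

    def init_quantile(k: int) -> np.ndarray:
        # spread along the total-AF axis; robust when clones overlap in a
        # subset of samples
        order = np.argsort(block.sum(axis=1))
        qs = [order[int(q * (n - 1))] for q in np.linspace(0, 1, k)]
        return block[qs].copy()

    def fit(k: int, mu: np.ndarray):
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        for _ in range(n_iter):
            # E step: log N(b | mu_c, sd) summed over samples
            logp = np.stack([
                -0.5 * (((block - mu[c]) ** 2) * prec).sum(axis=1) for c in range(k)
            ]).T + np.log(w)[None, :]               # (n, k)
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            resp = np.exp(logp - lse[:, None])
            ll = float(lse.sum())
            # M step: precision-weighted means
            for c in range(k):
                wgt = resp[:, c][:, None] * prec
                mu[c] = (wgt * block).sum(axis=0) / np.maximum(wgt.sum(axis=0), 1e-12)
            w = np.maximum(resp.mean(axis=0), 1e-9)
            w /= w.sum()
            if abs(ll - ll_prev) < 1e-8:
                break
            ll_prev = ll
        assign = resp.argmax(axis=1)
        return ll, assign

    best_assign, best_score = None, np.inf
    for k in range(1, max_k + 1):
        ll, assign = max(
            (fit(k, init(k)) for init in (init_farthest, init_quantile)),
            key=lambda t: t[0],
        )
        # AIC, deliberately permissive: an unsplit pair of clones is
        # unrecoverable downstream, while an oversplit clone is re-merged by
        # the unimodality-aware tolerance merge
        aic = -2 * ll + 2 * (k * s + (k - 1))
        if aic < best_score - 1e-9:
            best_score, best_assign = aic, assign
    return [
        list(np.flatnonzero(best_assign == c))
        for c in np.unique(best_assign)
    ]


def _threshold_merge(
    af: np.ndarray,
    sd: np.ndarray,
    member_lists: list[list[int]],
    merge_tol: float,
    noise_cap: float = 2.5,
) -> list[tuple[np.ndarray, list[int]]]:
    """Greedy merging of AF components under the tolerance, with a
    unimodality rescue for read-noise splits.

    A pair merges when its mean AFs differ by less than ``merge_tol`` in
    every sample; additionally, a pair within ``noise_cap`` read-noise sd
    everywhere merges if the union of its members is unimodal along the
    separation axis — a single clone partitioned by noise reproduces its
    parent Gaussian, whereas two true AF levels are bimodal.  The
    unimodality threshold follows the Marchenko-Pastur edge
    ``(1 + sqrt(s/n))^2`` (the split axis is itself selected from the data,
    inflating the variance ratio along it by exactly that factor under the
    null).
    """

    def stats(members: list[int]):
        rows = af[members]
        return rows.mean(axis=0), sd[members].mean(axis=0)

    groups = [list(m) for m in member_lists]
    means = [stats(m)[0] for m in groups]
    msds = [stats(m)[1] for m in groups]

    def mergeable(i: int, j: int) -> float | None:
        """Normalized distance if the pair may merge, else None."""
        d = np.abs(means[i] - means[j])
        pooled = np.sqrt(
            (len(groups[i]) * msds[i] ** 2 + len(groups[j]) * msds[j] ** 2)
            / (len(groups[i]) + len(groups[j]))
        )
        if (d < merge_tol).all():
            return float((d / merge_tol).max())
        cap = np.maximum(merge_tol, noise_cap * pooled)
        if not (d < cap).all():
            return None
        # unimodality along the separation axis
        axis = means[i] - means[j]
        norm = float(np.linalg.norm(axis))
        if norm == 0:
            return 0.0
        axis = axis / norm
        proj = np.concatenate([af[groups[i]] @ axis, af[groups[j]] @ axis])
        if len(proj) < 10:
            return None
        noise_var = float(((axis * pooled) ** 2).sum())
        ratio = float(np.var(proj, ddof=1)) / max(noise_var, 1e-12)
        s = af.shape[1]
        threshold = max(1.8, 1.25 * (1 + np.sqrt(s / len(proj))) ** 2)
        if ratio >= threshold:
            return None
        return float((d / cap).max())

    changed = True
    while changed and len(groups) > 1:
        changed = False
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                s = mergeable(i, j)
                if s is not None and (best is None or s < best[0]):
                    best = (s, i, j)
        if best is not None:
            _, i, j = best
            groups[i] = groups[i] + groups[j]
            means[i], msds[i] = stats(groups[i])
            del groups[j], means[j], msds[j]
            changed = True
    return [(m, g) for m, g in zip(means, groups)]


def cluster_vafs(
    af: np.ndarray,
    variant_ids: list[str],
    samples: list[str],
    af_positive: float = 0.05,
    merge_tol: float = 0.1,
    depth: np.ndarray | None = None,
) -> list[VAFCluster]:
    """Cluster variants with the same AF level in all samples.

    Variants are first partitioned by presence pattern (AF >= ``af_positive``).
    Within a pattern, AF vectors are grouped by a Gaussian mixture whose
    per-observation noise is the known binomial read-sampling error
    (``depth`` supplies read depths; 60x assumed when absent), with the
    component count selected by BIC; components whose mean AFs differ by
    less than ``merge_tol`` in every sample are then merged.  Clusters are
    ordered by descending total mean AF (the founding clone first).
    """
    af = np.nan_to_num(np.asarray(af, dtype=float), nan=0.0)
    if af.ndim != 2 or af.shape[1] != len(samples):
        raise UsageError("af must be variants x samples")
    if af.shape[0] == 0:
        logger.warning("no somatic variants to cluster")
        return []
    dp = np.full(af.shape, 60.0) if depth is None else np.maximum(depth, 1)
    sd = np.sqrt(np.maximum(af * (1 - af), 1e-4) / dp)
    patterns: dict[tuple, list[int]] = {}
    for i, row in enumerate(af >= af_positive):
        patterns.setdefault(tuple(row.tolist()), []).append(i)

    pre: list[list[int]] = []
    for idxs in patterns.values():
        for c in _em_components(af[idxs], sd[idxs]):
            pre.append([idxs[k] for k in c])
    # merge components (across patterns too) whose mean AFs agree within
    # tolerance in every sample; read-noise splits of one clone are rescued
    # by a unimodality test along the separation axis
    raw = _threshold_merge(af, sd, pre, merge_tol)

    raw.sort(key=lambda t: (-float(t[0].sum()), tuple(np.round(-t[0], 9)), t[1]))
    return [
        VAFCluster(
            id=f"C{i + 1}",
            member_variants=tuple(variant_ids[k] for k in idxs),
            samples=tuple(samples),
            mean_af=mean,
        )
        for i, (mean, idxs) in enumerate(raw)
    ]


def consolidate_clusters(
    clusters: list[VAFCluster],
    min_size: int = 5,
) -> list[VAFCluster]:
    """Absorb clusters below ``min_size`` members into the nearest large
    cluster (Chebyshev distance on mean AF).

    Read noise around the positivity cutoff flips single variants into
    spurious presence patterns; with >= ~30 variants defining each true
    clone, any tiny cluster is noise and is reassigned rather than treated
    as a clone.  The effective floor scales with the largest cluster (a
    fragment is anything well below the size of a real clone).  With no
    large cluster at all, the input is returned as is.
    """
    if clusters:
        min_size = max(min_size, int(round(0.3 * max(c.size for c in clusters))))
    big = [c for c in clusters if c.size >= min_size]
    small = [c for c in clusters if c.size < min_size]
    if not big or not small:
        return clusters
    merged = {c.id: (list(c.member_variants), c.mean_af * c.size, c.size) for c in big}
    for c in small:
        target = min(
            big, key=lambda b: (float(np.max(np.abs(b.mean_af - c.mean_af))), b.id)
        )
        members, af_sum, n = merged[target.id]
        merged[target.id] = (members + list(c.member_variants),
                             af_sum + c.mean_af * c.size, n + c.size)
    out = [
        VAFCluster(id=c.id, member_variants=tuple(m), samples=c.samples,
                   mean_af=af_sum / n)
        for c in big
        for (m, af_sum, n) in [merged[c.id]]
    ]
    out.sort(key=lambda c: -float(c.mean_af.sum()))
    return [
        VAFCluster(id=f"C{i + 1}", member_variants=c.member_variants,
                   samples=c.samples, mean_af=c.mean_af)
        for i, c in enumerate(out)
    ]


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

def prevalence(
    af: float,
    purity: float,
    copies_total: int = 2,
    copies_variant: int = 1,
) -> float:
    """Cellular prevalence of a clone from its variants' AF.

    ``af * (purity*copies_total + (1-purity)*2) / (purity*copies_variant)``,
    capped at 1.  For a het variant in a diploid region this is 2*AF/purity;
    a founding clone in a pure tumor (AF ~0.5) has prevalence 1.
    """
    if not (0 < purity <= 1):
        raise UsageError(f"purity must be in (0, 1], got {purity}")
    if copies_variant <= 0 or copies_variant > copies_total:
        raise UsageError("copies_variant must be in [1, copies_total]")
    raw = af * (purity * copies_total + (1 - purity) * 2) / (purity * copies_variant)
    if raw > 1:
        logger.warning("prevalence %.3f capped at 1.0 (af=%.3f, purity=%.2f)", raw, af, purity)
        return 1.0
    return float(raw)


def set_prevalences(
    clusters: list[VAFCluster],
    purities: dict[str, float],
    copies_total: int = 2,
    copies_variant: int = 1,
    af_positive: float = 0.05,
) -> list[VAFCluster]:
    """Attach purity-corrected per-sample prevalences to each cluster.

    Mean AFs below the positivity cutoff are treated as absence (prevalence
    0): sequencing-error reads otherwise leak tiny prevalences that bias
    tree selection.
    """
    for c in clusters:
        c.prevalence = np.array(
            [
                prevalence(float(a), purities[s], copies_total, copies_variant)
                if float(a) >= af_positive else 0.0
                for a, s in zip(c.mean_af, c.samples)
            ]
        )
    return clusters


# ---------------------------------------------------------------------------
# Tree enumeration
# ---------------------------------------------------------------------------

MAX_CLUSTERS = 12


def _find_root(P: np.ndarray, tolerance: float, pos: float) -> int:
    """Founding cluster: prevalence within tolerance of 1 in >= 1 sample,
    maximal presence set; ties -> larger total prevalence, then first id."""
    present = P >= pos
    candidates = [i for i in range(len(P)) if (P[i] >= 1 - tolerance).any()]
    if not candidates:
        logger.warning("no cluster reaches prevalence ~1; using maximal-presence cluster")
        candidates = list(range(len(P)))
    return min(
        candidates,
        key=lambda i: (-int(present[i].sum()), -float(P[i].sum()), i),
    )


def enumerate_trees(
    clusters: list[VAFCluster],
    tolerance: float = 0.1,
    af_positive: float = 0.05,
) -> SolutionSet:
    """Enumerate all rooted subclone trees satisfying the prevalence
    sum-constraint within tolerance; choose the minimal-violation tree.

    Constraints per sample: (a) a parent's prevalence + tolerance bounds the
    sum of its children's prevalences; (b) an ancestor's prevalence is at
    least its descendant's minus tolerance (ancestral variants have the
    larger AF).  Violation is the L1 slack actually used, summed over
    samples and nodes.
    """
    n = len(clusters)
    if n > MAX_CLUSTERS:
        raise UsageError(
            f"{n} clusters exceeds the enumeration guard ({MAX_CLUSTERS}); "
            "raise merge_tol to pre-merge clusters"
        )
    if any(c.prevalence is None for c in clusters):
        raise UsageError("prevalences not set; run set_prevalences first")
    if n == 0:
        return SolutionSet([], -1, [], [], tolerance, None, ["no clusters"])
    P = np.vstack([c.prevalence for c in clusters])
    root = _find_root(P, tolerance, af_positive)
    if n == 1:
        return SolutionSet(clusters, root, [(-1,)], [0.0], tolerance, 0)

    nodes = [i for i in range(n) if i != root]
    parents = np.full(n, -2, dtype=int)
    parents[root] = -1
    child_sum = np.zeros_like(P)
    trees: list[tuple[int, ...]] = []
    violations: list[float] = []

    def ok_edge(p: int, c: int) -> bool:
        return bool((P[p] >= P[c] - tolerance).all())

    def makes_cycle(p: int, c: int) -> bool:
        cur = p
        while cur >= 0 and parents[cur] != -2:
            cur = parents[cur]
            if cur == c:
                return True
        return False

    def rec(k: int):
        if k == len(nodes):
            viol = float(np.maximum(child_sum - P, 0.0).sum())
            trees.append(tuple(parents))
            violations.append(viol)
            return
        c = nodes[k]
        for p in range(n):
            if p == c or not ok_edge(p, c) or makes_cycle(p, c):
                continue
            new_sum = child_sum[p] + P[c]
            if (new_sum > P[p] + tolerance).any():
                continue
            parents[c] = p
            child_sum[p] = new_sum
            rec(k + 1)
            child_sum[p] = new_sum - P[c]
            parents[c] = -2
        return

    rec(0)
    if not trees:
        diags = []
        for c in range(n):
            feasible = [p for p in range(n) if p != c and ok_edge(p, c)]
            if not feasible:
                diags.append(
                    f"cluster {clusters[c].id} has no feasible parent "
                    f"(prevalence {np.round(P[c], 3).tolist()})"
                )
        return SolutionSet(clusters, root, [], [], tolerance, None,
                           diags or ["sum constraints jointly infeasible"])
    order = sorted(range(len(trees)), key=lambda i: trees[i])
    trees = [trees[i] for i in order]
    violations = [violations[i] for i in order]
    chosen = min(range(len(trees)), key=lambda i: (violations[i], trees[i]))
    return SolutionSet(clusters, root, trees, violations, tolerance, chosen)


# ---------------------------------------------------------------------------
# Multi-solution assembly
# ---------------------------------------------------------------------------

@dataclass
class JointTree:
    """Joint subclone tree over all samples, with per-sample prevalences."""

    graph: nx.DiGraph
    prevalence: pd.DataFrame       # clusters x samples
    conflicts: list[str] = field(default_factory=list)

    @property
    def root(self) -> str:
        roots = [n for n in self.graph if self.graph.in_degree(n) == 0]
        return roots[0] if roots else ""


def assemble_multi_sample(solutions: dict[str, SolutionSet]) -> JointTree:
    """Merge per-sample/per-group chosen trees into one joint tree.

    Cluster identity across solutions is by cluster id (established upstream
    from shared member variants).  A cluster with different parents in
    different solutions is resolved toward the parent minimizing total joint
    violation; irreconcilable parentage is kept as an explicit conflict
    report, never silently dropped.
    """
    prev_frames = []
    candidate_parents: dict[str, set[str]] = {}
    for name, sol in solutions.items():
        tree = sol.chosen_tree
        if tree is None:
            continue
        ids = [c.id for c in sol.clusters]
        prev_frames.append(
            pd.DataFrame(
                np.vstack([c.prevalence for c in sol.clusters]),
                index=ids, columns=list(sol.clusters[0].samples),
            )
        )
        for i, p in enumerate(tree):
            if p >= 0:
                candidate_parents.setdefault(ids[i], set()).add(ids[p])
            else:
                candidate_parents.setdefault(ids[i], set())
    if not prev_frames:
        return JointTree(nx.DiGraph(), pd.DataFrame(), ["no solutions to assemble"])
    prev = pd.concat(prev_frames).groupby(level=0).max()
    prev = prev.fillna(0.0)

    g = nx.DiGraph()
    g.add_nodes_from(prev.index)
    conflicts: list[str] = []
    resolved: dict[str, str] = {}
    for child in sorted(candidate_parents):
        cands = sorted(candidate_parents[child])
        if len(cands) <= 1:
            if cands:
                resolved[child] = cands[0]
            continue
        # score each candidate by the slack it would use across all samples
        def slack(parent: str) -> float:
            diff = prev.loc[child] - prev.loc[parent]
            return float(np.maximum(diff, 0.0).sum())

        scored = sorted(cands, key=lambda p: (slack(p), p))
        resolved[child] = scored[0]
        if slack(scored[0]) == slack(scored[1]):
            conflicts.append(
                f"{child}: parents {cands} tie at violation {slack(scored[0]):.3f}; "
                f"kept {scored[0]}"
            )
        else:
            conflicts.append(
                f"{child}: parents {cands} disagree; kept minimal-violation {scored[0]}"
            )
    for child, parent in resolved.items():
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        conflicts.append("irreconcilable parentage: joint graph contains a cycle")
    return JointTree(graph=g, prevalence=prev, conflicts=conflicts)
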