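"""Cross-sample phylogeny from somatic variant presence/absence.

Somatic variants on copy-stable chromosomes are encoded as binary
presence/absence per sample (present iff AF > 0.1).  Variants with identical
binary vectors are clustered — they arose in the same clone — and under the
infinite-sites assumption (each site mutates once, no reversion) the cluster
sample-sets must be pairwise nested or disjoint: a perfect phylogeny.
Samples that are mixtures of cell populations from different lineages break
this laminarity; they are detected by greedy conflict-count removal and
excluded from the tree.  Branch lengths are calibrated by the number of
variants on each branch.  An UPGMA dendrogram on Hamming distances serves as
an independent concordance check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from metastrack.errors import DegenerateMatrixError, UsageError
from metastrack.variant_io import MultiSampleVariantTable

logger = logging.getLogger(__name__)

NESTED = "nested"
DISJOINT = "disjoint"
CONFLICT = "conflict"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BinaryOccurrenceMatrix:
    """Variants x samples in {0,1}; rows with no presence are dropped."""

    variants: list[str]
    samples: list[str]
    v: np.ndarray                 # (n_variants, n_samples) uint8
    af_threshold: float = 0.1


@dataclass(frozen=True)
class VariantCluster:
    """A set of variants sharing one binary presence vector."""

    id: str
    member_variants: frozenset[str]
    sample_set: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_variants)


@dataclass
class SamplePhylogeny:
    """Rooted perfect-phylogeny tree: internal nodes are variant clusters,
    leaves are samples, branch lengths are variant counts."""

    tree: nx.DiGraph
    root: str
    mixture_samples: set[str] = field(default_factory=set)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.tree if self.tree.out_degree(n) == 0)

    def to_newick(self) -> str:
        def rec(node) -> str:
            children = sorted(self.tree.successors(node))
            length = self.tree.nodes[node].get("branch_length", 0)
            label = node if self.tree.out_degree(node) == 0 else ""
            if not children:
                return f"{label}:{length}"
            inner = ",".join(rec(c) for c in children)
            return f"({inner}){label}:{length}"

        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# Encoding and clustering
# ---------------------------------------------------------------------------

def encode_binary(
    table: MultiSampleVariantTable,
    chroms: list[str] | None = None,
    af_threshold: float = 0.1,
    samples: list[str] | None = None,
) -> BinaryOccurrenceMatrix:
    """Binary presence/absence of somatic variants (present iff AF > threshold).

    Restricted to the given chromosomes (copy-stable ones, by the caller's
    choice) and to tumor samples.  Missing AFs count as absent and are
    logged; all-absent rows are dropped.
    """
    if chroms is not None and len(chroms) == 0:
        raise UsageError("empty chromosome selection")
    samples = list(samples) if samples is not None else table.tumor_samples
    rows = table.somatic_flags.copy()
    if chroms is not None:
        rows &= np.isin(table.chrom, np.asarray(chroms, dtype=object))
    sub = table.subset(rows)
    af = sub.af[:, sub.sample_index(samples)]
    n_missing = int(np.isnan(af).sum())
    if n_missing:
        logger.warning("%d missing AF value(s) treated as absent", n_missing)
    v = (np.nan_to_num(af, nan=0.0) > af_threshold).astype(np.uint8)
    ids = [f"{c}:{p}:{r}>{a}" for c, p, r, a in zip(sub.chrom, sub.pos, sub.ref, sub.alt)]
    present = v.any(axis=1)
    return BinaryOccurrenceMatrix(
        variants=[i for i, k in zip(ids, present) if k],
        samples=samples,
        v=v[present],
        af_threshold=af_threshold,
    )


def cluster_variants(matrix: BinaryOccurrenceMatrix) -> list[VariantCluster]:
    """Partition variants by identical binary vectors.

    Cluster ids are assigned deterministically: descending sample-set size,
    then lexicographic sample set.
    """
    groups: dict[tuple, list[str]] = {}
    for vid, row in zip(matrix.variants, matrix.v):
        groups.setdefault(tuple(row.tolist()), []).append(vid)
    keyed = []
    for vec, members in groups.items():
        sample_set = frozenset(s for s, b in zip(matrix.samples, vec) if b)
        keyed.append((-len(sample_set), tuple(sorted(sample_set)), sample_set, members))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return [
        VariantCluster(id=f"K{i + 1}", member_variants=frozenset(members), sample_set=ss)
        for i, (_, _, ss, members) in enumerate(keyed)
    ]


def check_compatibility(c1: VariantCluster, c2: VariantCluster) -> str:
    """Three-gamete check on two clusters' sample sets."""
    a, b = c1.sample_set, c2.sample_set
    if a <= b or b <= a:
        return NESTED
    if not (a & b):
        return DISJOINT
    return CONFLICT


# ---------------------------------------------------------------------------
# Mixture detection
# ---------------------------------------------------------------------------

def _project(clusters: list[VariantCluster], keep: set[str]) -> list[VariantCluster]:
    """Re-project clusters onto a sample subset, re-merging collapsed vectors."""
    merged: dict[frozenset, set[str]] = {}
    for c in clusters:
        ss = frozenset(c.sample_set & keep)
        if not ss:
            continue
        merged.setdefault(ss, set()).update(c.member_variants)
    keyed = sorted(
        ((-len(ss), tuple(sorted(ss)), ss, mem) for ss, mem in merged.items()),
        key=lambda t: (t[0], t[1]),
    )
    return [
        VariantCluster(id=f"K{i + 1}", member_variants=frozenset(mem), sample_set=ss)
        for i, (_, _, ss, mem) in enumerate(keyed)
    ]


def flag_mixture_samples(
    clusters: list[VariantCluster],
) -> tuple[set[str], list[VariantCluster]]:
    """Greedily remove the sample implicated in the most pairwise conflicts
    until the cluster set is laminar.

    A sample is implicated in a conflicting pair when it lies in the
    intersection of the two sample sets (removing it can render them
    disjoint).  Ties break lexicographically.  Removing half or more of the
    samples aborts: the data violates infinite sites globally.
    """
    all_samples = sorted(set().union(*(c.sample_set for c in clusters))) if clusters else []
    n_total = len(all_samples)
    removed: set[str] = set()
    current = list(clusters)
    while True:
        counts: dict[str, int] = {}
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                if check_compatibility(current[i], current[j]) == CONFLICT:
                    for s in current[i].sample_set & current[j].sample_set:
                        counts[s] = counts.get(s, 0) + 1
        if not counts:
            return removed, current
        worst = min(counts, key=lambda s: (-counts[s], s))
        removed.add(worst)
        if 2 * len(removed) >= n_total:
            raise DegenerateMatrixError(
                f"removed {len(removed)} of {n_total} samples without reaching "
                "a conflict-free matrix"
            )
        current = _project(clusters, set(all_samples) - removed)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def build_perfect_phylogeny(
    clusters: list[VariantCluster],
    mixture_samples: set[str] | None = None,
) -> SamplePhylogeny:
    """Build the rooted tree implied by a laminar cluster family.

    Clusters nest by sample-set containment; each sample attaches as a leaf
    under the smallest cluster containing it.  Branch length of a cluster
    node is its variant count.  If no cluster spans all samples, a synthetic
    zero-length root is added.
    """
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if check_compatibility(clusters[i], clusters[j]) == CONFLICT:
                raise UsageError(
                    "residual conflict between clusters; run flag_mixture_samples first"
                )
    samples = sorted(set().union(*(c.sample_set for c in clusters))) if clusters else []
    g = nx.DiGraph()
    # sort big -> small so parents are seen before children
    ordered = sorted(clusters, key=lambda c: (-len(c.sample_set), sorted(c.sample_set)))
    root = "root"
    g.add_node(root, branch_length=0, clusters=())
    placed: list[tuple[str, VariantCluster]] = []
    for c in ordered:
        # big -> small ordering means the last strict superset is the smallest,
        # i.e. the immediate parent
        parent_nodes = [node for node, pc in placed if c.sample_set < pc.sample_set]
        parent = parent_nodes[-1] if parent_nodes else root
        g.add_node(c.id, branch_length=c.size, clusters=(c.id,),
                   sample_set=c.sample_set, n_variants=c.size)
        g.add_edge(parent, c.id)
        placed.append((c.id, c))
    for s in samples:
        holders = [(len(c.sample_set), node) for node, c in placed if s in c.sample_set]
        parent = min(holders)[1] if holders else root
        g.add_node(s, branch_length=0)
        g.add_edge(parent, s)
    # collapse the synthetic root if a single truncal cluster spans everything
    if g.out_degree(root) == 1 and clusters:
        only = next(iter(g.successors(root)))
        if g.nodes[only].get("sample_set") == frozenset(samples):
            g.remove_node(root)
            root = only
    return SamplePhylogeny(tree=g, root=root, mixture_samples=set(mixture_samples or ()))


def upgma_hamming(matrix: BinaryOccurrenceMatrix):
    """UPGMA dendrogram over samples from Hamming distances between their
    binary presence columns; concordance cross-check for the perfect
    phylogeny.  Returns ``(linkage, samples)`` (samples lexicographic)."""
    if len(matrix.samples) < 2:
        raise UsageError("UPGMA requires at least two samples")
    order = np.argsort(np.asarray(matrix.samples, dtype=object))
    samples = [matrix.samples[i] for i in order]
    cols = matrix.v.T[order].astype(float)
    condensed = pdist(cols, metric="hamming")
    return hierarchy.linkage(condensed, method="average"), samples


# ---------------------------------------------------------------------------
# Sharing statistics
# ---------------------------------------------------------------------------

def sharing_stats(
    table: MultiSampleVariantTable,
    primary_sample: str,
    af_threshold: float = 0.1,
) -> dict[str, tuple[float, float, float]]:
    """Per-sample (truncal, shared, private) fractions of somatic variants.

    For each non-primary tumor sample: among its present somatic variants,
    the fraction also present in the primary (truncal), present in at least
    one other non-primary sample but not the primary (shared), and present
    nowhere else (private).  The three fractions sum to 1.
    """
    if primary_sample not in table.samples:
        raise UsageError(f"unknown primary sample {primary_sample!r}")
    tumor = table.tumor_samples
    mat = encode_binary(table, chroms=None, af_threshold=af_threshold, samples=tumor)
    v = mat.v.astype(bool)
    idx = {s: i for i, s in enumerate(tumor)}
    p = idx[primary_sample]
    out: dict[str, tuple[float, float, float]] = {}
    for s in tumor:
        if s == primary_sample:
            continue
        j = idx[s]
        mine = v[:, j]
        n = int(mine.sum())
        if n == 0:
            out[s] = (0.0, 0.0, 0.0)
            continue
        in_primary = v[:, p] & mine
        others = [idx[t] for t in tumor if t not in (s, primary_sample)]
        in_other = v[:, others].any(axis=1) & mine if others else np.zeros_like(mine)
        truncal = int(in_primary.sum())
        shared = int((in_other & ~in_primary).sum())
        private = n - truncal - shared
        out[s] = (truncal / n, shared / n, private / n)
    return out
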