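"""Copy-number profile clustering and allele-specific CNV/LOH inference.

Two independent pieces of evidence are extracted from copy-number data:

1. *Sample grouping* — per-sample log2-ratio segments are binned into 1-Mb
   windows, pairwise Euclidean distances are computed over bins observed in
   both samples, and the samples are clustered by UPGMA.  Clusters that share
   enough discrete CNV events become metastatic groups.

2. *Allele-specific states* — within a somatic CNV region, inherited
   heterozygous variants sit on one of the two parental alleles; their AFs
   cluster at levels determined by how many copies of each allele a sample
   carries.  Comparing the AF clusters of two samples reveals whether the
   allele amplified in one is the allele retained in the other, and yields a
   partial time-ordering of allele states under a no-resurrection rule (an
   allele lost to copy number 0 never comes back).

The expected AF of a het variant carried on ``m`` of ``c`` tumor copies in a
sample of purity ``p`` is ``(p*m + (1-p)) / (p*c + (1-p)*2)``: the tumor
contributes ``m`` variant copies out of ``c``, contaminating normal cells
contribute 1 of 2.  At purity 1 this is ``m/c``; at c=2, m=1 it is 0.5 at any
purity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from metastrack.errors import AmbiguousStateError, DataError, UsageError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyNumberSegment:
    """One FACETS-style segment: 0-based half-open, total copy number,
    log2 tumor/normal ratio, LOH flag."""

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: int
    log2_ratio: float
    loh: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(f"segment start >= end: {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class AlleleSpecificState:
    """Copies of the two parental alleles at one locus in one sample.

    Allele labels A/B are arbitrary per locus but consistent across the
    samples they were jointly inferred for.
    """

    sample: str
    locus: tuple[str, int, int]
    count_a: int
    count_b: int

    @property
    def total_cn(self) -> int:
        return self.count_a + self.count_b


class Order(str, Enum):
    PRECEDES = "precedes"
    FOLLOWS = "follows"
    EQUAL = "equal"
    INCOMPARABLE = "incomparable"


@dataclass
class CnvProfileMatrix:
    """Samples x 1-Mb bins of log2 ratios; NaN marks uncovered bins."""

    values: pd.DataFrame          # index = samples, columns = (chrom, bin_start)
    bin_size: int

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def read_segments(path) -> list[CopyNumberSegment]:
    """Read a tab-delimited segment table
    (sample, chrom, start, end, total_cn, log2_ratio, loh)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CopyNumberSegment(
            sample=r.sample, chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            total_cn=int(r.total_cn), log2_ratio=float(r.log2_ratio),
            loh=bool(int(r.loh)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Binning and sample clustering
# ---------------------------------------------------------------------------

def bin_log2(segments: list[CopyNumberSegment], bin_size: int = 1_000_000) -> CnvProfileMatrix:
    """Bin per-sample log2 ratios into fixed windows.

    Each bin's value is the length-weighted mean log2 ratio of the segments
    overlapping it; bins with no coverage are NaN.  Overlapping segments
    within one sample are a data error.
    """
    samples = sorted({s.sample for s in segments})
    by_sample: dict[str, list[CopyNumberSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample[seg.sample].append(seg)
    # overlap check per sample+chrom
    for sample, segs in by_sample.items():
        for chrom, group in itertools.groupby(
            sorted(segs, key=lambda s: (s.chrom, s.start)), key=lambda s: s.chrom
        ):
            prev_end = -1
            for seg in group:
                if seg.start < prev_end:
                    raise DataError(
                        f"overlapping segments in {sample} at {chrom}:{seg.start}"
                    )
                prev_end = seg.end

    chrom_extent: dict[str, int] = {}
    for seg in segments:
        chrom_extent[seg.chrom] = max(chrom_extent.get(seg.chrom, 0), seg.end)
    bins = [
        (chrom, b)
        for chrom in sorted(chrom_extent)
        for b in range(0, chrom_extent[chrom], bin_size)
    ]
    bin_pos = {b: i for i, b in enumerate(bins)}

    weights = np.zeros((len(samples), len(bins)))
    sums = np.zeros((len(samples), len(bins)))
    for i, sample in enumerate(samples):
        for seg in by_sample[sample]:
            b0 = seg.start // bin_size
            b1 = (seg.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(seg.start, b * bin_size)
                hi = min(seg.end, (b + 1) * bin_size)
                j = bin_pos[(seg.chrom, b * bin_size)]
                weights[i, j] += hi - lo
                sums[i, j] += (hi - lo) * seg.log2_ratio
    with np.errstate(invalid="ignore"):
        vals = sums / weights
    vals[weights == 0] = np.nan
    df = pd.DataFrame(vals, index=samples, columns=pd.MultiIndex.from_tuples(bins))
    return CnvProfileMatrix(values=df, bin_size=bin_size)


def _pairwise_masked_euclidean(values: np.ndarray) -> np.ndarray:
    """Euclidean distance over bins non-missing in both samples of a pair."""
    n = len(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if not both.any():
                raise UsageError("a sample pair shares no covered bins")
            diff = values[i, both] - values[j, both]
            d[i, j] = d[j, i] = float(np.sqrt(np.sum(diff * diff)))
    return d


def cluster_profiles(matrix: CnvProfileMatrix):
    """UPGMA dendrogram over samples from masked Euclidean distances.

    Returns ``(linkage, samples)`` with samples in lexicographic order so the
    dendrogram is deterministic under input reordering.
    """
    samples = sorted(matrix.samples)
    if len(samples) < 2:
        raise UsageError("clustering requires at least two samples")
    vals = matrix.values.loc[samples].to_numpy()
    d = _pairwise_masked_euclidean(vals)
    condensed = d[np.triu_indices(len(samples), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    return link, samples


# ---------------------------------------------------------------------------
# Allele-specific state inference
# ---------------------------------------------------------------------------

def expected_af(m: int, c: int, purity: float) -> float:
    """Expected AF of an inherited het on ``m`` of ``c`` tumor copies."""
    if not (0 < purity <= 1):
        raise UsageError(f"purity must be in (0, 1], got {purity}")
    denom = purity * c + (1 - purity) * 2
    if denom == 0:
        return 0.0
    return (purity * m + (1 - purity)) / denom


def _best_split(afs: np.ndarray, cn: int, purity: float) -> tuple[tuple[int, int], np.ndarray]:
    """Infer the (count_a, count_b) split of total copy number that best
    explains the observed het AFs; returns the split and the per-variant
    allele assignment (0 = allele a, 1 = allele b)."""
    best = None
    for a in range((cn + 1) // 2, cn + 1):  # canonical: a >= b
        b = cn - a
        centers = np.array([expected_af(a, cn, purity), expected_af(b, cn, purity)])
        dist = np.abs(afs[:, None] - centers[None, :])
        assign = dist.argmin(axis=1)
        sse = float((dist[np.arange(len(afs)), assign] ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, (a, b), assign)
    return best[1], best[2]


def infer_allele_state_pair(
    afs_1: np.ndarray,
    afs_2: np.ndarray,
    cn_1: int,
    cn_2: int,
    purity_1: float = 1.0,
    purity_2: float = 1.0,
    locus: tuple[str, int, int] = ("chr?", 0, 1),
    samples: tuple[str, str] = ("sample1", "sample2"),
    min_vote: float = 0.9,
    min_variants: int = 10,
):
    """Jointly infer allele-specific copy states for two samples at one locus.

    ``afs_1``/``afs_2`` are AFs of the same inherited het variants in the two
    samples.  Each sample's AFs are assigned to the two expected cluster
    levels of the best copy-number split; each variant then votes on whether
    the major allele of sample 1 is the major allele of sample 2.  The
    majority orientation is returned with its vote fraction; below
    ``min_vote`` no call is made.

    Returns ``(state_1, state_2, concordant, vote_fraction)`` where
    ``concordant`` means allele A (major in sample 1) is the major/retained
    allele in sample 2.
    """
    afs_1 = np.asarray(afs_1, dtype=float)
    afs_2 = np.asarray(afs_2, dtype=float)
    if len(afs_1) != len(afs_2):
        raise UsageError("AF vectors must be paired per variant")
    if len(afs_1) < min_variants:
        raise UsageError(f"need >= {min_variants} inherited het variants, got {len(afs_1)}")

    split_1, assign_1 = _best_split(afs_1, cn_1, purity_1)
    split_2, assign_2 = _best_split(afs_2, cn_2, purity_2)

    # uninformative variants: both alleles at equal count in a sample, or AF
    # sitting in the het band (0.4, 0.6) at an LOH locus, carry no signal
    informative = np.ones(len(afs_1), dtype=bool)
    if split_1[0] == split_1[1]:
        informative[:] = False
    if split_2[0] == split_2[1]:
        informative[:] = False
    if split_1[1] == 0:  # LOH in sample 1
        informative &= ~((afs_1 > 0.4) & (afs_1 < 0.6))
    if split_2[1] == 0:
        informative &= ~((afs_2 > 0.4) & (afs_2 < 0.6))
    if not informative.any():
        raise AmbiguousStateError("no informative variants for allele orientation")

    same = assign_1[informative] == assign_2[informative]
    n_same = int(same.sum())
    n = int(informative.sum())
    concordant = n_same * 2 >= n
    vote_fraction = max(n_same, n - n_same) / n
    if vote_fraction < min_vote:
        raise AmbiguousStateError(
            f"allele orientation vote {vote_fraction:.2f} below {min_vote}"
        )

    state_1 = AlleleSpecificState(samples[0], locus, split_1[0], split_1[1])
    cb = split_2 if concordant else (split_2[1], split_2[0])
    state_2 = AlleleSpecificState(samples[1], locus, cb[0], cb[1])
    return state_1, state_2, concordant, vote_fraction


def reachable(x: AlleleSpecificState, y: AlleleSpecificState) -> bool:
    """True iff state ``y`` is reachable from ``x`` by copy-count changes
    without resurrecting an allele from count 0."""
    if x.locus != y.locus:
        raise UsageError("states at different loci are not comparable")
    return (x.count_a > 0 or y.count_a == 0) and (x.count_b > 0 or y.count_b == 0)


def order_allele_states(x: AlleleSpecificState, y: AlleleSpecificState) -> Order:
    """Partial time-order of two allele states under the no-resurrection rule."""
    fwd, back = reachable(x, y), reachable(y, x)
    if (x.count_a, x.count_b) == (y.count_a, y.count_b):
        return Order.EQUAL
    if fwd and not back:
        return Order.PRECEDES
    if back and not fwd:
        return Order.FOLLOWS
    return Order.INCOMPARABLE


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def _shared_event_count(vals: np.ndarray, deviation: float) -> int:
    """Count contiguous bin runs where every member deviates beyond the
    threshold in the same direction (NaN bins break runs)."""
    up = np.nanmin(vals, axis=0) > deviation
    down = np.nanmax(vals, axis=0) < -deviation
    any_nan = np.isnan(vals).any(axis=0)
    co = (up | down) & ~any_nan
    sign = np.where(up, 1, np.where(down, -1, 0))
    events = 0
    prev = 0
    for c, s in zip(co, sign):
        cur = s if c else 0
        if cur != 0 and cur != prev:
            events += 1
        prev = cur
    return events


def assign_groups(
    matrix: CnvProfileMatrix,
    shared_event_min: int = 2,
    deviation: float = 0.3,
) -> dict[str, str]:
    """Cut the UPGMA dendrogram at the largest merge-height gap and keep
    clusters sharing discrete CNV events as groups.

    A cluster of >= 2 samples becomes a group iff its members co-deviate
    beyond ``deviation`` log2 (same sign) in bins forming at least
    ``shared_event_min`` contiguous events.  Everything else is ``ungrouped``.
    """
    samples = sorted(matrix.samples)
    if len(samples) < 2:
        return {s: "ungrouped" for s in samples}
    link, samples = cluster_profiles(matrix)
    heights = link[:, 2]
    if len(heights) == 1 or heights.max() == 0:
        labels = np.ones(len(samples), dtype=int)
    else:
        gaps = np.diff(np.concatenate([[0.0], np.sort(heights)]))
        k = int(np.argmax(gaps))
        cut = (np.sort(heights)[k - 1] if k > 0 else 0.0) + gaps[k] / 2
        labels = hierarchy.fcluster(link, t=cut, criterion="distance")

    vals = matrix.values.loc[samples].to_numpy()
    out: dict[str, str] = {}
    gid = 0
    for lab in sorted(set(labels), key=lambda l: min(s for s, x in zip(samples, labels) if x == l)):
        members = [s for s, x in zip(samples, labels) if x == lab]
        rows = vals[[samples.index(s) for s in members]]
        if len(members) >= 2 and _shared_event_count(rows, deviation) >= shared_event_min:
            gid += 1
            for s in members:
                out[s] = f"G{gid}"
        else:
            for s in members:
                out[s] = "ungrouped"
    return out
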