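"""Read joint multi-sample VCFs, apply quality filters, and call somatic
variants against matched normals.

The canonical in-memory container is :class:`MultiSampleVariantTable`: a
column-oriented table of variant records with per-sample depth, alternate
read count and allele fraction (AF).  Somatic status is decided by the
two-normal rule: a variant is somatic iff in *every* normal sample its AF is
below 0.1 or its alternate read count is below five — i.e. the variant is
effectively absent from the germline.

Coordinates: VCF positions are 1-based; region masks are 0-based half-open
(BED convention).  Conversion happens at the mask boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from metastrack.errors import ConfigurationError, FormatError, UsageError

logger = logging.getLogger(__name__)

SOMATIC = "somatic"
INHERITED = "inherited"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# Region masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMask:
    """A set of genomic intervals with keep-inside or keep-outside polarity.

    Intervals are 0-based half-open and are normalized (sorted, merged) at
    construction, so membership queries are binary searches.
    """

    intervals: dict[str, np.ndarray]  # chrom -> (k, 2) array of [start, end)
    keep_inside: bool = True

    @classmethod
    def from_intervals(
        cls, intervals: list[tuple[str, int, int]], keep_inside: bool = True
    ) -> "RegionMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise UsageError(f"mask interval with start >= end: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(intervals=merged, keep_inside=keep_inside)

    @classmethod
    def from_bed(cls, path, keep_inside: bool = True) -> "RegionMask":
        """Load a 3+ column BED file (0-based half-open)."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        return cls.from_intervals(list(df.itertuples(index=False, name=None)), keep_inside)

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Vectorized interval membership for 0-based positions."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        for c in np.unique(chrom):
            ivs = self.intervals.get(str(c))
            sel = chrom == c
            if ivs is None or not sel.any():
                continue
            idx = np.searchsorted(ivs[:, 0], pos0[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = pos0[sel][ok] < ivs[idx[ok], 1]
            out[sel] = hit
        return out

    def keeps(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        inside = self.contains(chrom, pos0)
        return inside if self.keep_inside else ~inside


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

@dataclass
class MultiSampleVariantTable:
    """Variants x samples with depth, alternate count and allele fraction.

    ``af`` is NaN wherever depth is zero (AF undefined).  ``somatic_status``
    is None until :func:`call_somatic` runs; afterwards each record is one of
    ``somatic`` / ``inherited`` / ``indeterminate``.
    """

    chrom: np.ndarray            # (n,) object
    pos: np.ndarray              # (n,) int64, 1-based
    ref: np.ndarray              # (n,) object
    alt: np.ndarray              # (n,) object
    qual: np.ndarray             # (n,) float
    multiallelic: np.ndarray     # (n,) bool
    samples: list[str]
    normal_samples: list[str]
    depth: np.ndarray            # (n, s) int
    alt_count: np.ndarray        # (n, s) int
    somatic_status: np.ndarray | None = None  # (n,) object or None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alt_count.shape != self.depth.shape:
            raise UsageError("depth and alt_count shapes differ")
        if (self.alt_count > self.depth).any():
            raise FormatError("alt_count exceeds depth")

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def af(self) -> np.ndarray:
        """(n, s) allele fractions; NaN where depth is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.alt_count / self.depth
        out[self.depth == 0] = np.nan
        return out

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.samples if s not in self.normal_samples]

    @property
    def somatic_flags(self) -> np.ndarray:
        if self.somatic_status is None:
            raise UsageError("call_somatic has not been run")
        return self.somatic_status == SOMATIC

    def sample_index(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([idx[n] for n in names], dtype=int)
        except KeyError as e:
            raise ConfigurationError(f"unknown sample {e.args[0]!r}") from None

    def subset(self, mask: np.ndarray) -> "MultiSampleVariantTable":
        """Row subset preserving sample order and somatic status."""
        status = None if self.somatic_status is None else self.somatic_status[mask]
        return replace(
            self,
            chrom=self.chrom[mask], pos=self.pos[mask], ref=self.ref[mask],
            alt=self.alt[mask], qual=self.qual[mask],
            multiallelic=self.multiallelic[mask],
            depth=self.depth[mask], alt_count=self.alt_count[mask],
            somatic_status=status,
        )

    # -- round-trippable TSV ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "chrom": self.chrom, "pos": self.pos, "ref": self.ref,
            "alt": self.alt, "qual": self.qual,
            "multiallelic": self.multiallelic.astype(int),
        }
        af = self.af
        for j, s in enumerate(self.samples):
            cols[f"{s}.DP"] = self.depth[:, j]
            cols[f"{s}.AD"] = self.alt_count[:, j]
            cols[f"{s}.AF"] = np.round(af[:, j], 6)
        if self.somatic_status is not None:
            cols["somatic_status"] = self.somatic_status
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"#normals={','.join(self.normal_samples)}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MultiSampleVariantTable":
        with open(path) as fh:
            header = fh.readline().strip()
            normals = header.split("=", 1)[1].split(",") if "=" in header else []
            normals = [n for n in normals if n]
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        samples = [c[:-3] for c in df.columns if c.endswith(".DP")]
        depth = df[[f"{s}.DP" for s in samples]].to_numpy(dtype=int)
        alt_count = df[[f"{s}.AD" for s in samples]].to_numpy(dtype=int)
        status = (
            df["somatic_status"].to_numpy(dtype=object)
            if "somatic_status" in df.columns else None
        )
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            ref=df["ref"].to_numpy(dtype=object),
            alt=df["alt"].to_numpy(dtype=object),
            qual=df["qual"].to_numpy(dtype=float),
            multiallelic=df["multiallelic"].to_numpy(dtype=bool),
            samples=samples, normal_samples=normals,
            depth=depth, alt_count=alt_count, somatic_status=status,
        )


# ---------------------------------------------------------------------------
# VCF loading
# ---------------------------------------------------------------------------

def load_vcf(path, normal_names: list[str]) -> MultiSampleVariantTable:
    """Load a joint multi-sample VCF into a variant table.

    Per-sample alternate counts come from FORMAT/AD (preferred) or from
    AO/RO-style counts; depth from FORMAT/DP or the AD row sum.  Multi-allelic
    sites are retained but flagged for removal at filter time.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for n in normal_names:
        if n not in samples:
            raise ConfigurationError(f"normal sample {n!r} not present in VCF")

    chroms, poss, refs, alts, quals, multi = [], [], [], [], [], []
    depths, alt_counts = [], []
    for v in vcf:
        n_alt = len(v.ALT)
        ad = v.format("AD")
        if ad is not None:
            ad = np.asarray(ad, dtype=float)
            ad[ad < 0] = 0  # cyvcf2 encodes missing as large negatives
            alt_c = ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples))
            dp = v.format("DP")
            dp = ad.sum(axis=1) if dp is None else np.asarray(dp, dtype=float).ravel()
        else:
            ao, ro = v.format("AO"), v.format("RO")
            if ao is None or ro is None:
                raise FormatError(
                    f"no AD or AO/RO fields at {v.CHROM}:{v.POS} "
                    f"(samples {samples})"
                )
            ao = np.asarray(ao, dtype=float)
            alt_c = ao[:, 0] if ao.ndim > 1 else ao.ravel()
            dp = alt_c + np.asarray(ro, dtype=float).ravel()
        dp = np.nan_to_num(dp, nan=0.0)
        dp[dp < 0] = 0
        alt_c = np.nan_to_num(alt_c, nan=0.0)
        alt_c = np.minimum(alt_c, dp)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if n_alt else ".")
        quals.append(v.QUAL if v.QUAL is not None else 0.0)
        multi.append(n_alt > 1)
        depths.append(dp.astype(int))
        alt_counts.append(alt_c.astype(int))

    n = len(poss)
    return MultiSampleVariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        multiallelic=np.asarray(multi, dtype=bool),
        samples=samples,
        normal_samples=list(normal_names),
        depth=(np.vstack(depths) if n else np.zeros((0, len(samples)), int)),
        alt_count=(np.vstack(alt_counts) if n else np.zeros((0, len(samples)), int)),
    )


# ---------------------------------------------------------------------------
# Filtering and somatic calling
# ---------------------------------------------------------------------------

def filter_variants(
    table: MultiSampleVariantTable,
    min_quality: float = 30.0,
    min_depth: int = 15,
    accessibility: RegionMask | None = None,
    lcr: RegionMask | None = None,
) -> MultiSampleVariantTable:
    """Apply joint quality filters; strict inequalities throughout.

    Retains records with site quality > ``min_quality``, depth > ``min_depth``
    in every sample, position kept by both masks, and a single alternate
    allele.  Record order is preserved; filtering is idempotent.
    """
    if min_quality < 0 or min_depth < 0:
        raise UsageError("thresholds must be non-negative")
    keep = (table.qual > min_quality) & ~table.multiallelic
    keep &= (table.depth > min_depth).all(axis=1)
    pos0 = table.pos - 1  # VCF 1-based -> mask 0-based
    if accessibility is not None:
        keep &= accessibility.keeps(table.chrom, pos0)
    if lcr is not None:
        keep &= lcr.keeps(table.chrom, pos0)
    return table.subset(keep)


def call_somatic(table: MultiSampleVariantTable) -> MultiSampleVariantTable:
    """Flag somatic variants by the two-normal absence rule.

    A record is somatic iff for *every* normal sample its AF < 0.1 or its
    alternate count < 5.  A zero-depth normal makes the record indeterminate
    (absence cannot be asserted); it is excluded from the somatic set.
    """
    if not table.normal_samples:
        raise ConfigurationError("no normal samples declared")
    ni = table.sample_index(table.normal_samples)
    n_dp = table.depth[:, ni]
    n_alt = table.alt_count[:, ni]
    with np.errstate(divide="ignore", invalid="ignore"):
        n_af = np.where(n_dp > 0, n_alt / np.maximum(n_dp, 1), np.nan)
    absent = (n_af < 0.1) | (n_alt < 5)
    indeterminate = (n_dp == 0).any(axis=1)
    somatic = absent.all(axis=1) & ~indeterminate

    status = np.full(table.n_records, INHERITED, dtype=object)
    status[somatic] = SOMATIC
    status[indeterminate] = INDETERMINATE
    n_ind = int(indeterminate.sum())
    if n_ind:
        logger.warning("%d record(s) indeterminate (zero depth in a normal)", n_ind)
    out = table.subset(np.ones(table.n_records, dtype=bool))
    out.somatic_status = status
    return out
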