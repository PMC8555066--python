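"""Expression-based CNV scores and dropout-aware variant validation.

Copy-number events leave a footprint in bulk expression: averaging
log-expression over a moving window of 101 genes (ordered by genomic
position) smooths per-gene variability, and normalizing against low-purity
normal samples leaves a score whose sign tracks amplification/deletion.

Genomic variants are validated in paired RNA-seq while accounting for
binomial sampling dropout: a variant at WGS VAF ``v`` covered by ``d``
RNA-seq reads yields zero alternate reads with probability
``P0 = (1 - v)^d``; variants whose dropout probability exceeds a cutoff are
skipped rather than called unexpressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from metastrack.errors import UsageError

logger = logging.getLogger(__name__)

VALIDATED = "validated"
VALIDATED_IN_OTHER = "validated_in_other"
SKIPPED_DROPOUT = "skipped_dropout"
NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class RnaVariantObservation:
    """One genomic variant observed in one sample's RNA-seq."""

    variant_id: str
    rna_depth: int
    rna_alt: int
    wgs_vaf: float

    def __post_init__(self):
        if self.rna_alt > self.rna_depth:
            raise UsageError("rna_alt exceeds rna_depth")

    @property
    def eligible(self) -> bool:
        return self.wgs_vaf > 0.1 and self.rna_depth >= 10


def infer_expression_cnv(
    expr: pd.DataFrame,
    gene_chrom: pd.Series,
    normal_samples: list[str],
    window: int = 101,
) -> pd.DataFrame:
    """Relative copy-number scores from a TPM matrix (genes x samples).

    ``expr`` rows must be ordered by genomic position within chromosome
    (``gene_chrom`` gives each gene's chromosome).  Per gene: log2(TPM+1),
    centered across samples, then a center-aligned moving average over
    ``window`` genes within the chromosome (truncated at the ends), then
    subtraction of the mean windowed value over the normal samples.
    Chromosomes with fewer than ``window`` genes are skipped.
    """
    if not normal_samples:
        raise UsageError("normal_samples must be nonempty")
    missing = set(normal_samples) - set(expr.columns)
    if missing:
        raise UsageError(f"unknown normal samples: {sorted(missing)}")
    log = np.log2(expr + 1.0)
    centered = log.sub(log.mean(axis=1), axis=0)
    pieces = []
    for chrom in gene_chrom.unique():
        genes = gene_chrom.index[gene_chrom == chrom]
        if len(genes) < window:
            logger.warning("chromosome %s has %d < %d genes; skipped",
                           chrom, len(genes), window)
            continue
        smoothed = (
            centered.loc[genes]
            .rolling(window, center=True, min_periods=1)
            .mean()
        )
        pieces.append(smoothed)
    if not pieces:
        return pd.DataFrame(columns=expr.columns)
    smoothed = pd.concat(pieces)
    baseline = smoothed[normal_samples].mean(axis=1)
    return smoothed.sub(baseline, axis=0)


def dropout_probability(wgs_vaf: float, rna_depth: int) -> float:
    """Probability of sampling zero alternate reads: ``(1 - vaf)^depth``."""
    if not (0 <= wgs_vaf <= 1):
        raise UsageError(f"vaf must be in [0, 1], got {wgs_vaf}")
    if rna_depth < 0:
        raise UsageError("depth must be non-negative")
    return float((1.0 - wgs_vaf) ** rna_depth)


def classify_validation(
    obs: RnaVariantObservation,
    same_variant_in_other_samples: bool,
    p0_skip: float = 0.05,
) -> str:
    """Classify an eligible RNA observation of a genomic variant.

    Any alternate read validates the variant directly; otherwise presence in
    another sample's RNA (for a sample genomically carrying the variant)
    validates it indirectly; otherwise a high dropout probability skips the
    call; what remains is unexpressed (allele-specific expression or a
    genomic false positive).
    """
    if not obs.eligible:
        raise UsageError(
            "observation ineligible (needs wgs_vaf > 0.1 and rna_depth >= 10); "
            "filter upstream"
        )
    if obs.rna_alt >= 1:
        return VALIDATED
    if same_variant_in_other_samples:
        return VALIDATED_IN_OTHER
    if dropout_probability(obs.wgs_vaf, obs.rna_depth) > p0_skip:
        return SKIPPED_DROPOUT
    return NOT_EXPRESSED
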