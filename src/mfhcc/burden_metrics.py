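"""Per-lesion burden statistics: TMB, AMP/DEL calls, CNV score, MSI status.

TMB is the count of non-silent mutations per megabase of captured coding
sequence (36 Mb for the Agilent V6 exome design).  The CNV score summarizes
exome-wide copy-number burden: the sum over altered segments of segment
length (Mb) times the segment's relative copy-number deviation from sample
ploidy, |cn − ploidy| / ploidy.  MSI-H is called when the instability score
exceeds 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .variant_model import CnvSegment, Variant, is_nonsilent, normalize_chromosome

__all__ = [
    "BurdenSummary",
    "compute_tmb",
    "call_segment_state",
    "cnv_score",
    "msi_status",
    "gene_level_cnv",
    "relative_deviation_weight",
    "DEFAULT_CDS_MB",
    "DEFAULT_MSI_THRESHOLD",
]

DEFAULT_CDS_MB = 36.0
DEFAULT_MSI_THRESHOLD = 20.0


@dataclass(frozen=True)
class BurdenSummary:
    lesion_id: str
    tmb: float
    cnv_score: float
    msi_status: str
    ploidy: float


def compute_tmb(variants: Iterable[Variant], cds_mb: float = DEFAULT_CDS_MB) -> float:
    """Non-silent mutation count normalized by the captured CDS length in Mb."""
    if cds_mb <= 0:
        raise ValueError("cds_mb must be positive")
    return sum(1 for v in variants if is_nonsilent(v.classification)) / cds_mb


def call_segment_state(total_cn: int, ploidy: float) -> str:
    """AMP if total copy number exceeds twice the ploidy, DEL if zero, else NEUTRAL."""
    if total_cn < 0:
        raise ValueError("total_cn must be non-negative")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if total_cn == 0:
        return "DEL"
    if total_cn > 2 * ploidy:
        return "AMP"
    return "NEUTRAL"


def relative_deviation_weight(total_cn: int, ploidy: float) -> float:
    """Default altered weight: relative deviation of copy number from ploidy."""
    return abs(total_cn - ploidy) / ploidy


def cnv_score(
    segments: Iterable[CnvSegment],
    ploidy: float,
    weight: Callable[[int, float], float] = relative_deviation_weight,
) -> float:
    """Sum of length(Mb) x weight over segments with copy number off the ploidy.

    Segments whose total copy number equals the rounded ploidy contribute
    zero regardless of the weight function.  Additive over segments, hence
    invariant under splitting a segment into sub-segments of equal copy
    number.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    neutral_cn = round(ploidy)
    score = 0.0
    for seg in segments:
        if seg.total_cn == neutral_cn:
            continue
        score += (seg.length / 1e6) * weight(seg.total_cn, ploidy)
    return score


def msi_status(score: float, threshold: float = DEFAULT_MSI_THRESHOLD) -> str:
    """MSI-H iff the MSI score strictly exceeds the threshold (default 20)."""
    if score < 0:
        raise ValueError("MSI score must be non-negative")
    return "MSI-H" if score > threshold else "MSS"


def gene_level_cnv(
    segments: Sequence[CnvSegment],
    ploidy: float,
    gene_intervals: Iterable[tuple[str, str, int, int]],
) -> dict[str, str]:
    """Assign each gene the AMP/DEL/NEUTRAL state of the segment covering its midpoint.

    ``gene_intervals`` are (gene, chromosome, start, end) with 1-based
    inclusive coordinates.  Genes whose midpoint no segment covers are
    NEUTRAL.  The midpoint rule gives every gene a single unambiguous call
    even when it straddles a segment boundary.
    """
    states: dict[str, str] = {}
    for gene, chrom, start, end in gene_intervals:
        if start > end:
            raise ValueError(f"gene {gene}: start {start} > end {end}")
        mid = (start + end) // 2
        chrom = normalize_chromosome(chrom)
        state = "NEUTRAL"
        for seg in segments:
            if normalize_chromosome(seg.chromosome) == chrom and seg.start <= mid <= seg.end:
                state = call_segment_state(seg.total_cn, ploidy)
                break
        states[gene] = state
    return states
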