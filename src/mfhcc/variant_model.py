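"""Data model and I/O for somatic variant, copy-number and clinical tables.

Variants arrive in MAF-style tab-separated tables (vcf2maf column dialect);
copy-number segments in FACETS-like segment tables with a per-sample JSON
sidecar carrying ploidy/purity/MSI score; clinical data in a flat CSV with
one row per patient (two lesions each).

Coordinates are 1-based inclusive throughout (MAF convention).  Variant
identity for all sharing computations is the genomic key
``(chromosome, position, ref, alt)``; gene symbol and functional
classification are annotation-dependent and deliberately excluded.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "CnvSegment",
    "LesionProfile",
    "PatientPair",
    "MafFormatError",
    "MafRowError",
    "NONSILENT_CLASSES",
    "SILENT_CLASSES",
    "is_nonsilent",
    "variant_key",
    "normalize_chromosome",
    "canonical_classification",
    "read_maf",
    "write_maf",
    "read_segments",
    "write_segments",
    "read_sample_sidecar",
    "write_sample_sidecar",
    "read_clinical",
]


class MafFormatError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


class MafRowError(ValueError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


#: The nine non-silent functional classes counted by TMB.
NONSILENT_CLASSES = frozenset(
    {
        "Splice_Site",
        "Splice_Region",
        "Missense_Mutation",
        "Nonstop_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)

#: Recognized silent / non-coding classes (everything the nine-type rule excludes).
SILENT_CLASSES = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Translation_Start_Site",
        "Targeted_Region",
    }
)

_ALLELE_CHARS = frozenset("ACGT-")


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a contig label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        return label[3:]
    return label


def canonical_classification(label: str) -> str:
    """Canonicalize a Variant_Classification label: whitespace/hyphens -> underscore."""
    return re.sub(r"[\s\-]+", "_", str(label).strip())


def is_nonsilent(classification: str) -> bool:
    """True iff *classification* is one of the nine non-silent mutation types.

    Matching is exact after underscore canonicalization ("Missense Mutation"
    and "Missense_Mutation" are the same label).  A label outside the
    recognized vocabulary returns False and logs a warning.
    """
    canon = canonical_classification(classification)
    if canon in NONSILENT_CLASSES:
        return True
    if canon not in SILENT_CLASSES:
        log.warning("unrecognized Variant_Classification %r treated as silent", classification)
    return False


@dataclass(frozen=True)
class Variant:
    """One somatic mutation; the unit of all sharing computations.

    ``position`` is 1-based.  Indels use the MAF convention: insertions have
    ``ref_allele == "-"``, deletions ``alt_allele == "-"``.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: str = ""
    classification: str = ""
    vaf: Optional[float] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"{name} allele {allele!r} not a non-empty string over ACGT-")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and "-" not in (self.ref_allele, self.alt_allele)
        )


def variant_key(v: Variant) -> tuple[str, int, str, str]:
    """Genomic identity key; two variants are "the same mutation" iff keys match."""
    return (normalize_chromosome(v.chromosome), v.position, v.ref_allele, v.alt_allele)


@dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment with 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn:
            raise ValueError("minor_cn cannot exceed total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LesionProfile:
    """Everything measured on one tumor focus."""

    patient_id: str
    lesion_id: str
    variants: list[Variant] = field(default_factory=list)
    segments: list[CnvSegment] = field(default_factory=list)
    ploidy: float = 2.0
    msi_score: float = 0.0

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.msi_score < 0:
            raise ValueError("msi_score must be non-negative")
        seen: dict[tuple, Variant] = {}
        dupes = 0
        for v in self.variants:
            k = variant_key(v)
            if k in seen:
                dupes += 1
            else:
                seen[k] = v
        if dupes:
            warnings.warn(
                f"lesion {self.lesion_id}: collapsed {dupes} duplicate variant key(s)",
                stacklevel=2,
            )
            self.variants = list(seen.values())

    def variant_keys(self) -> frozenset:
        return frozenset(variant_key(v) for v in self.variants)


@dataclass
class PatientPair:
    """Two lesion profiles from one patient plus clinical fields."""

    patient_id: str
    lesion_a: LesionProfile
    lesion_b: LesionProfile
    pfs_months: float = 0.0
    event: bool = False
    pathology_call: str = "unknown"  # {"MO", "IM", "unknown"}

    def __post_init__(self):
        if not (self.lesion_a.patient_id == self.lesion_b.patient_id == self.patient_id):
            raise ValueError("both lesions must belong to the pair's patient")
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be non-negative")
        if self.pathology_call not in ("MO", "IM", "unknown"):
            raise ValueError(f"pathology_call must be MO/IM/unknown, got {self.pathology_call!r}")


# ---------------------------------------------------------------------------
# MAF I/O

REQUIRED_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)


def read_maf(path) -> dict[str, list[Variant]]:
    """Read a vcf2maf-dialect MAF, returning variants grouped by sample barcode.

    Rows are preserved verbatim (no filtering, no deduplication); VAF is
    derived from ``t_alt_count / t_depth`` when both columns are present.
    Groups appear in order of first occurrence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [col for col in REQUIRED_MAF_COLUMNS if col not in df.columns]
    if missing:
        raise MafFormatError(f"{path.name}: missing required column(s) {', '.join(missing)}")
    has_depth = "t_depth" in df.columns and "t_alt_count" in df.columns
    groups: dict[str, list[Variant]] = {}
    # +2: one for the header line, one for 1-based numbering
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            position = int(row["Start_Position"])
        except (TypeError, ValueError):
            raise MafRowError(
                f"unparseable Start_Position {row['Start_Position']!r}", lineno=i
            ) from None
        vaf = None
        if has_depth:
            try:
                depth = float(row["t_depth"])
                alt = float(row["t_alt_count"])
                if depth > 0:
                    vaf = min(1.0, alt / depth)
            except (TypeError, ValueError):
                vaf = None
        try:
            v = Variant(
                chromosome=row["Chromosome"],
                position=position,
                ref_allele=row["Reference_Allele"],
                alt_allele=row["Tumor_Seq_Allele2"],
                gene=row["Hugo_Symbol"],
                classification=row["Variant_Classification"],
                vaf=vaf,
            )
        except ValueError as exc:
            raise MafRowError(str(exc), lineno=i) from None
        groups.setdefault(row["Tumor_Sample_Barcode"], []).append(v)
    return groups


def write_maf(groups: Mapping[str, Sequence[Variant]], path) -> None:
    """Write grouped variants back to the MAF dialect read by :func:`read_maf`."""
    rows = []
    for sample, variants in groups.items():
        for v in variants:
            rows.append(
                {
                    "Hugo_Symbol": v.gene,
                    "Chromosome": v.chromosome,
                    "Start_Position": v.position,
                    "Reference_Allele": v.ref_allele,
                    "Tumor_Seq_Allele2": v.alt_allele,
                    "Variant_Classification": v.classification,
                    "Tumor_Sample_Barcode": sample,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_MAF_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segment-table and sidecar I/O (FACETS-like dialect)

SEGMENT_COLUMNS = ("chrom", "start", "end", "tcn", "lcn")


def read_segments(path) -> list[CnvSegment]:
    """Read a tab-separated segment table (chrom, start, end, tcn, lcn)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"{path.name}: missing required column {col!r}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments.append(
                CnvSegment(
                    chromosome=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    total_cn=int(row.tcn),
                    minor_cn=int(row.lcn),
                )
            )
        except ValueError as exc:
            raise MafRowError(str(exc), lineno=i) from None
    return segments


def write_segments(segments: Iterable[CnvSegment], path) -> None:
    rows = [
        {"chrom": s.chromosome, "start": s.start, "end": s.end, "tcn": s.total_cn, "lcn": s.minor_cn}
        for s in segments
    ]
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_sample_sidecar(path) -> dict:
    """Read the per-sample JSON sidecar (ploidy, purity, msi_score)."""
    with open(path) as fh:
        meta = json.load(fh)
    if "ploidy" not in meta:
        raise MafFormatError(f"{Path(path).name}: sidecar missing 'ploidy'")
    return meta


def write_sample_sidecar(meta: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(meta), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Clinical table

CLINICAL_COLUMNS = (
    "patient_id",
    "lesion_a_id",
    "lesion_b_id",
    "pfs_months",
    "event",
    "pathology_call",
)


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical CSV; validates columns and value domains."""
    df = pd.read_csv(path, dtype={"patient_id": str, "lesion_a_id": str, "lesion_b_id": str})
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"{Path(path).name}: missing required column {col!r}")
    if (df["pfs_months"] < 0).any():
        raise ValueError("pfs_months must be non-negative")
    bad = set(df["pathology_call"].astype(str)) - {"MO", "IM", "unknown"}
    if bad:
        raise ValueError(f"invalid pathology_call value(s): {sorted(bad)}")
    df["event"] = df["event"].astype(bool)
    return df
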