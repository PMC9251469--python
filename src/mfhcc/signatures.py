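"""Trinucleotide mutation spectra and signature-exposure fitting.

Single-nucleotide variants are binned into 96 classes: six pyrimidine-based
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) times the 4 x 4 flanking-base
combinations.  SNVs whose reference base is a purine are reverse-complemented
first (pyrimidine convention), so strand representation never matters.

A sample spectrum is expressed as a non-negative mixture of 30 reference
signatures by constrained least squares: minimize ||p - S e||_2 with e >= 0,
zero exposures below ``min_exposure`` (default 0.06), refit on the surviving
support, and renormalize to proportions.  Exposures are reduced for reporting
to the groups {sig1, sig3, sig6, sig10, others}.

The bundled matrix ``data/signatures_synthetic_v1.tsv`` is a SYNTHETIC
30-signature reference built by :func:`synthetic_signature_matrix`: it mimics
the structure of the COSMIC v2 catalogue (sig1 = CpG C>T deamination,
sig3 = near-flat, sig6 = broad C>T, sig10 = T[C>A]T-dominated; the rest are
sparse random spectra) but its numeric entries are generated, not measured.
Every fitting routine accepts any 96 x K probability matrix in its place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variant_model import Variant, normalize_chromosome

__all__ = [
    "CONTEXT_LABELS",
    "SUBSTITUTIONS",
    "ExposureVector",
    "trinucleotide_context",
    "build_context_vector",
    "fit_signatures",
    "reduce_exposures",
    "load_signature_matrix",
    "synthetic_signature_matrix",
    "DEFAULT_MIN_EXPOSURE",
    "DEFAULT_NAMED_SIGNATURES",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Fixed 96-context ordering: substitution-major, then 5' base, then 3' base.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}

DEFAULT_MIN_EXPOSURE = 0.06
DEFAULT_NAMED_SIGNATURES = (1, 3, 6, 10)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class NotAnSnvError(ValueError):
    """The variant is not a single-nucleotide substitution."""


class ReferenceMismatchError(ValueError):
    """The variant's ref allele disagrees with the reference sequence."""


def _fetch_triplet(reference, chromosome: str, position: int) -> str:
    """Reference bases at position-1 .. position+1 (1-based), uppercased.

    ``reference`` is a mapping of contig name to sliceable sequence
    (a :class:`pyfaidx.Fasta` or a plain dict of strings); contig lookup
    tolerates a chr prefix on either side.
    """
    wanted = normalize_chromosome(chromosome)
    contig = None
    for name in (chromosome, wanted, f"chr{wanted}"):
        try:
            contig = reference[name]
            break
        except KeyError:
            continue
    if contig is None:
        raise KeyError(f"contig {chromosome!r} not in reference")
    if position < 2 or position + 1 > len(contig):
        raise ValueError(f"position {position} too close to the contig edge for a triplet")
    return str(contig[position - 2 : position + 1]).upper()


def trinucleotide_context(v: Variant, reference) -> str:
    """96-class context label "X[R>A]Y" for an SNV, pyrimidine convention."""
    if not v.is_snv:
        raise NotAnSnvError(f"{v.ref_allele}>{v.alt_allele} is not a single-base substitution")
    triplet = _fetch_triplet(reference, v.chromosome, v.position)
    if triplet[1] != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.chromosome}:{v.position} reference base {triplet[1]} != ref allele {v.ref_allele}"
        )
    ref, alt = v.ref_allele, v.alt_allele
    if ref in ("A", "G"):  # purine: flip to the pyrimidine strand
        triplet = _revcomp(triplet)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"
    assert label in _CONTEXT_INDEX
    return label


def build_context_vector(snvs: Iterable[Variant], reference) -> np.ndarray:
    """Counts over the 96 contexts; the total equals the number of SNVs."""
    counts = np.zeros(96, dtype=np.int64)
    for v in snvs:
        counts[_CONTEXT_INDEX[trinucleotide_context(v, reference)]] += 1
    return counts


# ---------------------------------------------------------------------------
# Reference signature matrix


def synthetic_signature_matrix(n_signatures: int = 30, seed: int = 20220620) -> pd.DataFrame:
    """Deterministic synthetic stand-in for a 96 x 30 reference catalogue.

    Signatures 1, 3, 6 and 10 are given the qualitative structure their
    COSMIC namesakes are known for; the remaining columns are sparse random
    spectra.  Columns are probability vectors (sum 1).
    """
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.full(96, 0.15), size=n_signatures).T  # 96 x K

    def _peaks(pairs: Mapping[str, float], floor: float = 0.001) -> np.ndarray:
        col = np.full(96, floor)
        for label, mass in pairs.items():
            col[_CONTEXT_INDEX[label]] += mass
        return col / col.sum()

    # sig1: C>T at CpG sites (5-methylcytosine deamination)
    mat[:, 0] = _peaks({f"{b}[C>T]G": 0.2 for b in _BASES})
    # sig3: near-featureless flat spectrum
    mat[:, 2] = np.full(96, 1.0 / 96)
    # sig6: broad C>T with G-5' preference
    mat[:, 5] = _peaks(
        {f"G[C>T]{b}": 0.12 for b in _BASES} | {f"{b}[C>T]A": 0.05 for b in _BASES},
        floor=0.002,
    )
    # sig10: T[C>A]T / T[C>T]T dominated (POLE-like)
    mat[:, 9] = _peaks({"T[C>A]T": 0.45, "T[C>T]T": 0.3}, floor=0.002)

    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        mat,
        index=list(CONTEXT_LABELS),
        columns=[f"Signature.{k}" for k in range(1, n_signatures + 1)],
    )


def load_signature_matrix(path=None) -> pd.DataFrame:
    """Load a 96 x K signature TSV (rows = context labels, columns = signatures).

    With no path, loads the bundled synthetic reference catalogue.  Rows are
    reindexed to the canonical context order; column sums are validated.
    """
    if path is None:
        with resources.as_file(
            resources.files("mfhcc").joinpath("data/signatures_synthetic_v1.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} context rows")
    df = df.loc[list(CONTEXT_LABELS)]
    sums = df.to_numpy().sum(axis=0)
    if (df.to_numpy() < 0).any() or not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must be non-negative and sum to 1 (within 1e-6)")
    return df


# ---------------------------------------------------------------------------
# Exposure fitting


@dataclass(frozen=True)
class ExposureVector:
    """Per-sample signature exposures (proportions summing to 1) plus fit residual."""

    exposures: pd.Series  # indexed by signature column name
    residual: float

    def nonzero(self) -> pd.Series:
        return self.exposures[self.exposures > 0]


def fit_signatures(
    context_counts: np.ndarray,
    signature_matrix: pd.DataFrame,
    min_exposure: float = DEFAULT_MIN_EXPOSURE,
) -> ExposureVector:
    """Non-negative least-squares exposure fit with a minimum-exposure cutoff.

    The spectrum is normalized to proportions p, exposures solve
    min ||p - S e||_2 s.t. e >= 0; exposures below ``min_exposure`` (after
    normalization) are zeroed and the fit repeated on the surviving
    signatures, so lowering the cutoff can only enlarge the support and
    never worsens the residual.  Deterministic for fixed input.
    """
    counts = np.asarray(context_counts, dtype=float).ravel()
    if counts.shape != (96,):
        raise ValueError(f"expected a 96-vector of context counts, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot fit signatures to an all-zero context vector")
    if not (0.0 <= min_exposure < 1.0):
        raise ValueError("min_exposure must lie in [0, 1)")
    p = counts / total
    S = signature_matrix.to_numpy(dtype=float)

    e, _ = nnls(S, p)
    if e.sum() == 0:
        raise ValueError("degenerate fit: all exposures zero")
    props = e / e.sum()
    support = props >= min_exposure
    if not support.any():
        support[int(np.argmax(props))] = True

    e2 = np.zeros_like(e)
    e2[support], residual = nnls(S[:, support], p)
    if e2.sum() == 0:  # pathological; fall back to the unthresholded fit
        e2, residual = e, float(np.linalg.norm(p - S @ e))
    exposures = pd.Series(e2 / e2.sum(), index=signature_matrix.columns)
    return ExposureVector(exposures=exposures, residual=float(residual))


def reduce_exposures(
    exposure: ExposureVector | pd.Series,
    named: Sequence[int] = DEFAULT_NAMED_SIGNATURES,
) -> pd.Series:
    """Collapse exposures to named signature groups plus "others" (sum preserved)."""
    series = exposure.exposures if isinstance(exposure, ExposureVector) else exposure
    groups = {f"sig{k}": 0.0 for k in named}
    groups["others"] = 0.0
    named_cols = {f"Signature.{k}": f"sig{k}" for k in named}
    for col, value in series.items():
        groups[named_cols.get(str(col), "others")] += float(value)
    return pd.Series(groups)
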