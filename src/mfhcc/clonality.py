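"""Tumor-pair clonality: Jaccard index, MO/IM call, trunk/private partition, pair tree.

Two lesions descended from one clone (intrahepatic metastasis, IM) share a
trunk of somatic mutations acquired before divergence; independent primaries
(multicentric occurrence, MO) share essentially none.  The classifier is the
Jaccard index of the two lesions' variant-key sets with a decision threshold
of 0.01: sub-threshold sharing is called MO, otherwise IM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Sequence

import pandas as pd

__all__ = [
    "ClonalityResult",
    "PairTree",
    "jaccard_index",
    "classify_pair",
    "shared_private_partition",
    "build_pair_tree",
    "classify_sets",
    "results_to_frame",
    "DEFAULT_JACCARD_THRESHOLD",
]

DEFAULT_JACCARD_THRESHOLD = 0.01


def jaccard_index(set_a: AbstractSet, set_b: AbstractSet) -> float:
    """|A∩B| / |A∪B| over variant keys; symmetric, exact ratio.

    Raises ValueError when both sets are empty (the index, and hence the
    clonality call, is undefined).
    """
    a, b = frozenset(set_a), frozenset(set_b)
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard index undefined: both variant sets are empty")
    return len(a & b) / union


def classify_pair(j: float, threshold: float = DEFAULT_JACCARD_THRESHOLD) -> str:
    """Call a pair MO (j < threshold) or IM (j >= threshold).

    Equality at the threshold is called IM so the better-prognosis MO label
    requires strictly sub-threshold sharing.
    """
    if not (0.0 <= j <= 1.0):
        raise ValueError(f"Jaccard index must lie in [0, 1], got {j}")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return "MO" if j < threshold else "IM"


def shared_private_partition(
    set_a: AbstractSet, set_b: AbstractSet
) -> tuple[frozenset, frozenset, frozenset]:
    """Partition A∪B into (shared, private to A, private to B)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return a & b, a - b, b - a


@dataclass(frozen=True)
class ClonalityResult:
    """Per-patient clonality call with the counts behind it."""

    patient_id: str
    jaccard: float
    n_shared: int
    n_private_a: int
    n_private_b: int
    call: str

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_private_a + self.n_private_b

    @property
    def shared_percent(self) -> float:
        """Shared mutations as a percentage of the union."""
        return 100.0 * self.n_shared / self.n_union if self.n_union else 0.0


def classify_sets(
    patient_id: str,
    set_a: AbstractSet,
    set_b: AbstractSet,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> ClonalityResult:
    """Full classification of one pair from its two variant-key sets."""
    shared, priv_a, priv_b = shared_private_partition(set_a, set_b)
    j = jaccard_index(set_a, set_b)
    return ClonalityResult(
        patient_id=patient_id,
        jaccard=j,
        n_shared=len(shared),
        n_private_a=len(priv_a),
        n_private_b=len(priv_b),
        call=classify_pair(j, threshold),
    )


@dataclass(frozen=True)
class PairTree:
    """Rooted three-taxon tree (Normal, (A, B)) with mutation-count branch lengths.

    The trunk branch carries the shared mutations (acquired before the two
    lesions diverged); each leaf branch carries that lesion's private
    mutations.  ``trunk_genes`` lists gene symbols mutated on the trunk —
    candidate early drivers.
    """

    trunk_length: int
    branch_a_length: int
    branch_b_length: int
    label_a: str = "A"
    label_b: str = "B"
    trunk_genes: tuple[str, ...] = ()

    @property
    def newick(self) -> str:
        return (
            f"(Normal:0,({self.label_a}:{self.branch_a_length},"
            f"{self.label_b}:{self.branch_b_length}):{self.trunk_length});"
        )

    @property
    def total_mutations(self) -> int:
        return self.trunk_length + self.branch_a_length + self.branch_b_length


def build_pair_tree(
    result: ClonalityResult,
    label_a: str = "A",
    label_b: str = "B",
    trunk_genes: Iterable[str] = (),
) -> PairTree:
    """Construct the (combinatorially determined) two-lesion pair tree."""
    return PairTree(
        trunk_length=result.n_shared,
        branch_a_length=result.n_private_a,
        branch_b_length=result.n_private_b,
        label_a=label_a,
        label_b=label_b,
        trunk_genes=tuple(trunk_genes),
    )


def results_to_frame(results: Sequence[ClonalityResult]) -> pd.DataFrame:
    """Tabulate clonality results for the per-patient TSV output."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_shared": r.n_shared,
                "n_private_a": r.n_private_a,
                "n_private_b": r.n_private_b,
                "n_union": r.n_union,
                "jaccard": r.jaccard,
                "call": r.call,
            }
            for r in results
        ]
    )
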