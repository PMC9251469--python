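"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, exact integer
arithmetic, direct definitions) and shares no code path with the package.
"""

from __future__ import annotations

from math import comb


def jaccard_brute_force(set_a, set_b) -> float:
    """Double-loop intersection / union count, no set algebra."""
    a, b = list(set_a), list(set_b)
    inter = sum(1 for x in a if any(x == y for y in b))
    union_items = list(a)
    for y in b:
        if not any(y == x for x in a):
            union_items.append(y)
    return inter / len(union_items)


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    All tables with the observed margins are enumerated; those no more
    probable than the observed one (integer comparison of the shared-
    denominator numerators, so ties are exact) contribute to p.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    n_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        n_k = comb(r1, k) * comb(r2, c1 - k)
        if n_k <= n_obs:
            total += n_k
    return total / comb(n, c1)


def reverse_complement(seq: str) -> str:
    """Independent complementation via str.translate."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def segment_score_per_base(segments, ploidy) -> float:
    """CNV score by per-base summation (slow, definitionally additive)."""
    total = 0.0
    for seg in segments:
        if seg.total_cn == round(ploidy):
            continue
        w = abs(seg.total_cn - ploidy) / ploidy
        for _ in range(seg.start, seg.end + 1):
            total += w / 1e6
    return total
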