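"""Reproducibility utilities: pathway-set overlap test and top-k rank overlap."""

from __future__ import annotations

from scipy import stats

__all__ = ["overlap_p", "topk_overlap"]


def overlap_p(universe: int, size_a: int, size_b: int, overlap: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for the intersection of two
    sets of sizes ``size_a`` and ``size_b`` drawn from ``universe`` items."""
    if not (0 <= overlap <= min(size_a, size_b) and max(size_a, size_b) <= universe):
        raise ValueError("impossible overlap arguments")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def topk_overlap(ranked_a, ranked_b, k: int) -> float:
    """|top-k(A) ∩ top-k(B)| / k for two ranked lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    return len(set(ranked_a[:k]) & set(ranked_b[:k])) / k
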