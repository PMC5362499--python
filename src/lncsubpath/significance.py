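"""Permutation significance of subpathway regions.

Observed scores are means of RAW (unnormalised) quantities over the region:
node score = mean w_v; edge score = mean differentiality 1 - w_e = |dCor|
(large = dysregulated at both levels, so one right tail serves both).
Null scores are means of size-matched draws without replacement from
background pools: all PCGs associated with >=1 risk lncRNA (nodes) and all
edges from all pathways in the run (edges). P = #(S_rand >= S_obs) / R; its
resolution is exactly 1/R and a reported 0 means "< 1/R".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .weighting import WeightedPathway

__all__ = [
    "SubpathwayResult",
    "observed_scores",
    "permutation_p",
    "joint_p",
    "adjust",
    "report",
]


@dataclass
class SubpathwayResult:
    """One scored subpathway region."""

    pathway_id: str
    region_id: str
    nodes: tuple
    edges: tuple
    s_obs_node: float
    s_obs_edge: float | None
    p_node: float
    p_edge: float
    p_joint: float
    p_adjusted: float = float("nan")
    randomizations: int = 0
    lncrnas: tuple = ()
    key_lncrnas: tuple = ()
    importance: dict = field(default_factory=dict)


def observed_scores(nodes, edges, wp: WeightedPathway):
    """(mean raw node weight, mean edge differentiality) for a region; the
    edge score is None for edgeless regions (their edge-level P is 1)."""
    nodes = list(nodes)
    s_node = float(np.mean([wp.node_raw.get(v, 0.0) for v in nodes]))
    edges = list(edges)
    if not edges:
        return s_node, None
    s_edge = float(np.mean([1.0 - wp.edge_raw[frozenset(e)] for e in edges]))
    return s_node, s_edge


def permutation_p(
    s_obs: float | None,
    pool,
    k: int,
    randomizations: int = 1000,
    rng=None,
    strict_tail: bool = False,
    add_one: bool = False,
) -> float:
    """Permutation P for an observed mean against a background pool.

    Each randomization draws ``k`` pool values without replacement (with
    replacement, with a warning, when the pool is smaller than k) and takes
    their mean. ``strict_tail`` counts S_rand > S_obs instead of >=;
    ``add_one`` computes (count + 1) / (R + 1).
    """
    if s_obs is None:
        return 1.0
    if s_obs == -np.inf:
        return 1.0
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        return 1.0
    rng = np.random.default_rng(rng)
    R = int(randomizations)
    if R < 1:
        raise ValueError("need at least one randomization")
    replace = pool.size < k
    if replace:
        warnings.warn(
            f"background pool ({pool.size}) smaller than region size ({k}); "
            "sampling with replacement",
            RuntimeWarning,
            stacklevel=2,
        )
        draws = rng.integers(0, pool.size, size=(R, k))
    else:
        # vectorised k-subset sampling: first k of a random permutation per row
        keys = rng.random((R, pool.size))
        draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
    s_rand = pool[draws].mean(axis=1)
    count = int((s_rand > s_obs).sum() if strict_tail else (s_rand >= s_obs).sum())
    if add_one:
        return (count + 1) / (R + 1)
    return count / R


def joint_p(p_node: float, p_edge: float) -> float:
    """Product of the node- and edge-level P values, clamped to [0, 1]."""
    return float(min(max(p_node * p_edge, 0.0), 1.0))


def adjust(results, method: str = "bh"):
    """Fill ``p_adjusted`` across subpathways (BH default, 'bonferroni'
    optional). Returns the same list."""
    if not results:
        return results
    pvals = [r.p_joint for r in results]
    mm = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    padj = multipletests(pvals, method=mm)[1]
    for r, p in zip(results, padj):
        r.p_adjusted = float(p)
    return results


def report(results, require_lncrna: bool = True):
    """Final ordering: keep regions with >=1 associated risk lncRNA (unless
    disabled), sort by adjusted P, then joint P, then pathway/region id."""
    kept = [r for r in results if r.lncrnas or not require_lncrna]
    return sorted(kept, key=lambda r: (r.p_adjusted, r.p_joint, r.pathway_id, r.region_id))
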