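"""Key-lncRNA identification for one subpathway region.

Each associated lncRNA gets an importance score mixing its own differential
expression with a topology term over the region PCGs it is associated with:

    IS = gamma * |log2FC_L| + (1 - gamma) * sum_j d_LGj * D_Gj

where D_Gj is the degree of gene Gj inside the region's induced subgraph and
d_LGj = 1 + |r_case - r_control| is the correlation shift. The core set is
grown greedily down the IS ranking: a candidate is kept only when it strictly
increases the fraction q of region PCGs covered by the core set; the walk
stops once q >= pert. Rejected candidates are discarded permanently (single
pass).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LncImportance", "importance_score", "rank_lncrnas", "select_key_lncrnas"]


@dataclass(frozen=True)
class LncImportance:
    lncrna: str
    score: float
    abs_log2fc: float
    covered: frozenset  # region PCGs associated with this lncRNA


def importance_score(abs_log2fc: float, terms, gamma: float = 0.3) -> float:
    """IS from |log2FC_L| and (d_LGj, D_Gj) pairs over region genes."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    topo = sum(d * deg for d, deg in terms)
    return gamma * abs_log2fc + (1.0 - gamma) * topo


def rank_lncrnas(region_nodes, wp, lnc_fc, network, r_case=None, r_control=None,
                 gamma: float = 0.3) -> list[LncImportance]:
    """Rank the risk lncRNAs attached to a region by importance score.

    Uses the per-node lncRNA attachments recorded on the weighted pathway
    (lnc, d, |log2FC|); region-internal degree comes from the induced
    subgraph. Ties break by larger |log2FC|, then id.
    """
    region = set(region_nodes)
    sub = wp.pathway.graph.subgraph(region)
    per_lnc: dict[str, list] = {}
    fc_of: dict[str, float] = {}
    for g in region:
        for lnc, d, fc in wp.node_lncrnas.get(g, []):
            per_lnc.setdefault(lnc, []).append((g, d))
            fc_of[lnc] = fc
    out = []
    for lnc in sorted(per_lnc):
        terms = [(d, sub.degree(g)) for g, d in per_lnc[lnc]]
        fc = fc_of[lnc]
        score = importance_score(fc, terms, gamma)
        out.append(LncImportance(lnc, score, fc,
                                 frozenset(g for g, _ in per_lnc[lnc])))
    out.sort(key=lambda x: (-x.score, -x.abs_log2fc, x.lncrna))
    return out


def select_key_lncrnas(ranked, region_nodes, pert: float = 0.8) -> list[str]:
    """Greedy minimal core set covering >= ``pert`` of region PCGs.

    Seeds with the top-IS lncRNA, then walks the ranking; an lncRNA joins
    only when the covered fraction strictly increases, stopping once
    q >= pert or the list is exhausted.
    """
    if not 0.0 < pert <= 1.0:
        raise ValueError("pert must lie in (0, 1]")
    region = set(region_nodes)
    if not region or not ranked:
        return []
    core: list[str] = []
    covered: set = set()
    q = 0.0
    for imp in ranked:
        if core and q >= pert:
            break
        new_cov = covered | (imp.covered & region)
        q_new = len(new_cov) / len(region)
        if not core or q_new > q:
            core.append(imp.lncrna)
            covered = new_cov
            q = q_new
    return core
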