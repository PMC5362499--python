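"""End-to-end orchestration: expression -> risk lncRNAs -> pathway weights ->
PCST regions -> permutation significance -> key lncRNAs -> report.

Runs are defined over a pathway COLLECTION because the edge-level background
pool spans all edges of all supplied pathways. Per-region permutation streams
are derived from (seed, pathway id, region index, level), so a pathway's
node-level P values do not depend on which other pathways are in the run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import significance as sig
from .association_network import AssociationNetwork
from .expression_io import ExpressionPair, differential_table, filter_low_expression, select_risk_lncrnas
from .key_lncrna import rank_lncrnas, select_key_lncrnas
from .pcst import extract_subpathways
from .weighting import gene_raw_weights, group_correlations, weight_pathway

__all__ = ["RunConfig", "run", "results_frame"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run (defaults follow the method)."""

    alpha: float = 0.5          # node-weight mix between gene FC and lncRNA layer
    beta: float = 15.0          # prize scale after within-pathway normalisation
    gamma: float = 0.3          # importance-score mix for key lncRNAs
    pert: float = 0.8           # coverage target of the core lncRNA set
    pseudocount: float = 0.01   # added before log2 (FPKM scale)
    permutations: int = 1000
    fdr_cut: float = 0.25
    fc_hi: float = 1.5
    fc_lo: float = 2.0 / 3.0
    min_nonzero_frac: float = 0.2
    max_regions: int = 1
    seed: int = 0
    range_normalize: bool = False
    strict_tail: bool = False
    add_one: bool = False
    adjust_method: str = "bh"
    exact_threshold: int = 4
    require_lncrna: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _region_rng(seed: int, pathway_id: str, region_index: int, level: int):
    tag = zlib.crc32(pathway_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, region_index, level]))


def run(
    pair: ExpressionPair,
    pathways,
    network: AssociationNetwork,
    config: RunConfig | None = None,
):
    """Run the full identification. Returns (results, log) where results is
    the final sorted list of :class:`SubpathwayResult` and log records skip
    decisions, pool sizes and the risk lncRNA set."""
    cfg = config or RunConfig()
    log: dict = {"config": cfg.to_dict(), "skipped_pathways": [], "warnings": []}

    if cfg.min_nonzero_frac > 0:
        pair = filter_low_expression(pair, cfg.min_nonzero_frac)

    lnc_table = differential_table(pair.lnc, pair.groups, cfg.pseudocount)
    pcg_table = differential_table(pair.pcg, pair.groups, cfg.pseudocount)
    risk = select_risk_lncrnas(lnc_table, cfg.fdr_cut, cfg.fc_hi, cfg.fc_lo)
    log["risk_lncrnas"] = sorted(risk)
    if not risk:
        log["reason"] = "no risk lncRNAs at the configured FDR/FC thresholds"
        return [], log

    # background node pool: raw weights of every expressed PCG associated
    # with at least one risk lncRNA
    risk_set = set(risk)
    pool_genes = sorted(
        g for g in set(pair.pcg.index)
        if any(l in risk_set for l in network.lncrnas_for(g))
    )
    node_pool_w, _, _ = gene_raw_weights(
        pool_genes, pair, risk_set, network, cfg.alpha, cfg.pseudocount,
        pcg_table=pcg_table, lnc_table=lnc_table,
    )
    node_pool = np.array([node_pool_w[g] for g in pool_genes], dtype=float)
    log["node_pool_size"] = int(node_pool.size)

    # background edge pool: differentiality of all edges from all pathways
    all_genes = sorted({v for pw in pathways for v in pw.nodes if v in pair.pcg.index})
    r_case, r_control = group_correlations(pair, all_genes, cfg.pseudocount)
    edge_pool_vals = []
    for pw in pathways:
        for u, v in pw.graph.edges:
            if u in r_case.index and v in r_case.index:
                edge_pool_vals.append(abs(r_case.at[u, v] - r_control.at[u, v]))
            else:
                edge_pool_vals.append(0.0)  # unexpressed endpoints: unchanged edge
    edge_pool = np.array(edge_pool_vals, dtype=float)
    log["edge_pool_size"] = int(edge_pool.size)

    results = []
    for pw in sorted(pathways, key=lambda p: p.id):
        wp = weight_pathway(
            pw, pair, risk_set, network,
            alpha=cfg.alpha, beta=cfg.beta, pseudocount=cfg.pseudocount,
            range_normalize=cfg.range_normalize,
            pcg_table=pcg_table, lnc_table=lnc_table,
        )
        if wp is None:
            log["skipped_pathways"].append(pw.id)
            continue
        regions = extract_subpathways(wp, cfg.max_regions, cfg.exact_threshold)
        for k, sol in enumerate(regions, start=1):
            edges = sorted(wp.induced_edges(sol.nodes), key=sorted)
            s_node, s_edge = sig.observed_scores(sol.nodes, edges, wp)
            p_node = sig.permutation_p(
                s_node, node_pool, len(sol.nodes), cfg.permutations,
                rng=_region_rng(cfg.seed, pw.id, k, 0),
                strict_tail=cfg.strict_tail, add_one=cfg.add_one,
            )
            p_edge = sig.permutation_p(
                s_edge, edge_pool, len(edges), cfg.permutations,
                rng=_region_rng(cfg.seed, pw.id, k, 1),
                strict_tail=cfg.strict_tail, add_one=cfg.add_one,
            )
            lncs = sorted({l for v in sol.nodes for (l, _d, _fc) in wp.node_lncrnas.get(v, [])})
            ranked = rank_lncrnas(sol.nodes, wp, lnc_table["log2fc"], network, gamma=cfg.gamma)
            keys = select_key_lncrnas(ranked, sol.nodes, cfg.pert)
            results.append(sig.SubpathwayResult(
                pathway_id=pw.id,
                region_id=f"{pw.id}_{k}",
                nodes=tuple(sol.nodes),
                edges=tuple(tuple(sorted(e)) for e in edges),
                s_obs_node=s_node,
                s_obs_edge=s_edge if s_edge is not None else float("nan"),
                p_node=p_node,
                p_edge=p_edge,
                p_joint=sig.joint_p(p_node, p_edge),
                randomizations=cfg.permutations,
                lncrnas=tuple(lncs),
                key_lncrnas=tuple(keys),
                importance={x.lncrna: x.score for x in ranked},
            ))
    sig.adjust(results, cfg.adjust_method)
    final = sig.report(results, require_lncrna=cfg.require_lncrna)
    log["n_regions_tested"] = len(results)
    log["n_regions_reported"] = len(final)
    return final, log


def results_frame(results) -> pd.DataFrame:
    """Flatten results to the report table written by the CLI."""
    rows = []
    for r in results:
        rows.append({
            "pathway_id": r.pathway_id,
            "region_id": r.region_id,
            "n_nodes": len(r.nodes),
            "n_edges": len(r.edges),
            "s_obs_node": r.s_obs_node,
            "s_obs_edge": r.s_obs_edge,
            "p_node": r.p_node,
            "p_edge": r.p_edge,
            "p_joint": r.p_joint,
            "p_adjusted": r.p_adjusted,
            "lncrnas": ",".join(r.lncrnas),
            "key_lncrnas": ",".join(r.key_lncrnas),
            "nodes": ",".join(r.nodes),
        })
    cols = ["pathway_id", "region_id", "n_nodes", "n_edges", "s_obs_node", "s_obs_edge",
            "p_node", "p_edge", "p_joint", "p_adjusted", "lncrnas", "key_lncrnas", "nodes"]
    return pd.DataFrame(rows, columns=cols)
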