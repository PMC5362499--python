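"""Node prizes and edge costs for one pathway.

Raw node weight combines a gene's own differential expression with the
differential expression of its associated risk lncRNAs, amplified by the
between-condition shift of the gene-lncRNA correlation:

    w_v = alpha * |log2FC_v| + (1 - alpha) * sum_j d_vLj * |log2FC_Lj|
    d_vLj = 1 + |r_case(v, Lj) - r_control(v, Lj)|

Prizes are the within-pathway normalisation b_v = beta * (w_v - w_min) / w_max.
Raw edge weight w_e = 1 - |r_case - r_control| is LOW for dysregulated
interactions; costs are c_e = (w_e - w_emin) / w_emax. Dividing by the maximum
(rather than the range) is deliberate; ``range_normalize=True`` switches to
(max - min). Correlations are Pearson, computed per group on
log2(x + pseudocount); a group with fewer than 3 samples contributes a
correlation of 0 (with a warning). Pathway genes missing from the expression
matrix get w_v = 0 and neutral incident edges (w_e = 1) so topology is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_network import AssociationNetwork
from .expression_io import ExpressionPair, differential_table
from .pathway_graphs import PathwayGraph

__all__ = [
    "WeightedPathway",
    "correlation_shift",
    "node_weight",
    "normalize_node_weights",
    "edge_weight",
    "normalize_edge_weights",
    "weight_pathway",
    "gene_raw_weights",
    "group_correlations",
]


@dataclass
class WeightedPathway:
    """A pathway with per-node raw weights/prizes and per-edge raw
    weights/costs, plus the risk lncRNAs attached to each node."""

    pathway: PathwayGraph
    node_raw: dict = field(default_factory=dict)
    node_prize: dict = field(default_factory=dict)
    edge_raw: dict = field(default_factory=dict)       # frozenset({u,v}) -> w_e
    edge_cost: dict = field(default_factory=dict)      # frozenset({u,v}) -> c_e
    node_lncrnas: dict = field(default_factory=dict)   # node -> [(lnc, d, |log2FC_L|)]

    @classmethod
    def from_prizes(cls, graph_or_pathway, prizes: dict, costs: dict) -> "WeightedPathway":
        """Build directly from prize/cost maps (testing and ad-hoc use)."""
        pw = graph_or_pathway
        if not isinstance(pw, PathwayGraph):
            pw = PathwayGraph(id="adhoc", name="adhoc", graph=pw)
        costs = {frozenset(e): c for e, c in costs.items()}
        return cls(pathway=pw, node_prize=dict(prizes), node_raw=dict(prizes),
                   edge_cost=costs, edge_raw={e: 1.0 - c for e, c in costs.items()})

    def induced_edges(self, nodes) -> set[frozenset]:
        nodes = set(nodes)
        return {frozenset((u, v)) for u, v in self.pathway.graph.edges
                if u in nodes and v in nodes}


def correlation_shift(r_case: float, r_control: float) -> float:
    """d = 1 + |r_case - r_control|, in [1, 3]."""
    for r in (r_case, r_control):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    return 1.0 + abs(r_case - r_control)


def node_weight(abs_log2fc_v: float, lnc_terms, alpha: float = 0.5) -> float:
    """w_v from the gene's |log2FC| and its (d, |log2FC_L|) lncRNA terms."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lnc_sum = sum(d * fc for d, fc in lnc_terms)
    return alpha * abs_log2fc_v + (1.0 - alpha) * lnc_sum


def normalize_node_weights(raw: dict, beta: float = 15.0, range_normalize: bool = False) -> dict:
    """b_v = beta * (w_v - w_min) / w_max (as printed); all-zero or
    non-positive maximum collapses every prize to 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not raw:
        return {}
    vals = np.array(list(raw.values()), dtype=float)
    w_min, w_max = vals.min(), vals.max()
    denom = (w_max - w_min) if range_normalize else w_max
    if denom <= 0:
        return {v: 0.0 for v in raw}
    return {v: beta * (w - w_min) / denom for v, w in raw.items()}


def edge_weight(r_case: float, r_control: float) -> float:
    """w_e = 1 - |r_case - r_control|, in [-1, 1]."""
    return 1.0 - abs(r_case - r_control)


def normalize_edge_weights(raw: dict, range_normalize: bool = False) -> dict:
    """c_e = (w_e - w_emin) / w_emax; non-positive maximum -> all costs 0."""
    if not raw:
        return {}
    vals = np.array(list(raw.values()), dtype=float)
    w_min, w_max = vals.min(), vals.max()
    denom = (w_max - w_min) if range_normalize else w_max
    if denom <= 0:
        return {e: 0.0 for e in raw}
    return {e: (w - w_min) / denom for e, w in raw.items()}


def group_correlations(pair: ExpressionPair, features, pseudocount: float = 0.01):
    """Per-group Pearson correlation matrices (case, control) over ``features``
    (each present in either matrix), computed on log2(x + pseudocount).

    Returns (r_case, r_control) DataFrames. Groups with < 3 samples yield
    all-zero correlations with a warning.
    """
    stacked = pd.concat([pair.lnc, pair.pcg])
    feats = [f for f in features if f in stacked.index]
    logx = np.log2(stacked.loc[feats] + pseudocount)
    out = []
    for cols in (pair.case_samples, pair.control_samples):
        if len(cols) < 3:
            warnings.warn("group with <3 samples: correlations treated as 0", RuntimeWarning,
                          stacklevel=2)
            out.append(pd.DataFrame(0.0, index=feats, columns=feats))
            continue
        x = logx[cols].to_numpy(dtype=float)
        sd = x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        r = np.where(np.outer(sd > 0, sd > 0), r, 0.0)
        np.fill_diagonal(r, 1.0)
        out.append(pd.DataFrame(np.clip(r, -1, 1), index=feats, columns=feats))
    return out[0], out[1]


def _lnc_terms_for_gene(gene, risk_set, network, lnc_fc, r_case, r_control):
    terms, detail = [], []
    for lnc in network.lncrnas_for(gene):
        if lnc not in risk_set or lnc not in lnc_fc.index:
            continue
        if gene in r_case.index and lnc in r_case.index:
            d = correlation_shift(r_case.at[gene, lnc], r_control.at[gene, lnc])
        else:
            d = 1.0  # missing correlation -> no shift
        fc = abs(lnc_fc.at[lnc])
        terms.append((d, fc))
        detail.append((lnc, d, fc))
    return terms, detail


def gene_raw_weights(
    genes,
    pair: ExpressionPair,
    risk_lncrnas,
    network: AssociationNetwork,
    alpha: float = 0.5,
    pseudocount: float = 0.01,
    pcg_table: pd.DataFrame | None = None,
    lnc_table: pd.DataFrame | None = None,
):
    """Raw node weights w_v for ``genes`` (pathway-independent).

    Returns (weights dict, per-gene lncRNA detail dict, (r_case, r_control)).
    Genes absent from the expression matrix get w_v = 0.
    """
    risk_set = set(risk_lncrnas)
    if pcg_table is None:
        pcg_table = differential_table(pair.pcg, pair.groups, pseudocount)
    if lnc_table is None:
        lnc_table = differential_table(pair.lnc, pair.groups, pseudocount)
    lnc_fc = lnc_table["log2fc"]

    needed_lnc = sorted({l for g in genes for l in network.lncrnas_for(g) if l in risk_set})
    feats = [g for g in genes if g in pair.pcg.index] + [l for l in needed_lnc if l in pair.lnc.index]
    r_case, r_control = group_correlations(pair, feats, pseudocount)

    weights, detail = {}, {}
    for g in genes:
        if g not in pair.pcg.index:
            weights[g], detail[g] = 0.0, []
            continue
        terms, det = _lnc_terms_for_gene(g, risk_set, network, lnc_fc, r_case, r_control)
        weights[g] = node_weight(abs(pcg_table.at[g, "log2fc"]), terms, alpha)
        detail[g] = det
    return weights, detail, (r_case, r_control)


def weight_pathway(
    pathway: PathwayGraph,
    pair: ExpressionPair,
    risk_lncrnas,
    network: AssociationNetwork,
    alpha: float = 0.5,
    beta: float = 15.0,
    pseudocount: float = 0.01,
    range_normalize: bool = False,
    pcg_table: pd.DataFrame | None = None,
    lnc_table: pd.DataFrame | None = None,
) -> WeightedPathway | None:
    """Weight one pathway. Returns None (skip) when no pathway gene is
    associated with any risk lncRNA."""
    risk_set = set(risk_lncrnas)
    nodes = sorted(pathway.nodes)
    if not any(l in risk_set for g in nodes for l in network.lncrnas_for(g)):
        return None

    node_raw, node_lncs, (r_case, r_control) = gene_raw_weights(
        nodes, pair, risk_set, network, alpha, pseudocount, pcg_table, lnc_table
    )

    # edge weights need gene-gene correlations; reuse or extend the block
    genes_expr = [g for g in nodes if g in pair.pcg.index]
    missing = [g for g in genes_expr if g not in r_case.index]
    if missing:
        r_case, r_control = group_correlations(pair, list(r_case.index) + missing, pseudocount)

    edge_raw = {}
    for u, v in pathway.graph.edges:
        if u in r_case.index and v in r_case.index:
            w = edge_weight(r_case.at[u, v], r_control.at[u, v])
        else:
            w = 1.0  # endpoint without expression: neutral (unchanged) edge
        edge_raw[frozenset((u, v))] = w

    return WeightedPathway(
        pathway=pathway,
        node_raw=node_raw,
        node_prize=normalize_node_weights(node_raw, beta, range_normalize),
        edge_raw=edge_raw,
        edge_cost=normalize_edge_weights(edge_raw, range_normalize),
        node_lncrnas=node_lncs,
    )
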