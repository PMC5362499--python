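"""Synthetic matched lncRNA/mRNA datasets with planted dysregulation, and the
three built-in evaluation studies (sensitivity, false-positive rate, planted
region recall).

Generator model
---------------
Each dataset holds 150 PCGs and 50 lncRNAs over two equal sample groups drawn
from a multivariate normal on the log2 scale (baseline mean 5, unit
variance). Pathway edges and lncRNA-PCG associations carry a baseline
correlation rho0 = 0.6. A planted signal shifts the case-group mean of
affected nodes (and their associated lncRNAs) by log2(n) and lowers the
case-group correlation of affected edges/associations to rho0 - e. Matrices
made indefinite by the planted structure are repaired by eigenvalue clipping
(with diagonal renormalisation). Expression is emitted on the linear scale
(2**z), matching the non-negative abundance inputs of the pipeline.

The lncRNA-PCG association network is a seeded random bipartite graph
(each lncRNA attaches to ``mean_degree`` pathway genes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_network import AssociationNetwork, EDGE_COLUMNS
from .expression_io import ExpressionPair
from .pathway_graphs import fixture_pathways, planted_regions
from .pipeline import RunConfig, run

__all__ = [
    "SimulationScenario",
    "simulate_dataset",
    "simulate_null",
    "build_random_association",
    "run_sensitivity_study",
    "run_fpr_study",
    "run_recall_study",
]


@dataclass
class SimulationScenario:
    """Parameters of one simulation condition."""

    topology: str = "linear"      # pathway carrying the planted signal
    n: float = 2.0                # node fold change (case mean shift = log2(n))
    e: float = 0.5                # edge correlation change (rho0 -> rho0 - e)
    p: float = 0.5                # fraction of pathway nodes/edges altered
    N: int = 250                  # total sample count, split into two equal groups
    seed: int = 0
    n_pcgs: int = 150
    n_lncs: int = 50
    rho0: float = 0.6
    baseline_mean: float = 5.0    # log2 scale
    mean_degree: int = 2          # lncRNA attachments to pathway genes
    planted_region_nodes: list = field(default_factory=list)  # explicit regions (node lists)


def _layout(pathways, n_pcgs: int, n_lncs: int):
    pw_genes: list[str] = []
    for pw in pathways:
        pw_genes.extend(sorted(pw.nodes))
    if len(pw_genes) > n_pcgs:
        raise ValueError("pathway genes exceed n_pcgs")
    fillers = [f"bg{i:03d}" for i in range(1, n_pcgs - len(pw_genes) + 1)]
    genes = pw_genes + fillers
    lncs = [f"lnc{i:03d}" for i in range(1, n_lncs + 1)]
    return genes, lncs, pw_genes


def build_random_association(rng, pathway_genes, lnc_ids, mean_degree: int = 2) -> AssociationNetwork:
    """Seeded random bipartite lncRNA->pathway-gene attachment network."""
    rows = []
    k = min(mean_degree, len(pathway_genes))
    for lnc in lnc_ids:
        targets = rng.choice(len(pathway_genes), size=k, replace=False)
        for t in sorted(targets):
            rows.append((lnc, pathway_genes[t], "coexpr", "+", 3))
    return AssociationNetwork(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def _clip_to_correlation(C: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Nearest-PD-style repair: clip eigenvalues at eps, renormalise diagonal."""
    w, V = np.linalg.eigh(C)
    if w.min() >= eps:
        return C
    warnings.warn("indefinite correlation structure repaired by eigenvalue clipping",
                  RuntimeWarning, stacklevel=2)
    w = np.clip(w, eps, None)
    C2 = (V * w) @ V.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    return C2


def _structured_corr(feature_index: dict, pairs_rho: dict, size: int):
    """Correlation matrix over the features touched by any structured pair,
    repaired to PD; returns (sub-index list, cholesky factor)."""
    touched = sorted({i for pair in pairs_rho for i in pair})
    pos = {i: k for k, i in enumerate(touched)}
    C = np.eye(len(touched))
    for (i, j), rho in pairs_rho.items():
        C[pos[i], pos[j]] = C[pos[j], pos[i]] = rho
    C = _clip_to_correlation(C)
    return touched, np.linalg.cholesky(C + 1e-12 * np.eye(len(touched)))


def _sample_group(rng, mean: np.ndarray, touched, chol, n_samples: int) -> np.ndarray:
    """Draw n_samples columns; structured features correlated via chol."""
    n_feat = mean.size
    z = rng.standard_normal((n_feat, n_samples))
    if touched:
        z[touched, :] = chol @ rng.standard_normal((len(touched), n_samples))
    return mean[:, None] + z


def _assemble_pair(z_case, z_ctrl, genes, lncs, scenario) -> ExpressionPair:
    half = scenario.N // 2
    samples = [f"s{i:03d}" for i in range(1, 2 * half + 1)]
    groups = pd.Series(["case"] * half + ["control"] * half, index=samples)
    x = np.power(2.0, np.concatenate([z_case, z_ctrl], axis=1))
    feats = genes + lncs
    df = pd.DataFrame(x, index=feats, columns=samples)
    return ExpressionPair(lnc=df.loc[lncs], pcg=df.loc[genes], groups=groups)


def simulate_dataset(scenario: SimulationScenario, pathways=None, network=None):
    """Generate one planted-signal dataset.

    Returns (ExpressionPair, AssociationNetwork, truth) where truth records
    planted nodes, altered edges/associations and altered lncRNAs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x51A7, int(scenario.seed)]))
    pathways = list(pathways) if pathways is not None else list(fixture_pathways().values())
    genes, lncs, pw_genes = _layout(pathways, scenario.n_pcgs, scenario.n_lncs)
    if network is None:
        network = build_random_association(rng, pw_genes, lncs, scenario.mean_degree)

    target = next(pw for pw in pathways if pw.id == scenario.topology)
    t_nodes = sorted(target.nodes)
    t_edges = sorted(tuple(sorted(e)) for e in target.graph.edges)

    if scenario.planted_region_nodes:
        planted_nodes: set = set()
        altered_edges: set = set()
        for region in scenario.planted_region_nodes:
            region = set(region)
            planted_nodes |= region
            for pw in pathways:
                for u, v in pw.graph.edges:
                    if u in region and v in region:
                        altered_edges.add(tuple(sorted((u, v))))
    elif scenario.p > 0:
        # planted dysregulation forms a CONNECTED region: grow a random
        # breadth-first tree from a random seed node to ceil(p * |V|) nodes
        k_nodes = max(1, round(scenario.p * len(t_nodes)))
        seed_node = t_nodes[int(rng.integers(len(t_nodes)))]
        planted_nodes = {seed_node}
        frontier = [seed_node]
        while frontier and len(planted_nodes) < k_nodes:
            v = frontier.pop(0)
            nbrs = sorted(set(target.graph.neighbors(v)) - planted_nodes)
            rng.shuffle(nbrs)
            for u in nbrs:
                if len(planted_nodes) >= k_nodes:
                    break
                planted_nodes.add(u)
                frontier.append(u)
        induced = sorted(tuple(sorted((u, v))) for u, v in target.graph.edges
                         if u in planted_nodes and v in planted_nodes)
        k_edges = min(max(1, round(scenario.p * len(t_edges))), len(induced))
        altered_edges = {induced[i] for i in rng.choice(len(induced), k_edges, replace=False)}
    else:
        planted_nodes, altered_edges = set(), set()

    altered_lncs = sorted({l for g in planted_nodes for l in network.lncrnas_for(g)})
    altered_assoc = {(l, g) for l in altered_lncs for g in network.pcgs_for(l) if g in planted_nodes}

    feats = genes + lncs
    fidx = {f: i for i, f in enumerate(feats)}

    base_pairs: dict = {}
    for pw in pathways:
        for u, v in pw.graph.edges:
            base_pairs[(fidx[u], fidx[v])] = scenario.rho0
    for row in network.edges.itertuples():
        base_pairs[(fidx[row.pcg], fidx[row.lncrna])] = scenario.rho0

    case_pairs = dict(base_pairs)
    for u, v in altered_edges:
        case_pairs[(fidx[u], fidx[v])] = scenario.rho0 - scenario.e
    for l, g in altered_assoc:
        case_pairs[(fidx[g], fidx[l])] = scenario.rho0 - scenario.e

    touched0, chol0 = _structured_corr(fidx, base_pairs, len(feats))
    if case_pairs == base_pairs:
        touched1, chol1 = touched0, chol0  # exact null: identical covariance
    else:
        touched1, chol1 = _structured_corr(fidx, case_pairs, len(feats))

    mu_ctrl = np.full(len(feats), scenario.baseline_mean)
    mu_case = mu_ctrl.copy()
    shift = math.log2(scenario.n) if scenario.n > 0 else 0.0
    for f in list(planted_nodes) + altered_lncs:
        mu_case[fidx[f]] += shift

    half = scenario.N // 2
    z_case = _sample_group(rng, mu_case, touched1, chol1, half)
    z_ctrl = _sample_group(rng, mu_ctrl, touched0, chol0, half)
    pair = _assemble_pair(z_case, z_ctrl, genes, lncs, scenario)
    truth = {
        "planted_nodes": sorted(planted_nodes),
        "altered_edges": sorted(altered_edges),
        "altered_lncrnas": altered_lncs,
        "altered_associations": sorted(altered_assoc),
    }
    return pair, network, truth


def simulate_null(strategy: str, scenario: SimulationScenario, pathways=None, network=None):
    """Null dataset: identical means and covariances in both groups.

    'choi' uses compound-symmetry blocks (rho0) over each pathway's genes;
    'goel' draws a random correlation block per pathway per replicate. Both
    satisfy mu1 = mu2 and Sigma1 = Sigma2 exactly.
    """
    if strategy not in {"choi", "goel"}:
        raise ValueError("strategy must be 'choi' or 'goel'")
    rng = np.random.default_rng(np.random.SeedSequence([0x0511, int(scenario.seed)]))
    pathways = list(pathways) if pathways is not None else list(fixture_pathways().values())
    genes, lncs, pw_genes = _layout(pathways, scenario.n_pcgs, scenario.n_lncs)
    if network is None:
        network = build_random_association(rng, pw_genes, lncs, scenario.mean_degree)

    feats = genes + lncs
    fidx = {f: i for i, f in enumerate(feats)}
    pairs: dict = {}
    for pw in pathways:
        block = sorted(pw.nodes)
        if strategy == "choi":
            for i, u in enumerate(block):
                for v in block[i + 1:]:
                    pairs[(fidx[u], fidx[v])] = scenario.rho0
        else:
            k = len(block)
            A = rng.standard_normal((k, max(2, k // 2)))
            S = A @ A.T + np.eye(k)
            d = np.sqrt(np.diag(S))
            R = S / np.outer(d, d)
            for i in range(k):
                for j in range(i + 1, k):
                    pairs[(fidx[block[i]], fidx[block[j]])] = R[i, j]

    touched, chol = _structured_corr(fidx, pairs, len(feats))
    mu = np.full(len(feats), scenario.baseline_mean)
    half = scenario.N // 2
    z_case = _sample_group(rng, mu, touched, chol, half)
    z_ctrl = _sample_group(rng, mu, touched, chol, half)
    pair = _assemble_pair(z_case, z_ctrl, genes, lncs, scenario)
    return pair, network, {"strategy": strategy}


def _pipeline_config(permutations: int, seed: int, max_regions: int = 1) -> RunConfig:
    return RunConfig(permutations=permutations, seed=seed, max_regions=max_regions)


def run_sensitivity_study(
    ns=(2.0, 4.0, 7.0),
    es=(0.1, 0.5, 0.9),
    ps=(0.1, 0.5, 0.9),
    N: int = 250,
    replicates: int = 30,
    permutations: int = 200,
    seed: int = 0,
    topologies=("linear",),
) -> pd.DataFrame:
    """Significant-replicate ratios (joint P < 0.01 / 0.05) per grid cell."""
    pathways = list(fixture_pathways().values())
    rows = []
    cell = 0
    for topo in topologies:
        for n in ns:
            for e in es:
                for p in ps:
                    cell += 1
                    pvals, weights = [], []
                    for rep in range(replicates):
                        sc = SimulationScenario(
                            topology=topo, n=n, e=e, p=p, N=N,
                            seed=(seed * 1_000_003 + cell * 1009 + rep) % (2**31 - 1),
                        )
                        pair, net, _ = simulate_dataset(sc, pathways)
                        res, _ = run(pair, pathways, net,
                                     _pipeline_config(permutations, sc.seed))
                        hit = [r for r in res if r.pathway_id == topo]
                        pvals.append(hit[0].p_joint if hit else 1.0)
                        weights.append(hit[0].s_obs_node if hit else 0.0)
                    pvals = np.array(pvals)
                    rows.append({
                        "topology": topo, "n": n, "e": e, "p": p, "N": N,
                        "replicates": replicates,
                        "ratio_p01": float((pvals < 0.01).mean()),
                        "ratio_p05": float((pvals < 0.05).mean()),
                        "mean_weight": float(np.mean(weights)),
                        "mean_joint_p": float(pvals.mean()),
                    })
    return pd.DataFrame(rows)


def run_fpr_study(
    strategies=("choi", "goel"),
    topologies=("linear", "erbb"),
    N: int = 250,
    replicates: int = 100,
    alpha: float = 0.01,
    permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """False-positive rate per (strategy, topology): fraction of null
    replicates whose best reported subpathway attains joint P < alpha."""
    fixtures = fixture_pathways()
    rows = []
    cond = 0
    for strategy in strategies:
        for topo in topologies:
            cond += 1
            hits = 0
            for rep in range(replicates):
                sc = SimulationScenario(
                    topology=topo, p=0.0, N=N,
                    seed=(seed * 999_983 + cond * 7919 + rep) % (2**31 - 1),
                )
                pathways = [fixtures[topo]]
                pair, net, _ = simulate_null(strategy, sc, pathways)
                res, _ = run(pair, pathways, net,
                             _pipeline_config(permutations, sc.seed))
                if res and min(r.p_joint for r in res) < alpha:
                    hits += 1
            rows.append({
                "strategy": strategy, "topology": topo, "N": N,
                "replicates": replicates, "alpha": alpha,
                "fpr": hits / replicates if replicates else float("nan"),
            })
    return pd.DataFrame(rows)


def run_recall_study(
    n: float = 3.0,
    e: float = 0.5,
    N: int = 300,
    replicates: int = 20,
    permutations: int = 500,
    seed: int = 0,
    regions: dict | None = None,
) -> pd.DataFrame:
    """Mean per-region recall of the planted regions.

    recall = |identified subpathway nodes ∩ region| / |region|, with the
    identified set taken as the union of reported regions of the region's
    pathway in that replicate.
    """
    pathways = list(fixture_pathways().values())
    regions = regions or planted_regions()
    region_nodes = [set(v["nodes"]) for v in regions.values()]
    per_region: dict[str, list] = {k: [] for k in regions}
    for rep in range(replicates):
        sc = SimulationScenario(
            n=n, e=e, N=N,
            seed=(seed * 424_243 + rep) % (2**31 - 1),
            planted_region_nodes=[sorted(s) for s in region_nodes],
        )
        pair, net, _ = simulate_dataset(sc, pathways)
        res, _ = run(pair, pathways, net,
                     _pipeline_config(permutations, sc.seed, max_regions=3))
        found: dict[str, set] = {}
        for r in res:
            found.setdefault(r.pathway_id, set()).update(r.nodes)
        for rid, spec_ in regions.items():
            nodes = set(spec_["nodes"])
            got = found.get(spec_["pathway"], set())
            per_region[rid].append(len(got & nodes) / len(nodes))
    rows = [{
        "region": rid,
        "pathway": regions[rid]["pathway"],
        "size": len(regions[rid]["nodes"]),
        "replicates": replicates,
        "mean_recall": float(np.mean(vals)) if vals else float("nan"),
    } for rid, vals in per_region.items()]
    return pd.DataFrame(rows)
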