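"""Global lncRNA-PCG association network.

Two complementary evidence layers are supported:

* co-expression — per dataset, variable features are correlated (Pearson),
  Fisher-z P values are Bonferroni-corrected, and only extreme-tail pairs are
  retained; a pair enters the network when its correlation sign is consistent
  in at least ``min_support`` datasets;
* ceRNA — lncRNA and mRNA share significantly more miRNA partners than chance
  (hypergeometric upper tail) and rank in the top fraction by Jaccard
  coefficient among the lncRNA's candidate mRNAs.

Networks are bipartite: one edge per (lncRNA, PCG) pair after merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EDGE_COLUMNS = ["lncrna", "pcg", "provenance", "sign", "support"]

__all__ = [
    "AssociationNetwork",
    "MirnaInteractionTable",
    "variability_filter",
    "fisher_correlation_p",
    "build_coexpression_network",
    "shared_mirna_p",
    "jaccard",
    "build_cerna_network",
    "merge_networks",
    "read_network",
    "write_network",
]


@dataclass
class AssociationNetwork:
    """Bipartite lncRNA <-> PCG edge set.

    ``edges`` columns: lncrna, pcg, provenance in {coexpr, cerna, both},
    sign in {+, -, n/a}, support (dataset count; 0 for cerna-only edges).
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)[EDGE_COLUMNS]
        if self.edges.duplicated(subset=["lncrna", "pcg"]).any():
            raise ValueError("duplicate (lncRNA, PCG) edges")
        if (set(self.edges["lncrna"]) & set(self.edges["pcg"])):
            raise ValueError("network must be bipartite: lncRNA and PCG id sets overlap")
        self._lnc_of_pcg: dict[str, list[str]] = {}
        self._pcg_of_lnc: dict[str, list[str]] = {}
        for lnc, pcg in zip(self.edges["lncrna"], self.edges["pcg"]):
            self._lnc_of_pcg.setdefault(pcg, []).append(lnc)
            self._pcg_of_lnc.setdefault(lnc, []).append(pcg)

    def __len__(self) -> int:
        return len(self.edges)

    def lncrnas_for(self, pcg: str) -> list[str]:
        return self._lnc_of_pcg.get(pcg, [])

    def pcgs_for(self, lncrna: str) -> list[str]:
        return self._pcg_of_lnc.get(lncrna, [])

    @property
    def pcgs(self) -> set[str]:
        return set(self.edges["pcg"])

    @property
    def lncrnas(self) -> set[str]:
        return set(self.edges["lncrna"])


@dataclass
class MirnaInteractionTable:
    """miRNA partner sets per mRNA and per lncRNA (shared miRNA namespace)."""

    mrna_to_mirna: dict[str, set]
    lnc_to_mirna: dict[str, set]

    @property
    def universe(self) -> set:
        out: set = set()
        for s in self.mrna_to_mirna.values():
            out |= s
        for s in self.lnc_to_mirna.values():
            out |= s
        return out


def variability_filter(matrix: pd.DataFrame, cv_min: float = 0.3, top_frac: float = 0.75) -> list[str]:
    """Features whose coefficient of variation is >= ``cv_min`` AND ranks in
    the top ``top_frac`` of all features' CVs (ties at the cut included).

    Features with zero mean have undefined CV and are dropped.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >=3 samples to assess variability")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    valid = ~np.isnan(cv)
    if not valid.any():
        return []
    cut = np.quantile(cv[valid], 1.0 - top_frac)
    keep = valid & (cv >= cv_min) & (cv >= cut)
    return list(matrix.index[keep])


def fisher_correlation_p(r: float, n: int) -> float:
    """Two-sided P for a Pearson correlation via the Fisher z transform:
    z = atanh(r) * sqrt(n - 3), P = 2 * (1 - Phi(|z|))."""
    if n <= 3:
        raise ValueError("Fisher's asymptotic test requires n > 3")
    if abs(r) > 1:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) == 1:
        return 0.0
    z = math.atanh(r) * math.sqrt(n - 3)
    return 2.0 * stats.norm.sf(abs(z))


def _dataset_significant_pairs(
    lnc: pd.DataFrame,
    pcg: pd.DataFrame,
    adj_p_cut: float,
    extreme_frac: float,
    cv_min: float,
    top_frac: float,
) -> dict[tuple[str, str], int]:
    """One dataset's retained (lncRNA, PCG) -> sign (+1/-1)."""
    lnc_keep = variability_filter(lnc, cv_min, top_frac)
    pcg_keep = variability_filter(pcg, cv_min, top_frac)
    if not lnc_keep or not pcg_keep:
        return {}
    n = lnc.shape[1]
    lx = lnc.loc[lnc_keep].to_numpy(dtype=float)
    px = pcg.loc[pcg_keep].to_numpy(dtype=float)
    lz = (lx - lx.mean(axis=1, keepdims=True))
    pz = (px - px.mean(axis=1, keepdims=True))
    lz /= np.linalg.norm(lz, axis=1, keepdims=True)
    pz /= np.linalg.norm(pz, axis=1, keepdims=True)
    r = np.clip(lz @ pz.T, -1.0, 1.0)  # lnc x pcg PCC matrix

    n_pairs = r.size
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -0.999999999, 0.999999999)) * math.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = np.minimum(p * n_pairs, 1.0)  # Bonferroni over tested pairs

    lo = np.quantile(r, extreme_frac)
    hi = np.quantile(r, 1.0 - extreme_frac)
    keep = (p_adj < adj_p_cut) & ((r >= hi) | (r <= lo))
    out: dict[tuple[str, str], int] = {}
    ii, jj = np.nonzero(keep)
    for i, j in zip(ii, jj):
        out[(lnc_keep[i], pcg_keep[j])] = 1 if r[i, j] >= 0 else -1
    return out


def build_coexpression_network(
    datasets,
    adj_p_cut: float = 0.01,
    extreme_frac: float = 0.001,
    min_support: int = 3,
    cv_min: float = 0.3,
    top_frac: float = 0.75,
) -> AssociationNetwork:
    """Cross-dataset co-expression network.

    ``datasets`` is a sequence of (lnc_matrix, pcg_matrix) pairs (or objects
    with .lnc/.pcg). A pair is kept when the same correlation sign passes the
    per-dataset retention rule in at least ``min_support`` datasets.
    """
    if len(datasets) < min_support:
        raise ValueError(f"need at least min_support={min_support} datasets, got {len(datasets)}")
    pos: dict[tuple[str, str], int] = {}
    neg: dict[tuple[str, str], int] = {}
    for ds in datasets:
        lnc, pcg = (ds.lnc, ds.pcg) if hasattr(ds, "lnc") else ds
        for pair, sign in _dataset_significant_pairs(
            lnc, pcg, adj_p_cut, extreme_frac, cv_min, top_frac
        ).items():
            (pos if sign > 0 else neg)[pair] = (pos if sign > 0 else neg).get(pair, 0) + 1
    rows = []
    for pair in sorted(set(pos) | set(neg)):
        np_, nn = pos.get(pair, 0), neg.get(pair, 0)
        if max(np_, nn) < min_support or np_ == nn:
            continue
        sign, support = ("+", np_) if np_ > nn else ("-", nn)
        rows.append((pair[0], pair[1], "coexpr", sign, support))
    return AssociationNetwork(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def shared_mirna_p(N: int, M: int, n: int, m: int, inclusive: bool = False) -> float:
    """Upper-tail hypergeometric P for ``m`` shared miRNAs.

    N: miRNAs interacting with any lncRNA/mRNA; M: partners of the mRNA;
    n: partners of the lncRNA; m: shared. Default is the strictly-greater
    tail P(X > m) = 1 - sum_{k<=m} C(n,k) C(N-n,M-k) / C(N,M);
    ``inclusive=True`` gives P(X >= m).
    """
    if not (0 <= m <= min(n, M) <= N and M <= N and n <= N):
        raise ValueError(f"impossible hypergeometric arguments N={N}, M={M}, n={n}, m={m}")
    # scipy parameterisation: population N, successes n, draws M
    if inclusive:
        return float(stats.hypergeom.sf(m - 1, N, n, M))
    return float(stats.hypergeom.sf(m, N, n, M))


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def build_cerna_network(
    table: MirnaInteractionTable,
    p_cut: float = 0.05,
    top_frac: float = 0.20,
    inclusive: bool = False,
) -> AssociationNetwork:
    """ceRNA network: per lncRNA, candidate mRNAs sharing >=1 miRNA are kept
    when the shared-miRNA hypergeometric P < ``p_cut`` AND their Jaccard
    coefficient ranks in the top ``top_frac`` of that lncRNA's candidates
    (count = ceil(top_frac * n_candidates))."""
    N = len(table.universe)
    rows = []
    for lnc in sorted(table.lnc_to_mirna):
        lset = table.lnc_to_mirna[lnc]
        if not lset:
            continue
        cands = []
        for mrna in sorted(table.mrna_to_mirna):
            mset = table.mrna_to_mirna[mrna]
            shared = len(lset & mset)
            if shared == 0:
                continue
            p = shared_mirna_p(N, len(mset), len(lset), shared, inclusive=inclusive)
            cands.append((mrna, p, jaccard(lset, mset)))
        if not cands:
            continue
        k = math.ceil(top_frac * len(cands))
        jac_cut = sorted((c[2] for c in cands), reverse=True)[k - 1]
        for mrna, p, jac in cands:
            if p < p_cut and jac >= jac_cut:
                rows.append((lnc, mrna, "cerna", "n/a", 0))
    return AssociationNetwork(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def merge_networks(coexpr: AssociationNetwork, cerna: AssociationNetwork) -> AssociationNetwork:
    """Set union on (lncRNA, PCG); shared edges get provenance 'both' and keep
    the co-expression sign and support."""
    co = {(r.lncrna, r.pcg): r for r in coexpr.edges.itertuples()}
    ce = {(r.lncrna, r.pcg): r for r in cerna.edges.itertuples()}
    rows = []
    for pair in sorted(set(co) | set(ce)):
        if pair in co and pair in ce:
            r = co[pair]
            rows.append((r.lncrna, r.pcg, "both", r.sign, r.support))
        elif pair in co:
            r = co[pair]
            rows.append((r.lncrna, r.pcg, r.provenance, r.sign, r.support))
        else:
            r = ce[pair]
            rows.append((r.lncrna, r.pcg, r.provenance, r.sign, r.support))
    return AssociationNetwork(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def read_network(path) -> AssociationNetwork:
    """Load an edge-list TSV (lncrna, pcg, provenance, sign, support)."""
    df = pd.read_csv(path, sep="\t", dtype={"sign": str})
    return AssociationNetwork(df)


def write_network(net: AssociationNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)
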