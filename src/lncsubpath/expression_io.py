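"""Matched lncRNA/mRNA expression matrices: I/O, filtering, differential tests.

Expression values are non-negative abundances (FPKM-like). Differential
statistics are computed on log2(x + pseudocount); fold changes are ratios of
linear-scale group means. Two-group designs only ("case" vs "control"; a
tumour/normal contrast maps tumour -> case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CASE = "case"
CONTROL = "control"

__all__ = [
    "ExpressionPair",
    "read_expression_pair",
    "filter_low_expression",
    "differential_table",
    "select_risk_lncrnas",
]


class EmptyFilterError(ValueError):
    """No features survive filtering."""


@dataclass
class ExpressionPair:
    """Matched lncRNA and protein-coding-gene matrices over the same samples.

    Parameters
    ----------
    lnc : DataFrame, lncRNA x sample, non-negative abundances.
    pcg : DataFrame, PCG x sample, non-negative abundances.
    groups : Series mapping sample id -> {"case", "control"}.
    """

    lnc: pd.DataFrame
    pcg: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.lnc.columns) != list(self.pcg.columns):
            raise ValueError("lncRNA and PCG matrices must share the identical ordered sample set")
        missing = [s for s in self.lnc.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.loc[list(self.lnc.columns)]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        for name, mat in (("lnc", self.lnc), ("pcg", self.pcg)):
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"negative values in {name} matrix")
        overlap = set(self.lnc.index) & set(self.pcg.index)
        if overlap:
            raise ValueError(f"lncRNA and PCG identifiers must be disjoint: {sorted(overlap)[:5]}")
        for grp in (CASE, CONTROL):
            if not any(self.groups.loc[s] == grp for s in self.lnc.columns):
                raise ValueError(f"group '{grp}' has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lnc.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups.loc[s] == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(CONTROL)


def read_expression_pair(lnc_path, pcg_path, groups_path) -> ExpressionPair:
    """Read TSV matrices (first column = feature id) plus a two-column
    sample->group TSV and assemble an :class:`ExpressionPair`."""
    lnc = pd.read_csv(lnc_path, sep="\t", index_col=0)
    pcg = pd.read_csv(pcg_path, sep="\t", index_col=0)
    grp = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionPair(lnc=lnc, pcg=pcg, groups=grp)


def filter_low_expression(pair: ExpressionPair, min_nonzero_frac: float = 0.2) -> ExpressionPair:
    """Drop features with non-zero values in fewer than ``min_nonzero_frac``
    of the samples ("at least" semantics: exactly the threshold is kept)."""
    if not 0 < min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must be in (0, 1]")

    def keep(mat: pd.DataFrame) -> pd.DataFrame:
        frac = (mat.to_numpy() != 0).sum(axis=1) / mat.shape[1]
        return mat.loc[frac >= min_nonzero_frac]

    lnc, pcg = keep(pair.lnc), keep(pair.pcg)
    if lnc.empty or pcg.empty:
        raise EmptyFilterError("no features survive filtering")
    return ExpressionPair(lnc=lnc, pcg=pcg, groups=pair.groups)


def differential_table(
    matrix: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-feature two-group differential expression.

    Returns a DataFrame indexed by feature with columns:

    - ``fc``      linear fold change (mean_case + pc) / (mean_control + pc)
    - ``log2fc``  its log2
    - ``pvalue``  two-sided two-sample t-test on log2(x + pc)
    - ``padj``    Benjamini-Hochberg over all rows
    - ``degenerate``  True where both within-group variances were zero (the
      t statistic is undefined; P is reported as 1, not NaN)
    """
    case_cols = [s for s in matrix.columns if groups.loc[s] == CASE]
    ctrl_cols = [s for s in matrix.columns if groups.loc[s] == CONTROL]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >=2 samples per group for the t-test")

    x_case = matrix[case_cols].to_numpy(dtype=float)
    x_ctrl = matrix[ctrl_cols].to_numpy(dtype=float)

    fc = (x_case.mean(axis=1) + pseudocount) / (x_ctrl.mean(axis=1) + pseudocount)
    log2fc = np.log2(fc)

    l_case = np.log2(x_case + pseudocount)
    l_ctrl = np.log2(x_ctrl + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(l_case, l_ctrl, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (l_case.var(axis=1) == 0) & (l_ctrl.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero within-group variance; P set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"fc": fc, "log2fc": log2fc, "pvalue": pvals, "padj": padj, "degenerate": degenerate},
        index=matrix.index,
    )


def select_risk_lncrnas(
    table: pd.DataFrame,
    fdr_cut: float = 0.25,
    fc_hi: float = 1.5,
    fc_lo: float = 2 / 3,
) -> list[str]:
    """Differentially expressed lncRNAs: adjusted P < fdr_cut and linear fold
    change strictly > fc_hi or strictly < fc_lo."""
    mask = (table["padj"] < fdr_cut) & ((table["fc"] > fc_hi) | (table["fc"] < fc_lo))
    return list(table.index[mask])
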