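import numpy as np
import pandas as pd
import pytest

from lncsubpath.expression_io import ExpressionPair


def make_pair(lnc: dict, pcg: dict, n_case: int, n_ctrl: int) -> ExpressionPair:
    """Assemble an ExpressionPair from feature -> value-list dicts; the first
    ``n_case`` samples are cases."""
    samples = [f"s{i}" for i in range(n_case + n_ctrl)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    lnc_df = pd.DataFrame.from_dict(lnc, orient="index", columns=samples, dtype=float)
    pcg_df = pd.DataFrame.from_dict(pcg, orient="index", columns=samples, dtype=float)
    return ExpressionPair(lnc=lnc_df, pcg=pcg_df, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pair():
    """4 case + 4 control samples, 2 lncRNAs, 3 PCGs, mild structure."""
    rng = np.random.default_rng(7)
    base = rng.uniform(1, 10, size=(5, 8))
    lnc = {"lncA": base[0], "lncB": base[1]}
    pcg = {"geneA": base[2], "geneB": base[3], "geneC": base[4]}
    return make_pair(lnc, pcg, 4, 4)
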