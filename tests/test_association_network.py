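import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lncsubpath.association_network import (
    EDGE_COLUMNS,
    AssociationNetwork,
    MirnaInteractionTable,
    build_cerna_network,
    build_coexpression_network,
    fisher_correlation_p,
    jaccard,
    merge_networks,
    shared_mirna_p,
    variability_filter,
)


def hypergeom_tail_exact(N, M, n, m):
    """Independent oracle: exact strictly-greater tail by direct summation."""
    total = Fraction(0)
    denom = math.comb(N, M)
    for k in range(m + 1, min(n, M) + 1):
        total += Fraction(math.comb(n, k) * math.comb(N - n, M - k), denom)
    return total


class TestVariabilityFilter:
    def test_constant_row_dropped(self):
        m = pd.DataFrame({"a": [5, 5, 5], "b": [1, 2, 9]}, index=["s1", "s2", "s3"]).T
        assert "a" not in variability_filter(m)

    def test_cv_arithmetic(self):
        # values (1,1,4): mean 2, sd ~1.732, CV ~0.866 passes the CV test
        m = pd.DataFrame([[1, 1, 4]], index=["x"], columns=["s1", "s2", "s3"])
        assert variability_filter(m) == ["x"]

    def test_identical_cvs_all_kept(self):
        m = pd.DataFrame([[1, 2, 3], [2, 4, 6], [10, 20, 30]],
                         index=list("abc"), columns=["s1", "s2", "s3"])
        assert variability_filter(m) == ["a", "b", "c"]

    def test_zero_mean_dropped(self):
        m = pd.DataFrame([[0, 0, 0], [1, 5, 9]], index=["z", "v"],
                         columns=["s1", "s2", "s3"])
        assert variability_filter(m) == ["v"]


class TestFisherCorrelationP:
    def test_null_correlation(self):
        assert fisher_correlation_p(0.0, 30) == pytest.approx(1.0)

    def test_reference_value(self):
        assert fisher_correlation_p(0.5, 28) == pytest.approx(0.0060, abs=2e-4)

    def test_sign_symmetry(self):
        assert fisher_correlation_p(-0.5, 28) == fisher_correlation_p(0.5, 28)

    def test_perfect_correlation_and_small_n(self):
        assert fisher_correlation_p(1.0, 10) == 0.0
        with pytest.raises(ValueError):
            fisher_correlation_p(0.5, 3)


class TestSharedMirnaP:
    def test_reference_value(self):
        assert shared_mirna_p(20, 5, 4, 2) == pytest.approx(496 / 15504, rel=1e-9)

    def test_full_tail_consumed(self):
        assert shared_mirna_p(20, 5, 4, 4) == pytest.approx(0.0, abs=1e-12)

    def test_no_interactions(self):
        assert shared_mirna_p(20, 5, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_impossible_arguments(self):
        with pytest.raises(ValueError):
            shared_mirna_p(10, 5, 4, 5)

    def test_matches_direct_summation_small_grid(self):
        for N in (6, 11, 17):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(n, M) + 1):
                        expect = float(hypergeom_tail_exact(N, M, n, m))
                        assert shared_mirna_p(N, M, n, m) == pytest.approx(expect, abs=1e-10)

    def test_inclusive_tail_option(self):
        # P(X >= m) = P(X > m-1)
        assert shared_mirna_p(20, 5, 4, 2, inclusive=True) == pytest.approx(
            float(hypergeom_tail_exact(20, 5, 4, 1)), rel=1e-9
        )


class TestJaccard:
    @pytest.mark.parametrize("a, b, expect", [
        ({1, 2}, {1, 2}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4, 5, 6}, 2 / 6),
        (set(), set(), 0.0),
    ])
    def test_values(self, a, b, expect):
        assert jaccard(a, b) == pytest.approx(expect)


def _coexpr_dataset(seed, sign=1, n=30):
    """One dataset where lnc1 ~ gene1 strongly (given sign), others noise."""
    rng = np.random.default_rng(seed)
    g1 = rng.uniform(5, 35, n)
    lnc1 = (g1 if sign > 0 else 40.0 - g1) + rng.normal(0, 0.5, n)
    lnc = pd.DataFrame({"lnc1": lnc1,
                        **{f"lnc{i}": rng.uniform(5, 35, n) for i in range(2, 5)}}).T
    pcg = pd.DataFrame({"gene1": g1,
                        **{f"gene{i}": rng.uniform(5, 35, n) for i in range(2, 5)}}).T
    lnc.columns = pcg.columns = [f"s{i}" for i in range(n)]
    return lnc, pcg


def _build(datasets, min_support=3):
    # top_frac=1 keeps every variable feature so the cross-dataset
    # sign-consistency rule is what is exercised here
    return build_coexpression_network(datasets, extreme_frac=0.2,
                                      min_support=min_support, top_frac=1.0)


class TestCoexpressionNetwork:
    def test_consistent_pair_included_with_support(self):
        net = _build([_coexpr_dataset(s) for s in range(5)])
        edge = net.edges[(net.edges.lncrna == "lnc1") & (net.edges.pcg == "gene1")]
        assert len(edge) == 1
        assert edge.iloc[0]["sign"] == "+"
        assert edge.iloc[0]["support"] >= 3

    def test_negative_correlation_carries_minus_sign(self):
        net = _build([_coexpr_dataset(s, sign=-1) for s in range(3)])
        edge = net.edges[(net.edges.lncrna == "lnc1") & (net.edges.pcg == "gene1")]
        assert len(edge) == 1
        assert edge.iloc[0]["sign"] == "-"

    def test_inconsistent_signs_excluded(self):
        datasets = [_coexpr_dataset(0, 1), _coexpr_dataset(1, 1), _coexpr_dataset(2, -1)]
        net = _build(datasets)
        assert net.edges[(net.edges.lncrna == "lnc1") & (net.edges.pcg == "gene1")].empty

    def test_support_monotonicity(self):
        datasets = [_coexpr_dataset(s) for s in range(5)]
        sizes = [len(_build(datasets, min_support=k)) for k in (3, 4, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_datasets(self):
        with pytest.raises(ValueError, match="min_support"):
            build_coexpression_network([_coexpr_dataset(0)], min_support=3)

    def test_no_significant_pairs_gives_empty_network(self):
        rng = np.random.default_rng(0)
        datasets = []
        for _ in range(3):
            lnc = pd.DataFrame(rng.uniform(1, 2, (2, 20)), index=["lnc1", "lnc2"])
            pcg = pd.DataFrame(rng.uniform(1, 2, (2, 20)), index=["g1", "g2"])
            lnc.columns = pcg.columns = [f"s{i}" for i in range(20)]
            datasets.append((lnc, pcg))
        net = build_coexpression_network(datasets)
        assert len(net) == 0


class TestCernaNetwork:
    def test_dominant_sharing_pair_kept(self):
        mirnas = {f"m{i}" for i in range(20)}
        table = MirnaInteractionTable(
            mrna_to_mirna={"geneA": set(list(mirnas)[:6]),
                           **{f"gene{i}": {f"m{i + 10}"} for i in range(2, 8)}},
            lnc_to_mirna={"lncX": set(list(mirnas)[:6])},
        )
        net = build_cerna_network(table)
        assert ("lncX", "geneA") in set(zip(net.edges.lncrna, net.edges.pcg))

    def test_single_candidate_with_significant_p_kept(self):
        table = MirnaInteractionTable(
            mrna_to_mirna={"geneA": {"m1", "m2", "m3"},
                           "geneB": {"m9", "m10", "m11", "m12"}},
            lnc_to_mirna={"lncX": {"m1", "m2", "m3", "m4"}},
        )
        net = build_cerna_network(table)
        pairs = set(zip(net.edges.lncrna, net.edges.pcg))
        assert ("lncX", "geneA") in pairs
        assert ("lncX", "geneB") not in pairs  # shares no miRNA

    def test_nonsignificant_p_excluded_despite_jaccard(self):
        # one shared miRNA out of a tiny universe: P(X > 1) large
        table = MirnaInteractionTable(
            mrna_to_mirna={"geneA": {"m1", "m2"}},
            lnc_to_mirna={"lncX": {"m1", "m3"}},
        )
        net = build_cerna_network(table, p_cut=0.01)
        assert len(net) == 0


class TestMergeAndInvariants:
    def _net(self, pairs, provenance="coexpr", sign="+"):
        rows = [(l, g, provenance, sign if provenance == "coexpr" else "n/a",
                 3 if provenance == "coexpr" else 0) for l, g in pairs]
        return AssociationNetwork(pd.DataFrame(rows, columns=EDGE_COLUMNS))

    def test_disjoint_edge_sets_add(self):
        merged = merge_networks(self._net([("l1", "g1")]),
                                self._net([("l2", "g2")], "cerna"))
        assert len(merged) == 2

    def test_identical_edge_sets_marked_both(self):
        merged = merge_networks(self._net([("l1", "g1")]),
                                self._net([("l1", "g1")], "cerna"))
        assert len(merged) == 1
        assert merged.edges.iloc[0]["provenance"] == "both"
        assert merged.edges.iloc[0]["sign"] == "+"

    def test_partial_overlap(self):
        merged = merge_networks(self._net([("l1", "g1"), ("l1", "g2")]),
                                self._net([("l1", "g2"), ("l1", "g3")], "cerna"))
        assert len(merged) == 3
        prov = dict(zip(merged.edges.pcg, merged.edges.provenance))
        assert prov == {"g1": "coexpr", "g2": "both", "g3": "cerna"}

    def test_bipartite_enforced(self):
        bad = pd.DataFrame([("x", "x", "coexpr", "+", 3)], columns=EDGE_COLUMNS)
        with pytest.raises(ValueError, match="bipartite"):
            AssociationNetwork(bad)

    def test_duplicates_rejected(self):
        bad = pd.DataFrame([("l", "g", "coexpr", "+", 3), ("l", "g", "cerna", "n/a", 0)],
                           columns=EDGE_COLUMNS)
        with pytest.raises(ValueError, match="duplicate"):
            AssociationNetwork(bad)
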