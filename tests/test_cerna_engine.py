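import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cescan import (
    CeRNAParams,
    MreIndex,
    adjust_fdr,
    aggregate_mres,
    build_pairs,
    cerna_score,
    hypergeom_pvalue,
    pairs_to_frame,
)
from cescan.cerna_engine import CeRNAPair
from cescan.io_formats import SITE_COLUMNS
from oracles import bh_stepup, closed_form_hypergeom_tail, enumerate_hypergeom_tail


def _site_rows(rows):
    """rows: (transcript_id, biotype, mirna_id, t_start)"""
    return pd.DataFrame(
        [
            [tid, tid, bt, mid, "8mer", s, s + 8, 0, s + 8, 40.0, None, None]
            for tid, bt, mid, s in rows
        ],
        columns=SITE_COLUMNS,
    )


class TestAggregation:
    def test_counts_and_totals(self):
        idx = aggregate_mres(
            _site_rows(
                [("t1", "lncRNA", "a", 10), ("t1", "lncRNA", "a", 50),
                 ("t1", "lncRNA", "b", 90), ("t1", "lncRNA", "b", 130),
                 ("t1", "lncRNA", "b", 170)]
            )
        )
        assert idx.total("t1") == 5 and idx.mirnas("t1") == {"a", "b"}

    def test_empty_table_empty_index(self):
        idx = aggregate_mres(_site_rows([]))
        assert idx.transcripts == []

    def test_duplicate_rows_counted_once(self):
        rows = _site_rows([("t1", "lncRNA", "a", 10), ("t1", "lncRNA", "a", 10)])
        assert aggregate_mres(rows).total("t1") == 1


class TestScore:
    def test_direct_ratio(self):
        assert cerna_score(3, 10) == pytest.approx(0.3)

    def test_all_shared_is_one(self):
        assert cerna_score(7, 7) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cerna_score(0, 0)


class TestHypergeometricTest:
    def test_spot_configuration(self):
        """(M_T=10, m_p=4, m_n=5, m_c=3): (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5)."""
        assert hypergeom_pvalue(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)
        # verified against full enumeration of all C(10,5) draws
        assert enumerate_hypergeom_tail(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-15)

    def test_zero_overlap_is_exactly_one(self):
        assert hypergeom_pvalue(50, 10, 20, 0) == 1.0

    def test_full_margin_is_one(self):
        """m_p = M_T: every draw overlaps completely, so the tail is 1."""
        assert hypergeom_pvalue(10, 10, 4, 4) == pytest.approx(1.0)

    def test_closed_form_agreement_medium_sizes(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            M = int(rng.integers(2, 200))
            mp = int(rng.integers(0, M + 1))
            mn = int(rng.integers(0, M + 1))
            mc = int(rng.integers(0, min(mp, mn) + 1))
            assert hypergeom_pvalue(M, mp, mn, mc) == pytest.approx(
                closed_form_hypergeom_tail(M, mp, mn, mc), rel=1e-9, abs=1e-12
            )

    def test_log_space_stability_extreme_tail(self):
        p = hypergeom_pvalue(20000, 300, 300, 150)
        assert 0 < p < 1e-100

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 0), (10, 4, 5, 5), (10, 4, 5, -1), (0, 0, 0, 0)]
    )
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_pvalue(*args)


class TestBuildPairs:
    def _indexes(self):
        lnc = MreIndex({"L1": {"a": 2, "b": 1, "c": 1}, "L2": {"d": 3}})
        mrna = MreIndex({"P1": {"b": 1, "c": 2, "d": 1}, "P2": {"e": 1}})
        return lnc, mrna

    def test_shared_set_and_margins(self):
        lnc, mrna = self._indexes()
        pairs = build_pairs(lnc, mrna, CeRNAParams(M_T=10))
        by_key = {(p.lnc_id, p.mrna_id): p for p in pairs}
        p = by_key[("L1", "P1")]
        assert p.shared_mirnas == {"b", "c"} and (p.m_n, p.m_p, p.m_c) == (3, 3, 2)
        assert p.shared_mre_count == 2 and p.total_mre_lnc == 4
        assert p.cerna_score == pytest.approx(0.5)

    def test_disjoint_sets_make_no_pair(self):
        lnc, mrna = self._indexes()
        pairs = build_pairs(lnc, mrna, CeRNAParams(M_T=10))
        assert ("L2", "P2") not in {(p.lnc_id, p.mrna_id) for p in pairs}

    def test_sorted_by_shared_count_then_pvalue(self):
        lnc = MreIndex({"L1": {m: 1 for m in "abcde"}, "L2": {"a": 1, "b": 1}})
        mrna = MreIndex({"P1": {m: 1 for m in "abcde"}})
        pairs = build_pairs(lnc, mrna, CeRNAParams(M_T=20))
        assert [(p.lnc_id, p.m_c) for p in pairs] == [("L1", 5), ("L2", 2)]

    def test_small_universe_rejected(self):
        lnc, mrna = self._indexes()
        with pytest.raises(ValueError, match="M_T"):
            build_pairs(lnc, mrna, CeRNAParams(M_T=2))

    def test_default_universe_is_observed_mirnas(self):
        lnc, mrna = self._indexes()
        pairs = build_pairs(lnc, mrna, CeRNAParams())
        ref = build_pairs(lnc, mrna, CeRNAParams(M_T=5))  # union {a..e}
        assert [p.p_value for p in pairs] == [p.p_value for p in ref]

    def test_score_swaps_but_mc_and_p_do_not(self):
        """Denominating by the mRNA changes the score, never m_c or p."""
        lnc, mrna = self._indexes()
        a = build_pairs(lnc, mrna, CeRNAParams(M_T=10))
        b = build_pairs(lnc, mrna, CeRNAParams(M_T=10, mrna_denominated=True))
        for pa, pb in zip(a, b):
            assert (pa.m_c, pa.p_value) == (pb.m_c, pb.p_value)
        assert any(
            pa.cerna_score != pb.cerna_score for pa, pb in zip(a, b)
        )


class TestFdr:
    def test_single_pair_identity(self):
        (p,) = adjust_fdr([_pair(0.05)])
        assert p.q_value == pytest.approx(0.05)

    def test_hand_computed_stepup(self):
        pairs = adjust_fdr([_pair(0.01), _pair(0.02), _pair(0.03)])
        assert [p.q_value for p in pairs] == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        pairs = adjust_fdr([_pair(1.0), _pair(1.0)])
        assert [p.q_value for p in pairs] == [1.0, 1.0]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=30))
    def test_matches_textbook_stepup(self, ps):
        got = [p.q_value for p in adjust_fdr([_pair(p) for p in ps])]
        assert got == pytest.approx(bh_stepup(ps))

    def test_matches_statsmodels_reference(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        ps = [0.001, 0.2, 0.04, 0.9, 0.04, 0.5]
        got = [p.q_value for p in adjust_fdr([_pair(p) for p in ps])]
        ref = statsmodels.multipletests(ps, method="fdr_bh")[1]
        assert got == pytest.approx(list(ref))


def _pair(p):
    return CeRNAPair(
        lnc_id="L", mrna_id="P", shared_mirnas=frozenset({"a"}), m_p=1, m_n=1,
        shared_mre_count=1, total_mre_lnc=1, cerna_score=1.0, p_value=p,
    )


class TestPairFrame:
    def test_columns_and_shared_list_sorted(self):
        pair = CeRNAPair(
            "L", "P", frozenset({"mb", "ma"}), 2, 2, 2, 4, 0.5, 0.1, 0.1
        )
        df = pairs_to_frame([pair])
        assert df.at[0, "shared_miRNA_list"] == "ma,mb"
        assert df.at[0, "n_shared_miRNAs"] == 2
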