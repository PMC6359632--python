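"""Tiered expression calls: single-protein rules, table fixtures, symmetry."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from nsafde import (
    Call,
    DEFAULT_THRESHOLDS,
    DifferentialExpression,
    Tier,
    call_expression,
)
from .conftest import make_matrix


class TestCallExpression:
    @pytest.mark.parametrize(
        "sc_ref, sc_cmp, ratio, p, expected",
        [
            # high tier: modest 1.61-fold clears the 1.5 cutoff
            (98.7, 181.3, 1.61, 0.0, Call.OVEREXPRESSED),
            # medium governs a medium/very-low pair; 0.05 <= 0.5
            (34.0, 1.7, 0.05, 0.0, Call.UNDEREXPRESSED),
            # absent from comparison group -> unique to reference
            (2.0, 0.0, 0.0, math.nan, Call.UNIQUE_TO_REF),
            (0.0, 3.0, math.inf, math.nan, Call.UNIQUE_TO_CMP),
            (0.0, 0.0, math.nan, math.nan, Call.ABSENT_IN_BOTH),
            # ratio 1 is never differential
            (50.0, 50.0, 1.0, 1.0, Call.NOT_SIGNIFICANT),
            # significant p but ratio inside the dead zone
            (50.0, 60.0, 1.2, 0.001, Call.NOT_SIGNIFICANT),
            # good ratio but p above the medium ceiling
            (50.0, 150.0, 3.0, 0.06, Call.NOT_SIGNIFICANT),
            # very-low tier demands p <= 0.001
            (3.0, 6.0, 3.0, 0.005, Call.NOT_SIGNIFICANT),
            (3.0, 6.0, 3.0, 0.001, Call.OVEREXPRESSED),
            # boundary ratios are inclusive
            (30.0, 60.0, 2.0, 0.01, Call.OVEREXPRESSED),
            (90.0, 60.0, 2 / 3, 0.01, Call.UNDEREXPRESSED),
        ],
    )
    def test_call_rules(self, sc_ref, sc_cmp, ratio, p, expected):
        dc = call_expression(sc_ref, sc_cmp, ratio, p)
        assert dc.call is expected

    def test_governing_tier_recorded(self):
        dc = call_expression(9.0, 22.0, 2.25, 0.0)
        assert dc.tier_ref is Tier.LOW
        assert dc.tier_cmp is Tier.MEDIUM
        assert dc.governing_tier is Tier.MEDIUM
        assert dc.call is Call.OVEREXPRESSED  # 2.25 >= medium's 2.0, not low's 2.5

    @given(
        sc_ref=st.floats(0.5, 5000),
        sc_cmp=st.floats(0.5, 5000),
        ratio=st.floats(0.01, 100),
        p=st.floats(0, 1),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_group_swap_symmetry(self, sc_ref, sc_cmp, ratio, p):
        """Swapping the groups inverts the ratio and flips OE <-> UE."""
        # stay clear of the cutoffs themselves: 1/(1/r) is not exact in
        # floating point, so a ratio within one ulp of a cutoff can land on
        # different sides before and after the swap
        for cut in (1.5, 2.0, 2.5, 2 / 3, 0.5, 0.4):
            assume(abs(ratio - cut) > 1e-9 and abs(1.0 / ratio - cut) > 1e-9)
        forward = call_expression(sc_ref, sc_cmp, ratio, p).call
        backward = call_expression(sc_cmp, sc_ref, 1.0 / ratio, p).call
        flip = {
            Call.OVEREXPRESSED: Call.UNDEREXPRESSED,
            Call.UNDEREXPRESSED: Call.OVEREXPRESSED,
            Call.NOT_SIGNIFICANT: Call.NOT_SIGNIFICANT,
        }
        assert backward is flip[forward]

    @given(
        sc=st.floats(0.5, 5000),
        ratio=st.floats(0.01, 50),
        bump=st.floats(0.0, 50),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_monotone_in_ratio(self, sc, ratio, bump):
        """With p below every ceiling, increasing the ratio never demotes an
        overexpressed call to not-significant."""
        first = call_expression(sc, sc, ratio, 0.0).call
        second = call_expression(sc, sc, ratio + bump, 0.0).call
        if first is Call.OVEREXPRESSED:
            assert second is Call.OVEREXPRESSED


class TestTableFixtures:
    def test_neat_comparison_counts(self, neat_fixture):
        matrix, ratios = neat_fixture
        res = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
        assert res.n_dep == 26
        assert res.n_overexpressed == 16
        assert res.n_underexpressed == 10
        assert res.n_proteins_union == 126

    def test_neat_comparison_reproduces_each_reported_call(self, neat_table, neat_fixture):
        matrix, ratios = neat_fixture
        res = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
        got = res.calls.loc[neat_table.index, "call"]
        expected = neat_table["reported_call"].map(
            {"OE": Call.OVEREXPRESSED.value, "UE": Call.UNDEREXPRESSED.value}
        )
        assert (got == expected).all()

    def test_decoys_all_not_significant(self, neat_fixture):
        matrix, ratios = neat_fixture
        res = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
        decoys = res.calls[res.calls.index.str.startswith("BKG")]
        assert (decoys["call"] == Call.NOT_SIGNIFICANT.value).all()

    def test_processed_comparison_counts(self, processed_fixture):
        matrix, ratios = processed_fixture
        res = DifferentialExpression(matrix, "group2", "group4", nsaf_ratios=ratios).fit()
        assert res.n_dep == 6
        assert res.n_underexpressed == 4
        assert res.n_overexpressed == 1
        assert res.n_unique == 1
        assert res.calls.loc["Q8TF71", "call"] == Call.UNIQUE_TO_REF.value

    def test_swapping_groups_flips_every_call(self, neat_fixture):
        matrix, ratios = neat_fixture
        fwd = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
        inv = {a: 1.0 / r if r > 0 else math.inf for a, r in ratios.items()}
        bwd = DifferentialExpression(matrix, "group3", "group1", nsaf_ratios=inv).fit()
        assert bwd.n_overexpressed == fwd.n_underexpressed
        assert bwd.n_underexpressed == fwd.n_overexpressed
        assert bwd.n_dep == fwd.n_dep


class TestModelInterface:
    def test_computed_ratio_pipeline(self):
        """Without overrides the model computes NSAF ratios from the counts."""
        m = make_matrix(
            {
                "R1": {"A": 100, "B": 100}, "R2": {"A": 110, "B": 90},
                "C1": {"A": 300, "B": 100}, "C2": {"A": 310, "B": 110},
            },
            {"R1": ("ref", 1), "R2": ("ref", 2), "C1": ("cmp", 1), "C2": ("cmp", 2)},
        )
        res = DifferentialExpression(m, "ref", "cmp").fit()
        # A's NSAF share rises from ~0.51 to ~0.75, ratio ~1.45
        assert res.calls.loc["A", "nsaf_ratio"] == pytest.approx(1.45, abs=0.05)

    def test_same_group_rejected(self, neat_fixture):
        matrix, _ = neat_fixture
        with pytest.raises(ValueError):
            DifferentialExpression(matrix, "group1", "group1")

    def test_unknown_group_rejected(self, neat_fixture):
        matrix, _ = neat_fixture
        with pytest.raises(Exception, match="unknown group"):
            DifferentialExpression(matrix, "group1", "groupX")

    def test_report_formatting(self, processed_fixture):
        matrix, ratios = processed_fixture
        res = DifferentialExpression(matrix, "group2", "group4", nsaf_ratios=ratios).fit()
        report = res.report().set_index("accession")
        assert report.loc["Q8TF71", "Expression"] == "Unique to group2"
        assert report.loc["Q8TF71", "NSAF_ratio"] == "0.00"
        assert report.loc["P12074", "Expression"] == "OE"
        assert report.loc["O75969", "SC_ref"] == 146.3

    def test_summary_dict_keys(self, neat_fixture):
        matrix, ratios = neat_fixture
        res = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
        s = res.summary_dict()
        assert s["n_dep"] == s["n_oe"] + s["n_ue"] + s["n_unique"] == 26
        assert s["dep_fraction_percent"] == pytest.approx(100 * 26 / 126, abs=0.01)
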