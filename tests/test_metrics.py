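"""Rule layer: derived metrics, per-biopsy calls, case aggregation."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystiquant.metrics import (
    aggregate_case,
    classify_inflammation,
    light_chain_call,
    lymphoplasmacytic_density,
    plasma_cell_ratio,
    summarize_light_chain,
)

densities = st.floats(min_value=0, max_value=1e4, allow_nan=False)


class TestDerivedMetrics:
    def test_lymphoplasmacytic_sum(self):
        assert lymphoplasmacytic_density(0, 0, 0) == 0
        assert lymphoplasmacytic_density(100, 50, 50) == 200

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            lymphoplasmacytic_density(-1, 0, 0)

    def test_plasma_ratio_examples(self):
        assert plasma_cell_ratio(100, 100, 200) == pytest.approx(50.0)
        assert plasma_cell_ratio(300, 100, 0) == 0.0

    def test_plasma_ratio_undefined_flagged_not_zero(self):
        assert math.isnan(plasma_cell_ratio(0, 0, 0))

    @settings(max_examples=200, derandomize=True)
    @given(densities, densities, densities)
    def test_sum_dominates_parts_and_ratio_bounded(self, a, b, c):
        total = lymphoplasmacytic_density(a, b, c)
        assert total >= max(a, b, c)
        if total > 0:
            assert 0.0 <= plasma_cell_ratio(a, b, c) <= 100.0


class TestInflammation:
    @pytest.mark.parametrize("density,call", [
        (199.9, "normal"), (200.0, "inflamed"), (1500.0, "inflamed"),
        (0.0, "normal"),
    ])
    def test_boundary_convention(self, density, call):
        assert classify_inflammation(density).call == call

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            classify_inflammation(-5.0)

    def test_custom_cutoff(self):
        assert classify_inflammation(150.0, cutoff=100.0).call == "inflamed"


class TestLightChainCall:
    @pytest.mark.parametrize("k,l,call,side", [
        (300, 20, "restricted", "kappa"),      # ratio 15 > 5.5, total 320
        (40, 5, "polytypic", "none"),          # ratio 8 but total 45 <= 50
        (10, 60, "restricted", "lambda"),      # ratio 0.167 < 0.7, total 70
        (100, 50, "polytypic", "none"),        # ratio 2 in normal band
        (100, 0, "restricted", "kappa"),       # ratio +inf
        (0, 100, "restricted", "lambda"),      # ratio 0
        (0, 0, "polytypic", "none"),           # both zero -> undefined ratio
        (275, 50, "polytypic", "none"),        # ratio exactly 5.5 not aberrant
        (35, 50, "polytypic", "none"),         # ratio exactly 0.7 not aberrant
        (30, 20, "polytypic", "none"),         # total exactly 50: floor strict
    ])
    def test_truth_table(self, k, l, call, side):
        res = light_chain_call(k, l, True)
        assert (res.call, res.restricted_side) == (call, side)

    def test_not_evaluable_short_circuits(self):
        res = light_chain_call(1000, 1, False)
        assert res.call == "not_evaluable"

    def test_infinite_ratio_reported(self):
        assert light_chain_call(100, 0, True).kl_ratio == math.inf

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            light_chain_call(-1, 5, True)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(min_value=0.3, max_value=1e3),
        st.floats(min_value=0.3, max_value=1e3),
        st.floats(min_value=1.0, max_value=50.0),
    )
    def test_scale_invariance_above_floor(self, k, l, factor):
        """Joint rescaling keeping the floor satisfied never flips the call."""
        base = light_chain_call(k * 100, l * 100, True)
        scaled = light_chain_call(k * 100 * factor, l * 100 * factor, True)
        assert base.call == scaled.call
        assert base.restricted_side == scaled.restricted_side


class TestCaseAggregation:
    def _lc(self, call, side="none"):
        return light_chain_call(
            *{"restricted": (300.0, 20.0) if side != "lambda" else (10.0, 300.0),
              "polytypic": (100.0, 50.0)}.get(call, (0.0, 0.0)),
            call != "not_evaluable",
        )

    def test_one_restricted_biopsy_makes_case_positive(self):
        summary = aggregate_case(
            "c1", "HIC",
            {"BG": self._lc("restricted"), "HL": self._lc("polytypic")},
        )
        assert summary.case_light_chain == "positive"

    def test_all_not_evaluable_case(self):
        summary = aggregate_case(
            "c25", "HIC",
            {"BG": self._lc("not_evaluable"), "HL": self._lc("not_evaluable")},
        )
        assert summary.case_light_chain == "not_evaluable"

    def test_single_evaluable_negative_biopsy(self):
        summary = aggregate_case(
            "c6", "HIC",
            {"BG": self._lc("polytypic"), "HL": self._lc("not_evaluable")},
        )
        assert summary.case_light_chain == "negative"

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            aggregate_case("c0", "HIC", {})

    def test_case_inflamed_is_any_biopsy(self):
        summary = aggregate_case(
            "c2", "HIC", {"BG": self._lc("polytypic")},
            {"BG": classify_inflammation(100.0),
             "HL": classify_inflammation(800.0)},
        )
        assert summary.case_inflamed


class TestSummarize:
    def test_all_polytypic_cohort_zero_positive(self):
        table = pd.DataFrame({
            "case_id": ["a", "a", "b"],
            "site": ["BG", "HL", "BG"],
            "call": ["polytypic"] * 3,
            "restricted_side": ["none"] * 3,
        })
        counts = summarize_light_chain(table)
        assert counts["positive_cases"] == 0
        assert counts["positive_specimens"] == 0
        assert counts["evaluable_specimens"] == 3
        assert counts["evaluable_cases"] == 2

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            summarize_light_chain(pd.DataFrame({"case_id": []}))
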