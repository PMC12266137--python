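"""ddCt quantification, dilution design, hit calling and 4PL fitting."""

import numpy as np
import pandas as pd
import pytest

from spliceaso.pharmacology import (
    DoseResponseModel,
    call_hits,
    ddct_fold_change,
    fit_dose_response,
    serial_dilution,
)
from spliceaso.simulate import simulate_dose_response


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition",
                                       "ct_target", "ct_housekeeping"])


class TestDdct:
    def test_calibrator_is_unity(self):
        t = _ct_table([("s1", "mock", 24.0, 18.0), ("s1", "mock", 24.2, 18.2),
                       ("s2", "treated", 23.0, 18.0)])
        out = ddct_fold_change(t, "mock")
        mock = out[out.condition == "mock"]
        assert mock["fold"].values == pytest.approx([1.0])
        assert mock["percent"].values == pytest.approx([100.0])

    @pytest.mark.parametrize("ddct,fold", [(0.0, 1.0), (-1.0, 2.0), (4.644, 0.04)])
    def test_closed_form(self, ddct, fold):
        # one calibrator at dCt 6, one sample shifted by ddct
        t = _ct_table([("cal", "mock", 24.0, 18.0),
                       ("s", "aso", 24.0 + ddct, 18.0)])
        out = ddct_fold_change(t, "mock")
        got = out.loc[out.condition == "aso", "fold"].item()
        assert got == pytest.approx(fold, rel=1e-3)

    def test_technical_replicates_averaged_before_calibration(self):
        t = _ct_table([("s1", "mock", 24.0, 18.0), ("s1", "mock", 26.0, 18.0),
                       ("s2", "aso", 25.0, 18.0)])
        out = ddct_fold_change(t, "mock")
        assert len(out) == 2  # one row per (condition, sample)
        assert out.loc[out.condition == "aso", "ddct"].item() == pytest.approx(0.0)

    def test_missing_calibrator_raises(self):
        t = _ct_table([("s", "aso", 24.0, 18.0)])
        with pytest.raises(ValueError, match="calibrator"):
            ddct_fold_change(t, "mock")


class TestSerialDilution:
    def test_paper_screen_design(self):
        doses = serial_dilution(20, 4, 5)
        assert doses.tolist() == [20, 5, 1.25, 0.3125, 0.078125]
        assert round(doses.min(), 3) == 0.078

    def test_cycloheximide_design(self):
        assert serial_dilution(50, 2, 6).min() == pytest.approx(1.5625)

    def test_single_point(self):
        assert serial_dilution(7.5, 4, 1).tolist() == [7.5]


class TestCallHits:
    def test_strict_inequality_at_threshold(self):
        hits = call_hits({"a": 120.0, "b": 125.0, "c": 126.0}, 125.0)
        assert hits == ["c"]

    def test_no_effect_no_hits_and_controls_excluded(self):
        assert call_hits({"a": 100.0, "NTC": 300.0}, 125.0, controls=("NTC",)) == []

    def test_monotone_in_threshold(self):
        vals = {f"a{i}": 100.0 + 10 * i for i in range(8)}
        assert set(call_hits(vals, 150.0)) <= set(call_hits(vals, 125.0))

    def test_dose_selection_from_table(self):
        df = pd.DataFrame({
            "id": ["a"] * 2 + ["b"] * 2,
            "dose": [20.0, 5.0, 20.0, 5.0],
            "response": [160.0, 120.0, 120.0, 180.0],
        })
        assert call_hits(df, 140.0, at_dose=20.0) == ["a"]
        with pytest.raises(ValueError, match="missing"):
            call_hits(df, 140.0, at_dose=1.25)

    def test_planted_effects_all_called(self):
        """Power check: ASOs with a true 160% effect and SD-5 noise are all
        called at the 140% threshold."""
        rng = np.random.default_rng(12)
        truth = {f"hit{i}": 160.0 for i in range(6)} | {f"null{i}": 100.0 for i in range(6)}
        observed = {k: v + rng.normal(0, 5) for k, v in truth.items()}
        hits = call_hits(observed, 140.0)
        assert set(hits) == {k for k in truth if k.startswith("hit")}


DOSES = serial_dilution(20, 4, 5)


class TestDoseResponseFit:
    def test_noiseless_exact_recovery(self):
        t = simulate_dose_response(2.0, 1.5, DOSES, 0.0, seed=1, mode="stimulation")
        fit = fit_dose_response(t, mode="stimulation")
        assert fit.converged and fit.baseline_adjusted
        assert fit.ec50 == pytest.approx(2.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.5, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_inhibition_noiseless_recovery(self):
        t = simulate_dose_response(1.5, 1.0, DOSES, 0.0, seed=1, mode="inhibition")
        fit = fit_dose_response(t, mode="inhibition")
        assert fit.mode == "inhibition" and not fit.baseline_adjusted
        assert fit.ic50 == pytest.approx(1.5, rel=1e-6)

    def test_response_at_ec50_is_half_span(self):
        t = simulate_dose_response(2.0, 1.2, DOSES, 0.0, seed=1)
        fit = fit_dose_response(t)
        # normalized model value at the fitted EC50
        y = fit.top / (1 + (fit.ec50 / fit.ec50) ** fit.hill)
        assert 100 * y / fit.top == pytest.approx(50.0)

    def test_scale_equivariance_exact_power_of_two(self):
        t = simulate_dose_response(2.0, 1.5, DOSES, 10.0, seed=2)
        fit = fit_dose_response(t)
        scaled = t.copy()
        scaled["dose"] *= 8.0
        fit8 = fit_dose_response(scaled)
        assert fit8.ec50 == 8.0 * fit.ec50  # identical floating-point path

    def test_negative_adjusted_responses_tolerated(self):
        t = simulate_dose_response(2.0, 1.5, DOSES, 0.0, seed=1)
        t.loc[t["dose"] == t["dose"].min(), "response"] = 95.0  # below mock
        fit = fit_dose_response(t)
        assert fit.converged

    def test_monte_carlo_median_error_within_20pct(self):
        errs = []
        for s in range(60):
            t = simulate_dose_response(2.0, 1.0, DOSES, 5.0, seed=100 + s)
            fit = fit_dose_response(t)
            errs.append(abs(fit.ec50 - 2.0) / 2.0)
        assert np.median(errs) <= 0.20

    def test_replicate_means_policy(self):
        t = simulate_dose_response(2.0, 1.5, DOSES, 0.0, seed=1)
        model = DoseResponseModel.from_dataframe(t, replicate_policy="means")
        assert model.dose.size == 5
        assert model.fit().ec50 == pytest.approx(2.0, rel=1e-6)

    def test_too_few_doses_warns_and_invalid_inputs_raise(self):
        t = simulate_dose_response(1.0, 1.0, [4.0, 1.0], 0.0, seed=1)
        with pytest.warns(UserWarning, match="fewer than 4"):
            fit_dose_response(t)
        with pytest.raises(ValueError, match="distinct doses"):
            DoseResponseModel([1.0, 1.0], [10.0, 12.0])

    def test_summary_mentions_potency(self):
        t = simulate_dose_response(2.0, 1.5, DOSES, 0.0, seed=1)
        s = fit_dose_response(t).summary()
        assert "EC50" in s and "Hill" in s
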