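"""Clinical utility index: curve, averaging, selection rule and scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuidose import cui
from cuidose import trial_data as td
from cuidose.exposure_response import ERModel, Scenario
from cuidose.posterior import ExposureReplicates


def er(beta0, beta1, outcome=td.Outcome.ORR, metric="Cmax"):
    return ERModel(beta0=beta0, beta1=beta1, dispersion=1.0, metric=metric,
                   outcome=outcome, scenario=Scenario.ALL, n_units=10)


def brute_force_select(avg_cuis, doses, tau):
    """Independent oracle: the highest dose whose whole escalation prefix
    clears the threshold."""
    best = doses[0]
    for k in range(1, len(doses)):
        ok = all(
            100.0 * (avg_cuis[j] - avg_cuis[j - 1]) / avg_cuis[j - 1] >= tau
            for j in range(1, k + 1)
        )
        if ok:
            best = doses[k]
    return best


def replicates_from(dose_values: dict[float, np.ndarray],
                    metric="Cmax") -> ExposureReplicates:
    rows = [(d, metric, i, float(v)) for d, vals in dose_values.items()
            for i, v in enumerate(vals)]
    return ExposureReplicates(frame=pd.DataFrame(
        rows, columns=["dose_mgkg", "metric", "replicate", "value"]))


class TestCuiCurve:
    def test_weight_one_is_orr_probability(self):
        o, d = er(-2.0, 3e-5), er(-2.5, 1e-5, td.Outcome.DLT)
        x = np.linspace(0, 1e5, 7)
        np.testing.assert_allclose(cui.cui_curve(o, d, 1.0, x),
                                   1 / (1 + np.exp(-(-2.0 + 3e-5 * x))))

    def test_weight_zero_is_dlt_complement(self):
        o, d = er(-2.0, 3e-5), er(-2.5, 1e-5, td.Outcome.DLT)
        x = np.linspace(0, 1e5, 7)
        np.testing.assert_allclose(cui.cui_curve(o, d, 0.0, x),
                                   1 - 1 / (1 + np.exp(-(-2.5 + 1e-5 * x))))

    def test_equal_probabilities_give_half_at_p_half(self):
        """When p_orr = p_dlt = 0.5, CUI = w/2 + (1-w)/2 = 1/2 for any w."""
        o, d = er(0.0, 0.0), er(0.0, 0.0, td.Outcome.DLT)
        for w in (0.1, 0.5, 0.81):
            assert cui.cui_curve(o, d, w, np.array([1.0]))[0] == pytest.approx(0.5)

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            cui.cui_curve(er(-2, 3e-5), er(-2, 1e-5, td.Outcome.DLT, metric="AUC"),
                          0.5, np.array([1.0]))

    @settings(max_examples=60, deadline=None)
    @given(b0o=st.floats(-4, 4), b1o=st.floats(-1e-4, 1e-4),
           b0d=st.floats(-4, 4), b1d=st.floats(-1e-4, 1e-4),
           w=st.floats(0, 1))
    def test_bounded_in_unit_interval(self, b0o, b1o, b0d, b1d, w):
        x = np.linspace(0, 2e5, 50)
        vals = cui.cui_curve(er(b0o, b1o), er(b0d, b1d, td.Outcome.DLT), w, x)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            cui.cui_curve(er(-2, 3e-5), er(-2, 1e-5, td.Outcome.DLT), 1.2,
                          np.array([1.0]))


class TestAverageCui:
    def test_constant_curve(self):
        assert cui.average_cui(lambda x: np.full_like(x, 0.37),
                               np.array([1.0, 5.0, 9.0])) == pytest.approx(0.37)

    def test_linear_curve_is_midpoint(self):
        fn = lambda x: 0.1 + 0.002 * x  # noqa: E731
        got = cui.average_cui(fn, np.array([10.0, 110.0]), n_grid=501)
        assert got == pytest.approx((fn(np.array([10.0]))[0] + fn(np.array([110.0]))[0]) / 2,
                                    rel=1e-9)

    def test_single_replicate_degenerates_to_point_value(self):
        fn = lambda x: 0.1 + 0.002 * x  # noqa: E731
        assert cui.average_cui(fn, np.array([50.0])) == pytest.approx(0.2)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            cui.average_cui(lambda x: x, np.array([]))


class TestSelectDose:
    def test_flowchart_hand_trace(self):
        """(0.50, 0.60, 0.63) at tau=10%: +20% accepted, +5% rejected."""
        assert cui.select_dose([0.50, 0.60, 0.63], [1.0, 2.0, 3.0], 10.0) == 2.0

    def test_all_improvements_clear_threshold(self):
        assert cui.select_dose([0.3, 0.4, 0.55], [1, 2, 3], 10.0) == 3

    def test_first_improvement_fails(self):
        assert cui.select_dose([0.50, 0.51, 0.99], [1, 2, 3], 10.0) == 1

    def test_matches_brute_force_oracle_on_random_vectors(self):
        """1000 random average-CUI vectors against prefix enumeration."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            avg = rng.uniform(0.05, 0.95, k)
            doses = np.arange(1, k + 1, dtype=float)
            tau = float(rng.choice([0.0, 2.5, 5.0, 10.0, 20.0]))
            assert cui.select_dose(avg, doses, tau) == brute_force_select(
                list(avg), list(doses), tau)

    def test_selection_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            avg = rng.uniform(0.1, 0.9, 7)
            doses = np.arange(1.0, 8.0)
            sel = [cui.select_dose(avg, doses, t)
                   for t in (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0)]
            assert all(a >= b for a, b in zip(sel, sel[1:]))


class TestScan:
    def _models(self, orr_slope=4e-5, dlt_slope=1e-6):
        return {Scenario.ALL: {td.Outcome.ORR: er(-2.0, orr_slope),
                               td.Outcome.DLT: er(-3.0, dlt_slope, td.Outcome.DLT)}}

    def _reps(self, doses=(1.0, 2.0, 3.6, 4.8), scale=20000.0):
        rng = np.random.default_rng(0)
        return replicates_from({d: scale * d * np.exp(rng.normal(0, 0.2, 200))
                                for d in doses})

    def test_zero_threshold_selects_top_dose_when_improving(self):
        res = cui.scan(self._models(), self._reps(), [1.0, 2.0, 3.6, 4.8],
                       weight_grid=(30.0, 50.0, 81.0), threshold_grid=(0.0,))
        assert (res.selections.selected_dose == 4.8).all()

    def test_strong_efficacy_flat_safety_prefers_high_doses(self):
        res = cui.scan(self._models(), self._reps(), [1.0, 2.0, 3.6, 4.8],
                       weight_grid=tuple(np.arange(10.0, 91.0, 5.0)),
                       threshold_grid=(2.5,))
        assert res.selections.selected_dose.median() >= 3.6

    def test_monotone_threshold_property_over_grids(self):
        res = cui.scan(self._models(orr_slope=3e-5, dlt_slope=2e-5),
                       self._reps(), [1.0, 2.0, 3.6, 4.8])
        piv = res.selections.pivot_table(index=["scenario", "w_orr"],
                                         columns="threshold_pct",
                                         values="selected_dose")
        taus = sorted(piv.columns)
        for a, b in zip(taus, taus[1:]):
            assert (piv[b] <= piv[a]).all()

    def test_missing_scenario_skipped_with_note(self):
        res = cui.scan(self._models(), self._reps(), [1.0, 2.0, 3.6, 4.8],
                       weight_grid=(50.0,), threshold_grid=(5.0,))
        assert any("phase1" in s for s in res.skipped)
        assert set(res.selections.scenario) == {"all"}

    def test_selection_frequency_sums_to_one(self):
        res = cui.scan(self._models(), self._reps(), [1.0, 2.0, 3.6, 4.8])
        freq = res.selection_frequency()
        sums = freq.groupby(["scenario", "threshold_pct"]).frequency.sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cui.scan(self._models(), self._reps(), [1.0], weight_grid=())
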