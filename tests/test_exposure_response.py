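"""Weighted quasi-binomial exposure-response fits."""

import numpy as np
import pytest

from cuidose import exposure_response as er
from cuidose import synthetic
from cuidose import trial_data as td
from cuidose.exposure_response import (ERUnit, InsufficientRangeError, Scenario,
                                       assemble_units, fit_er, predict_p)
from cuidose.pk_twocmt import ExposureSummary


def _arm(arm_id, dose, phase="I", cancer="breast", schedule="Q3W", n=20):
    return td.StudyArm(study_id="S1", arm_id=arm_id, phase=phase,
                       cancer_type=cancer, drug="TDM1", dose_mgkg=dose,
                       schedule=schedule, n=n, median_weight_kg=70.0)


def small_dataset():
    """One study, two cancers x two dose arms, plus a weekly arm."""
    ds = td.Dataset()
    specs = [("A1", 2.4, "breast"), ("A2", 3.6, "breast"),
             ("A3", 2.4, "gastric"), ("A4", 3.6, "gastric")]
    for arm_id, dose, cancer in specs:
        ds.arms.append(_arm(arm_id, dose, cancer=cancer))
        ds.exposures[arm_id] = ExposureSummary(cmax=20000.0 * dose)
        ds.outcomes[(arm_id, td.Outcome.ORR)] = td.OutcomeCount(
            arm_ref=arm_id, outcome=td.Outcome.ORR, events=5, total=20)
    ds.arms.append(_arm("A5", 2.4, schedule="QW"))
    ds.exposures["A5"] = ExposureSummary(cmax=48000.0)
    ds.outcomes[("A5", td.Outcome.ORR)] = td.OutcomeCount(
        arm_ref="A5", outcome=td.Outcome.ORR, events=9, total=20)
    ds.validate()
    return ds


def simulate_units(beta0, beta1, n_units, seed, x_lo=5000.0, x_hi=90000.0,
                   n_per_unit=40):
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_lo, x_hi, n_units)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    ev = rng.binomial(n_per_unit, p)
    return [ERUnit(arm_ref=str(i), exposure=float(x[i]), outcome=td.Outcome.ORR,
                   events=int(ev[i]), total=n_per_unit, phase=td.Phase.I)
            for i in range(n_units)]


class TestAssembleUnits:
    def test_cancer_by_dose_counting(self):
        units = assemble_units(small_dataset(), "Cmax", "ORR", "all")
        assert len(units) == 4  # 2 cancers x 2 arms; weekly arm excluded
        assert {u.arm_ref for u in units} == {"A1", "A2", "A3", "A4"}

    def test_weekly_arms_excluded(self):
        units = assemble_units(small_dataset(), "Cmax", "ORR", "all")
        assert "A5" not in {u.arm_ref for u in units}

    def test_phase_filter_empty_raises(self):
        ds = small_dataset()
        for i, a in enumerate(ds.arms):
            ds.arms[i] = a.model_copy(update={"phase": td.Phase.III})
        with pytest.raises(InsufficientRangeError, match="phase"):
            assemble_units(ds, "Cmax", "ORR", "phase1")

    def test_scenario_nesting(self):
        ds = synthetic.generate(synthetic.SimConfig(n_studies=40, seed=3))
        u1 = {u.arm_ref for u in assemble_units(ds, "Cmax", "ORR", "phase1")}
        u12 = {u.arm_ref for u in assemble_units(ds, "Cmax", "ORR", "phase1_2")}
        uall = {u.arm_ref for u in assemble_units(ds, "Cmax", "ORR", "all")}
        assert u1 <= u12 <= uall

    def test_weight_is_sqrt_total(self):
        units = assemble_units(small_dataset(), "Cmax", "ORR", "all")
        assert all(u.weight == pytest.approx(np.sqrt(u.total)) for u in units)


class TestFitER:
    def test_constant_response_gives_zero_slope(self):
        units = [ERUnit(arm_ref=str(i), exposure=x, outcome=td.Outcome.ORR,
                        events=6, total=20, phase=td.Phase.I)
                 for i, x in enumerate((1e4, 3e4, 9e4))]
        m = fit_er(units)
        assert m.beta1 == pytest.approx(0.0, abs=1e-6 / 1e4)
        assert m.beta0 == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_single_exposure_value_rejected(self):
        units = [ERUnit(arm_ref=str(i), exposure=5e4, outcome=td.Outcome.ORR,
                        events=e, total=20, phase=td.Phase.I)
                 for i, e in enumerate((3, 6, 9))]
        with pytest.raises(InsufficientRangeError):
            fit_er(units)

    def test_coefficient_recovery_coverage(self):
        """Truth within 2 quasi-binomial SEs in >= 90% of 100 replicates."""
        beta0, beta1 = -2.0, 3.0e-5
        hits0 = hits1 = 0
        for rep in range(100):
            m = fit_er(simulate_units(beta0, beta1, 50, seed=rep))
            hits0 += abs(m.beta0 - beta0) < 2 * m.se_beta0
            hits1 += abs(m.beta1 - beta1) < 2 * m.se_beta1
        assert hits0 >= 90
        assert hits1 >= 90

    def test_weight_doubles_influence(self):
        """A unit re-entered with 4x the sample size moves the slope about
        twice as far from the leave-one-out fit (weight sqrt(4) = 2)."""
        base = simulate_units(-2.0, 3.0e-5, 30, seed=7)
        extreme = ERUnit(arm_ref="x", exposure=95000.0, outcome=td.Outcome.ORR,
                         events=2, total=40, phase=td.Phase.I)
        heavy = ERUnit(arm_ref="x", exposure=95000.0, outcome=td.Outcome.ORR,
                       events=8, total=160, phase=td.Phase.I)
        b_without = fit_er(base).beta1
        d_light = fit_er(base + [extreme]).beta1 - b_without
        d_heavy = fit_er(base + [heavy]).beta1 - b_without
        assert d_heavy / d_light == pytest.approx(2.0, rel=0.35)

    def test_common_weight_scaling_leaves_coefficients(self):
        units = simulate_units(-2.0, 3.0e-5, 25, seed=9)
        m1 = fit_er(units)
        tripled = [ERUnit(arm_ref=u.arm_ref, exposure=u.exposure,
                          outcome=u.outcome, events=u.events * 9,
                          total=u.total * 9, phase=u.phase) for u in units]
        m9 = fit_er(tripled)
        # same proportions, 9x totals -> weights scale by 3; coefficients match
        assert m9.beta0 == pytest.approx(m1.beta0, rel=1e-6)
        assert m9.beta1 == pytest.approx(m1.beta1, rel=1e-6)

    def test_separation_flagged(self):
        units = [ERUnit(arm_ref=str(i), exposure=x, outcome=td.Outcome.ORR,
                        events=e, total=20, phase=td.Phase.I)
                 for i, (x, e) in enumerate(
                     [(1e4, 0), (2e4, 0), (3e4, 0), (7e4, 20), (8e4, 20), (9e4, 20)])]
        m = fit_er(units)
        assert m.separation


class TestPredict:
    def test_half_probability_at_logit_zero(self):
        m = er.ERModel(beta0=-2.0, beta1=4.0e-5, dispersion=1.0, metric="Cmax",
                       outcome=td.Outcome.ORR, scenario=Scenario.ALL, n_units=5)
        assert float(predict_p(m, 2.0 / 4.0e-5)) == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        m = er.ERModel(beta0=-1.3, beta1=2.5e-5, dispersion=1.0, metric="Cmax",
                       outcome=td.Outcome.ORR, scenario=Scenario.ALL, n_units=5)
        x = np.linspace(0, 1e5, 11)
        np.testing.assert_allclose(predict_p(m, x),
                                   1 / (1 + np.exp(-(-1.3 + 2.5e-5 * x))),
                                   rtol=1e-12)

    def test_monotone_in_exposure(self):
        m = er.ERModel(beta0=-1.0, beta1=3.0e-5, dispersion=1.0, metric="Cmax",
                       outcome=td.Outcome.ORR, scenario=Scenario.ALL, n_units=5)
        p = predict_p(m, np.linspace(0, 2e5, 200))
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))
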