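"""Summary-level mixed-effects estimation: identifiability, weighting and
diagnostics."""

import numpy as np
import pytest

from cuidose import mbma, synthetic
from cuidose import trial_data as td
from cuidose.mbma import BSVParams, FitOptions, ResidualError
from cuidose.pk_twocmt import DoseEvent, PKParams, concentration

from conftest import make_fit_result

TIMES = [1.5, 4.0, 24.0, 72.0, 168.0, 336.0, 504.0]


def noiseless_dataset(pk: PKParams, doses=(1.2, 2.4, 3.6), n=30, weight=70.0):
    ds = td.Dataset()
    for i, dose in enumerate(doses):
        arm_id = f"A{i}"
        ds.arms.append(td.StudyArm(
            study_id=f"S{i}", arm_id=arm_id, phase="I", cancer_type="breast",
            drug="TDM1", dose_mgkg=dose, schedule="Q3W", n=n,
            median_weight_kg=weight))
        conc = concentration(np.array(TIMES), DoseEvent(dose_mg=dose * weight), pk)
        ds.conc[arm_id] = td.ConcSeries(arm_ref=arm_id, times=TIMES,
                                        conc=[float(c) for c in conc])
    ds.validate()
    return ds


class TestNoiselessIdentifiability:
    def test_exact_recovery_from_noise_free_curves(self, tdm1_params):
        """Noise-free single-study data pins every fixed effect to 0.1%."""
        ds = noiseless_dataset(tdm1_params)
        fr = mbma.fit(ds, FitOptions(n_starts=1, compute_rse=False,
                                     truncated=False))
        assert fr.pk.CL == pytest.approx(tdm1_params.CL, rel=1e-3)
        assert fr.pk.Vc == pytest.approx(tdm1_params.Vc, rel=1e-3)
        assert fr.pk.Vp == pytest.approx(tdm1_params.Vp, rel=1e-3)
        assert fr.pk.Q == pytest.approx(tdm1_params.Q, rel=1e-3)


class TestLikelihoodShape:
    def test_truth_beats_perturbed_parameters_on_large_data(self):
        """Consistency smoke test: the generating values out-score +/-50%
        perturbations of each fixed effect on a large dataset."""
        ds = synthetic.generate(synthetic.recovery_config("TDM1", 120, seed=21))
        tab = mbma.prepare_arms(ds)
        opts = FitOptions()
        truth = np.array([np.log(0.809), np.log(3.283), np.log(0.748),
                          np.log(1.120), np.log(0.334), np.log(0.221),
                          np.arctanh(0.825), np.log(2633.766), np.log(0.430)])
        nll_truth = mbma._LaplaceNLL(tab, opts)(truth)
        # CL and Vc are the well-identified fixed effects at this design;
        # Vp and Q carry little information (their reported precision is
        # the weakest of the fixed effects)
        for k in range(2):
            for fac in (0.5, 1.5):
                pert = truth.copy()
                pert[k] += np.log(fac)
                assert mbma._LaplaceNLL(tab, opts)(pert) > nll_truth


class TestWeighting:
    def test_sqrt_n_scaling_of_residual_sd(self):
        """Quadrupling the arm size halves the proportional error SD, so
        identical raw residuals standardise to twice the value."""
        f = np.array([[50000.0, 2000.0]])
        sd_small, _ = mbma._sigma(f, a=0.0, b=0.4, sqrt_n=np.array([np.sqrt(10.0)]),
                                  error_form="additive", weight_constant=False)
        sd_big, _ = mbma._sigma(f, a=0.0, b=0.4, sqrt_n=np.array([np.sqrt(40.0)]),
                                error_form="additive", weight_constant=False)
        np.testing.assert_allclose(sd_small / sd_big, 2.0)

    def test_standardised_residuals_shrink_with_n_in_diagnostics(self, tdm1_params):
        """Same raw deviation, one arm 4x larger: std residuals ~2x bigger."""
        ds = td.Dataset()
        for arm_id, n in (("A0", 10), ("A1", 40)):
            ds.arms.append(td.StudyArm(
                study_id=arm_id, arm_id=arm_id, phase="I", cancer_type="breast",
                drug="TDM1", dose_mgkg=3.6, schedule="Q3W", n=n,
                median_weight_kg=70.0))
            f = concentration(np.array(TIMES), DoseEvent(dose_mg=3.6 * 70.0),
                              tdm1_params)
            ds.conc[arm_id] = td.ConcSeries(arm_ref=arm_id, times=TIMES,
                                            conc=[float(c * 1.05) for c in f])
        fr = make_fit_result(tdm1_params, bsv=BSVParams(1e-12, 1e-12, 0.0),
                             error=ResidualError(a=0.0, b=0.4))
        diag = mbma.diagnostics(fr, ds, n_sim=10, seed=0)
        gof = diag["gof"]
        r0 = gof[gof.arm_id == "A0"].std_resid.to_numpy()
        r1 = gof[gof.arm_id == "A1"].std_resid.to_numpy()
        np.testing.assert_allclose(r1 / r0, 2.0, rtol=1e-6)


class TestBtavSensitivity:
    def test_likelihoods_agree_when_one_arm_per_study(self):
        """With single-arm studies the arm-within-study level carries no
        information: at matched parameters and vanishing BTAV SDs the two
        marginal likelihoods coincide, so the conventions estimate the same
        fixed effects."""
        ds = synthetic.generate(synthetic.recovery_config("TDM1", 8, seed=31))
        tab = mbma.prepare_arms(ds)
        opts = FitOptions()
        theta = np.array([np.log(0.809), np.log(3.283), np.log(0.748),
                          np.log(1.120), np.log(0.334), np.log(0.221),
                          np.arctanh(0.825), np.log(2633.766), np.log(0.430)])
        nll_arms = mbma._LaplaceNLL(tab, opts)(theta)
        nll_sep = mbma._BtavNLL(tab, opts)(
            np.concatenate([theta, [np.log(1e-4)] * 2]))
        assert nll_sep == pytest.approx(nll_arms, abs=0.05)

    def test_separate_btav_fit_reports_btav_level(self):
        """The sensitivity estimator runs end to end and returns the extra
        arm-within-study SDs."""
        cfg = synthetic.SimConfig(n_studies=4, seed=31, n_range=(20, 40),
                                  arms_per_study=(2, 2), p_weekly=0.0,
                                  phase_mix={td.Phase.I: 1.0, td.Phase.II: 0.0,
                                             td.Phase.III: 0.0, td.Phase.IV: 0.0})
        ds = synthetic.generate(cfg)
        fr = mbma.fit(ds, FitOptions(n_starts=1, compute_rse=False,
                                     btav_mode="separate_btav", maxiter=60))
        assert fr.btav is not None
        assert np.isfinite([fr.pk.CL, fr.pk.Vc, fr.btav.omega_CL]).all()

    def test_unknown_mode_rejected(self):
        ds = synthetic.generate(synthetic.recovery_config("TDM1", 4, seed=1))
        with pytest.raises(ValueError):
            mbma.fit(ds, FitOptions(btav_mode="bogus"))


class TestDiagnostics:
    def test_zero_residuals_on_noiseless_generating_data(self, tdm1_params):
        ds = noiseless_dataset(tdm1_params)
        fr = make_fit_result(tdm1_params, bsv=BSVParams(1e-12, 1e-12, 0.0),
                             error=ResidualError(a=100.0, b=0.1))
        diag = mbma.diagnostics(fr, ds, n_sim=10, seed=0)
        assert np.max(np.abs(diag["gof"].std_resid)) < 1e-8

    def test_vpc_coverage_on_well_specified_data(self):
        """~90% of observations inside the 5-95% band when the model that
        simulates the bands is the one that generated the data."""
        ds = synthetic.generate(synthetic.recovery_config("TDM1", 30, seed=41))
        fr = make_fit_result(synthetic.TRUE_PK[td.Drug.TDM1],
                             bsv=synthetic.TRUE_BSV[td.Drug.TDM1],
                             error=synthetic.TRUE_ERROR[td.Drug.TDM1])
        vpc = mbma.diagnostics(fr, ds, n_sim=300, seed=1)["vpc"]
        cover = vpc.inside_90.mean()
        assert 0.78 <= cover <= 0.99

    def test_vpc_detects_understated_noise(self):
        """Data generated with doubled proportional error spill out of
        bands simulated at the nominal error: coverage drops below both
        the well-specified run and the nominal 90%."""
        fr = make_fit_result(synthetic.TRUE_PK[td.Drug.TDM1],
                             bsv=synthetic.TRUE_BSV[td.Drug.TDM1],
                             error=synthetic.TRUE_ERROR[td.Drug.TDM1])
        ds_ok = synthetic.generate(synthetic.recovery_config("TDM1", 30, seed=41))
        cov_ok = mbma.diagnostics(fr, ds_ok, n_sim=300, seed=1)["vpc"].inside_90.mean()
        cfg = synthetic.recovery_config("TDM1", 30, seed=41).model_copy(
            update={"true_error": ResidualError(a=2633.766, b=0.860)})
        ds_mis = synthetic.generate(cfg)
        cov_mis = mbma.diagnostics(fr, ds_mis, n_sim=300, seed=1)["vpc"].inside_90.mean()
        assert cov_mis < cov_ok
        assert cov_mis < 0.90

    def test_diagnostics_require_convergence(self, tdm1_params):
        fr = make_fit_result(tdm1_params)
        fr.convergence = False
        with pytest.raises(ValueError):
            mbma.diagnostics(fr, noiseless_dataset(tdm1_params))


class TestPreparation:
    def test_dose_finding_filter(self):
        cfg = synthetic.SimConfig(n_studies=20, seed=51)
        ds = synthetic.generate(cfg)
        tab_all = mbma.prepare_arms(ds)
        tab_df = mbma.prepare_arms(ds, dose_finding_only=True)
        assert tab_df.n_arms <= tab_all.n_arms
        by_study = {}
        for a in ds.arms:
            if a.phase == td.Phase.I:
                by_study.setdefault(a.study_id, set()).add(a.dose_mgkg)
        multi = {s for s, d in by_study.items() if len(d) >= 2}
        assert set(tab_df.study_ids) <= multi

    def test_too_few_arms_rejected(self, tdm1_params):
        ds = noiseless_dataset(tdm1_params, doses=(3.6,))
        with pytest.raises(ValueError):
            mbma.fit(ds)
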