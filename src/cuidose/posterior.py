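"""Bayesian individual dynamic predictions from a fitted population model.

For a study arm with observed summary concentrations, the posterior of its
random-effect pair (eta_CL, eta_Vc) is

    p(eta | y) ∝ p(y | eta) N(eta; 0, Omega_hat),

with the likelihood using the fitted square-root-of-n-weighted residual
model.  The sampler is a seeded random-walk Metropolis in the 2-D eta
space (4 chains, 1000 warm-up and 1000 kept draws each by default),
proposal covariance scaled from the Laplace curvature at the posterior
mode; convergence is summarised by split-Rhat and effective sample size.
Arms without concentration data fall back to prior draws and are flagged.

Exposure simulation then propagates parameter draws through the
closed-form model: for each dose level of the escalation grid,
``n_replicates`` (default 1000) parameter draws produce Cmax, Cmin(504 h)
and cycle-1 AUC replicates for a subject of the configured median body
weight.  Fixed-effect uncertainty is not propagated by default; an option
adds draws from the estimation covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mbma
from . import trial_data as td
from .pk_twocmt import (CYCLE_END_H, DEFAULT_INFUSION_H,
                        auc_0_t_arrays, concentration_arrays)

#: exposure metrics simulated per dose level
METRICS = ("Cmax", "Cmin", "AUC")

DEFAULT_N_REPLICATES = 1000


@dataclass
class PosteriorDraws:
    arm_ref: str
    draws: np.ndarray  # (size, 2) eta pairs
    size: int
    rhat: float = float("nan")
    ess: float = float("nan")
    from_prior: bool = False

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)


def _neg_log_post(eta: np.ndarray, sub: mbma._ArmTable, nat, Oinv, logdetO, opts):
    return mbma._gval(sub, eta.reshape(-1, 2), nat, Oinv, logdetO, opts)


def _nat_tuple(fit: mbma.FitResult) -> tuple:
    return (fit.pk.CL, fit.pk.Vc, fit.pk.Vp, fit.pk.Q,
            fit.bsv.omega_CL, fit.bsv.omega_Vc, fit.bsv.rho,
            fit.error.a, fit.error.b)


def sample_posterior(arm_id: str, ds: td.Dataset, fit: mbma.FitResult,
                     n_draws: int = 1000, seed: int = 0,
                     n_chains: int = 4, warmup: int = 1000,
                     keep: int = 1000) -> PosteriorDraws:
    """Draw (eta_CL, eta_Vc) conditional on the arm's concentration data.

    Degenerate prior (both omegas ~ 0) returns the point mass at zero.
    An arm without concentration data yields prior draws, flagged.
    """
    rng = np.random.default_rng(seed)
    bsv = fit.bsv
    if bsv.omega_CL < 1e-8 and bsv.omega_Vc < 1e-8:
        return PosteriorDraws(arm_ref=arm_id, draws=np.zeros((n_draws, 2)),
                              size=n_draws, rhat=1.0, ess=float(n_draws))
    Omega = bsv.cov() + 1e-12 * np.eye(2)
    if arm_id not in ds.conc:
        L = np.linalg.cholesky(Omega)
        draws = rng.standard_normal((n_draws, 2)) @ L.T
        return PosteriorDraws(arm_ref=arm_id, draws=draws, size=n_draws,
                              from_prior=True)

    opts = fit.options
    tab = mbma.prepare_arms(ds, dose_finding_only=False, min_points=1, min_arms=1)
    try:
        i = tab.arm_ids.index(arm_id)
    except ValueError as exc:
        raise KeyError(f"arm {arm_id!r} not in the prepared dataset") from exc
    sub = mbma._ArmTable(
        arm_ids=[arm_id], study_ids=[tab.study_ids[i]],
        t=tab.t[i:i + 1], y=tab.y[i:i + 1], mask=tab.mask[i:i + 1],
        n=tab.n[i:i + 1], dose_mg=tab.dose_mg[i:i + 1],
    )
    nat = _nat_tuple(fit)
    Oinv, logdetO = mbma._omega_inv(nat[4], nat[5], nat[6])

    # mode + curvature give the proposal scale
    eta_hat, _, H = mbma._inner_newton(sub, nat, Oinv, logdetO, opts,
                                       np.zeros((1, 2)))
    cov = np.linalg.inv(H[0] + 1e-12 * np.eye(2))
    prop_chol = np.linalg.cholesky(cov * (2.4**2 / 2.0) + 1e-14 * np.eye(2))

    chains = np.empty((n_chains, keep, 2))
    for c in range(n_chains):
        eta = eta_hat[0] + 0.5 * (prop_chol @ rng.standard_normal(2))
        lp = -_neg_log_post(eta, sub, nat, Oinv, logdetO, opts)[0]
        kept = np.empty((keep, 2))
        for it in range(warmup + keep):
            prop = eta + prop_chol @ rng.standard_normal(2)
            lp_prop = -_neg_log_post(prop, sub, nat, Oinv, logdetO, opts)[0]
            if np.log(rng.random()) < lp_prop - lp:
                eta, lp = prop, lp_prop
            if it >= warmup:
                kept[it - warmup] = eta
        chains[c] = kept

    import arviz as az

    idata = az.convert_to_dataset(chains[:, :, :], dims={"x": ["eta_dim"]})
    rhat = float(np.max(az.rhat(idata)["x"].values))
    ess = float(np.min(az.ess(idata)["x"].values))

    pooled = chains.reshape(-1, 2)
    if n_draws < len(pooled):
        idx = np.linspace(0, len(pooled) - 1, n_draws).astype(int)
        pooled = pooled[idx]
    return PosteriorDraws(arm_ref=arm_id, draws=pooled, size=len(pooled),
                          rhat=rhat, ess=ess)


def pooled_posterior_for_dose(ds: td.Dataset, fit: mbma.FitResult,
                              dose_mgkg: float, n_draws: int, seed: int,
                              rel_tol: float = 1e-9) -> np.ndarray | None:
    """Posterior eta draws pooled over arms at a dose level, weighted by n.

    Returns None when no arm at the dose level has concentration data, in
    which case the caller falls back to the population distribution.
    """
    arms = [a for a in ds.arms
            if abs(a.dose_mgkg - dose_mgkg) <= rel_tol * max(dose_mgkg, 1.0)
            and a.arm_id in ds.conc]
    if not arms:
        return None
    rng = np.random.default_rng(seed)
    weights = np.array([a.n for a in arms], float)
    counts = np.maximum(np.round(weights / weights.sum() * n_draws).astype(int), 1)
    draws = []
    for a, k in zip(arms, counts):
        pd_a = sample_posterior(a.arm_id, ds, fit, n_draws=int(k),
                                seed=int(rng.integers(2**31 - 1)))
        draws.append(pd_a.draws)
    pooled = np.concatenate(draws, axis=0)
    idx = rng.permutation(len(pooled))[:n_draws]
    if len(idx) < n_draws:  # round-off shortfall: resample with replacement
        extra = rng.integers(0, len(pooled), n_draws - len(idx))
        idx = np.concatenate([idx, extra])
    return pooled[idx]


@dataclass
class ExposureReplicates:
    """Long-format container of simulated exposure replicates."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def values(self, dose_mgkg: float, metric: str) -> np.ndarray:
        sel = (self.frame["dose_mgkg"] == dose_mgkg) & (self.frame["metric"] == metric)
        return self.frame.loc[sel, "value"].to_numpy()

    @property
    def n_records(self) -> int:
        return len(self.frame)


def simulate_exposures(fit: mbma.FitResult, doses_mgkg, weight_kg: float,
                       n_replicates: int = DEFAULT_N_REPLICATES, seed: int = 0,
                       ds: td.Dataset | None = None,
                       condition_on_data: bool = False,
                       infusion_h: float = DEFAULT_INFUSION_H,
                       propagate_uncertainty: bool = False) -> ExposureReplicates:
    """Simulate per-dose exposure replicates for a median-weight subject.

    Each dose level receives ``n_replicates`` draws of (eta_CL, eta_Vc) —
    posterior draws conditioned on same-dose arm data when
    ``condition_on_data`` and a dataset are given, otherwise draws from the
    fitted population distribution — pushed through the closed-form model.
    With ``propagate_uncertainty`` the fixed effects are additionally drawn
    from the estimation covariance per replicate.
    """
    doses_mgkg = list(doses_mgkg)
    if not doses_mgkg:
        raise ValueError("dose grid must be non-empty")
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    rng = np.random.default_rng(seed)
    Omega = fit.bsv.cov() + 1e-15 * np.eye(2)
    L = np.linalg.cholesky(Omega)

    rows = []
    for dose in doses_mgkg:
        eta = None
        if condition_on_data and ds is not None:
            eta = pooled_posterior_for_dose(
                ds, fit, dose, n_replicates, seed=int(rng.integers(2**31 - 1)))
        if eta is None:
            eta = (rng.standard_normal((n_replicates, 2)) @ L.T
                   if (fit.bsv.omega_CL > 0 or fit.bsv.omega_Vc > 0)
                   else np.zeros((n_replicates, 2)))
        if propagate_uncertainty and fit.cov_transformed is not None:
            cov_fx = fit.cov_transformed[:4, :4]
            z = rng.multivariate_normal(np.zeros(4), cov_fx, size=n_replicates)
            CLv = fit.pk.CL * np.exp(z[:, 0] + eta[:, 0])
            Vcv = fit.pk.Vc * np.exp(z[:, 1] + eta[:, 1])
            Vpv = fit.pk.Vp * np.exp(z[:, 2])
            Qv = fit.pk.Q * np.exp(z[:, 3])
        else:
            CLv = fit.pk.CL * np.exp(eta[:, 0])
            Vcv = fit.pk.Vc * np.exp(eta[:, 1])
            Vpv = np.full(n_replicates, fit.pk.Vp)
            Qv = np.full(n_replicates, fit.pk.Q)
        dose_mg = dose * weight_kg
        cmax = concentration_arrays(
            np.full(n_replicates, infusion_h), dose_mg, infusion_h, CLv, Vcv, Vpv, Qv)
        cmin = concentration_arrays(
            np.full(n_replicates, CYCLE_END_H), dose_mg, infusion_h, CLv, Vcv, Vpv, Qv)
        auc = auc_0_t_arrays(
            np.full(n_replicates, CYCLE_END_H), dose_mg, infusion_h, CLv, Vcv, Vpv, Qv)
        for metric, vals in (("Cmax", cmax), ("Cmin", cmin), ("AUC", auc)):
            for r, v in enumerate(vals):
                rows.append((dose, metric, r, float(v)))
    frame = pd.DataFrame(rows, columns=["dose_mgkg", "metric", "replicate", "value"])
    return ExposureReplicates(frame=frame)
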