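"""Closed-form two-compartment IV-infusion pharmacokinetics.

The structural model used throughout the package: linear elimination from a
central compartment (volume ``Vc``, clearance ``CL``) exchanging with one
peripheral compartment (volume ``Vp``, intercompartmental clearance ``Q``).
Clearances are given in L/day (the convention of the published parameter
tables for antibody-drug conjugates); time is handled internally in hours
and concentrations in ng/mL (1 mg/L = 1000 ng/mL for these large molecules,
since amounts are in mg and volumes in L).

All functions are vectorised over time and, where noted, over parameter
arrays, because the meta-analysis fitter and the exposure simulator evaluate
the model for many study arms / replicates at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HOURS_PER_DAY = 24.0
#: mg/L (== ug/mL) -> ng/mL
MGL_TO_NGML = 1000.0
#: default cycle-1 infusion duration (90 min)
DEFAULT_INFUSION_H = 1.5
#: end of the 21-day dosing cycle
CYCLE_END_H = 504.0


@dataclass(frozen=True)
class PKParams:
    """Fixed-effect parameters of the two-compartment model.

    CL and Q are clearances in L/day; Vc and Vp are volumes in L.
    """

    CL: float
    Vc: float
    Vp: float
    Q: float

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "Vp", "Q"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PK parameter {name} must be strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.Vc, self.Vp, self.Q], dtype=float)


@dataclass(frozen=True)
class DoseEvent:
    """A single IV infusion: absolute amount in mg over ``infusion_duration_h`` hours."""

    dose_mg: float
    infusion_duration_h: float = DEFAULT_INFUSION_H
    start_h: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        if self.infusion_duration_h <= 0:
            raise ValueError("infusion_duration_h must be positive")


def _hybrid_constants(CL, Vc, Vp, Q):
    """Micro constants and hybrid rates (per hour) from L/day clearances.

    Returns (alpha, beta, A, B) where A, B are the bolus bi-exponential
    coefficients normalised so that A + B = 1.
    """
    CLh = np.asarray(CL, float) / HOURS_PER_DAY
    Qh = np.asarray(Q, float) / HOURS_PER_DAY
    Vc = np.asarray(Vc, float)
    Vp = np.asarray(Vp, float)
    k10 = CLh / Vc
    k12 = Qh / Vc
    k21 = Qh / Vp
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = alpha - beta
    # alpha == beta only on a measure-zero parameter set; nudge to keep the
    # bi-exponential form defined
    denom = np.where(denom == 0, np.finfo(float).tiny, denom)
    A = (alpha - k21) / denom
    B = (k21 - beta) / denom
    return alpha, beta, A, B


def concentration(t, dose: DoseEvent, p: PKParams) -> np.ndarray:
    """Central-compartment concentration (ng/mL) at times ``t`` (hours).

    Standard bi-exponential solution for a zero-order infusion; zero before
    the infusion starts, continuous everywhere.
    """
    return concentration_arrays(
        t, dose.dose_mg, dose.infusion_duration_h, p.CL, p.Vc, p.Vp, p.Q, start_h=dose.start_h
    )


def concentration_arrays(t, dose_mg, infusion_h, CL, Vc, Vp, Q, start_h=0.0) -> np.ndarray:
    """Vectorised concentration: parameter arguments broadcast against ``t``.

    Used by the fitter with per-arm parameter arrays of shape (n_arms, 1)
    against time arrays of shape (n_arms, n_times).
    """
    t = np.asarray(t, float) - start_h
    alpha, beta, A, B = _hybrid_constants(CL, Vc, Vp, Q)
    Vc = np.asarray(Vc, float)
    T = np.asarray(infusion_h, float)
    R0 = np.asarray(dose_mg, float) / T  # mg/h
    te = np.clip(t, 0.0, T)  # time infused so far
    dt = np.maximum(t - T, 0.0)  # time since end of infusion
    c = (R0 / Vc) * (
        A * (-np.expm1(-alpha * te)) / alpha * np.exp(-alpha * dt)
        + B * (-np.expm1(-beta * te)) / beta * np.exp(-beta * dt)
    )
    return c * MGL_TO_NGML


def auc_0_t(t, dose: DoseEvent, p: PKParams) -> float | np.ndarray:
    """Analytic AUC (ng·h/mL) of the central concentration from 0 to ``t`` hours."""
    t = np.asarray(t, float) - dose.start_h
    return auc_0_t_arrays(t, dose.dose_mg, dose.infusion_duration_h,
                          p.CL, p.Vc, p.Vp, p.Q)


def auc_0_t_arrays(t, dose_mg, infusion_h, CL, Vc, Vp, Q) -> np.ndarray:
    """Vectorised analytic AUC(0-t); parameter arguments broadcast."""
    t = np.asarray(t, float)
    alpha, beta, A, B = _hybrid_constants(CL, Vc, Vp, Q)
    T = np.asarray(infusion_h, float)
    R0 = np.asarray(dose_mg, float) / T
    te = np.clip(t, 0.0, T)
    dt = np.maximum(t - T, 0.0)

    def _piece(lam, coef):
        during = coef / lam * (te + np.expm1(-lam * te) / lam)
        amp = coef * (-np.expm1(-lam * T)) / lam
        return during + amp / lam * (-np.expm1(-lam * dt))

    return (R0 / np.asarray(Vc, float)) * (_piece(alpha, A) + _piece(beta, B)) * MGL_TO_NGML


def auc_inf(dose: DoseEvent, p: PKParams) -> float:
    """AUC extrapolated to infinity: dose/CL, in ng·h/mL."""
    return dose.dose_mg / (p.CL / HOURS_PER_DAY) * MGL_TO_NGML


@dataclass
class ExposureSummary:
    """Cycle-1 exposure metrics for one arm or simulated replicate.

    Any field may be None when the metric was not reported (observed data)
    or not requested.
    """

    cmax: float | None = None
    cmin_504h: float | None = None
    auc_0_504h: float | None = None
    auc_inf: float | None = None

    def validate(self) -> None:
        for name in ("cmax", "cmin_504h", "auc_0_504h", "auc_inf"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.auc_0_504h is not None and self.auc_inf is not None:
            if self.auc_0_504h > self.auc_inf * (1 + 1e-9):
                raise ValueError("auc_0_504h exceeds auc_inf")
        if self.cmax is not None and self.cmin_504h is not None:
            if self.cmin_504h > self.cmax * (1 + 1e-9):
                raise ValueError("cmin_504h exceeds cmax")


def exposures(dose: DoseEvent, p: PKParams) -> ExposureSummary:
    """Cycle-1 exposure metrics from the closed form.

    Cmax is the concentration at end of infusion (for this linear model the
    post-infusion profile is decreasing, so the two definitions coincide);
    Cmin is the trough at 504 h; AUCs are analytic.
    """
    t_end = dose.start_h + dose.infusion_duration_h
    return ExposureSummary(
        cmax=float(concentration(t_end, dose, p)),
        cmin_504h=float(concentration(dose.start_h + CYCLE_END_H, dose, p)),
        auc_0_504h=float(auc_0_t(dose.start_h + CYCLE_END_H, dose, p)),
        auc_inf=auc_inf(dose, p),
    )


def half_lives(p: PKParams) -> tuple[float, float]:
    """Distribution and terminal half-lives (days) from the hybrid rates."""
    alpha, beta, _, _ = _hybrid_constants(p.CL, p.Vc, p.Vp, p.Q)
    return (
        float(np.log(2.0) / alpha / HOURS_PER_DAY),
        float(np.log(2.0) / beta / HOURS_PER_DAY),
    )
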