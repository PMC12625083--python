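"""Synthetic summary-level trial data with the structure the pipeline assumes.

The generator emulates a literature-derived meta-analytic dataset: a set of
"studies" (a phase-I study contributes several escalating dose arms, later
phases one or two arms near the therapeutic dose), each arm carrying a
study-level log-normal deviation of clearance and central volume, noisy
summary concentrations whose residual scatter shrinks with the square root
of the arm size, exposure metrics derived from the arm's noiseless profile,
binomial efficacy/safety counts driven by logistic exposure-response curves
on the arm's true Cmax, and configurable missingness of the reported
metrics.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import trial_data as td
from .mbma import BSVParams, ResidualError
from .pk_twocmt import (DEFAULT_INFUSION_H, DoseEvent, ExposureSummary,
                        PKParams, concentration, exposures)

#: fitted structural parameters used as generating truth per drug
TRUE_PK = {
    td.Drug.TDM1: PKParams(CL=0.809, Vc=3.283, Vp=0.748, Q=1.120),
    td.Drug.TDXD: PKParams(CL=0.585, Vc=2.785, Vp=1.243, Q=0.652),
}
TRUE_BSV = {
    td.Drug.TDM1: BSVParams(omega_CL=0.334, omega_Vc=0.221, rho=0.825),
    td.Drug.TDXD: BSVParams(omega_CL=0.084, omega_Vc=0.038, rho=0.915),
}
TRUE_ERROR = {
    td.Drug.TDM1: ResidualError(a=2633.766, b=0.430),
    td.Drug.TDXD: ResidualError(a=3043.004, b=0.338),
}
#: escalation grids (mg/kg); the T-DXd grid interpolates between the four
#: publicly named levels 0.8, 3.2, 5.4 and 6.4 to reach seven levels
DOSE_GRIDS = {
    td.Drug.TDM1: (0.3, 0.6, 1.2, 1.8, 2.4, 3.6, 4.8),
    td.Drug.TDXD: (0.8, 1.6, 2.4, 3.2, 5.4, 6.4, 8.0),
}
#: observed median body weights (kg)
MEDIAN_WEIGHTS = {td.Drug.TDM1: 69.4, td.Drug.TDXD: 59.0}

_CANCERS = {
    td.Drug.TDM1: ("breast", "breast", "breast", "gastric"),
    td.Drug.TDXD: ("breast", "breast", "lung", "gastric", "colorectal"),
}


class ERTruth(BaseModel):
    """Generating logistic exposure-response curve: logit p = beta0 + beta1*x."""

    beta0: float
    beta1: float


class SimConfig(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    drug: td.Drug = td.Drug.TDM1
    n_studies: int = 20
    phase_mix: dict[td.Phase, float] = {
        td.Phase.I: 0.45, td.Phase.II: 0.30, td.Phase.III: 0.15, td.Phase.IV: 0.10,
    }
    dose_grid: tuple[float, ...] | None = None
    arms_per_study: tuple[int, int] = (1, 3)
    #: probability that a phase-I study is a multi-dose escalation study
    p_dose_finding: float = 0.8
    #: probability of a weekly-schedule arm (excluded from ER downstream)
    p_weekly: float = 0.1
    n_range: tuple[int, int] = (10, 60)
    weight_mean_kg: float | None = None
    weight_sd_kg: float = 12.0
    sample_times: tuple[float, ...] = (1.5, 4.0, 24.0, 72.0, 168.0, 336.0, 504.0)
    infusion_h: float = DEFAULT_INFUSION_H
    true_pk: PKParams | None = None
    true_bsv: BSVParams | None = None
    true_error: ResidualError | None = None
    true_er_orr: ERTruth | None = None
    true_er_dlt: ERTruth | None = None
    missingness: dict[str, float] = {
        "median_weight_kg": 0.15, "cmax": 0.25, "cmin_504": 0.55,
        "auc_0_504": 0.45, "auc_inf": 0.35, "orr": 0.20, "dlt": 0.20,
    }
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if abs(sum(self.phase_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phase_mix must sum to 1")
        if any(p < 0 for p in self.phase_mix.values()):
            raise ValueError("phase_mix probabilities must be >= 0")
        grid = self.resolved_dose_grid()
        if len(grid) == 0:
            raise ValueError("dose_grid must be non-empty")
        if not all(b > a > 0 for a, b in zip(grid, grid[1:])) or grid[0] <= 0:
            raise ValueError("dose_grid must be strictly increasing and positive")
        for k, p in self.missingness.items():
            if not (0 <= p <= 1):
                raise ValueError(f"missingness[{k!r}] must lie in [0, 1]")
        return self

    def resolved_dose_grid(self) -> tuple[float, ...]:
        return self.dose_grid if self.dose_grid is not None else DOSE_GRIDS[self.drug]

    def resolved(self, name: str):
        v = getattr(self, "true_" + name if name != "weight" else "weight_mean_kg")
        if v is not None:
            return v
        return {
            "pk": TRUE_PK, "bsv": TRUE_BSV, "error": TRUE_ERROR,
            "weight": MEDIAN_WEIGHTS,
            "er_orr": _DEFAULT_ER_ORR, "er_dlt": _DEFAULT_ER_DLT,
        }[name][self.drug]


def _default_er(drug: td.Drug, p_low: float, p_high: float) -> ERTruth:
    """Logistic curve anchored at the typical Cmax of the lowest/highest dose."""
    pk = TRUE_PK[drug]
    w = MEDIAN_WEIGHTS[drug]
    grid = DOSE_GRIDS[drug]
    x_lo = exposures(DoseEvent(dose_mg=grid[0] * w), pk).cmax
    x_hi = exposures(DoseEvent(dose_mg=grid[-1] * w), pk).cmax
    l_lo, l_hi = np.log(p_low / (1 - p_low)), np.log(p_high / (1 - p_high))
    beta1 = (l_hi - l_lo) / (x_hi - x_lo)
    return ERTruth(beta0=l_lo - beta1 * x_lo, beta1=beta1)


# Response roughly 5% at the lowest escalation dose rising to ~45-50% at the
# top dose; composite DLT from ~8% to ~35%: the shapes reported for these
# drug classes in early-phase escalation data.
_DEFAULT_ER_ORR = {d: _default_er(d, 0.05, 0.48) for d in td.Drug}
_DEFAULT_ER_DLT = {d: _default_er(d, 0.08, 0.35) for d in td.Drug}


@dataclass
class _ArmPlan:
    study_id: str
    arm_id: str
    phase: td.Phase
    dose_mgkg: float
    schedule: td.Schedule
    cancer: str


def _plan_arms(cfg: SimConfig, rng: np.random.Generator) -> list[_ArmPlan]:
    grid = cfg.resolved_dose_grid()
    phases = list(cfg.phase_mix)
    probs = np.array([cfg.phase_mix[p] for p in phases])
    cancers = _CANCERS[cfg.drug]
    plans: list[_ArmPlan] = []
    for s in range(cfg.n_studies):
        study_id = f"S{s + 1:03d}"
        phase = phases[rng.choice(len(phases), p=probs)]
        lo, hi = cfg.arms_per_study
        if phase == td.Phase.I and rng.random() < cfg.p_dose_finding and len(grid) >= 2:
            # escalation study: >= 2 consecutive dose levels
            k = int(rng.integers(2, max(hi, 2) + 1))
            k = min(k, len(grid))
            start = int(rng.integers(0, len(grid) - k + 1))
            doses = grid[start:start + k]
        elif phase == td.Phase.I:
            doses = (grid[int(rng.integers(0, len(grid)))],)
        else:
            # later phases study the upper (therapeutic) part of the grid
            k = int(rng.integers(lo, hi + 1))
            top = grid[max(len(grid) - 3, 0):]
            doses = tuple(sorted(set(
                top[int(rng.integers(0, len(top)))] for _ in range(max(k, 1))
            )))
        cancer = cancers[int(rng.integers(0, len(cancers)))]
        for j, dose in enumerate(doses):
            sched = td.Schedule.QW if rng.random() < cfg.p_weekly else td.Schedule.Q3W
            plans.append(_ArmPlan(
                study_id=study_id, arm_id=f"{study_id}A{j + 1}", phase=phase,
                dose_mgkg=float(dose), schedule=sched, cancer=cancer,
            ))
    return plans


def generate(cfg: SimConfig) -> td.Dataset:
    """Generate a validated synthetic dataset from the config."""
    rng = np.random.default_rng(cfg.seed)
    pk: PKParams = cfg.resolved("pk")
    bsv: BSVParams = cfg.resolved("bsv")
    err: ResidualError = cfg.resolved("error")
    er_orr: ERTruth = cfg.resolved("er_orr")
    er_dlt: ERTruth = cfg.resolved("er_dlt")
    w_mean = cfg.weight_mean_kg if cfg.weight_mean_kg is not None else MEDIAN_WEIGHTS[cfg.drug]
    miss = cfg.missingness
    L = np.linalg.cholesky(bsv.cov() + 1e-15 * np.eye(2))

    ds = td.Dataset()
    for plan in _plan_arms(cfg, rng):
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        weight = float(np.clip(rng.normal(w_mean, cfg.weight_sd_kg), 40.0, 130.0))
        eta = L @ rng.standard_normal(2)
        arm_pk = PKParams(CL=pk.CL * np.exp(eta[0]), Vc=pk.Vc * np.exp(eta[1]),
                          Vp=pk.Vp, Q=pk.Q)
        dose = DoseEvent(dose_mg=plan.dose_mgkg * weight, infusion_duration_h=cfg.infusion_h)
        times = np.asarray(cfg.sample_times, float)
        f = concentration(times, dose, arm_pk)
        sd = (err.a + (err.b / np.sqrt(n)) * f)
        obs = f + rng.standard_normal(len(times)) * sd
        # summary tables never contain non-positive mean concentrations:
        # points whose noisy value falls at or below zero go unreported
        keep = obs > 0

        exp_true = exposures(dose, arm_pk)
        p_orr = 1.0 / (1.0 + np.exp(-(er_orr.beta0 + er_orr.beta1 * exp_true.cmax)))
        p_dlt = 1.0 / (1.0 + np.exp(-(er_dlt.beta0 + er_dlt.beta1 * exp_true.cmax)))
        orr_events = int(rng.binomial(n, p_orr))
        dlt_events = int(rng.binomial(n, p_dlt))

        ds.arms.append(td.StudyArm(
            study_id=plan.study_id, arm_id=plan.arm_id, phase=plan.phase,
            cancer_type=plan.cancer, drug=cfg.drug, dose_mgkg=plan.dose_mgkg,
            schedule=plan.schedule, n=n,
            median_weight_kg=None if rng.random() < miss.get("median_weight_kg", 0) else weight,
        ))
        if np.any(keep):
            ds.conc[plan.arm_id] = td.ConcSeries(
                arm_ref=plan.arm_id, times=[float(t) for t in times[keep]],
                conc=[float(c) for c in obs[keep]],
            )
        ds.exposures[plan.arm_id] = ExposureSummary(
            cmax=None if rng.random() < miss.get("cmax", 0) else exp_true.cmax,
            cmin_504h=None if rng.random() < miss.get("cmin_504", 0) else exp_true.cmin_504h,
            auc_0_504h=None if rng.random() < miss.get("auc_0_504", 0) else exp_true.auc_0_504h,
            auc_inf=None if rng.random() < miss.get("auc_inf", 0) else exp_true.auc_inf,
        )
        if not rng.random() < miss.get("orr", 0):
            ds.outcomes[(plan.arm_id, td.Outcome.ORR)] = td.OutcomeCount(
                arm_ref=plan.arm_id, outcome=td.Outcome.ORR, events=orr_events, total=n,
            )
        if not rng.random() < miss.get("dlt", 0):
            # component counts whose maximum is the composite count
            reduction = dlt_events
            reported = int(rng.binomial(dlt_events, 0.6)) if dlt_events else 0
            disc = int(rng.binomial(dlt_events, 0.4)) if dlt_events else 0
            ds.dlt_components[plan.arm_id] = td.DltComponents(
                dlt_reported=reported if plan.phase == td.Phase.I else None,
                dose_reduction=reduction, discontinuation=disc,
                interruption_delay=None, total=n,
            )
            ds.outcomes[(plan.arm_id, td.Outcome.DLT)] = td.derive_composite_dlt(
                ds.dlt_components[plan.arm_id], plan.arm_id,
            )
    ds.validate()
    return ds


def load_config(path) -> SimConfig:
    """Read a SimConfig from a declarative JSON file of field/value pairs
    (field names as in SimConfig; omitted fields take their defaults)."""
    from pathlib import Path

    return SimConfig.model_validate_json(Path(path).read_text())


def recovery_config(drug: td.Drug | str, n_arms: int, seed: int) -> SimConfig:
    """Config for parameter-recovery experiments: one arm per study so the
    number of meta-units is exact, every PK-relevant field observed."""
    return SimConfig(
        drug=td.Drug(drug),
        n_studies=n_arms,
        arms_per_study=(1, 1),
        p_dose_finding=0.0,
        p_weekly=0.0,
        phase_mix={td.Phase.I: 1.0, td.Phase.II: 0.0, td.Phase.III: 0.0, td.Phase.IV: 0.0},
        missingness={"median_weight_kg": 0.0, "cmax": 0.0, "cmin_504": 0.0,
                     "auc_0_504": 0.0, "auc_inf": 0.0, "orr": 0.0, "dlt": 0.0},
        seed=seed,
    )
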