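"""Weighted quasi-binomial logistic exposure-response models.

The unit of analysis is a cancer-type x dose arm on the three-weekly
schedule; the response is the arm-level event proportion (objective
response, composite dose-limiting toxicity, ...), the regressor a cycle-1
exposure metric, and each unit enters the iteratively reweighted fit with
prior weight sqrt(n).  Overdispersion relative to the binomial is absorbed
by a quasi-likelihood dispersion factor (weighted Pearson chi-square over
residual degrees of freedom), exactly as a quasibinomial GLM does, so the
coefficient estimates are those of the weighted binomial fit while standard
errors scale with sqrt(dispersion).

Development-stage scenarios restrict the trial phases contributing units:
``phase1`` (escalation data only), ``phase1_2`` (through phase II) and
``all`` (including phase III and post-approval experience).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import trial_data as td

_METRIC_FIELDS = {
    "Cmax": "cmax",
    "Cmin": "cmin_504h",
    "AUC": "auc_0_504h",
    "AUCinf": "auc_inf",
}


class Scenario(str, enum.Enum):
    PHASE1 = "phase1"
    PHASE1_2 = "phase1_2"
    ALL = "all"

    @property
    def phases(self) -> frozenset[td.Phase]:
        return {
            Scenario.PHASE1: frozenset({td.Phase.I}),
            Scenario.PHASE1_2: frozenset({td.Phase.I, td.Phase.II}),
            Scenario.ALL: frozenset(td.Phase),
        }[self]


@dataclass(frozen=True)
class ERUnit:
    arm_ref: str
    exposure: float
    outcome: td.Outcome
    events: int
    total: int
    phase: td.Phase

    @property
    def weight(self) -> float:
        return float(np.sqrt(self.total))


class InsufficientRangeError(ValueError):
    """The exposure values do not span a range that supports a slope."""


@dataclass
class ERModel:
    beta0: float
    beta1: float
    dispersion: float
    metric: str
    outcome: td.Outcome
    scenario: Scenario
    n_units: int
    se_beta0: float = float("nan")
    se_beta1: float = float("nan")
    separation: bool = False
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0, "beta1": self.beta1, "dispersion": self.dispersion,
            "metric": self.metric, "outcome": self.outcome.value,
            "scenario": self.scenario.value, "n_units": self.n_units,
            "se_beta0": self.se_beta0, "se_beta1": self.se_beta1,
            "separation": self.separation,
        }


def assemble_units(ds: td.Dataset, metric: str, outcome: td.Outcome | str,
                   scenario: Scenario | str) -> list[ERUnit]:
    """Collect the analysis units for one metric/outcome/scenario.

    Three-weekly arms only; arms missing the metric or the outcome drop out.
    Raises a descriptive error when a filter leaves nothing.
    """
    outcome = td.Outcome(outcome)
    scenario = Scenario(scenario)
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"unknown PK metric {metric!r}; choose from {list(_METRIC_FIELDS)}")
    fld = _METRIC_FIELDS[metric]
    phases = scenario.phases

    q3w = [a for a in ds.arms if a.schedule == td.Schedule.Q3W]
    if not q3w:
        raise InsufficientRangeError("no arms on the three-weekly schedule")
    in_phase = [a for a in q3w if a.phase in phases]
    if not in_phase:
        raise InsufficientRangeError(f"no Q3W arms in phases {sorted(p.value for p in phases)}")
    units = []
    for a in in_phase:
        exp = ds.exposures.get(a.arm_id)
        x = getattr(exp, fld) if exp is not None else None
        oc = ds.outcomes.get((a.arm_id, outcome))
        if x is None or oc is None:
            continue
        units.append(ERUnit(arm_ref=a.arm_id, exposure=float(x), outcome=outcome,
                            events=oc.events, total=oc.total, phase=a.phase))
    if not units:
        raise InsufficientRangeError(
            f"no {scenario.value} Q3W units report both {metric} and {outcome.value}")
    return units


def fit_er(units: list[ERUnit], metric: str = "Cmax",
           scenario: Scenario | str = Scenario.ALL,
           log_exposure: bool = False) -> ERModel:
    """Weighted quasi-binomial logistic fit on arm-level proportions.

    Coefficients come from a binomial GLM on proportions with prior weights
    sqrt(n); the dispersion is the weighted Pearson chi-square divided by
    the residual degrees of freedom.
    """
    scenario = Scenario(scenario)
    if len(units) < 3:
        raise ValueError(f"need >= 3 units to fit an exposure-response model, got {len(units)}")
    x = np.array([u.exposure for u in units])
    if log_exposure:
        if np.any(x <= 0):
            raise ValueError("log_exposure requires strictly positive exposures")
        x = np.log(x)
    if np.unique(x).size < 2:
        raise InsufficientRangeError("insufficient exposure range: single exposure value")
    p = np.array([u.events / u.total for u in units])
    w = np.array([u.weight for u in units])
    outcome = units[0].outcome

    X = sm.add_constant(x)
    model = sm.GLM(p, X, family=sm.families.Binomial(), var_weights=w)
    messages: list[str] = []
    separation = False
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise InsufficientRangeError(f"GLM failed: {exc}") from exc
    for wmsg in caught:
        messages.append(str(wmsg.message))
    mu = res.fittedvalues
    if np.any(mu < 1e-9) or np.any(mu > 1 - 1e-9) or np.abs(res.params[1]) * np.ptp(x) > 50:
        separation = True
        messages.append("possible complete separation: fitted probabilities at 0/1")
    dof = max(len(units) - 2, 1)
    pearson = float(np.sum(w * (p - mu) ** 2 / np.maximum(mu * (1 - mu), 1e-12)))
    dispersion = pearson / dof
    se = np.sqrt(np.maximum(np.diag(res.cov_params()), 0)) * np.sqrt(max(dispersion, 1e-300))
    return ERModel(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        dispersion=float(dispersion), metric=metric, outcome=outcome,
        scenario=scenario, n_units=len(units),
        se_beta0=float(se[0]), se_beta1=float(se[1]),
        separation=separation, messages=messages,
    )


def predict_p(model: ERModel, exposure) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor on an exposure grid."""
    x = np.asarray(exposure, float)
    return 1.0 / (1.0 + np.exp(-(model.beta0 + model.beta1 * x)))


def fit_all_scenarios(ds: td.Dataset, metric: str = "Cmax",
                      outcomes: tuple[td.Outcome, ...] = (td.Outcome.ORR, td.Outcome.DLT),
                      ) -> dict[Scenario, dict[td.Outcome, ERModel]]:
    """Fit every outcome for the three development-stage scenarios.

    Scenarios (or outcomes within them) that cannot be assembled or fitted
    are omitted rather than raising.
    """
    out: dict[Scenario, dict[td.Outcome, ERModel]] = {}
    for scen in Scenario:
        fits: dict[td.Outcome, ERModel] = {}
        for outc in outcomes:
            try:
                units = assemble_units(ds, metric, outc, scen)
                fits[outc] = fit_er(units, metric=metric, scenario=scen)
            except (InsufficientRangeError, ValueError):
                continue
        if fits:
            out[scen] = fits
    return out


def models_to_frame(models: dict[Scenario, dict[td.Outcome, ERModel]]) -> pd.DataFrame:
    rows = [m.to_dict() for fits in models.values() for m in fits.values()]
    return pd.DataFrame(rows)
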