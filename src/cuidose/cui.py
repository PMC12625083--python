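"""Clinical utility index (CUI): construction, per-dose averaging, and
threshold-based dose selection.

The CUI combines efficacy and safety into one bounded score.  With an
objective-response model p_orr(x) and a dose-limiting-toxicity model
p_dlt(x) on a shared exposure metric x, the additive two-attribute form is

    CUI(x) = w * p_orr(x) + (1 - w) * (1 - p_dlt(x)),    w in [0, 1],

a weighted sum of utilities that each live in [0, 1], so the CUI does too.
The per-dose summary is the *average* CUI: the trapezoidal integral of
CUI(x) over the span of that dose's simulated exposure replicates divided
by the span (a degenerate span reduces to the point value), which accounts
for between-subject exposure variability at a fixed dose.

Dose selection walks the escalation grid from the lowest dose and keeps
escalating while the relative improvement in average CUI over the previous
dose meets the threshold tau (in percent); the selected dose is the last
one accepted.  Scans over weight and threshold grids summarise how the
selection responds to the efficacy-safety trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import trial_data as td
from .exposure_response import ERModel, Scenario, predict_p
from .posterior import ExposureReplicates

#: default ORR-weight grid: 10-90% in 0.5-point steps
DEFAULT_WEIGHT_GRID = tuple(np.round(np.arange(10.0, 90.0 + 1e-9, 0.5), 1))
#: default CUI threshold grid (percent)
DEFAULT_THRESHOLD_GRID = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)


@dataclass(frozen=True)
class UtilitySpec:
    """Weights and utility maps of the two-attribute additive CUI."""

    w_orr: float
    u_orr: Callable[[np.ndarray], np.ndarray]
    u_dlt: Callable[[np.ndarray], np.ndarray]

    @property
    def w_dlt(self) -> float:
        return 1.0 - self.w_orr

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_orr <= 1.0):
            raise ValueError("w_orr must lie in [0, 1]")


def cui_curve(er_orr: ERModel, er_dlt: ERModel, w: float,
              grid) -> np.ndarray:
    """CUI values on an exposure grid: w*p_orr + (1-w)*(1-p_dlt)."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    if er_orr.metric != er_dlt.metric:
        raise ValueError(
            f"exposure metric mismatch: {er_orr.metric!r} vs {er_dlt.metric!r}")
    grid = np.asarray(grid, float)
    return w * predict_p(er_orr, grid) + (1.0 - w) * (1.0 - predict_p(er_dlt, grid))


def average_cui(cui_fn: Callable[[np.ndarray], np.ndarray],
                exposure_values: np.ndarray, n_grid: int = 201,
                trim: tuple[float, float] | None = None) -> float:
    """Average CUI over a dose's exposure span: integral / range.

    ``exposure_values`` are the simulated replicates for one dose level;
    the span is their min-max (or a percentile trim).  A degenerate span
    returns the CUI at the single exposure.
    """
    x = np.asarray(exposure_values, float)
    if x.size == 0:
        raise ValueError("no exposure replicates")
    if trim is not None:
        lo, hi = np.percentile(x, trim)
    else:
        lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return float(np.asarray(cui_fn(np.array([lo])))[0])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.asarray(cui_fn(grid), float)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def improvements_pct(avg_cuis: Sequence[float]) -> list[float]:
    """Relative percent change of each dose's average CUI vs the previous."""
    out = [float("nan")]
    for prev, cur in zip(avg_cuis, avg_cuis[1:]):
        out.append(100.0 * (cur - prev) / prev if prev != 0 else float("inf"))
    return out


def select_dose(avg_cuis: Sequence[float], doses: Sequence[float],
                tau: float) -> float:
    """Sequential escalation: keep stepping up while the relative average-CUI
    improvement meets or exceeds ``tau`` percent; stop at the first failure."""
    if len(avg_cuis) != len(doses) or len(doses) == 0:
        raise ValueError("avg_cuis and doses must be equal-length and non-empty")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    imps = improvements_pct(avg_cuis)
    selected = doses[0]
    for k in range(1, len(doses)):
        if imps[k] >= tau:
            selected = doses[k]
        else:
            break
    return float(selected)


@dataclass
class CUIResult:
    """Average CUI per dose and the threshold-selected dose for one setting."""

    dose_grid: tuple[float, ...]
    avg_cui: tuple[float, ...]
    improvement_pct: tuple[float, ...]
    threshold: float
    selected_dose: float
    scenario: Scenario
    w_orr: float

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.value, "w_orr": self.w_orr,
            "threshold_pct": self.threshold, "selected_dose": self.selected_dose,
            "dose_grid": list(self.dose_grid), "avg_cui": list(self.avg_cui),
            "improvement_pct": list(self.improvement_pct),
        }


def evaluate(er_orr: ERModel, er_dlt: ERModel, replicates: ExposureReplicates,
             doses: Sequence[float], w: float, tau: float,
             metric: str = "Cmax", scenario: Scenario | str = Scenario.ALL,
             trim: tuple[float, float] | None = None) -> CUIResult:
    """Average CUI per dose from exposure replicates, then select the dose."""
    scenario = Scenario(scenario)
    fn = lambda x: cui_curve(er_orr, er_dlt, w, x)  # noqa: E731
    avgs = [average_cui(fn, replicates.values(d, metric), trim=trim) for d in doses]
    return CUIResult(
        dose_grid=tuple(float(d) for d in doses),
        avg_cui=tuple(avgs),
        improvement_pct=tuple(improvements_pct(avgs)),
        threshold=float(tau),
        selected_dose=select_dose(avgs, list(doses), tau),
        scenario=scenario, w_orr=float(w),
    )


@dataclass
class ScanResult:
    """Grid scan over (scenario, threshold, weight)."""

    selections: pd.DataFrame  # scenario, threshold_pct, w_orr, selected_dose
    skipped: list[str] = field(default_factory=list)

    def selection_frequency(self) -> pd.DataFrame:
        """Share of weight settings selecting each dose, per scenario x tau."""
        g = (self.selections
             .groupby(["scenario", "threshold_pct", "selected_dose"])
             .size().rename("count").reset_index())
        totals = g.groupby(["scenario", "threshold_pct"])["count"].transform("sum")
        g["frequency"] = g["count"] / totals
        return g

    def median_weight_per_dose(self) -> pd.DataFrame:
        """Median ORR weight among the settings that select each dose."""
        return (self.selections
                .groupby(["scenario", "threshold_pct", "selected_dose"])["w_orr"]
                .median().rename("median_w_orr").reset_index())


def scan(er_by_scenario: dict[Scenario, dict[td.Outcome, ERModel]],
         replicates: ExposureReplicates, doses: Sequence[float],
         weight_grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
         threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
         metric: str = "Cmax",
         trim: tuple[float, float] | None = None) -> ScanResult:
    """Selected dose for every (scenario, threshold, weight) combination.

    Weights are given in percent (as the grids are quoted); scenarios with
    a missing ORR or DLT fit are skipped with a note.
    """
    if len(list(weight_grid)) == 0 or len(list(threshold_grid)) == 0:
        raise ValueError("weight and threshold grids must be non-empty")
    rows = []
    skipped = []
    for scen in Scenario:
        fits = er_by_scenario.get(scen)
        if not fits or td.Outcome.ORR not in fits or td.Outcome.DLT not in fits:
            skipped.append(f"scenario {scen.value}: missing ORR or DLT fit")
            continue
        er_orr, er_dlt = fits[td.Outcome.ORR], fits[td.Outcome.DLT]
        # average CUI is linear in w: precompute the two utility averages
        fn_orr = lambda x: predict_p(er_orr, x)  # noqa: E731
        fn_dlt = lambda x: 1.0 - predict_p(er_dlt, x)  # noqa: E731
        a_orr = np.array([average_cui(fn_orr, replicates.values(d, metric), trim=trim)
                          for d in doses])
        a_dlt = np.array([average_cui(fn_dlt, replicates.values(d, metric), trim=trim)
                          for d in doses])
        for w_pct in weight_grid:
            w = w_pct / 100.0
            avgs = w * a_orr + (1 - w) * a_dlt
            for tau in threshold_grid:
                rows.append({
                    "scenario": scen.value, "threshold_pct": float(tau),
                    "w_orr": float(w_pct),
                    "selected_dose": select_dose(avgs, list(doses), tau),
                })
    return ScanResult(selections=pd.DataFrame(rows), skipped=skipped)
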