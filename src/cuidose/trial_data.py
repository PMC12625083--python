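"""Summary-level trial dataset: schema, CSV round-trip, validation, imputation.

The unit of record is a study arm — one cancer-type x dose combination from a
published trial, carrying its sample size, median body weight, cycle-1
summary concentration-time points, reported exposure metrics and outcome
counts.  Missing values are encoded as empty CSV cells; concentration series
are stored as semicolon-separated lists so that the file stays one row per
arm.

Imputation follows three rules used when assembling exposure-response
inputs from literature data:

* missing body weight <- sample-size-weighted median of the observed arm
  weights (each arm's weight replicated ``n`` times before the median);
* missing cycle-1 AUC <- AUC_inf x AUC ratio, the ratio being the median of
  AUC/AUC_inf over arms reporting both;
* any other missing exposure metric <- median of that metric over arms of
  the same drug at the same dose level.

The composite dose-limiting-toxicity (DLT) count for an arm is the most
frequent of the reported components: DLT proper, dose reduction, drug
discontinuation, or interruption/delay.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from .pk_twocmt import ExposureSummary


class Phase(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class Drug(str, enum.Enum):
    TDM1 = "TDM1"
    TDXD = "TDXd"


class Schedule(str, enum.Enum):
    Q3W = "Q3W"
    QW = "QW"


class Outcome(str, enum.Enum):
    ORR = "ORR"
    DLT = "DLT"
    PFS = "PFS"
    OS = "OS"


class ValidationError(ValueError):
    """A row violated a schema invariant; message names the arm and field."""


class StudyArm(BaseModel):
    study_id: str
    arm_id: str
    phase: Phase
    cancer_type: str
    drug: Drug
    dose_mgkg: float
    schedule: Schedule
    n: int
    median_weight_kg: float | None = None

    @field_validator("dose_mgkg")
    @classmethod
    def _dose_positive(cls, v: float) -> float:
        if not (v > 0):
            raise ValueError("dose_mgkg must be > 0")
        return v

    @field_validator("n")
    @classmethod
    def _n_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n must be >= 1")
        return v

    @field_validator("median_weight_kg")
    @classmethod
    def _weight_positive(cls, v: float | None) -> float | None:
        if v is not None and not (v > 0):
            raise ValueError("median_weight_kg must be > 0 when present")
        return v


class ConcSeries(BaseModel):
    arm_ref: str
    times: list[float]
    conc: list[float]
    summary_stat: str = "mean"

    @model_validator(mode="after")
    def _check(self) -> "ConcSeries":
        if len(self.times) != len(self.conc):
            raise ValueError("times and conc must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty concentration series")
        t = np.asarray(self.times)
        if not np.all(np.diff(t) > 0) or not np.all(t > 0):
            raise ValueError("times must be positive and strictly increasing")
        c = np.asarray(self.conc)
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("conc must be finite and >= 0")
        return self


class OutcomeCount(BaseModel):
    arm_ref: str
    outcome: Outcome
    events: int
    total: int

    @model_validator(mode="after")
    def _check(self) -> "OutcomeCount":
        if self.total < 1:
            raise ValueError("total must be >= 1")
        if not (0 <= self.events <= self.total):
            raise ValueError("events must satisfy 0 <= events <= total")
        return self


class DltComponents(BaseModel):
    """Component counts feeding the composite DLT endpoint."""

    dlt_reported: int | None = None
    dose_reduction: int | None = None
    discontinuation: int | None = None
    interruption_delay: int | None = None
    total: int

    @model_validator(mode="after")
    def _check(self) -> "DltComponents":
        if self.total < 1:
            raise ValueError("total must be >= 1")
        for name in ("dlt_reported", "dose_reduction", "discontinuation", "interruption_delay"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= self.total):
                raise ValueError(f"{name} must satisfy 0 <= count <= total")
        return self

    def present(self) -> dict[str, int]:
        return {
            k: v
            for k, v in (
                ("dlt_reported", self.dlt_reported),
                ("dose_reduction", self.dose_reduction),
                ("discontinuation", self.discontinuation),
                ("interruption_delay", self.interruption_delay),
            )
            if v is not None
        }


def derive_composite_dlt(c: DltComponents, arm_ref: str = "") -> OutcomeCount:
    """Composite DLT = the most frequent of the present component counts."""
    present = c.present()
    if not present:
        raise ValidationError(f"arm {arm_ref!r}: all DLT components missing")
    return OutcomeCount(
        arm_ref=arm_ref, outcome=Outcome.DLT, events=max(present.values()), total=c.total
    )


# ---------------------------------------------------------------------------
# dataset container

CSV_COLUMNS = [
    "study_id", "arm_id", "phase", "cancer_type", "drug", "dose_mgkg",
    "schedule", "n", "median_weight_kg", "time_h", "conc_ngml",
    "cmax", "cmin_504", "auc_0_504", "auc_inf",
    "orr_events", "orr_total", "dlt_events", "dlt_total",
    "dlt_reported", "dose_reduction", "discontinuation", "interruption_delay",
    "pfs_events", "pfs_total", "os_events", "os_total",
]

_OUTCOME_COLS = {
    Outcome.ORR: ("orr_events", "orr_total"),
    Outcome.DLT: ("dlt_events", "dlt_total"),
    Outcome.PFS: ("pfs_events", "pfs_total"),
    Outcome.OS: ("os_events", "os_total"),
}


@dataclass
class Dataset:
    """Validated in-memory dataset keyed by globally unique ``arm_id``."""

    arms: list[StudyArm] = field(default_factory=list)
    conc: dict[str, ConcSeries] = field(default_factory=dict)
    exposures: dict[str, ExposureSummary] = field(default_factory=dict)
    outcomes: dict[tuple[str, Outcome], OutcomeCount] = field(default_factory=dict)
    dlt_components: dict[str, DltComponents] = field(default_factory=dict)
    #: (arm_id, field) pairs filled in by imputation rather than observed
    imputed: set[tuple[str, str]] = field(default_factory=set)

    def arm(self, arm_id: str) -> StudyArm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    def validate(self) -> None:
        seen: set[str] = set()
        for a in self.arms:
            if a.arm_id in seen:
                raise ValidationError(f"duplicate arm_id {a.arm_id!r}")
            seen.add(a.arm_id)
        for ref in list(self.conc) + list(self.exposures) + list(self.dlt_components):
            if ref not in seen:
                raise ValidationError(f"dangling arm reference {ref!r}")
        for (ref, _), oc in self.outcomes.items():
            if ref not in seen or oc.arm_ref != ref:
                raise ValidationError(f"dangling outcome reference {ref!r}")
        for exp in self.exposures.values():
            exp.validate()

    # -- frame conversion ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            row: dict = {c: None for c in CSV_COLUMNS}
            row.update(
                study_id=a.study_id, arm_id=a.arm_id, phase=a.phase.value,
                cancer_type=a.cancer_type, drug=a.drug.value, dose_mgkg=a.dose_mgkg,
                schedule=a.schedule.value, n=a.n, median_weight_kg=a.median_weight_kg,
            )
            cs = self.conc.get(a.arm_id)
            if cs is not None:
                row["time_h"] = ";".join(_fmt(t) for t in cs.times)
                row["conc_ngml"] = ";".join(_fmt(c) for c in cs.conc)
            ex = self.exposures.get(a.arm_id)
            if ex is not None:
                row["cmax"] = ex.cmax
                row["cmin_504"] = ex.cmin_504h
                row["auc_0_504"] = ex.auc_0_504h
                row["auc_inf"] = ex.auc_inf
            for outcome, (ecol, tcol) in _OUTCOME_COLS.items():
                oc = self.outcomes.get((a.arm_id, outcome))
                if oc is not None:
                    row[ecol] = oc.events
                    row[tcol] = oc.total
            dc = self.dlt_components.get(a.arm_id)
            if dc is not None:
                row["dlt_reported"] = dc.dlt_reported
                row["dose_reduction"] = dc.dose_reduction
                row["discontinuation"] = dc.discontinuation
                row["interruption_delay"] = dc.interruption_delay
                row["dlt_total"] = dc.total if row["dlt_total"] is None else row["dlt_total"]
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_json(self, path: str | Path) -> None:
        payload = json.loads(self.to_frame().to_json(orient="records"))
        Path(path).write_text(json.dumps(payload, indent=1))


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _get(row, col):
    v = row.get(col)
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return v


def _get_int(row, col, where):
    v = _get(row, col)
    if v is None:
        return None
    f = float(v)
    if f != int(f):
        raise ValidationError(f"{where}: column {col!r} must be an integer, got {v}")
    return int(f)


def from_frame(df: pd.DataFrame, drug: Drug | str | None = None) -> Dataset:
    """Build and validate a Dataset from the wide one-row-per-arm frame."""
    if drug is not None:
        drug = Drug(drug)
    ds = Dataset()
    for i, row in enumerate(df.to_dict(orient="records")):
        where = f"row {i} (arm_id={row.get('arm_id')!r})"
        try:
            arm = StudyArm(
                study_id=str(_get(row, "study_id")),
                arm_id=str(_get(row, "arm_id")),
                phase=_get(row, "phase"),
                cancer_type=str(_get(row, "cancer_type")),
                drug=_get(row, "drug"),
                dose_mgkg=float(_get(row, "dose_mgkg")),
                schedule=_get(row, "schedule"),
                n=_get_int(row, "n", where),
                median_weight_kg=(None if _get(row, "median_weight_kg") is None
                                  else float(_get(row, "median_weight_kg"))),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{where}: {exc}") from exc
        if drug is not None and arm.drug != drug:
            continue
        ds.arms.append(arm)

        t_raw, c_raw = _get(row, "time_h"), _get(row, "conc_ngml")
        if t_raw is not None and c_raw is not None:
            try:
                ds.conc[arm.arm_id] = ConcSeries(
                    arm_ref=arm.arm_id,
                    times=[float(x) for x in str(t_raw).split(";")],
                    conc=[float(x) for x in str(c_raw).split(";")],
                )
            except ValueError as exc:
                raise ValidationError(f"{where}: concentration series: {exc}") from exc

        exp = ExposureSummary(
            cmax=None if _get(row, "cmax") is None else float(_get(row, "cmax")),
            cmin_504h=None if _get(row, "cmin_504") is None else float(_get(row, "cmin_504")),
            auc_0_504h=None if _get(row, "auc_0_504") is None else float(_get(row, "auc_0_504")),
            auc_inf=None if _get(row, "auc_inf") is None else float(_get(row, "auc_inf")),
        )
        if any(v is not None for v in vars(exp).values()):
            try:
                exp.validate()
            except ValueError as exc:
                raise ValidationError(f"{where}: {exc}") from exc
            ds.exposures[arm.arm_id] = exp

        for outcome, (ecol, tcol) in _OUTCOME_COLS.items():
            ev, tot = _get_int(row, ecol, where), _get_int(row, tcol, where)
            if ev is None and tot is None:
                continue
            if ev is None or tot is None:
                raise ValidationError(f"{where}: {outcome.value} needs both events and total")
            try:
                ds.outcomes[(arm.arm_id, outcome)] = OutcomeCount(
                    arm_ref=arm.arm_id, outcome=outcome, events=ev, total=tot
                )
            except ValueError as exc:
                raise ValidationError(f"{where}: {exc}") from exc

        comp = {k: _get_int(row, k, where)
                for k in ("dlt_reported", "dose_reduction", "discontinuation",
                          "interruption_delay")}
        if any(v is not None for v in comp.values()):
            tot = _get_int(row, "dlt_total", where)
            if tot is None:
                raise ValidationError(f"{where}: DLT components present but dlt_total missing")
            try:
                dc = DltComponents(total=tot, **comp)
            except ValueError as exc:
                raise ValidationError(f"{where}: {exc}") from exc
            ds.dlt_components[arm.arm_id] = dc
            if (arm.arm_id, Outcome.DLT) not in ds.outcomes:
                ds.outcomes[(arm.arm_id, Outcome.DLT)] = derive_composite_dlt(dc, arm.arm_id)
    ds.validate()
    return ds


def read_dataset(path: str | Path, drug: Drug | str | None = None) -> Dataset:
    """Read and validate a dataset CSV (UTF-8, empty cells = missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # parse errors carry pandas' row/column context
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return from_frame(df, drug=drug)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    df = ds.to_frame()
    out = df.copy()

    def _cell(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return _fmt(v) if isinstance(v, float) else str(v)

    for col in out.columns:
        out[col] = out[col].map(_cell)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# imputation

def weighted_median(values: Iterable[float], weights: Iterable[int]) -> float:
    """Median of each value replicated ``weight`` times (midpoint on ties)."""
    expanded = np.repeat(np.asarray(list(values), float),
                         np.asarray(list(weights), int))
    if expanded.size == 0:
        raise ValueError("no observed values to take a median over")
    return float(np.median(expanded))


def impute_weight(ds: Dataset) -> Dataset:
    """Fill missing arm body weights with the n-weighted median of observed ones."""
    observed = [(a.median_weight_kg, a.n) for a in ds.arms if a.median_weight_kg is not None]
    if not observed and any(a.median_weight_kg is None for a in ds.arms):
        raise ValidationError("cannot impute body weight: no arm reports it")
    if observed:
        med = weighted_median(*zip(*observed))
        for i, a in enumerate(ds.arms):
            if a.median_weight_kg is None:
                ds.arms[i] = a.model_copy(update={"median_weight_kg": med})
                ds.imputed.add((a.arm_id, "median_weight_kg"))
    return ds


def estimate_auc_ratio(ds: Dataset) -> float | None:
    """Median AUC(0-504)/AUC_inf across arms reporting both (None if none do)."""
    ratios = [
        e.auc_0_504h / e.auc_inf
        for a in ds.arms
        if (e := ds.exposures.get(a.arm_id)) is not None
        and e.auc_0_504h is not None and e.auc_inf is not None and e.auc_inf > 0
        and (a.arm_id, "auc_0_504h") not in ds.imputed
    ]
    return float(np.median(ratios)) if ratios else None


def impute_auc(auc_inf_value: float, ratio: float) -> float:
    """Cycle-1 AUC from AUC_inf and the cycle-capture ratio."""
    if not (auc_inf_value > 0):
        raise ValueError("auc_inf must be > 0")
    if not (0 < ratio <= 1):
        raise ValueError("AUC ratio must lie in (0, 1]")
    return auc_inf_value * ratio


def impute_missing_exposures(ds: Dataset) -> Dataset:
    """Apply both exposure imputation rules, in order.

    First fill missing cycle-1 AUCs from AUC_inf via the median observed
    ratio; then fill any remaining missing metric with the median of that
    metric across arms of the same drug at the same dose level.  Arms with
    no donors keep the value missing (they drop out of exposure-response
    assembly for that metric).
    """
    ratio = estimate_auc_ratio(ds)
    if ratio is not None:
        for a in ds.arms:
            e = ds.exposures.get(a.arm_id)
            if e is not None and e.auc_0_504h is None and e.auc_inf is not None:
                e.auc_0_504h = impute_auc(e.auc_inf, min(ratio, 1.0))
                ds.imputed.add((a.arm_id, "auc_0_504h"))

    for metric in ("cmax", "cmin_504h", "auc_0_504h", "auc_inf"):
        donors: dict[tuple[Drug, float], list[float]] = {}
        for a in ds.arms:
            e = ds.exposures.get(a.arm_id)
            if e is not None and getattr(e, metric) is not None \
                    and (a.arm_id, metric) not in ds.imputed:
                donors.setdefault((a.drug, a.dose_mgkg), []).append(getattr(e, metric))
        for a in ds.arms:
            e = ds.exposures.get(a.arm_id)
            if e is None:
                e = ds.exposures[a.arm_id] = ExposureSummary()
            if getattr(e, metric) is None:
                pool = donors.get((a.drug, a.dose_mgkg), [])
                if pool:
                    setattr(e, metric, float(np.median(pool)))
                    ds.imputed.add((a.arm_id, metric))
    # clamp imputed values so cross-metric invariants still hold; observed
    # values are never touched
    for a in ds.arms:
        e = ds.exposures.get(a.arm_id)
        if e is None:
            continue
        if e.auc_0_504h is not None and e.auc_inf is not None and e.auc_0_504h > e.auc_inf:
            if (a.arm_id, "auc_0_504h") in ds.imputed:
                e.auc_0_504h = e.auc_inf
            elif (a.arm_id, "auc_inf") in ds.imputed:
                e.auc_inf = e.auc_0_504h
        if e.cmin_504h is not None and e.cmax is not None and e.cmin_504h > e.cmax:
            if (a.arm_id, "cmin_504h") in ds.imputed:
                e.cmin_504h = e.cmax
            elif (a.arm_id, "cmax") in ds.imputed:
                e.cmax = e.cmin_504h
        e.validate()
    return ds
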