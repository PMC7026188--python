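"""Creatinine-ratio AKI e-alert algorithm.

Each creatinine measurement is compared against a per-measurement baseline:
the lowest creatinine value recorded for the same patient in the preceding
12 months if any exists, otherwise the age-appropriate upper reference limit.
The fold-rise (measurement / baseline) maps to an AKI stage:

========  =================
stage     fold-rise ``r``
========  =================
none      ``r < 1.5``
1         ``1.5 <= r < 2``
2         ``2 <= r < 3``
3         ``r >= 3``
========  =================

The lookback window is strictly before the index measurement,
``[t - 365 d, t)``: a measurement never serves as its own baseline, and
same-timestamp duplicates are excluded from each other's windows (earlier
same-day values remain eligible).  Measurements with no prior-year baseline
never raise an alert; instead they are annotated with whether their value
exceeds the reference limit ("above reference" single high values).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .reference import (
    DAYS_PER_YEAR,
    ELIGIBLE_AGE_MAX_DAYS,
    ELIGIBLE_AGE_MIN_DAYS,
    ReferenceTable,
)

LOOKBACK = timedelta(days=DAYS_PER_YEAR)

STAGE_NONE = 0

BASELINE_PRIOR_MINIMUM = "prior_minimum"
BASELINE_REFERENCE_LIMIT = "reference_upper_limit"

#: Required columns of a measurement table, in canonical order.
MEASUREMENT_COLUMNS = [
    "patient_id",
    "measured_at",
    "creatinine_umol_l",
    "age_days",
    "sex",
    "centre",
]

ALERT_COLUMNS = MEASUREMENT_COLUMNS + ["baseline_value", "baseline_source", "ratio", "stage"]


@dataclass(frozen=True)
class CreatinineMeasurement:
    """One timestamped plasma creatinine result for one patient."""

    patient_id: str
    measured_at: datetime
    value: float  # µmol/L
    age_days: float
    sex: str = "any"
    centre: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(f"creatinine must be positive, got {self.value}")


@dataclass(frozen=True)
class BaselineResult:
    """A resolved baseline and where it came from."""

    value: float  # µmol/L
    source: str  # BASELINE_PRIOR_MINIMUM or BASELINE_REFERENCE_LIMIT
    window_start: datetime
    window_end: datetime


@dataclass(frozen=True)
class AKIAlert:
    """A measurement whose fold-rise over baseline reaches stage 1 or above."""

    measurement: CreatinineMeasurement
    baseline: BaselineResult
    ratio: float
    stage: int


def stage_from_ratio(ratio: float) -> int:
    """Map a fold-rise to an AKI stage (0 = no alert).

    Thresholds are lower-inclusive: exactly 1.5x is stage 1, exactly 2x is
    stage 2, exactly 3x is stage 3.
    """
    if not ratio > 0:
        raise ValidationError(f"fold-rise must be positive, got {ratio}")
    if ratio < 1.5:
        return STAGE_NONE
    if ratio < 2.0:
        return 1
    if ratio < 3.0:
        return 2
    return 3


def compute_baseline(
    history: Iterable[CreatinineMeasurement],
    t: datetime,
    age_days: float,
    sex: str,
    reference: ReferenceTable,
) -> BaselineResult:
    """Resolve the baseline for an index time ``t`` from one patient's history.

    Returns the minimum value among history measurements with
    ``t - 365 d <= measured_at < t`` (source ``prior_minimum``); if the window
    is empty, falls back to the age-referenced upper limit (source
    ``reference_upper_limit``).
    """
    window_start = t - LOOKBACK
    in_window = [m.value for m in history if window_start <= m.measured_at < t]
    if in_window:
        return BaselineResult(
            value=min(in_window),
            source=BASELINE_PRIOR_MINIMUM,
            window_start=window_start,
            window_end=t,
        )
    return BaselineResult(
        value=reference.upper_limit(age_days, sex),
        source=BASELINE_REFERENCE_LIMIT,
        window_start=window_start,
        window_end=t,
    )


def evaluate_measurement(
    m: CreatinineMeasurement,
    history: Iterable[CreatinineMeasurement],
    reference: ReferenceTable,
) -> Optional[AKIAlert]:
    """Stage one measurement against its history; None when below stage 1."""
    baseline = compute_baseline(history, m.measured_at, m.age_days, m.sex, reference)
    ratio = m.value / baseline.value
    stage = stage_from_ratio(ratio)
    if stage == STAGE_NONE:
        return None
    return AKIAlert(measurement=m, baseline=baseline, ratio=ratio, stage=stage)


@dataclass
class StreamResult:
    """Output of :func:`evaluate_stream`.

    ``annotations`` carries one row per input measurement (canonical order)
    with the resolved baseline, fold-rise, stage, a ``has_prior_baseline``
    flag and — for measurements lacking a prior-year baseline — an
    ``above_reference`` flag.  ``alerts`` is the subset with stage >= 1.
    """

    annotations: pd.DataFrame
    alerts: pd.DataFrame


def _validate_stream_frame(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise SchemaError(
            f"measurement table is missing columns {missing}; expected {MEASUREMENT_COLUMNS}"
        )
    df = measurements.loc[:, MEASUREMENT_COLUMNS].copy()
    df["measured_at"] = pd.to_datetime(df["measured_at"])
    df["creatinine_umol_l"] = df["creatinine_umol_l"].astype(float)
    df["age_days"] = df["age_days"].astype(float)
    if (df["creatinine_umol_l"] <= 0).any():
        bad = df.index[df["creatinine_umol_l"] <= 0].tolist()
        raise ValidationError(f"non-positive creatinine values at rows {bad[:5]}")
    return df


def evaluate_stream(
    measurements: pd.DataFrame,
    reference: ReferenceTable,
    *,
    exclude_alert_values_from_baseline: bool = False,
) -> StreamResult:
    """Run the e-alert algorithm over a multi-patient measurement table.

    The table is processed in canonical order (patient, time, value), so the
    result is independent of input row order.  Per patient, the 12-month
    rolling minimum is maintained with a monotonic deque, giving O(n) work
    per patient rather than the naive O(n²) full scan.

    When ``exclude_alert_values_from_baseline`` is set, values that
    themselves triggered an alert are withheld from later baseline windows
    (off by default: the algorithm's baseline is simply the lowest prior-year
    value).
    """
    df = _validate_stream_frame(measurements)
    df = df.sort_values(
        ["patient_id", "measured_at", "creatinine_umol_l", "age_days"], kind="mergesort"
    ).reset_index(drop=True)

    n = len(df)
    has_prior = np.zeros(n, dtype=bool)
    baseline_value = np.empty(n, dtype=float)
    baseline_source = np.empty(n, dtype=object)
    ratio = np.empty(n, dtype=float)
    stage = np.zeros(n, dtype=np.int8)
    above_reference = np.full(n, None, dtype=object)

    window = np.timedelta64(DAYS_PER_YEAR, "D")
    times_all = df["measured_at"].to_numpy()
    vals_all = df["creatinine_umol_l"].to_numpy()
    ages_all = df["age_days"].to_numpy()
    sexes_all = df["sex"].to_numpy()
    pids = df["patient_id"].to_numpy()

    start = 0
    while start < n:
        stop = start
        while stop < n and pids[stop] == pids[start]:
            stop += 1
        dq: deque[tuple[np.datetime64, float]] = deque()
        i = start
        while i < stop:
            j = i
            while j < stop and times_all[j] == times_all[i]:
                j += 1
            t = times_all[i]
            cutoff = t - window
            while dq and dq[0][0] < cutoff:
                dq.popleft()
            base = dq[0][1] if dq else None
            for k in range(i, j):
                if base is not None:
                    has_prior[k] = True
                    baseline_value[k] = base
                    baseline_source[k] = BASELINE_PRIOR_MINIMUM
                else:
                    limit = reference.upper_limit(ages_all[k], str(sexes_all[k]))
                    baseline_value[k] = limit
                    baseline_source[k] = BASELINE_REFERENCE_LIMIT
                    above_reference[k] = bool(vals_all[k] > limit)
                r = vals_all[k] / baseline_value[k]
                ratio[k] = r
                stage[k] = stage_from_ratio(r)
            for k in range(i, j):
                if exclude_alert_values_from_baseline and stage[k] >= 1:
                    continue
                v = vals_all[k]
                while dq and dq[-1][1] > v:
                    dq.pop()
                dq.append((times_all[k], v))
            i = j
        start = stop

    annotations = df.assign(
        has_prior_baseline=has_prior,
        baseline_value=baseline_value,
        baseline_source=baseline_source,
        ratio=ratio,
        stage=stage,
        above_reference=pd.array(above_reference, dtype="boolean"),
    )
    alerts = (
        annotations.loc[annotations["stage"] >= 1, ALERT_COLUMNS]
        .reset_index(drop=True)
    )
    return StreamResult(annotations=annotations, alerts=alerts)


def eligible_age(age_days: float,
                 age_min_days: int = ELIGIBLE_AGE_MIN_DAYS,
                 age_max_days: int = ELIGIBLE_AGE_MAX_DAYS) -> bool:
    """Whether an age falls in the configurable eligibility window."""
    return age_min_days <= age_days < age_max_days
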