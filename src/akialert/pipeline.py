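"""End-to-end orchestration: validate input, stage every measurement,
aggregate the cohort report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import CohortReport, build_report, summarise_patients
from .ealert import evaluate_stream
from .io import prepare_measurements, read_measurements
from .reference import ELIGIBLE_AGE_MAX_DAYS, ELIGIBLE_AGE_MIN_DAYS, ReferenceTable


@dataclass
class PipelineResult:
    measurements: pd.DataFrame      # validated, typed input rows
    rejects: pd.DataFrame           # rows excluded, with reasons
    annotations: pd.DataFrame       # per-measurement staging annotations
    alerts: pd.DataFrame            # measurements at stage >= 1
    patient_summaries: pd.DataFrame
    report: CohortReport


def run_pipeline(
    measurements: pd.DataFrame | str | Path,
    reference: Optional[ReferenceTable] = None,
    audit: Optional[pd.DataFrame] = None,
    *,
    age_min_days: float = ELIGIBLE_AGE_MIN_DAYS,
    age_max_days: float = ELIGIBLE_AGE_MAX_DAYS,
    exclude_alert_values_from_baseline: bool = False,
    continuity_correction: bool = False,
    rate_digits: int = 1,
    mix_digits: int = 0,
) -> PipelineResult:
    """Run validation, staging and aggregation over a measurement table.

    ``measurements`` may be a CSV path or a DataFrame (typed or raw
    strings); malformed rows land in ``rejects`` rather than aborting.
    """
    if reference is None:
        reference = ReferenceTable.default()
    if isinstance(measurements, (str, Path)):
        clean, rejects = read_measurements(
            measurements, age_min_days=age_min_days, age_max_days=age_max_days
        )
    else:
        clean, rejects = prepare_measurements(
            measurements, age_min_days=age_min_days, age_max_days=age_max_days
        )
    stream = evaluate_stream(
        clean, reference,
        exclude_alert_values_from_baseline=exclude_alert_values_from_baseline,
    )
    baseline_alerts = stream.alerts.loc[stream.alerts["baseline_source"] == "prior_minimum"]
    summaries = summarise_patients(baseline_alerts)
    report = build_report(
        stream.annotations,
        stream.alerts,
        patient_summaries=summaries,
        audit=audit,
        continuity_correction=continuity_correction,
        rate_digits=rate_digits,
        mix_digits=mix_digits,
    )
    return PipelineResult(
        measurements=clean,
        rejects=rejects,
        annotations=stream.annotations,
        alerts=stream.alerts,
        patient_summaries=summaries,
        report=report,
    )
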