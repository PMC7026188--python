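"""Cohort-level aggregation of e-alert output.

Produces the headline epidemiological quantities: measurement-level alert
rates (overall and restricted to measurements with a prior-year baseline),
the above-reference fraction among measurements without one, the stage mix
over alerts, per-patient worst-stage summaries with age bands, per-centre
distributions, and — when a case-note audit table is supplied — the
recognition/management proportions.

Percentages are rounded half-away-from-zero; a rate with a zero denominator
is reported as undefined (``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from . import stats as _stats
from .errors import ValidationError
from .reference import DAYS_PER_YEAR

#: Half-open age bands in years, matching the reporting convention
#: (<1, 1-<6, 6-<11, 11-<16, 16-<18).
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("<1y", 0, 1),
    ("1-<6y", 1, 6),
    ("6-<11y", 6, 11),
    ("11-<16y", 11, 16),
    ("16-<18y", 16, 18),
)

AGE_BAND_LABELS = tuple(label for label, _, _ in AGE_BANDS)

RECOGNITION_CATEGORIES = ("yes", "no", "no_information")


def round_half_away(x: float, digits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, digits: int = 1) -> Optional[float]:
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    Returns ``None`` (undefined) when the denominator is zero.
    """
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, digits)


def age_band(age_days: float) -> str:
    """Assign an age in days to its half-open year band (365-day years)."""
    years = age_days / DAYS_PER_YEAR
    for label, lo, hi in AGE_BANDS:
        if lo <= years < hi:
            return label
    raise ValidationError(f"age {age_days} d outside the banded range [0,18) years")


def summarise_patients(alerts: pd.DataFrame) -> pd.DataFrame:
    """One row per alerted patient: worst stage, alert count, age band, centre.

    The age band is fixed at the patient's first alert, so a patient alerting
    across a birthday is counted in exactly one band.
    """
    if alerts.empty:
        return pd.DataFrame(
            columns=["patient_id", "worst_stage", "n_alerts", "age_band", "centre"]
        )
    if not alerts["stage"].between(1, 3).all():
        raise ValidationError("alerts must have stage in {1,2,3}")
    ordered = alerts.sort_values(["patient_id", "measured_at"], kind="mergesort")
    first = ordered.groupby("patient_id", sort=True).first()
    grouped = ordered.groupby("patient_id", sort=True)
    out = pd.DataFrame(
        {
            "patient_id": first.index,
            "worst_stage": grouped["stage"].max().to_numpy(),
            "n_alerts": grouped.size().to_numpy(),
            "age_band": [age_band(a) for a in first["age_days"]],
            "centre": first["centre"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class CohortReport:
    """Headline aggregates for one analysed measurement stream."""

    n_measurements: int
    n_with_prior_baseline: int
    n_without_prior_baseline: int
    n_above_reference: int
    n_alerts: int
    n_reference_baseline_alerts: int
    n_alert_patients: int
    alert_rate_all: Optional[float]          # % of all measurements
    alert_rate_restricted: Optional[float]   # % of measurements with a prior baseline
    above_reference_rate: Optional[float]    # % of measurements without one
    baseline_coverage: Optional[float]       # % of measurements with a prior baseline
    stage_counts: dict[int, int] = field(default_factory=dict)
    stage_mix: dict[int, Optional[float]] = field(default_factory=dict)
    age_band_counts: dict[str, int] = field(default_factory=dict)
    age_band_percents: dict[str, Optional[float]] = field(default_factory=dict)
    per_centre: dict[str, dict] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)
    audit: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "n_measurements": self.n_measurements,
            "n_with_prior_baseline": self.n_with_prior_baseline,
            "n_without_prior_baseline": self.n_without_prior_baseline,
            "n_above_reference": self.n_above_reference,
            "n_alerts": self.n_alerts,
            "n_reference_baseline_alerts": self.n_reference_baseline_alerts,
            "n_alert_patients": self.n_alert_patients,
            "alert_rate_all_pct": self.alert_rate_all,
            "alert_rate_restricted_pct": self.alert_rate_restricted,
            "above_reference_rate_pct": self.above_reference_rate,
            "baseline_coverage_pct": self.baseline_coverage,
            "stage_counts": {str(k): v for k, v in sorted(self.stage_counts.items())},
            "stage_mix_pct": {str(k): v for k, v in sorted(self.stage_mix.items())},
            "age_band_counts": dict(self.age_band_counts),
            "age_band_percents": dict(self.age_band_percents),
            "per_centre": self.per_centre,
            "comparisons": self.comparisons,
            "audit": self.audit,
        }

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_table(self) -> str:
        """Human-readable multi-section summary."""
        def fmt(x):
            return "undefined" if x is None else f"{x:g}%"

        lines = [
            "Cohort report",
            "=============",
            f"measurements analysed            {self.n_measurements:>10,}",
            f"  with prior-year baseline       {self.n_with_prior_baseline:>10,}"
            f"  ({fmt(self.baseline_coverage)})",
            f"  without prior-year baseline    {self.n_without_prior_baseline:>10,}",
            f"  above reference (no baseline)  {self.n_above_reference:>10,}"
            f"  ({fmt(self.above_reference_rate)})",
            f"AKI alerts                       {self.n_alerts:>10,}"
            f"  ({fmt(self.alert_rate_all)} of all, "
            f"{fmt(self.alert_rate_restricted)} of those with baseline)",
            f"alerted patients                 {self.n_alert_patients:>10,}",
            f"stage>=1 vs reference fallback   {self.n_reference_baseline_alerts:>10,}"
            "  (not counted as AKI alerts)",
            "",
            "Stage mix over alerts:",
        ]
        for s in (1, 2, 3):
            lines.append(
                f"  stage {s}: {self.stage_counts.get(s, 0):,} ({fmt(self.stage_mix.get(s))})"
            )
        lines.append("")
        lines.append("Alerted patients by age band:")
        for label in AGE_BAND_LABELS:
            lines.append(
                f"  {label:>8}: {self.age_band_counts.get(label, 0):,}"
                f" ({fmt(self.age_band_percents.get(label))})"
            )
        if self.per_centre:
            lines.append("")
            lines.append("Alerted patients by centre:")
            for centre in sorted(self.per_centre):
                c = self.per_centre[centre]
                mix = ", ".join(
                    f"stage {s}: {fmt(c['stage_mix_pct'].get(str(s)))}" for s in (1, 2, 3)
                )
                lines.append(f"  {centre}: {c['n_patients']:,} patients ({mix})")
        for name, comp in sorted(self.comparisons.items()):
            lines.append("")
            lines.append(
                f"{name}: chi2 = {comp['statistic']:.2f}, df = {comp['df']}, "
                f"p = {comp['p_value']:.3g}"
            )
        if self.audit:
            a = self.audit
            lines.append("")
            lines.append(
                f"Case-note audit (n = {a['n_audited']}): recognised "
                f"{a['counts']['yes']} ({fmt(a['percents']['yes'])}), not recognised "
                f"{a['counts']['no']} ({fmt(a['percents']['no'])}), no information "
                f"{a['counts']['no_information']} ({fmt(a['percents']['no_information'])})"
            )
        return "\n".join(lines) + "\n"


def build_report(
    annotations: pd.DataFrame,
    alerts: pd.DataFrame,
    patient_summaries: Optional[pd.DataFrame] = None,
    audit: Optional[pd.DataFrame] = None,
    *,
    rate_digits: int = 1,
    mix_digits: int = 0,
    continuity_correction: bool = False,
) -> CohortReport:
    """Aggregate annotated stream output into a :class:`CohortReport`.

    ``rate_digits`` applies to measurement-level rates (default one decimal),
    ``mix_digits`` to stage-mix and age-band percentages (default integers).

    Only alerts staged against a prior-year minimum enter the headline
    counts, rates and patient summaries; "single high values" staged against
    the reference-limit fallback are tallied separately
    (``n_reference_baseline_alerts``) and, when above the limit, in the
    above-reference fraction.
    """
    if "baseline_source" in alerts.columns and len(alerts):
        baseline_alerts = alerts.loc[alerts["baseline_source"] == "prior_minimum"]
        n_ref_alerts = int((alerts["baseline_source"] == "reference_upper_limit").sum())
    else:
        baseline_alerts = alerts
        n_ref_alerts = 0
    if patient_summaries is None:
        patient_summaries = summarise_patients(baseline_alerts)

    n_measurements = int(len(annotations))
    n_with = int(annotations["has_prior_baseline"].sum()) if n_measurements else 0
    n_without = n_measurements - n_with
    above = annotations.loc[~annotations["has_prior_baseline"], "above_reference"]
    n_above = int(above.fillna(False).sum()) if n_without else 0
    n_alerts = int(len(baseline_alerts))
    n_patients = int(len(patient_summaries))

    stage_counts = {s: int((baseline_alerts["stage"] == s).sum()) for s in (1, 2, 3)} if n_alerts else {1: 0, 2: 0, 3: 0}
    stage_mix = {s: percentage(c, n_alerts, mix_digits) for s, c in stage_counts.items()}

    band_counts = {label: 0 for label in AGE_BAND_LABELS}
    if n_patients:
        for label, cnt in patient_summaries["age_band"].value_counts().items():
            band_counts[label] = int(cnt)
    band_percents = {
        label: percentage(cnt, n_patients, mix_digits) for label, cnt in band_counts.items()
    }

    per_centre: dict[str, dict] = {}
    if n_patients:
        for centre, sub in patient_summaries.groupby("centre", sort=True):
            centre_stages = {s: int((sub["worst_stage"] == s).sum()) for s in (1, 2, 3)}
            per_centre[str(centre)] = {
                "n_patients": int(len(sub)),
                "stage_counts": {str(s): c for s, c in centre_stages.items()},
                "stage_mix_pct": {
                    str(s): percentage(c, len(sub), mix_digits) for s, c in centre_stages.items()
                },
            }

    comparisons = _build_comparisons(
        annotations, n_alerts, n_with, n_above, n_without, continuity_correction
    )

    audit_summary = recognition_summary(audit) if audit is not None and len(audit) else None

    return CohortReport(
        n_measurements=n_measurements,
        n_with_prior_baseline=n_with,
        n_without_prior_baseline=n_without,
        n_above_reference=n_above,
        n_alerts=n_alerts,
        n_reference_baseline_alerts=n_ref_alerts,
        n_alert_patients=n_patients,
        alert_rate_all=percentage(n_alerts, n_measurements, rate_digits),
        alert_rate_restricted=percentage(n_alerts, n_with, rate_digits),
        above_reference_rate=percentage(n_above, n_without, rate_digits),
        baseline_coverage=percentage(n_with, n_measurements, rate_digits),
        stage_counts=stage_counts,
        stage_mix=stage_mix,
        age_band_counts=band_counts,
        age_band_percents=band_percents,
        per_centre=per_centre,
        comparisons=comparisons,
        audit=audit_summary,
    )


def _build_comparisons(annotations, n_alerts, n_with, n_above, n_without, correction):
    comparisons: dict[str, dict] = {}
    # alert rate among baseline-bearing measurements vs above-reference rate
    # among baseline-free measurements, as a 2x2 with columns event / non-event
    table = [[n_alerts, n_with - n_alerts], [n_above, n_without - n_above]]
    if min(n_with, n_without) > 0 and all(min(row) >= 0 for row in table):
        try:
            ct = _stats.ContingencyTable.from_counts(
                table,
                row_labels=["with_prior_baseline", "without_prior_baseline"],
                col_labels=["event", "no_event"],
            )
            res = _stats.chi_squared_test(ct, continuity_correction=correction)
            comparisons["alert_rate_vs_above_reference"] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "continuity_correction": bool(correction),
            }
        except _stats.DegenerateTableError:
            pass
    # centre heterogeneity of the measurement-level alert rate
    if len(annotations):
        counts = (
            annotations.assign(alert=annotations["stage"] >= 1)
            .groupby("centre", sort=True)["alert"]
            .agg(["sum", "count"])
        )
        rows = [[int(s), int(c - s)] for s, c in zip(counts["sum"], counts["count"])]
        if len(rows) >= 2:
            try:
                ct = _stats.ContingencyTable.from_counts(
                    rows,
                    row_labels=[str(i) for i in counts.index],
                    col_labels=["alert", "no_alert"],
                )
                res = _stats.chi_squared_test(ct)
                comparisons["centre_heterogeneity"] = {
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }
            except _stats.DegenerateTableError:
                pass
    return comparisons


def recognition_summary(audit: pd.DataFrame, digits: int = 0) -> dict:
    """Three-way recognition split plus per-management-item rates.

    ``audit`` needs a ``recognised`` column with values in
    ``{"yes", "no", "no_information"}``; every other column except
    ``patient_id`` is treated as a yes/no management item and summarised
    within the recognised and not-recognised groups.
    """
    if audit.empty:
        raise ValidationError("audit table is empty")
    rec = audit["recognised"].astype(str)
    unknown = sorted(set(rec) - set(RECOGNITION_CATEGORIES))
    if unknown:
        raise ValidationError(
            f"unknown recognition categories {unknown}; expected {RECOGNITION_CATEGORIES}"
        )
    n = len(audit)
    counts = {cat: int((rec == cat).sum()) for cat in RECOGNITION_CATEGORIES}
    percents = {cat: percentage(c, n, digits) for cat, c in counts.items()}

    item_cols = [c for c in audit.columns if c not in ("patient_id", "recognised")]
    items: dict[str, dict] = {}
    truthy = {"1", "true", "yes", "y"}
    for col in item_cols:
        flags = audit[col].astype(str).str.strip().str.lower().isin(truthy)
        items[col] = {}
        for cat in ("yes", "no"):
            mask = rec == cat
            items[col][cat] = {
                "n": int(flags[mask].sum()),
                "pct": percentage(int(flags[mask].sum()), int(mask.sum()), digits),
            }
    return {
        "n_audited": n,
        "counts": counts,
        "percents": percents,
        "management_items": items,
    }
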