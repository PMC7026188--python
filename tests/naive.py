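"""Independent brute-force re-implementation of the staging algorithm.

Used only as a test oracle: for every measurement it rescans the patient's
entire history (O(n^2)) instead of maintaining a rolling window, and spells
out the staging thresholds directly.  It shares no code with the package's
evaluate_stream beyond the reference-table lookup.
"""

from datetime import timedelta

import pandas as pd

LOOKBACK = timedelta(days=365)


def naive_stage(ratio: float) -> int:
    if ratio >= 3.0:
        return 3
    if ratio >= 2.0:
        return 2
    if ratio >= 1.5:
        return 1
    return 0


def naive_evaluate(measurements: pd.DataFrame, reference) -> pd.DataFrame:
    """Annotate every measurement by full scan; returns rows sorted canonically."""
    df = measurements.copy()
    df["measured_at"] = pd.to_datetime(df["measured_at"])
    rows = []
    for pid, sub in df.groupby("patient_id"):
        recs = sub.to_dict("records")
        for m in recs:
            t = m["measured_at"]
            prior = [
                r["creatinine_umol_l"]
                for r in recs
                if t - LOOKBACK <= r["measured_at"] < t
            ]
            if prior:
                baseline = min(prior)
                source = "prior_minimum"
                has_prior = True
                above = None
            else:
                baseline = reference.upper_limit(m["age_days"], m["sex"])
                source = "reference_upper_limit"
                has_prior = False
                above = m["creatinine_umol_l"] > baseline
            ratio = m["creatinine_umol_l"] / baseline
            rows.append(
                {
                    **m,
                    "has_prior_baseline": has_prior,
                    "baseline_value": baseline,
                    "baseline_source": source,
                    "ratio": ratio,
                    "stage": naive_stage(ratio),
                    "above_reference": above,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["patient_id", "measured_at", "creatinine_umol_l", "age_days"], kind="mergesort"
    ).reset_index(drop=True)
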