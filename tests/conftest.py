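import numpy as np
import pandas as pd
import pytest

from akialert import ReferenceInterval, ReferenceTable


@pytest.fixture(scope="session")
def two_row_table() -> ReferenceTable:
    """Infant limit 40, everyone else 100, covering the whole eligible range."""
    return ReferenceTable(
        [
            ReferenceInterval(29, 365, "any", 40.0),
            ReferenceInterval(365, 6570, "any", 100.0),
        ]
    )


@pytest.fixture(scope="session")
def default_reference() -> ReferenceTable:
    return ReferenceTable.default()


def random_cohort(rng: np.random.Generator, n_patients: int,
                  mean_measurements: float = 4.0) -> pd.DataFrame:
    """Random multi-patient measurement table spanning the lookback boundary.

    Values are drawn wide enough that prior minima, reference fallbacks and
    all three stages occur; times straddle a year so the 365-day window is
    exercised at both edges.
    """
    rows = []
    t0 = pd.Timestamp("2012-07-01")
    for i in range(n_patients):
        n = 1 + rng.poisson(mean_measurements)
        age0 = rng.uniform(40, 5800)  # span <= 684 d keeps ages inside [29, 6570)
        sex = rng.choice(["male", "female", "any"])
        centre = f"C{rng.integers(1, 4)}"
        offsets = rng.uniform(-500, 184, size=n)  # days, incl. pre-window points
        values = np.exp(rng.normal(np.log(35), 0.6, size=n))
        for off, v in zip(offsets, values):
            t = t0 + pd.Timedelta(minutes=int(round(off * 24 * 60)))
            rows.append((f"P{i}", t, float(v), age0 + off - offsets.min(), sex, centre))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "measured_at", "creatinine_umol_l", "age_days", "sex", "centre"],
    )
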