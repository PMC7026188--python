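"""Age-indexed upper reference limits for plasma creatinine.

The e-alert algorithm needs an age-appropriate upper reference limit in two
places: as the fallback baseline when a patient has no creatinine measurement
in the previous 12 months, and as the screen that flags a "single high value"
among measurements lacking any prior-year baseline.

Limits are stored as half-open age intervals ``[age_min_days, age_max_days)``
in µmol/L.  A bundled default table ships with the package; it contains
*illustrative* paediatric upper limits by age band and is not a clinical
reference — production use should supply a locally validated table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ReferenceCoverageError, SchemaError, ValidationError

#: Days per year used throughout the package (lookback window, age bands).
DAYS_PER_YEAR = 365

#: Eligibility window: neonates under 29 days are excluded, as is age >= 18 y.
ELIGIBLE_AGE_MIN_DAYS = 29
ELIGIBLE_AGE_MAX_DAYS = 18 * DAYS_PER_YEAR

SEXES = ("any", "male", "female")

REFERENCE_COLUMNS = ["age_min_days", "age_max_days", "sex", "upper_limit_umol_l"]


@dataclass(frozen=True)
class ReferenceInterval:
    """One age band with its upper reference limit.

    ``sex`` is ``"any"`` for age-only rows; ``"male"``/``"female"`` rows take
    precedence over ``"any"`` rows at lookup time.
    """

    age_min_days: int
    age_max_days: int
    sex: str
    upper_limit_umol_l: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex category {self.sex!r}; expected one of {SEXES}")
        if not self.age_min_days < self.age_max_days:
            raise ValidationError(
                f"age_min_days ({self.age_min_days}) must be < age_max_days ({self.age_max_days})"
            )
        if not self.upper_limit_umol_l > 0:
            raise ValidationError(f"upper_limit_umol_l must be positive, got {self.upper_limit_umol_l}")

    def contains(self, age_days: float) -> bool:
        return self.age_min_days <= age_days < self.age_max_days


class ReferenceTable:
    """Validated collection of :class:`ReferenceInterval` rows.

    On construction the table is checked for (i) non-overlapping intervals
    within each sex category and (ii) gap-free coverage of the eligible age
    range ``[age_min_days, age_max_days)`` for every sex after applying the
    precedence rule (sex-specific rows may overlay ``any`` rows).
    """

    def __init__(
        self,
        intervals: Iterable[ReferenceInterval],
        *,
        age_min_days: int = ELIGIBLE_AGE_MIN_DAYS,
        age_max_days: int = ELIGIBLE_AGE_MAX_DAYS,
    ) -> None:
        self.intervals: tuple[ReferenceInterval, ...] = tuple(intervals)
        if not self.intervals:
            raise ValidationError("reference table is empty")
        if not age_min_days < age_max_days:
            raise ValidationError("age_min_days must be < age_max_days")
        self.age_min_days = age_min_days
        self.age_max_days = age_max_days
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ReferenceTable":
        missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(
                f"reference table is missing columns {missing}; expected {REFERENCE_COLUMNS}"
            )
        intervals = [
            ReferenceInterval(
                age_min_days=int(row.age_min_days),
                age_max_days=int(row.age_max_days),
                sex=str(row.sex),
                upper_limit_umol_l=float(row.upper_limit_umol_l),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(intervals, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ReferenceTable":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    @classmethod
    def from_json(cls, path: str | Path, **kwargs) -> "ReferenceTable":
        with open(path) as fh:
            records = json.load(fh)
        return cls.from_dataframe(pd.DataFrame.from_records(records), **kwargs)

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "ReferenceTable":
        """Load from CSV or JSON, dispatching on the file suffix."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path, **kwargs)
        return cls.from_csv(path, **kwargs)

    @classmethod
    def default(cls) -> "ReferenceTable":
        """The bundled illustrative table (age-only bands, not clinical)."""
        with resources.files("akialert.data").joinpath("reference_default.csv").open("rb") as fh:
            return cls.from_dataframe(pd.read_csv(fh))

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        by_sex: dict[str, list[tuple[int, ReferenceInterval]]] = {s: [] for s in SEXES}
        for idx, iv in enumerate(self.intervals):
            by_sex[iv.sex].append((idx, iv))
        # non-overlap within each sex category
        for sex, rows in by_sex.items():
            rows_sorted = sorted(rows, key=lambda r: r[1].age_min_days)
            for (i_a, a), (i_b, b) in zip(rows_sorted, rows_sorted[1:]):
                if b.age_min_days < a.age_max_days:
                    raise ValidationError(
                        f"overlapping {sex!r} intervals: row {i_a} "
                        f"[{a.age_min_days},{a.age_max_days}) and row {i_b} "
                        f"[{b.age_min_days},{b.age_max_days})"
                    )
        # gap-free coverage of the eligible range for each resolved sex
        for sex in ("male", "female"):
            applicable = sorted(
                by_sex[sex] + by_sex["any"], key=lambda r: (r[1].age_min_days, r[1].age_max_days)
            )
            cursor = self.age_min_days
            for idx, iv in applicable:
                if iv.age_max_days <= cursor:
                    continue
                if iv.age_min_days > cursor:
                    raise ValidationError(
                        f"coverage gap for sex {sex!r} at ages [{cursor},{iv.age_min_days}) "
                        f"before row {idx}"
                    )
                cursor = iv.age_max_days
                if cursor >= self.age_max_days:
                    break
            if cursor < self.age_max_days:
                raise ValidationError(
                    f"coverage gap for sex {sex!r} at ages [{cursor},{self.age_max_days})"
                )

    # -- queries ----------------------------------------------------------

    def upper_limit(self, age_days: float, sex: str = "any") -> float:
        """Upper reference limit (µmol/L) for an age, honouring sex precedence.

        Membership is half-open: an age exactly at an interval boundary
        belongs to the upper interval.
        """
        if not (self.age_min_days <= age_days < self.age_max_days):
            raise ReferenceCoverageError(
                f"age {age_days} d outside covered range "
                f"[{self.age_min_days},{self.age_max_days}) d"
            )
        if sex in ("male", "female"):
            for iv in self.intervals:
                if iv.sex == sex and iv.contains(age_days):
                    return iv.upper_limit_umol_l
        for iv in self.intervals:
            if iv.sex == "any" and iv.contains(age_days):
                return iv.upper_limit_umol_l
        raise ReferenceCoverageError(f"no reference interval covers age {age_days} d for sex {sex!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.age_min_days, iv.age_max_days, iv.sex, iv.upper_limit_umol_l) for iv in self.intervals],
            columns=REFERENCE_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __repr__(self) -> str:
        return (
            f"ReferenceTable({len(self.intervals)} intervals, "
            f"ages [{self.age_min_days},{self.age_max_days}) d)"
        )


def load_reference_table(source: str | Path | pd.DataFrame | Sequence[ReferenceInterval],
                         **kwargs) -> ReferenceTable:
    """Load and validate a reference table from a CSV/JSON path or DataFrame."""
    if isinstance(source, ReferenceTable):
        return source
    if isinstance(source, pd.DataFrame):
        return ReferenceTable.from_dataframe(source, **kwargs)
    if isinstance(source, (str, Path)):
        return ReferenceTable.load(source, **kwargs)
    return ReferenceTable(source, **kwargs)


def upper_reference_limit(age_days: float, sex: str, table: ReferenceTable) -> float:
    """Functional alias for :meth:`ReferenceTable.upper_limit`."""
    return table.upper_limit(age_days, sex)
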