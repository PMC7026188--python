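"""Seeded synthetic paediatric creatinine streams with known ground truth.

The generator emulates the laboratory extract the pipeline consumes: per
patient, an age-dependent stable baseline (a fraction of the age reference
upper limit), Poisson-distributed measurement times over a six-month study
window, optional prior-year measurements (controlling the baseline-lookback
coverage), an optionally injected AKI episode — a rectangular elevation of
the latent creatinine by a factor drawn inside a target stage's fold-rise
interval — and multiplicative lognormal measurement noise.

Because every patient draws from two dedicated RNG substreams (one for
demographics/times/noise, one for the episode), raising the episode
prevalence with a fixed seed only *adds* episodes; everything else about the
cohort is unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ealert import MEASUREMENT_COLUMNS
from .errors import ValidationError
from .reference import ReferenceTable

#: fold-rise interval the episode factor is drawn from, per target stage
STAGE_FACTOR_INTERVALS = {1: (1.5, 2.0), 2: (2.0, 3.0), 3: (3.0, 6.0)}

_BAND_BOUNDS_DAYS = ((40, 365), (365, 2190), (2190, 4015), (4015, 5840), (5840, 6570))
_CENTRES = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass
class SimulationConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults mirror the conditions of a six-month multi-centre paediatric
    laboratory extract: a July–December study window, ~75% of patients with
    prior-year measurements, a 62/16/22 stage mix for injected episodes, and
    an age distribution weighted toward the under-6s.
    """

    n_patients: int = 500
    study_start: str = "2012-07-01"
    study_end: str = "2012-12-31"
    lookback_coverage: float = 0.75
    measurement_rate: float = 4.0
    episode_prevalence: float = 0.12
    stage_mix: tuple[float, float, float] = (0.62, 0.16, 0.22)
    baseline_fraction_of_limit: tuple[float, float] = (0.4, 0.8)
    noise_cv: float = 0.05
    age_band_weights: tuple[float, ...] = (0.20, 0.39, 0.17, 0.19, 0.05)
    centre_weights: tuple[float, ...] = (0.245, 0.031, 0.017, 0.138, 0.211, 0.358)
    episode_length_days: tuple[float, float] = (2.0, 14.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in ("lookback_coverage", "episode_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.measurement_rate < 0:
            raise ValidationError("measurement_rate must be >= 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if len(self.stage_mix) != 3 or any(p < 0 for p in self.stage_mix):
            raise ValidationError("stage_mix must be three non-negative probabilities")
        if not math.isclose(sum(self.stage_mix), 1.0, abs_tol=1e-9):
            raise ValidationError("stage_mix must sum to 1")
        lo, hi = self.baseline_fraction_of_limit
        if not (0 < lo <= hi):
            raise ValidationError("baseline_fraction_of_limit must satisfy 0 < lo <= hi")
        if len(self.age_band_weights) != len(_BAND_BOUNDS_DAYS) or any(
            w < 0 for w in self.age_band_weights
        ) or sum(self.age_band_weights) <= 0:
            raise ValidationError("age_band_weights must be 5 non-negative weights")
        if len(self.centre_weights) != len(_CENTRES) or any(
            w < 0 for w in self.centre_weights
        ) or sum(self.centre_weights) <= 0:
            raise ValidationError("centre_weights must be 6 non-negative weights")
        lo, hi = self.episode_length_days
        if not (0 < lo <= hi):
            raise ValidationError("episode_length_days must satisfy 0 < lo <= hi")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ValidationError("study_start must precede study_end")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("stage_mix", "baseline_fraction_of_limit", "age_band_weights",
                    "centre_weights", "episode_length_days"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """Latent state behind one simulated cohort."""

    patients: pd.DataFrame  # one row per patient
    latent: pd.DataFrame    # one row per measurement, aligned with the table
    config: SimulationConfig

    def latent_measurements(self) -> pd.DataFrame:
        """The measurement table with noise-free latent values substituted."""
        df = self.latent.loc[:, MEASUREMENT_COLUMNS[:2] + ["latent_value"]].copy()
        df = df.rename(columns={"latent_value": "creatinine_umol_l"})
        for col in ("age_days", "sex", "centre"):
            df[col] = self.latent[col]
        return df.loc[:, MEASUREMENT_COLUMNS]


def _noise_factors(z: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones_like(z)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * z - 0.5 * sigma * sigma)  # mean-one lognormal


def simulate_cohort(
    config: SimulationConfig,
    reference: Optional[ReferenceTable] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a measurement table and its ground truth.

    Identical ``config`` (including seed) reproduces the output exactly.
    An injected episode is guaranteed at least one in-window measurement
    (one is added at the episode midpoint if the Poisson draw left none), so
    every episode is observable in the data.
    """
    config.validate()
    if reference is None:
        reference = ReferenceTable.default()

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    span_days = (end - start) / pd.Timedelta(days=1)

    band_w = np.asarray(config.age_band_weights, dtype=float)
    band_w = band_w / band_w.sum()
    centre_w = np.asarray(config.centre_weights, dtype=float)
    centre_w = centre_w / centre_w.sum()
    stage_w = np.asarray(config.stage_mix, dtype=float)

    pat_rows = []
    meas_rows = []
    id_width = len(str(config.n_patients))

    for i in range(config.n_patients):
        rng_base = np.random.default_rng([config.seed, i, 0])
        rng_epi = np.random.default_rng([config.seed, i, 1])
        pid = f"P{i + 1:0{id_width}d}"

        band = int(rng_base.choice(len(_BAND_BOUNDS_DAYS), p=band_w))
        lo, hi = _BAND_BOUNDS_DAYS[band]
        hi_draw = min(hi, int(6570 - span_days - 1)) if band == len(_BAND_BOUNDS_DAYS) - 1 else hi
        age_at_start = float(rng_base.uniform(lo, hi_draw))
        sex = "male" if rng_base.uniform() < 0.5 else "female"
        centre = str(rng_base.choice(np.asarray(_CENTRES, dtype=object), p=centre_w))
        limit = reference.upper_limit(age_at_start, sex)
        frac = float(rng_base.uniform(*config.baseline_fraction_of_limit))
        baseline = frac * limit

        has_lookback = bool(rng_base.uniform() < config.lookback_coverage)
        n_meas = int(rng_base.poisson(config.measurement_rate))
        offsets = np.sort(rng_base.uniform(0.0, span_days, size=n_meas))
        pre_offsets = np.array([], dtype=float)
        if has_lookback:
            max_back = min(90.0, age_at_start - 29.0)
            if max_back > 1.0:
                k = int(rng_base.integers(1, 4))
                pre_offsets = -np.sort(rng_base.uniform(1.0, max_back, size=k))[::-1]
        z_base = rng_base.standard_normal(len(pre_offsets) + n_meas)

        # episode substream: the presence draw always comes first so that a
        # larger prevalence turns the same patients (plus new ones) episodic
        u_episode = float(rng_epi.uniform())
        has_episode = u_episode < config.episode_prevalence
        target_stage = 0
        e_start = e_end = np.nan
        factor = 1.0
        extra = None
        if has_episode:
            target_stage = int(rng_epi.choice((1, 2, 3), p=stage_w))
            length = float(rng_epi.uniform(*config.episode_length_days))
            length = min(length, span_days)
            e_start = float(rng_epi.uniform(0.0, span_days - length))
            e_end = e_start + length
            f_lo, f_hi = STAGE_FACTOR_INTERVALS[target_stage]
            factor = float(rng_epi.uniform(f_lo, f_hi))
            if not np.any((offsets >= e_start) & (offsets <= e_end)):
                extra = (0.5 * (e_start + e_end), float(rng_epi.standard_normal()))

        all_offsets = np.concatenate([pre_offsets, offsets])
        zs = z_base
        if extra is not None:
            all_offsets = np.append(all_offsets, extra[0])
            zs = np.append(zs, extra[1])
        order = np.argsort(all_offsets, kind="stable")
        all_offsets = all_offsets[order]
        zs = zs[order]

        in_episode = (
            (all_offsets >= e_start) & (all_offsets <= e_end)
            if has_episode
            else np.zeros_like(all_offsets, dtype=bool)
        )
        latent = np.where(in_episode, baseline * factor, baseline)
        measured = latent * _noise_factors(zs, config.noise_cv)

        exceeds = bool((not has_lookback) and np.any(latent[all_offsets >= 0] > limit))
        pat_rows.append(
            (pid, age_at_start, sex, centre, baseline, limit, has_lookback,
             has_episode, target_stage, e_start, e_end, factor, exceeds)
        )
        minutes = np.rint(all_offsets * 24 * 60).astype(np.int64)
        for off_min, v, lv, ep, off in zip(minutes, measured, latent, in_episode, all_offsets):
            t = start + pd.Timedelta(minutes=int(off_min))
            meas_rows.append((pid, t, float(v), age_at_start + float(off), sex, centre, float(lv), bool(ep)))

    patients = pd.DataFrame(
        pat_rows,
        columns=[
            "patient_id", "age_at_start_days", "sex", "centre", "true_baseline",
            "reference_limit", "has_lookback", "has_episode", "target_stage",
            "episode_start_day", "episode_end_day", "episode_factor",
            "exceeds_limit_without_lookback",
        ],
    )
    full = pd.DataFrame(
        meas_rows,
        columns=MEASUREMENT_COLUMNS + ["latent_value", "in_episode"],
    )
    measurements = full.loc[:, MEASUREMENT_COLUMNS].copy()
    latent = full.loc[:, MEASUREMENT_COLUMNS[:2] + ["age_days", "sex", "centre",
                                                    "latent_value", "in_episode"]].copy()
    return measurements, GroundTruth(patients=patients, latent=latent, config=config)


@dataclass
class Scorecard:
    """Episode-detection performance of the pipeline against ground truth."""

    n_patients: int
    n_episode_patients: int
    n_detected_episode_patients: int
    n_false_positive_patients: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    sensitivity_by_stage: dict[int, Optional[float]]
    confusion: pd.DataFrame  # rows: target stage, cols: assigned worst stage

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_episode_patients": self.n_episode_patients,
            "n_detected_episode_patients": self.n_detected_episode_patients,
            "n_false_positive_patients": self.n_false_positive_patients,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_by_stage": {str(k): v for k, v in self.sensitivity_by_stage.items()},
            "confusion": {
                str(t): {str(a): int(self.confusion.loc[t, a]) for a in self.confusion.columns}
                for t in self.confusion.index
            },
        }


def scorecard(alerts: pd.DataFrame, truth: GroundTruth) -> Scorecard:
    """Patient-level detection sensitivity/specificity and stage confusion.

    A patient counts as detected when they carry at least one alert; the
    assigned stage for the confusion matrix is their worst alert stage.
    """
    truth_ids = set(truth.patients["patient_id"])
    alert_ids = set(alerts["patient_id"]) if len(alerts) else set()
    stray = alert_ids - truth_ids
    if stray:
        raise ValidationError(f"alerts reference patients absent from ground truth: {sorted(stray)[:5]}")

    worst = (
        alerts.groupby("patient_id")["stage"].max() if len(alerts) else pd.Series(dtype=int)
    )
    pats = truth.patients
    episode = pats["has_episode"].to_numpy(dtype=bool)
    detected = pats["patient_id"].isin(worst.index).to_numpy()

    n_epi = int(episode.sum())
    n_non = int((~episode).sum())
    n_det = int((episode & detected).sum())
    n_fp = int((~episode & detected).sum())

    sens_by_stage: dict[int, Optional[float]] = {}
    for s in (1, 2, 3):
        mask = episode & (pats["target_stage"].to_numpy() == s)
        sens_by_stage[s] = float((mask & detected).sum() / mask.sum()) if mask.sum() else None

    confusion = pd.DataFrame(0, index=[1, 2, 3], columns=[1, 2, 3], dtype=int)
    det_pats = pats.loc[episode & detected]
    for pid, target in zip(det_pats["patient_id"], det_pats["target_stage"]):
        confusion.loc[int(target), int(worst[pid])] += 1

    return Scorecard(
        n_patients=int(len(pats)),
        n_episode_patients=n_epi,
        n_detected_episode_patients=n_det,
        n_false_positive_patients=n_fp,
        sensitivity=(n_det / n_epi) if n_epi else None,
        specificity=((n_non - n_fp) / n_non) if n_non else None,
        sensitivity_by_stage=sens_by_stage,
        confusion=confusion,
    )
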