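"""Synthetic cohorts and wrist-monitor streams with known ground truth.

The generator emulates a small older-adult walking/exercise intervention
cohort: baseline characteristics (anthropometrics, resting heart rate,
six-minute-walk distance, questionnaire scores) are drawn around published
cohort summary statistics, and each participant carries one of two latent
adherence phenotypes. The *adherent* phenotype has a lower resting heart
rate and a lower perceived-risk-of-over-activity score (the configured
effect sizes) and systematically higher true adherence; the *non-adherent*
phenotype is the mirror image. A behavioral model then places walking and
exercise sessions on a calendar and renders them as minute-level streams
(walking seconds + minute-mean heart rate), so the whole derivation →
scoring → profiling chain can be tested closed-loop against known labels.

Defaults are parameter choices that reproduce the cohort-level summary
statistics the generator targets; they are not claims about individuals.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .adherence import Prescription
from .minutes import DailyMinutes, DayStream, MinuteRecord
from .physiology import HrZone, SixMwtInputs, hrr_zone, kervio_crf, tanaka_hrmax

__all__ = [
    "ADHERENT",
    "NON_ADHERENT",
    "FeatureDist",
    "CohortSpec",
    "SessionBehavior",
    "BehaviorSpec",
    "GroundTruth",
    "SimulatedStreams",
    "default_feature_distributions",
    "default_outcome_distributions",
    "generate_cohort",
    "generate_streams",
    "participant_zone",
]

ADHERENT = "adherent"
NON_ADHERENT = "non_adherent"

#: baseline feature columns used by the profiling chain
PROFILE_FEATURES = [
    "age_yr",
    "sex_male",
    "bmi_kg_m2",
    "hr_rest_bpm",
    "sixmwt_distance_m",
    "crf_rel_ml_kg_min",
    "pcs12",
    "mcs12",
    "fss",
    "ese",
    "apq_engagement",
    "apq_risk_overactivity",
    "squash_walking_min",
]


@dataclass(frozen=True)
class FeatureDist:
    """Marginal distribution for one baseline feature.

    ``normal`` draws are clipped to the instrument bounds; ``lognormal``
    draws are parameterized so the *un-truncated* mean and SD match the
    targets (used for heavily right-skewed self-report minutes).
    """

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None
    dist: str = "normal"  # "normal" | "lognormal"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "lognormal":
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            values = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        else:
            values = rng.normal(self.mean, self.sd, size=n)
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        return np.clip(values, lo, hi)


def default_feature_distributions() -> dict[str, FeatureDist]:
    """Questionnaire-score marginals anchored to the cohort baseline table."""
    return {
        "pcs12": FeatureDist(53.5, 3.2),
        "mcs12": FeatureDist(58.4, 2.1),
        "fss": FeatureDist(2.50, 0.77, lower=1.0, upper=7.0),
        "ese": FeatureDist(62.7, 23.6, lower=0.0, upper=100.0),
        "apq_engagement": FeatureDist(2.68, 0.92, lower=1.0, upper=5.0),
        "apq_risk_overactivity": FeatureDist(2.45, 0.98, lower=1.0, upper=5.0),
        "squash_walking_min": FeatureDist(153.0, 180.0, lower=0.0, dist="lognormal"),
    }


def default_outcome_distributions() -> dict[str, tuple[tuple[float, float], tuple[float, float]]]:
    """Latent per-phenotype outcome distributions ((adherent), (non-adherent)).

    Adherence outcomes are fractions (1.0 = 100%); their mixtures land near
    the cohort-level intervention-week adherence summaries. The 6-MWT change
    encodes the observed pattern of a decline concentrated in the
    non-adherent phenotype.
    """
    return {
        "walking_program_adherence": ((0.85, 0.30), (0.30, 0.22)),
        "exercise_program_adherence": ((1.75, 0.55), (0.55, 0.35)),
        "sixmwt_change_m": ((5.0, 15.0), (-25.0, 15.0)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-generation parameters (means/SDs in the units of the field names).

    ``phenotype_mix`` is the adherent fraction (default 0.4, matching the
    4-vs-6 cluster split of the emulated cohort). ``effect_sizes`` are
    pooled-SD shifts applied symmetrically around each feature's mean, with
    the adherent phenotype on the *lower* side. Resting heart rate is
    specified per phenotype directly because the emulated subgroups differ
    in spread as well as location.
    """

    n_participants: int = 10
    seed: int = 0
    age_mean: float = 73.8
    age_sd: float = 2.3
    male_fraction: float = 0.6
    height_mean_cm: float = 170.0
    height_sd_cm: float = 11.0
    body_mass_mean_kg: float = 81.6
    body_mass_sd_kg: float = 13.8
    hr_rest_adherent: tuple[float, float] = (65.0, 5.0)       # mean, sd (bpm)
    hr_rest_nonadherent: tuple[float, float] = (78.0, 15.0)
    sixmwt_mean_m: float = 508.0
    sixmwt_sd_m: float = 60.0
    vo2_rest_mean: float = 300.0  # mL/min seated rest
    vo2_rest_sd: float = 40.0
    phenotype_mix: float = 0.4
    exact_split: bool = False
    feature_distributions: Mapping[str, FeatureDist] = field(
        default_factory=default_feature_distributions
    )
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"apq_risk_overactivity": 1.0}
    )
    outcome_distributions: Mapping[
        str, tuple[tuple[float, float], tuple[float, float]]
    ] = field(default_factory=default_outcome_distributions)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least 2 participants")
        if not (0.0 <= self.phenotype_mix <= 1.0):
            raise ValueError("phenotype_mix must lie in [0, 1]")
        for name, sd in (
            ("age_sd", self.age_sd),
            ("height_sd_cm", self.height_sd_cm),
            ("body_mass_sd_kg", self.body_mass_sd_kg),
            ("sixmwt_sd_m", self.sixmwt_sd_m),
        ):
            if sd <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.effect_sizes) - set(self.feature_distributions)
        if unknown:
            raise ValueError(f"effect_sizes reference unknown features: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Latent phenotype labels and latent outcome values per participant."""

    labels: dict[str, str]
    outcomes: pd.DataFrame  # indexed by participant_id

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "outcomes": {
                pid: {k: float(v) for k, v in row.items()}
                for pid, row in self.outcomes.to_dict(orient="index").items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            labels=dict(payload["labels"]),
            outcomes=pd.DataFrame.from_dict(payload["outcomes"], orient="index"),
        )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a baseline feature table plus its latent ground truth.

    Deterministic for a fixed ``spec.seed``. The adherent phenotype sits
    ``effect_size`` pooled SDs *below* the non-adherent phenotype on each
    effect-carrying feature (split symmetrically around the cohort mean so
    cohort-level summaries stay on target).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    if spec.exact_split:
        n_adh = int(round(spec.phenotype_mix * n))
        is_adherent = np.zeros(n, dtype=bool)
        is_adherent[rng.permutation(n)[:n_adh]] = True
    else:
        is_adherent = rng.random(n) < spec.phenotype_mix

    pids = [f"P{i + 1:02d}" for i in range(n)]
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 60.0, 90.0)
    sex_male = (rng.random(n) < spec.male_fraction).astype(int)
    height = np.clip(rng.normal(spec.height_mean_cm, spec.height_sd_cm, n), 140.0, 200.0)
    mass = np.clip(rng.normal(spec.body_mass_mean_kg, spec.body_mass_sd_kg, n), 40.0, 150.0)

    hr_rest = np.empty(n)
    for pheno, (mu, sd) in (
        (True, spec.hr_rest_adherent),
        (False, spec.hr_rest_nonadherent),
    ):
        mask = is_adherent == pheno
        hr_rest[mask] = rng.normal(mu, sd, mask.sum())
    hr_rest = np.clip(hr_rest, 40.0, 120.0)

    distance = np.clip(rng.normal(spec.sixmwt_mean_m, spec.sixmwt_sd_m, n), 100.0, 1000.0)
    vo2_rest = np.clip(rng.normal(spec.vo2_rest_mean, spec.vo2_rest_sd, n), 150.0, None)

    table: dict[str, np.ndarray] = {
        "age_yr": age,
        "sex_male": sex_male.astype(float),
        "height_cm": height,
        "body_mass_kg": mass,
        "bmi_kg_m2": mass / (height / 100.0) ** 2,
        "hr_rest_bpm": hr_rest,
        "sixmwt_distance_m": distance,
    }

    crf = [
        kervio_crf(
            SixMwtInputs(
                age=a, body_mass=m, height=h, distance=d, vo2_rest=v, hr_test=r
            )
        )
        for a, m, h, d, v, r in zip(age, mass, height, distance, vo2_rest, hr_rest)
    ]
    table["crf_abs_ml_min"] = np.array([c.vo2max_abs for c in crf])
    table["crf_rel_ml_kg_min"] = np.array([c.vo2max_rel for c in crf])

    for name, dist in spec.feature_distributions.items():
        es = float(spec.effect_sizes.get(name, 0.0))
        shift = es * dist.sd / 2.0
        values = dist.sample(rng, n)
        values = np.where(is_adherent, values - shift, values + shift)
        lo = -np.inf if dist.lower is None else dist.lower
        hi = np.inf if dist.upper is None else dist.upper
        table[name] = np.clip(values, lo, hi)

    profiles = pd.DataFrame(table, index=pd.Index(pids, name="participant_id"))
    profiles = profiles.reset_index()

    outcome_rows: dict[str, np.ndarray] = {}
    for name, ((mu_a, sd_a), (mu_n, sd_n)) in spec.outcome_distributions.items():
        values = np.where(
            is_adherent,
            rng.normal(mu_a, sd_a, n),
            rng.normal(mu_n, sd_n, n),
        )
        if name.endswith("adherence"):
            values = np.clip(values, 0.0, None)
        outcome_rows[name] = values
    outcomes = pd.DataFrame(outcome_rows, index=pd.Index(pids, name="participant_id"))

    labels = {
        pid: (ADHERENT if flag else NON_ADHERENT)
        for pid, flag in zip(pids, is_adherent)
    }
    return profiles, GroundTruth(labels=labels, outcomes=outcomes)


# ---------------------------------------------------------------------------
# behavioral stream model


@dataclass(frozen=True)
class SessionBehavior:
    """Daily session behavior for one phenotype and one program."""

    attempt_prob: float          # planned-day session probability
    unplanned_prob: float        # non-planned-day session probability
    duration_mean_min: float
    duration_sd_min: float
    zone_fidelity: float = 1.0   # exercise: per-minute P(HR lands in zone)

    def __post_init__(self) -> None:
        for name in ("attempt_prob", "unplanned_prob", "zone_fidelity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.duration_mean_min <= 0 or self.duration_sd_min < 0:
            raise ValueError("session durations must be positive")

    def draw_duration(self, rng: np.random.Generator) -> int:
        dur = rng.normal(self.duration_mean_min, self.duration_sd_min)
        return int(np.clip(round(dur), 1, 180))


def _default_behaviors() -> dict[str, dict[str, SessionBehavior]]:
    return {
        "walking": {
            ADHERENT: SessionBehavior(0.90, 0.50, 35.0, 8.0),
            NON_ADHERENT: SessionBehavior(0.55, 0.15, 27.0, 9.0),
        },
        "exercise": {
            ADHERENT: SessionBehavior(0.95, 0.30, 28.0, 6.0, zone_fidelity=0.9),
            NON_ADHERENT: SessionBehavior(0.50, 0.10, 18.0, 6.0, zone_fidelity=0.8),
        },
    }


@dataclass(frozen=True)
class BehaviorSpec:
    """Phenotype-conditional behavior plus day-level environment effects.

    ``weather_dropout_prob`` is a cohort-shared Bernoulli per calendar day
    (a bad-weather day suppresses all outdoor sessions). ``hr_noise_sd`` is
    the Gaussian minute-mean HR noise around the session/rest setpoint.
    """

    walking: Mapping[str, SessionBehavior] = field(
        default_factory=lambda: _default_behaviors()["walking"]
    )
    exercise: Mapping[str, SessionBehavior] = field(
        default_factory=lambda: _default_behaviors()["exercise"]
    )
    #: per-minute probability that a non-session minute spikes into the
    #: exercise zone (brief exertion the watch counts as exercise because
    #: exercise minutes carry no minimum-bout rule); per phenotype
    incidental_zone_prob: Mapping[str, float] = field(
        default_factory=lambda: {ADHERENT: 0.030, NON_ADHERENT: 0.015}
    )
    weather_dropout_prob: float = 0.10
    hr_noise_sd: float = 4.0
    hr_dropout_prob: float = 0.02     # optical dropouts, non-session minutes only
    wear_start_min: int = 7 * 60
    wear_end_min: int = 22 * 60

    def __post_init__(self) -> None:
        if not (0.0 <= self.weather_dropout_prob <= 1.0):
            raise ValueError("weather_dropout_prob must lie in [0, 1]")
        if not (0 <= self.wear_start_min < self.wear_end_min <= 1440):
            raise ValueError("wear window must satisfy 0 <= start < end <= 1440")

    @classmethod
    def ideal(cls) -> "BehaviorSpec":
        """Fully compliant behavior: every planned session happens, at the
        exact prescribed duration, with perfect HR-zone fidelity and no
        unplanned sessions, weather dropouts, or HR signal loss."""
        return cls(
            walking={
                ADHERENT: SessionBehavior(1.0, 0.0, 30.0, 0.0),
                NON_ADHERENT: SessionBehavior(1.0, 0.0, 30.0, 0.0),
            },
            exercise={
                ADHERENT: SessionBehavior(1.0, 0.0, 25.0, 0.0, zone_fidelity=1.0),
                NON_ADHERENT: SessionBehavior(1.0, 0.0, 25.0, 0.0, zone_fidelity=1.0),
            },
            incidental_zone_prob={ADHERENT: 0.0, NON_ADHERENT: 0.0},
            weather_dropout_prob=0.0,
            hr_dropout_prob=0.0,
        )


@dataclass(frozen=True)
class SimulatedStreams:
    """Generated streams plus the per-day ground-truth tallies behind them."""

    streams: list[DayStream]
    true_daily: dict[str, list[DailyMinutes]]


def participant_zone(age: float, hr_rest: float, rx: Prescription) -> HrZone:
    """Personal Karvonen zone at the prescription's HRR fractions."""
    return hrr_zone(hr_rest, tanaka_hrmax(age), rx.zone.lower_frac, rx.zone.upper_frac)


def generate_streams(
    profiles: pd.DataFrame,
    truth: GroundTruth,
    behavior: BehaviorSpec,
    rx: Prescription,
    n_weeks: int,
    seed: int,
    start_date: dt.date = dt.date(2020, 1, 6),
    walking_only_ids: Iterable[str] = (),
) -> SimulatedStreams:
    """Render per-minute wrist-monitor streams for ``n_weeks`` Monday-anchored weeks.

    Sessions are placed inside the wear window (walking in the morning
    block, exercise in the late afternoon, never overlapping). Walking
    sessions produce contiguous full walking minutes; exercise-session
    minutes land in the participant's personal Karvonen zone with the
    phenotype's ``zone_fidelity``. Non-exercise minutes hover near resting
    HR and are kept strictly below the zone's lower bound, so the exercise
    tally reflects sessions only.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if start_date.weekday() != 0:
        raise ValueError("start_date must be a Monday")
    walking_only = set(walking_only_ids)

    n_days = 7 * n_weeks
    weather_rng = np.random.default_rng([int(seed), 999_983])
    bad_weather = weather_rng.random(n_days) < behavior.weather_dropout_prob

    wear_minutes = np.arange(behavior.wear_start_min, behavior.wear_end_min)
    n_wear = wear_minutes.size

    streams: list[DayStream] = []
    true_daily: dict[str, list[DailyMinutes]] = {}

    for pidx, row in enumerate(profiles.itertuples(index=False)):
        pid = str(row.participant_id)
        label = truth.labels[pid]
        zone = participant_zone(row.age_yr, row.hr_rest_bpm, rx)
        walk_beh = behavior.walking[label]
        ex_beh = behavior.exercise[label]
        rng = np.random.default_rng([int(seed), pidx])
        rest_hr = float(row.hr_rest_bpm)
        reserve = tanaka_hrmax(row.age_yr) - rest_hr
        walk_setpoint = rest_hr + 0.30 * reserve
        hr_cap = zone.lower - 1.0  # non-exercise minutes never enter the zone

        daily: list[DailyMinutes] = []
        for d in range(n_days):
            date = start_date + dt.timedelta(days=d)
            weekday = date.weekday()

            walk_dur = ex_dur = 0
            walk_start = ex_start = -1
            if not bad_weather[d]:
                planned = weekday in rx.planned_walk_days
                p = walk_beh.attempt_prob if planned else walk_beh.unplanned_prob
                if rng.random() < p:
                    walk_dur = walk_beh.draw_duration(rng)
                    walk_start = behavior.wear_start_min + 60 + int(rng.integers(0, 240))
                do_exercise = not (rx.walking_only or pid in walking_only)
                if do_exercise:
                    planned_ex = weekday in rx.planned_exercise_days
                    p = ex_beh.attempt_prob if planned_ex else ex_beh.unplanned_prob
                    if rng.random() < p:
                        ex_dur = ex_beh.draw_duration(rng)
                        ex_start = behavior.wear_start_min + 480 + int(rng.integers(0, 180))

            walking_seconds = np.zeros(n_wear)
            hr = rest_hr + rng.normal(0.0, behavior.hr_noise_sd, n_wear)
            in_zone_count = 0

            if walk_dur > 0:
                sl = slice(walk_start - behavior.wear_start_min,
                           walk_start - behavior.wear_start_min + walk_dur)
                walking_seconds[sl] = 60.0
                hr[sl] = walk_setpoint + rng.normal(0.0, behavior.hr_noise_sd, walk_dur)
            hr = np.clip(hr, 25.0, hr_cap)

            session_mask = np.zeros(n_wear, dtype=bool)
            if walk_dur > 0:
                session_mask[walk_start - behavior.wear_start_min :
                             walk_start - behavior.wear_start_min + walk_dur] = True
            if ex_dur > 0:
                sl = slice(ex_start - behavior.wear_start_min,
                           ex_start - behavior.wear_start_min + ex_dur)
                session_mask[sl] = True
                in_zone = rng.random(ex_dur) < ex_beh.zone_fidelity
                mid = 0.5 * (zone.lower + zone.upper)
                ex_hr = np.where(
                    in_zone,
                    np.clip(
                        mid + rng.normal(0.0, behavior.hr_noise_sd, ex_dur),
                        zone.lower,
                        zone.upper,
                    ),
                    np.clip(
                        zone.lower - 8.0 + rng.normal(0.0, behavior.hr_noise_sd, ex_dur),
                        25.0,
                        hr_cap,
                    ),
                )
                hr[sl] = ex_hr
                in_zone_count = int(in_zone.sum())

            # brief non-session excursions into the zone: counted as exercise
            # because the exercise tally has no minimum-bout rule
            p_inc = float(behavior.incidental_zone_prob.get(label, 0.0))
            if p_inc > 0 and not bad_weather[d]:
                incidental = (rng.random(n_wear) < p_inc) & ~session_mask
                n_inc = int(incidental.sum())
                if n_inc:
                    hr[incidental] = zone.lower + 0.3 * zone.width * rng.random(n_inc)
                    in_zone_count += n_inc
            else:
                incidental = np.zeros(n_wear, dtype=bool)

            missing = np.zeros(n_wear, dtype=bool)
            if behavior.hr_dropout_prob > 0:
                missing = (
                    (rng.random(n_wear) < behavior.hr_dropout_prob)
                    & ~session_mask
                    & ~incidental
                )

            midnight = dt.datetime.combine(date, dt.time())
            records = tuple(
                MinuteRecord(
                    timestamp=midnight + dt.timedelta(minutes=int(m)),
                    walking_seconds=float(w),
                    mean_hr=None if miss else float(h),
                )
                for m, w, h, miss in zip(wear_minutes, walking_seconds, hr, missing)
            )
            streams.append(DayStream(participant_id=pid, date=date, records=records))

            # ground-truth tallies under the same counting rules
            true_walk = float(walk_dur) if walk_dur * 60 >= 110 else 0.0
            daily.append(
                DailyMinutes(
                    date=date,
                    walking_minutes=true_walk,
                    exercise_minutes=float(in_zone_count),
                    participant_id=pid,
                )
            )
        true_daily[pid] = daily

    return SimulatedStreams(streams=streams, true_daily=true_daily)
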