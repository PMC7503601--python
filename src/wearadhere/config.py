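"""Study configuration: one YAML/JSON document drives the whole pipeline.

The document mirrors the study design: a cohort spec, a behavior spec, a
prescription, a Monday-anchored calendar (baseline week + intervention
weeks), one top-level seed, and stage toggles. The top-level seed is fanned
out deterministically as ``stage_seed = seed + stage_index`` so stages stay
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .adherence import Prescription
from .physiology import hrr_zone
from .synthetic import BehaviorSpec, CohortSpec, SessionBehavior

__all__ = ["StudyConfig", "ConfigIssue", "load_config", "validate_config"]

#: stage order used for seed fan-out (stage_seed = seed + index)
STAGES = ("simulate", "derive", "adhere", "profile", "stats")


@dataclass(frozen=True)
class ConfigIssue:
    """One structured validation finding."""

    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.message}"


@dataclass(frozen=True)
class StudyConfig:
    """Everything one pipeline run needs, with study-shaped defaults."""

    seed: int = 0
    output_dir: str = "run_output"
    start_date: dt.date = dt.date(2020, 1, 6)   # a Monday, wintertime
    n_baseline_weeks: int = 1
    n_intervention_weeks: int = 2
    cohort: CohortSpec = field(default_factory=CohortSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    prescription: Prescription = field(default_factory=Prescription)
    walking_only_ids: tuple[str, ...] = ()
    run_profiling: bool = True
    run_stats: bool = True
    profile_target: str = "exercise_program_adherence"
    selection_seeds: int = 10    # seed sweep size at pilot scale (n < 20)

    @property
    def n_weeks(self) -> int:
        return self.n_baseline_weeks + self.n_intervention_weeks

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + STAGES.index(stage)

    def week_labels(self) -> dict[dt.date, str]:
        labels: dict[dt.date, str] = {}
        for w in range(self.n_weeks):
            monday = self.start_date + dt.timedelta(weeks=w)
            if w < self.n_baseline_weeks:
                labels[monday] = "baseline" if self.n_baseline_weeks == 1 else f"baseline{w + 1}"
            else:
                labels[monday] = f"week{w - self.n_baseline_weeks + 1}"
        return labels

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dt.date):
                return obj.isoformat()
            if isinstance(obj, (frozenset, set, tuple)):
                return sorted(convert(v) for v in obj)
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        return convert(self)

    def config_hash(self) -> str:
        """Content hash, stable under key reordering of the source document."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _session_behavior(raw: dict[str, Any], default: SessionBehavior) -> SessionBehavior:
    return dataclasses.replace(default, **raw)


def _build_prescription(raw: dict[str, Any]) -> Prescription:
    raw = dict(raw)
    lower = raw.pop("zone_lower_frac", 0.50)
    upper = raw.pop("zone_upper_frac", 0.80)
    for key in ("planned_walk_days", "planned_exercise_days"):
        if key in raw:
            raw[key] = frozenset(int(d) for d in raw[key])
    # reference zone at cohort-mean physiology; per-participant zones are
    # recomputed from the fractions at derivation time
    zone = hrr_zone(73.0, 211.0 - 0.8 * 73.8, lower, upper)
    return Prescription(zone=zone, **raw)


def load_config(source: str | Path | dict[str, Any]) -> StudyConfig:
    """Build a StudyConfig from a YAML/JSON file or an equivalent mapping.

    Every key is optional; omitted keys take the study defaults. Unknown
    keys raise immediately so typos cannot silently fall back to defaults.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse config {source}: {exc}") from exc
    else:
        raw = dict(source)

    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    if "start_date" in raw:
        value = raw.pop("start_date")
        kwargs["start_date"] = value if isinstance(value, dt.date) else dt.date.fromisoformat(str(value))
    if "cohort" in raw:
        kwargs["cohort"] = CohortSpec(**raw.pop("cohort"))
    if "behavior" in raw:
        b = dict(raw.pop("behavior"))
        default = BehaviorSpec()
        for program in ("walking", "exercise"):
            if program in b:
                b[program] = {
                    pheno: _session_behavior(v, getattr(default, program)[pheno])
                    for pheno, v in b[program].items()
                }
        kwargs["behavior"] = dataclasses.replace(default, **b)
    if "prescription" in raw:
        kwargs["prescription"] = _build_prescription(raw.pop("prescription"))
    if "walking_only_ids" in raw:
        kwargs["walking_only_ids"] = tuple(str(p) for p in raw.pop("walking_only_ids"))
    kwargs.update(raw)
    return StudyConfig(**kwargs)


def validate_config(config: StudyConfig | str | Path | dict[str, Any]) -> list[ConfigIssue]:
    """Structured pre-flight checks; an empty list means the config is runnable.

    Construction already rejects hard invariant violations (they surface as
    issues here rather than exceptions); this adds cross-field and
    plausibility checks.
    """
    issues: list[ConfigIssue] = []
    if not isinstance(config, StudyConfig):
        try:
            config = load_config(config)
        except Exception as exc:  # parse/constructor failures become issues
            return [ConfigIssue("config", str(exc))]

    if config.start_date.weekday() != 0:
        issues.append(ConfigIssue("start_date", "study calendar must start on a Monday"))
    if config.n_baseline_weeks < 0 or config.n_intervention_weeks < 1:
        issues.append(
            ConfigIssue("calendar", "need n_baseline_weeks >= 0 and n_intervention_weeks >= 1")
        )
    rx = config.prescription
    zone = rx.zone
    if not (0.0 < zone.lower_frac < zone.upper_frac <= 1.0):
        issues.append(
            ConfigIssue(
                "prescription.zone",
                f"HRR fractions must satisfy 0 < lower < upper <= 1, got "
                f"({zone.lower_frac}, {zone.upper_frac})",
            )
        )
    if rx.walk_target_min_per_day <= 0:
        issues.append(ConfigIssue("prescription.walk_target_min_per_day", "must be positive"))
    if not rx.walking_only and rx.exercise_target_min_per_day <= 0:
        issues.append(
            ConfigIssue("prescription.exercise_target_min_per_day", "must be positive")
        )
    if config.cohort.n_participants < 2:
        issues.append(ConfigIssue("cohort.n_participants", "need at least 2 participants"))
    valid_targets = set(config.cohort.outcome_distributions)
    if config.profile_target not in valid_targets:
        issues.append(
            ConfigIssue(
                "profile_target",
                f"{config.profile_target!r} not among generated outcomes {sorted(valid_targets)}",
            )
        )
    known_ids = {f"P{i + 1:02d}" for i in range(config.cohort.n_participants)}
    stray = set(config.walking_only_ids) - known_ids
    if stray:
        issues.append(
            ConfigIssue("walking_only_ids", f"ids not in the generated cohort: {sorted(stray)}")
        )
    return issues
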