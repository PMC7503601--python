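"""End-to-end orchestration: simulate → derive → adhere → profile → stats.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually; ``run_pipeline`` chains
them and records a manifest (config hash, package version, per-stage output
files). A stage failure leaves earlier outputs intact and marks the
manifest with the failed stage before the error propagates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import summaries_to_frame, summarize_weeks
from .config import StudyConfig
from .minutes import read_streams_csv, summarize_day, write_streams_csv
from .profiling import (
    kmeans_two,
    mean_split,
    selection_frequencies,
    shadow_feature_selection,
)
from .stats import PairedSample, mixed_anova, paired_compare, pearson_r, rm_anova
from .synthetic import (
    PROFILE_FEATURES,
    GroundTruth,
    generate_cohort,
    generate_streams,
    participant_zone,
)

__all__ = ["RunManifest", "PipelineError", "run_pipeline",
           "stage_simulate", "stage_derive", "stage_adhere",
           "stage_profile", "stage_stats"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records which."""


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    package_version: str
    output_dir: str
    stages: dict[str, list[str]] = field(default_factory=dict)   # stage -> output files
    timings_s: dict[str, float] = field(default_factory=dict)
    failed_at: str | None = None

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        self.stages[stage] = sorted(str(p.name) for p in outputs)
        self.timings_s[stage] = round(elapsed, 3)

    def all_outputs(self) -> set[str]:
        return {name for files in self.stages.values() for name in files}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: StudyConfig, outdir: Path) -> list[Path]:
    """Generate the cohort, its ground truth, pre/post measurements, and streams."""
    seed = config.stage_seed("simulate")
    cohort_spec = dataclasses.replace(config.cohort, seed=seed)
    profiles, truth = generate_cohort(cohort_spec)
    sim = generate_streams(
        profiles,
        truth,
        config.behavior,
        config.prescription,
        n_weeks=config.n_weeks,
        seed=seed + 1000,
        start_date=config.start_date,
        walking_only_ids=config.walking_only_ids,
    )

    cohort_path = outdir / "cohort.csv"
    profiles.to_csv(cohort_path, index=False)
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)

    # observable pre/post measurements (the latent change made measurable)
    meas = profiles[["participant_id", "sixmwt_distance_m"]].rename(
        columns={"sixmwt_distance_m": "sixmwt_pre_m"}
    )
    meas["sixmwt_post_m"] = (
        meas["sixmwt_pre_m"].to_numpy()
        + truth.outcomes["sixmwt_change_m"].reindex(meas["participant_id"]).to_numpy()
    )
    meas_path = outdir / "measurements.csv"
    meas.to_csv(meas_path, index=False)

    streams_path = outdir / "streams.csv"
    write_streams_csv(sim.streams, streams_path)

    true_rows = [
        {
            "participant_id": pid,
            "date": d.date.isoformat(),
            "walking_minutes": d.walking_minutes,
            "exercise_minutes": d.exercise_minutes,
        }
        for pid, days in sim.true_daily.items()
        for d in days
    ]
    true_path = outdir / "true_daily_minutes.csv"
    pd.DataFrame(true_rows).to_csv(true_path, index=False)
    return [cohort_path, truth_path, meas_path, streams_path, true_path]


def stage_derive(config: StudyConfig, outdir: Path) -> list[Path]:
    """Minute streams → daily walking/exercise tallies, per-participant zones."""
    streams = read_streams_csv(outdir / "streams.csv")
    profiles = pd.read_csv(outdir / "cohort.csv").set_index("participant_id")
    rows = []
    for stream in streams:
        row = profiles.loc[stream.participant_id]
        zone = participant_zone(row["age_yr"], row["hr_rest_bpm"], config.prescription)
        day = summarize_day(stream, zone)
        rows.append(
            {
                "participant_id": stream.participant_id,
                "date": day.date.isoformat(),
                "walking_minutes": day.walking_minutes,
                "exercise_minutes": day.exercise_minutes,
                "n_walking_bouts": sum(1 for b in day.bouts if b.kind == "walking"),
            }
        )
    path = outdir / "daily_minutes.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _daily_from_csv(path: Path):
    from .minutes import DailyMinutes

    frame = pd.read_csv(path, dtype={"participant_id": str})
    per_pid: dict[str, list] = {}
    for row in frame.itertuples(index=False):
        per_pid.setdefault(row.participant_id, []).append(
            DailyMinutes(
                date=dt.date.fromisoformat(row.date),
                walking_minutes=float(row.walking_minutes),
                exercise_minutes=float(row.exercise_minutes),
                participant_id=row.participant_id,
            )
        )
    return per_pid


def stage_adhere(config: StudyConfig, outdir: Path) -> list[Path]:
    """Daily tallies → weekly program/volume adherence per participant."""
    per_pid = _daily_from_csv(outdir / "daily_minutes.csv")
    labels = config.week_labels()
    frames = []
    for pid, days in sorted(per_pid.items()):
        rx = config.prescription
        if pid in config.walking_only_ids:
            rx = dataclasses.replace(rx, walking_only=True)
        summaries = summarize_weeks(days, rx, participant_id=pid)
        frames.append(summaries_to_frame(summaries, week_labels=labels))
    path = outdir / "adherence_summaries.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return [path]


def _measured_target(config: StudyConfig, outdir: Path) -> pd.Series:
    """Per-participant intervention-week mean of the profiling target metric."""
    adherence = pd.read_csv(outdir / "adherence_summaries.csv", dtype={"participant_id": str})
    metric = config.profile_target.replace("_", " ").replace("adherence", "adherence").strip()
    metric = {
        "walking program adherence": "walking program adherence",
        "exercise program adherence": "exercise program adherence",
        "exercise volume adherence": "exercise volume adherence",
        "walking volume adherence": "walking volume adherence",
    }[metric]
    intervention = adherence[adherence["week"].str.startswith("week")]
    sub = intervention[intervention["metric"] == metric]
    return sub.groupby("participant_id")["value_percent"].mean() / 100.0


def stage_profile(config: StudyConfig, outdir: Path) -> list[Path]:
    """Shadow-feature selection → k=2 clustering → mean split, on measured adherence."""
    profiles = pd.read_csv(outdir / "cohort.csv", dtype={"participant_id": str})
    target = _measured_target(config, outdir)
    table = profiles.copy()
    table["target"] = table["participant_id"].map(target)
    table = table.dropna(subset=["target"])
    features = [f for f in PROFILE_FEATURES if f in table.columns]

    seed = config.stage_seed("profile")
    outputs: list[Path] = []
    if len(table) < 20:
        # pilot scale: a single run is unstable, report frequencies across seeds
        freqs = selection_frequencies(
            table,
            "target",
            seeds=range(seed, seed + config.selection_seeds),
            features=features,
        )
        freq_path = outdir / "selection_frequencies.csv"
        freqs.to_csv(freq_path, index_label="feature")
        outputs.append(freq_path)
        selected = list(freqs.index[freqs["confirmed"] > 0.5])
        if not selected:
            selected = list(freqs["confirmed"].sort_values(ascending=False).index[:2])
    else:
        report = shadow_feature_selection(table, "target", features=features, seed=seed)
        rep_path = outdir / "selection_report.json"
        report.to_json(rep_path)
        outputs.append(rep_path)
        selected = report.confirmed or list(
            pd.Series(report.hits).sort_values(ascending=False).index[:2]
        )

    cluster = kmeans_two(table, selected, seed=seed)
    cl_path = outdir / "clusters.json"
    cluster.to_json(cl_path)
    outputs.append(cl_path)

    split = mean_split(dict(zip(table["participant_id"], table["target"])))
    ms_path = outdir / "mean_split.json"
    ms_path.write_text(
        json.dumps(
            {"mean": split.mean, "labels": split.labels, "degenerate": split.degenerate},
            indent=2,
            sort_keys=True,
        )
    )
    outputs.append(ms_path)
    return outputs


def _weekly_wide(outdir: Path, metric: str) -> pd.DataFrame:
    adherence = pd.read_csv(outdir / "adherence_summaries.csv", dtype={"participant_id": str})
    sub = adherence[adherence["metric"] == metric]
    return sub.pivot_table(
        index="participant_id", columns="week", values="value_percent", aggfunc="first"
    )


_METRIC_NAMES = (
    "walking program adherence",
    "walking volume adherence",
    "exercise program adherence",
    "exercise volume adherence",
)


def stage_stats(config: StudyConfig, outdir: Path) -> list[Path]:
    """Adherence-over-weeks ANOVA, pre/post comparisons, groupwise mixed ANOVA,
    and baseline-factor correlations."""
    outputs: list[Path] = []
    rows = []
    adherence = pd.read_csv(outdir / "adherence_summaries.csv", dtype={"participant_id": str})
    week_order = [lbl for lbl in config.week_labels().values()]
    for metric in _METRIC_NAMES:
        sub = adherence[adherence["metric"] == metric].copy()
        if sub.empty:
            continue
        sub["time"] = pd.Categorical(sub["week"], categories=week_order, ordered=True)
        long = sub.rename(columns={"participant_id": "id", "value_percent": "value"})[
            ["id", "time", "value"]
        ].sort_values(["id", "time"])
        long["time"] = long["time"].astype(str)
        try:
            res = rm_anova(long)
            rows.append({"analysis": f"{metric} across weeks", **_flat(res)})
        except ValueError as exc:
            rows.append({"analysis": f"{metric} across weeks", "error": str(exc)})

    meas = pd.read_csv(outdir / "measurements.csv", dtype={"participant_id": str})
    sample = PairedSample(
        ids=tuple(meas["participant_id"]),
        values_a=tuple(meas["sixmwt_pre_m"]),
        values_b=tuple(meas["sixmwt_post_m"]),
        label_a="pre",
        label_b="post",
    )
    rows.append({"analysis": "6-MWT pre vs post", **_flat(paired_compare(sample))})

    # time x group on the 6-MWT, groups from the baseline mean split and,
    # when available, from the adherence clustering
    groupings: dict[str, dict[str, int]] = {}
    split = mean_split(dict(zip(meas["participant_id"], meas["sixmwt_pre_m"])))
    if not split.degenerate:
        groupings["sixmwt_mean_split"] = split.labels
    clusters_path = outdir / "clusters.json"
    if clusters_path.exists():
        payload = json.loads(clusters_path.read_text())
        groupings["adherence_clusters"] = {
            str(k): int(v) for k, v in payload["assignments"].items()
        }
    for name, labels in groupings.items():
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "id": meas["participant_id"],
                        "time": when,
                        "group": meas["participant_id"].map(labels),
                        "value": meas[col],
                    }
                )
                for when, col in (("pre", "sixmwt_pre_m"), ("post", "sixmwt_post_m"))
            ],
            ignore_index=True,
        ).dropna(subset=["group"])
        try:
            result = mixed_anova(long)
            for part in ("interaction", "time", "group"):
                rows.append(
                    {"analysis": f"6-MWT time x {name} [{part}]", **_flat(getattr(result, part))}
                )
            for eff in result.simple_effects:
                rows.append({"analysis": f"6-MWT {name} follow-up {eff.label}", **_flat(eff)})
        except ValueError as exc:
            rows.append({"analysis": f"6-MWT time x {name}", "error": str(exc)})

    stats_path = outdir / "stats_tests.csv"
    pd.DataFrame(rows).to_csv(stats_path, index=False)
    outputs.append(stats_path)

    # baseline factors vs intervention adherence, Pearson
    profiles = pd.read_csv(outdir / "cohort.csv", dtype={"participant_id": str}).set_index(
        "participant_id"
    )
    corr_rows = []
    for metric in _METRIC_NAMES:
        wide = _weekly_wide(outdir, metric)
        week_cols = [c for c in wide.columns if str(c).startswith("week")]
        if not week_cols:
            continue
        outcome = wide[week_cols].mean(axis=1)
        for feature in PROFILE_FEATURES:
            if feature not in profiles.columns:
                continue
            joined = pd.concat([profiles[feature], outcome.rename("outcome")], axis=1).dropna()
            if len(joined) < 3 or joined[feature].nunique() < 2 or joined["outcome"].nunique() < 2:
                continue
            res = pearson_r(joined[feature], joined["outcome"])
            corr_rows.append(
                {
                    "feature": feature,
                    "outcome": metric,
                    "n": len(joined),
                    "r": res.statistic,
                    "p_value": res.p_value,
                }
            )
    corr_path = outdir / "correlations.csv"
    pd.DataFrame(corr_rows).to_csv(corr_path, index=False)
    outputs.append(corr_path)
    return outputs


def _flat(res) -> dict:
    d = res.to_dict()
    df = d.pop("df")
    if isinstance(df, tuple):
        d["df1"], d["df2"] = df
    else:
        d["df1"] = df
    ci = d.pop("ci95")
    if ci is not None:
        d["ci95_low"], d["ci95_high"] = ci
    return d


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "derive": stage_derive,
    "adhere": stage_adhere,
    "profile": stage_profile,
    "stats": stage_stats,
}


def run_pipeline(config: StudyConfig) -> RunManifest:
    """Run every enabled stage in order; idempotent for a fixed config."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=__version__,
        output_dir=str(outdir),
    )
    enabled = ["simulate", "derive", "adhere"]
    if config.run_profiling:
        enabled.append("profile")
    if config.run_stats:
        enabled.append("stats")
    manifest_path = outdir / "manifest.json"
    for stage in enabled:
        start = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            manifest.failed_at = stage
            manifest.write(manifest_path)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, time.perf_counter() - start)
    manifest.write(manifest_path)
    return manifest
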