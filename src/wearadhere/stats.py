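"""Normality-gated comparison toolkit for small repeated-measures designs.

Dispatch logic mirrors common practice in small exercise-intervention
cohorts: every analysis first checks Gaussianity with the D'Agostino-Pearson
K² omnibus test, then routes to the parametric test (paired t,
repeated-measures ANOVA with Greenhouse-Geisser correction under sphericity
violation, two-way mixed ANOVA) or its rank-based fallback (Wilcoxon
signed-rank, Friedman). Pearson correlations and interaction follow-ups
(simple main effects, Welch-corrected between-group t when variances are
unequal) round out the set. Significance is 0.05 two-tailed throughout.

Heavy lifting is delegated to scipy.stats and pingouin; this module owns the
gating, dispatch, and uniform result records.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "GAUSSIAN",
    "NON_GAUSSIAN",
    "NormalityResult",
    "PairedSample",
    "TestResult",
    "MixedAnovaResult",
    "normality_gate",
    "paired_compare",
    "rm_anova",
    "mixed_anova",
    "pearson_r",
]

ALPHA = 0.05
GAUSSIAN = "gaussian"
NON_GAUSSIAN = "non_gaussian"

#: validity floor of the D'Agostino-Pearson omnibus test
_NORMALITY_MIN_N = 8


@dataclass(frozen=True)
class NormalityResult:
    label: str                      # gaussian / non_gaussian
    p_value: float | None = None    # None when the test could not run
    flags: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # truthy iff gaussian
        return self.label == GAUSSIAN


def normality_gate(values: Sequence[float]) -> NormalityResult:
    """D'Agostino-Pearson K² omnibus gate at alpha = 0.05.

    Samples below the test's validity floor (n < 8) and zero-variance
    samples are routed to the non-Gaussian branch with an explanatory flag
    rather than an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _NORMALITY_MIN_N:
        return NormalityResult(NON_GAUSSIAN, None, (f"n={x.size} below validity floor 8",))
    if np.ptp(x) == 0:
        return NormalityResult(NON_GAUSSIAN, None, ("zero variance",))
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        stat, p = stats.normaltest(x)
    return NormalityResult(GAUSSIAN if p >= ALPHA else NON_GAUSSIAN, float(p))


@dataclass(frozen=True)
class PairedSample:
    """Matched pre/post (or A/B) measurements keyed by participant id."""

    ids: tuple[str, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    label_a: str = "pre"
    label_b: str = "post"

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.values_a) == len(self.values_b)):
            raise ValueError("ids, values_a and values_b must have equal lengths")
        if len(self.ids) < 3:
            raise ValueError("need at least 3 matched pairs")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.values_b, dtype=float) - np.asarray(
            self.values_a, dtype=float
        )


@dataclass(frozen=True)
class TestResult:
    """Uniform record of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    direction: int = 0                       # sign of the effect (b - a or group 1 - 2)
    correction_applied: bool = False
    mean_difference: float | None = None
    ci95: tuple[float, float] | None = None
    label: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "label": self.label,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
            "correction_applied": self.correction_applied,
            "mean_difference": self.mean_difference,
            "ci95": self.ci95,
        }


def paired_compare(sample: PairedSample) -> TestResult:
    """Paired t-test, or Wilcoxon signed-rank when the differences fail the gate.

    The t branch reports the mean difference (b - a) with its 95% CI.
    """
    d = sample.differences
    n = d.size
    if np.all(d == 0):
        return TestResult(
            test_name="paired_t",
            statistic=0.0,
            p_value=1.0,
            df=float(n - 1),
            mean_difference=0.0,
            ci95=(0.0, 0.0),
            flags=("all differences zero",),
        )
    gate = normality_gate(d)
    if gate:
        t, p = stats.ttest_rel(sample.values_b, sample.values_a)
        mean = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        crit = stats.t.ppf(0.975, n - 1)
        return TestResult(
            test_name="paired_t",
            statistic=float(t),
            p_value=float(p),
            df=float(n - 1),
            direction=int(np.sign(mean)),
            mean_difference=mean,
            ci95=(mean - crit * se, mean + crit * se),
        )
    stat, p = stats.wilcoxon(sample.values_b, sample.values_a)
    return TestResult(
        test_name="wilcoxon_signed_rank",
        statistic=float(stat),
        p_value=float(p),
        direction=int(np.sign(float(np.median(d)))),
        mean_difference=float(d.mean()),
        flags=gate.flags,
    )


def _complete_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot id x time, keeping complete cases only and the time order given."""
    for col in ("id", "time", "value"):
        if col not in long.columns:
            raise ValueError(f"long table must have column {col!r}")
    times = list(pd.unique(long["time"]))
    wide = long.pivot_table(index="id", columns="time", values="value", aggfunc="first")
    wide = wide.reindex(columns=times).dropna()
    return wide


def rm_anova(long: pd.DataFrame) -> TestResult:
    """One-way repeated-measures ANOVA with Friedman fallback.

    Cells (time levels) are gated with the D'Agostino-Pearson test; if any
    cell fails, the Friedman test is used. Otherwise sphericity is assessed
    (Mauchly) and the Greenhouse-Geisser corrected degrees of freedom and p
    are reported when it is violated (only possible with >= 3 levels).
    """
    wide = _complete_wide(long)
    if len(wide) < 2:
        raise ValueError("need at least 2 complete cases")
    times = list(wide.columns)
    k = len(times)
    if k < 2:
        raise ValueError("need at least 2 time levels")

    if np.allclose(wide.to_numpy().std(axis=0).sum(), 0) or np.allclose(
        np.ptp(wide.to_numpy(), axis=1), 0
    ):
        # no within-id change at all
        return TestResult(
            test_name="rm_anova",
            statistic=0.0,
            p_value=1.0,
            df=(float(k - 1), float((k - 1) * (len(wide) - 1))),
            flags=("no within-subject variation",),
        )

    gates = [normality_gate(wide[t]) for t in times]
    if not all(gates):
        stat, p = stats.friedmanchisquare(*(wide[t] for t in times))
        return TestResult(
            test_name="friedman",
            statistic=float(stat),
            p_value=float(p),
            df=float(k - 1),
            flags=tuple(f for g in gates for f in g.flags),
        )

    data = wide.reset_index().melt(id_vars="id", var_name="time", value_name="value")
    aov = pg.rm_anova(
        data=data, dv="value", within="time", subject="id", correction=True, detailed=True
    )
    row = aov.iloc[0]
    df1, df2 = float(row["DF"]), float(aov.iloc[1]["DF"])
    corrected = False
    p = float(row["p_unc"])
    if k >= 3 and "sphericity" in aov.columns and not bool(row["sphericity"]):
        # Mauchly violated: Greenhouse-Geisser corrected p and df
        eps = float(row["eps"])
        p = float(row["p_GG_corr"])
        df1, df2 = df1 * eps, df2 * eps
        corrected = True
    return TestResult(
        test_name="rm_anova",
        statistic=float(row["F"]),
        p_value=p,
        df=(df1, df2),
        correction_applied=corrected,
    )


@dataclass(frozen=True)
class MixedAnovaResult:
    """Two-way mixed ANOVA (time within, group between) with follow-ups."""

    interaction: TestResult
    time: TestResult
    group: TestResult
    simple_effects: tuple[TestResult, ...] = field(default_factory=tuple)


def _between_t(a: np.ndarray, b: np.ndarray, label: str) -> TestResult:
    """Independent-samples t; Welch correction on a Levene violation."""
    _, p_lev = stats.levene(a, b)
    welch = p_lev < ALPHA
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = float(a.size + b.size - 2)
    return TestResult(
        test_name="welch_t" if welch else "independent_t",
        statistic=float(t),
        p_value=float(p),
        df=float(df),
        direction=int(np.sign(a.mean() - b.mean())),
        correction_applied=welch,
        mean_difference=float(a.mean() - b.mean()),
        label=label,
    )


def mixed_anova(
    long: pd.DataFrame,
    followups: str = "auto",
) -> MixedAnovaResult:
    """2 (group, between) x T (time, within) mixed ANOVA.

    ``followups="auto"`` computes simple main effects (between-group t at
    each time, paired t within each group) when the interaction is
    significant; ``"always"`` and ``"never"`` override.
    """
    for col in ("id", "time", "group", "value"):
        if col not in long.columns:
            raise ValueError(f"long table must have column {col!r}")
    groups = list(pd.unique(long["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    per_group = long.groupby("group")["id"].nunique()
    if (per_group < 2).any():
        raise ValueError("each group needs at least 2 members")

    wide = long.pivot_table(index=["id", "group"], columns="time", values="value").dropna()
    complete = wide.reset_index()
    data = complete.melt(id_vars=["id", "group"], var_name="time", value_name="value")

    diffs = wide.to_numpy()[:, -1] - wide.to_numpy()[:, 0]
    if np.ptp(diffs) == 0:
        # no within-subject variation anywhere: the within-subject error is
        # zero and the F ratios for time and interaction are degenerate;
        # report null results and test the group effect on subject means
        g_labels = complete["group"].to_numpy()
        means = wide.to_numpy().mean(axis=1)
        f_grp, p_grp = stats.f_oneway(means[g_labels == groups[0]], means[g_labels == groups[1]])
        null = dict(statistic=0.0, p_value=1.0, df=(1.0, float(len(complete) - 2)),
                    flags=("no within-subject variation",))
        return MixedAnovaResult(
            interaction=TestResult(test_name="mixed_anova_interaction", label="interaction", **null),
            time=TestResult(test_name="mixed_anova_time", label="time", **null),
            group=TestResult(
                test_name="mixed_anova_group",
                statistic=float(f_grp),
                p_value=float(p_grp),
                df=(1.0, float(len(complete) - 2)),
                label="group",
            ),
        )

    aov = pg.mixed_anova(
        data=data, dv="value", within="time", between="group", subject="id"
    )
    aov = aov.set_index("Source")

    def _row(source: str, name: str) -> TestResult:
        r = aov.loc[source]
        return TestResult(
            test_name=f"mixed_anova_{name}",
            statistic=float(r["F"]),
            p_value=float(r["p_unc"]),
            df=(float(r["DF1"]), float(r["DF2"])),
            label=name,
        )

    interaction = _row("Interaction", "interaction")
    time_eff = _row("time", "time")
    group_eff = _row("group", "group")

    simple: list[TestResult] = []
    if followups == "always" or (followups == "auto" and interaction.significant):
        times = list(wide.columns)
        g1, g2 = groups
        for t in times:
            a = complete.loc[complete["group"] == g1, t].to_numpy(dtype=float)
            b = complete.loc[complete["group"] == g2, t].to_numpy(dtype=float)
            simple.append(_between_t(a, b, label=f"{g1}_vs_{g2}@{t}"))
        for g in groups:
            sub = complete[complete["group"] == g]
            if len(sub) >= 3:
                sample = PairedSample(
                    ids=tuple(sub["id"].astype(str)),
                    values_a=tuple(sub[times[0]]),
                    values_b=tuple(sub[times[-1]]),
                    label_a=str(times[0]),
                    label_b=str(times[-1]),
                )
                res = paired_compare(sample)
                simple.append(
                    TestResult(
                        test_name=res.test_name,
                        statistic=res.statistic,
                        p_value=res.p_value,
                        df=res.df,
                        direction=res.direction,
                        correction_applied=res.correction_applied,
                        mean_difference=res.mean_difference,
                        ci95=res.ci95,
                        label=f"time_within_{g}",
                        flags=res.flags,
                    )
                )
    return MixedAnovaResult(
        interaction=interaction,
        time=time_eff,
        group=group_eff,
        simple_effects=tuple(simple),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the two-tailed t-transform p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        test_name="pearson_r",
        statistic=float(r),
        p_value=float(p),
        df=float(x.size - 2),
        direction=int(np.sign(r)),
    )
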