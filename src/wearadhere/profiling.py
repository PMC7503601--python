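"""Baseline-factor profiling: shadow-feature selection, k=2 clustering, mean split.

The chain mirrors a data-driven adherence-profiling workflow:

1. **Shadow-feature selection** (an all-relevant, Boruta-style scheme):
   every iteration appends an independently permuted copy of each candidate
   feature to the design matrix, fits a random-forest regressor on the
   augmented matrix, and scores a *hit* for each undecided real feature
   whose importance exceeds the best shadow's. Accumulated hit counts are
   tested against a Binomial(iterations, 1/2) null, two-sided with a
   Bonferroni correction over the candidate features; features drift into
   ``confirmed`` / ``rejected`` and the loop stops when none remain
   ``tentative`` (or at ``max_iter``, after which tentative features are
   resolved by comparing their median importance with the median of the
   best-shadow history).
2. **k-means with k = 2** on the selected features, z-score standardized
   (the selected variables live on incommensurate scales — questionnaire
   points vs beats/min — so unstandardized distances would be dominated by
   the widest-ranged feature).
3. **Mean split** of an outcome into strictly-above-mean and
   at-or-below-mean groups, the simple benchmark grouping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "SelectionReport",
    "ClusterResult",
    "MeanSplit",
    "DegenerateTargetError",
    "DegenerateClusterError",
    "shadow_feature_selection",
    "selection_frequencies",
    "kmeans_two",
    "mean_split",
]

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


class DegenerateTargetError(ValueError):
    """Raised when the selection target is constant."""


class DegenerateClusterError(ValueError):
    """Raised when the input cannot support two non-empty clusters."""


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of a shadow-feature selection run."""

    status: dict[str, str]                 # feature -> confirmed/tentative/rejected
    hits: dict[str, int]                   # shadow-beating iterations per feature
    iterations: int
    importance_history: pd.DataFrame       # one row per iteration; includes shadow_max
    seed: int
    alpha: float
    target: str

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f, s in self.status.items() if s == TENTATIVE]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target": self.target,
            "seed": self.seed,
            "alpha": self.alpha,
            "iterations": self.iterations,
            "status": self.status,
            "hits": self.hits,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _importances(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if mode == "impurity":
        return forest.feature_importances_
    if mode == "permutation":
        result = permutation_importance(
            forest,
            X,
            y,
            n_repeats=3,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        return result.importances_mean
    raise ValueError(f"unknown importance mode {mode!r}")


def shadow_feature_selection(
    table: pd.DataFrame,
    target: str,
    features: Sequence[str] | None = None,
    seed: int = 0,
    max_iter: int = 50,
    alpha: float = 0.01,
    n_trees: int = 100,
    importance: str = "impurity",
    rough_fix: bool = False,
) -> SelectionReport:
    """All-relevant feature selection against permuted shadow copies.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per participant; numeric feature columns plus the target.
    target : str
        Name of the outcome column to regress on.
    features : sequence of str, optional
        Candidate columns; defaults to every numeric column except the target.
    alpha : float
        Two-sided level of the binomial hit-count test, Bonferroni-corrected
        over the number of candidate features.
    importance : {"impurity", "permutation"}
        Random-forest importance flavor. Impurity (mean decrease in
        impurity) is the default: with shadow features in the design matrix
        its optimistic bias cancels out of the real-vs-shadow comparison,
        and it costs nothing beyond the fit. Permutation importance follows
        the classical shadow-feature formulation at several times the cost.
    rough_fix : bool
        Resolve features still tentative at ``max_iter`` by comparing their
        median importance with the median of the best-shadow trace. Off by
        default: the post-hoc fix trades the binomial gate's false-positive
        control for a forced decision, so undecided features stay
        ``tentative`` unless the caller opts in.
    """
    if target not in table.columns:
        raise KeyError(f"target column {target!r} not in table")
    if features is None:
        features = [
            c
            for c in table.columns
            if c != target and pd.api.types.is_numeric_dtype(table[c])
        ]
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    work = table[[*features, target]].dropna()
    if len(work) < 5:
        raise ValueError("need at least 5 complete rows")
    y = work[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateTargetError(f"target {target!r} is constant")

    rng = np.random.default_rng(seed)
    status = {f: TENTATIVE for f in features}
    hits = {f: 0 for f in features}
    n_feat = len(features)
    alpha_corr = alpha / n_feat  # Bonferroni over candidates
    history: list[dict[str, float]] = []

    X_real = work[features].to_numpy(dtype=float)
    iteration = 0
    for iteration in range(1, max_iter + 1):
        active = [f for f in features if status[f] != REJECTED]
        idx = [features.index(f) for f in active]
        X_act = X_real[:, idx]
        # keep at least 5 shadows so the max-shadow bar stays honest once
        # most candidates are rejected (repeat active columns as needed)
        shadow_src = list(range(X_act.shape[1]))
        while len(shadow_src) < 5:
            shadow_src.extend(range(X_act.shape[1]))
        shadows = np.column_stack(
            [rng.permutation(X_act[:, j]) for j in shadow_src]
        )
        X_aug = np.hstack([X_act, shadows])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X_aug, y)
        imp = _importances(forest, X_aug, y, importance, rng)
        real_imp = dict(zip(active, imp[: len(active)]))
        shadow_max = float(imp[len(active):].max())
        history.append({**real_imp, "shadow_max": shadow_max})

        for f in active:
            if status[f] == TENTATIVE and real_imp[f] > shadow_max:
                hits[f] += 1

        for f in features:
            if status[f] != TENTATIVE:
                continue
            k = hits[f]
            if stats.binom.sf(k - 1, iteration, 0.5) < alpha_corr:
                status[f] = CONFIRMED
            elif stats.binom.cdf(k, iteration, 0.5) < alpha_corr:
                status[f] = REJECTED
        if not any(s == TENTATIVE for s in status.values()):
            break

    hist = pd.DataFrame(history)

    # optional rough fix for features still undecided at max_iter: median
    # importance across iterations vs the median of the best-shadow trace
    if rough_fix and any(s == TENTATIVE for s in status.values()) and not hist.empty:
        median_shadow = float(hist["shadow_max"].median())
        for f in features:
            if status[f] == TENTATIVE:
                med = float(hist[f].median()) if f in hist else -np.inf
                status[f] = CONFIRMED if med > median_shadow else REJECTED

    return SelectionReport(
        status=status,
        hits=hits,
        iterations=iteration,
        importance_history=hist,
        seed=seed,
        alpha=alpha,
        target=target,
    )


def selection_frequencies(
    table: pd.DataFrame,
    target: str,
    seeds: Iterable[int],
    **kwargs,
) -> pd.DataFrame:
    """Per-feature status frequencies across seeds.

    At pilot scale (tens of rows) a single selection run is unstable; this
    reports, per feature, the fraction of seeds on which it was confirmed /
    tentative / rejected so instability is visible rather than hidden.
    """
    counts: dict[str, dict[str, int]] = {}
    total = 0
    for s in seeds:
        report = shadow_feature_selection(table, target, seed=int(s), **kwargs)
        total += 1
        for f, st in report.status.items():
            counts.setdefault(f, {CONFIRMED: 0, TENTATIVE: 0, REJECTED: 0})[st] += 1
    rows = {
        f: {k: v / total for k, v in c.items()} for f, c in counts.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[
        [CONFIRMED, TENTATIVE, REJECTED]
    ]


@dataclass(frozen=True)
class ClusterResult:
    """k=2 clustering outcome in standardized feature space."""

    assignments: dict[str, int]        # participant -> 1 or 2
    centroids: np.ndarray              # (2, n_features), standardized units
    iterations_to_convergence: int
    inertia: float
    seed: int
    features: tuple[str, ...]
    standardized: bool = True

    def group(self, label: int) -> list[str]:
        return [pid for pid, g in self.assignments.items() if g == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": list(self.features),
            "seed": self.seed,
            "inertia": self.inertia,
            "iterations_to_convergence": self.iterations_to_convergence,
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments,
            "standardized": self.standardized,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def kmeans_two(
    table: pd.DataFrame,
    features: Sequence[str],
    seed: int = 0,
    standardize: bool = True,
    n_init: int = 10,
    id_column: str = "participant_id",
) -> ClusterResult:
    """Lloyd's k-means with k=2 on (by default z-scored) selected features.

    Runs ``n_init`` k-means++ restarts and keeps the lowest-inertia
    solution; deterministic for a fixed seed. Clusters are relabelled so
    cluster 1 has the lexicographically smaller centroid, making labels
    invariant to row order.
    """
    features = list(features)
    if not features:
        raise ValueError("features must be non-empty")
    if len(table) < 3:
        raise ValueError("need at least 3 rows to cluster")
    ids = (
        table[id_column].astype(str).tolist()
        if id_column in table.columns
        else [str(i) for i in table.index]
    )
    X = table[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("clustering input contains missing values")
    if np.unique(X, axis=0).shape[0] < 2:
        raise DegenerateClusterError("fewer than 2 distinct points")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            constant = [f for f, s in zip(features, sd) if s == 0]
            raise DegenerateClusterError(f"constant features cannot be z-scored: {constant}")
        X = (X - X.mean(axis=0)) / sd

    km = KMeans(n_clusters=2, n_init=n_init, tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    if len(set(labels)) < 2:
        raise DegenerateClusterError("k-means produced an empty cluster")

    order = np.lexsort(km.cluster_centers_.T[::-1])  # sort centroids lexicographically
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    assignments = {pid: relabel[int(g)] for pid, g in zip(ids, labels)}
    centroids = km.cluster_centers_[order]
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        iterations_to_convergence=int(km.n_iter_),
        inertia=float(km.inertia_),
        seed=seed,
        features=tuple(features),
        standardized=standardize,
    )


@dataclass(frozen=True)
class MeanSplit:
    """Mean-split grouping: 1 = strictly above the mean, 2 = at or below."""

    mean: float
    labels: dict[str, int]
    degenerate: bool = field(default=False)  # all values equal -> one empty group

    def group(self, label: int) -> list[str]:
        return [pid for pid, g in self.labels.items() if g == label]


def mean_split(values: pd.Series | dict[str, float]) -> MeanSplit:
    """Split participants at the arithmetic mean of an outcome."""
    series = pd.Series(values).astype(float).dropna()
    if len(series) < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(series.mean())
    labels = {str(k): (1 if v > mean else 2) for k, v in series.items()}
    groups = set(labels.values())
    return MeanSplit(mean=mean, labels=labels, degenerate=len(groups) < 2)
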