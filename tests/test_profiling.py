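"""Shadow-feature selection, k=2 clustering, mean split."""

import numpy as np
import pandas as pd
import pytest

from wearadhere.profiling import (
    DegenerateClusterError,
    DegenerateTargetError,
    kmeans_two,
    mean_split,
    selection_frequencies,
    shadow_feature_selection,
)
from wearadhere.synthetic import (
    ADHERENT,
    CohortSpec,
    PROFILE_FEATURES,
    generate_cohort,
)


def noise_table(rng, n, n_noise, signal=None):
    """n rows: optional planted-signal feature + pure-noise features + target."""
    cols = {f"noise{i}": rng.normal(size=n) for i in range(n_noise)}
    target = rng.normal(size=n)
    if signal is not None:
        cols["signal"] = target + rng.normal(0, signal, size=n)
    cols["y"] = target
    return pd.DataFrame(cols)


class TestShadowFeatureSelection:
    def test_planted_signal_confirmed_noise_rejected(self):
        """One feature tracking the target among nine noise features: the
        signal is confirmed and most noise rejected, across seeds."""
        hits = rejections = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            table = noise_table(rng, n=60, n_noise=9, signal=0.3)
            report = shadow_feature_selection(table, "y", seed=seed)
            hits += report.status["signal"] == "confirmed"
            rejections += sum(
                report.status[f"noise{i}"] == "rejected" for i in range(9)
            ) >= 7
        assert hits >= 0.9 * n_seeds
        assert rejections >= 0.9 * n_seeds

    def test_pure_noise_mostly_rejected(self):
        """Null behavior on all-noise designs.

        The Bonferroni-corrected binomial gate rejects nearly every noise
        feature. An irreducible exception is the luckiest feature: the top
        order statistic of the chance feature-target correlations is
        scale-free in n and can persistently beat the best shadow, so a
        single spurious confirmation occurs in a minority of datasets. The
        test pins that measured behavior: most runs confirm nothing, at
        most one feature is ever confirmed, and most features are rejected.
        """
        n_seeds = 16
        zero_confirmed = 0
        total_confirmed = 0
        total_rejected = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(7000 + seed)
            table = noise_table(rng, n=60, n_noise=8)
            report = shadow_feature_selection(table, "y", seed=seed, alpha=0.01)
            zero_confirmed += len(report.confirmed) == 0
            total_confirmed += len(report.confirmed)
            total_rejected += len(report.rejected)
            assert len(report.confirmed) <= 2
        assert zero_confirmed >= 0.6 * n_seeds
        assert total_confirmed <= 0.1 * 8 * n_seeds        # ~5% of feature slots
        assert total_rejected >= 0.7 * 8 * n_seeds

    def test_duplicated_informative_feature_both_kept(self):
        """All-relevant property: a duplicate of the signal is not rejected."""
        rng = np.random.default_rng(3)
        table = noise_table(rng, n=60, n_noise=6, signal=0.3)
        table["signal_copy"] = table["signal"] + rng.normal(0, 0.01, len(table))
        report = shadow_feature_selection(table, "y", seed=3)
        assert report.status["signal"] != "rejected"
        assert report.status["signal_copy"] != "rejected"

    def test_affine_rescaling_leaves_selection_invariant(self):
        rng = np.random.default_rng(4)
        table = noise_table(rng, n=50, n_noise=5, signal=0.4)
        base = shadow_feature_selection(table, "y", seed=7)
        scaled = table.copy()
        scaled["signal"] = scaled["signal"] * 1000.0 - 5.0
        scaled["noise0"] = scaled["noise0"] * 1e-4 + 2.0
        rerun = shadow_feature_selection(scaled, "y", seed=7)
        assert base.status == rerun.status

    def test_constant_target_rejected(self):
        rng = np.random.default_rng(5)
        table = noise_table(rng, n=30, n_noise=4)
        table["y"] = 1.0
        with pytest.raises(DegenerateTargetError):
            shadow_feature_selection(table, "y")

    def test_report_bookkeeping(self):
        rng = np.random.default_rng(6)
        table = noise_table(rng, n=40, n_noise=4, signal=0.3)
        report = shadow_feature_selection(table, "y", seed=1, max_iter=25)
        assert report.iterations <= 25
        assert set(report.status) == {"signal"} | {f"noise{i}" for i in range(4)}
        assert "shadow_max" in report.importance_history.columns
        assert len(report.importance_history) == report.iterations
        assert all(0 <= h <= report.iterations for h in report.hits.values())

    def test_frequencies_across_seeds_sum_to_one(self):
        rng = np.random.default_rng(7)
        table = noise_table(rng, n=20, n_noise=4, signal=0.3)
        freqs = selection_frequencies(table, "y", seeds=range(3), max_iter=20)
        assert np.allclose(freqs.sum(axis=1), 1.0)
        assert freqs.loc["signal", "confirmed"] >= freqs.loc["noise0", "confirmed"]


class TestKmeansTwo:
    def test_separable_point_masses_split_by_second_iteration(self):
        rng = np.random.default_rng(0)
        a = rng.normal([-1, -1], 0.01, size=(8, 2))
        b = rng.normal([1, 1], 0.01, size=(8, 2))
        table = pd.DataFrame(np.vstack([a, b]), columns=["x1", "x2"])
        table["participant_id"] = [f"P{i:02d}" for i in range(16)]
        result = kmeans_two(table, ["x1", "x2"], seed=0)
        groups = [result.assignments[f"P{i:02d}"] for i in range(16)]
        assert groups[:8] == [groups[0]] * 8
        assert groups[8:] == [groups[8]] * 8
        assert groups[0] != groups[8]
        assert result.iterations_to_convergence <= 2

    def test_identical_rows_degenerate(self):
        table = pd.DataFrame({"x": [1.0] * 5, "participant_id": list("abcde")})
        with pytest.raises(DegenerateClusterError):
            kmeans_two(table, ["x"], seed=0)

    def test_row_permutation_only_relabels(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "x": np.concatenate([rng.normal(-2, 0.5, 6), rng.normal(2, 0.5, 6)]),
                "participant_id": [f"P{i:02d}" for i in range(12)],
            }
        )
        base = kmeans_two(table, ["x"], seed=3)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        perm = kmeans_two(shuffled, ["x"], seed=3)
        assert base.assignments == perm.assignments

    def test_final_assignment_is_fixed_point(self):
        """Each point sits with its nearest centroid and each centroid is the
        mean of its members (Lloyd fixed point, standardized space)."""
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "u": np.concatenate([rng.normal(0, 1, 10), rng.normal(4, 1, 10)]),
                "v": rng.normal(size=20),
                "participant_id": [f"P{i:02d}" for i in range(20)],
            }
        )
        res = kmeans_two(table, ["u", "v"], seed=5)
        X = table[["u", "v"]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        labels = np.array([res.assignments[p] for p in table["participant_id"]]) - 1
        for k in (0, 1):
            np.testing.assert_allclose(
                res.centroids[k], Z[labels == k].mean(axis=0), atol=1e-8
            )
        d = ((Z[:, None, :] - res.centroids[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(d.argmin(axis=1), labels)

    def test_constant_feature_cannot_be_standardized(self):
        table = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 3.0], "c": [5.0] * 4, "participant_id": list("abcd")}
        )
        with pytest.raises(DegenerateClusterError):
            kmeans_two(table, ["x", "c"], seed=0)


class TestMeanSplit:
    def test_six_walk_distances_split_three_three(self):
        values = {f"P{i}": v for i, v in enumerate([400, 450, 500, 560, 570, 580])}
        split = mean_split(values)
        assert split.mean == pytest.approx(510.0)
        assert len(split.group(1)) == 3 and len(split.group(2)) == 3
        assert set(split.group(1)) == {"P3", "P4", "P5"}

    def test_two_values(self):
        split = mean_split({"a": 0.0, "b": 1.0})
        assert split.mean == pytest.approx(0.5)
        assert split.labels == {"b": 1, "a": 2}

    def test_all_equal_flagged_degenerate(self):
        split = mean_split({"a": 2.0, "b": 2.0, "c": 2.0})
        assert split.degenerate
        assert split.group(1) == []

    def test_boundary_value_goes_below(self):
        split = mean_split({"a": 0.0, "b": 1.0, "c": 2.0})
        assert split.labels["b"] == 2  # exactly at the mean

    def test_four_six_structure_on_cohort_like_distances(self):
        """A 10-person cohort built with 4 high / 6 low six-minute-walk
        distances around the published 508 +/- 60 m summary mean-splits 4/6."""
        values = dict(zip(
            [f"P{i:02d}" for i in range(10)],
            [560, 575, 590, 555, 470, 480, 460, 475, 455, 465],
        ))
        split = mean_split(values)
        assert len(split.group(1)) == 4 and len(split.group(2)) == 6
        assert 440 < np.mean(list(values.values())) < 580

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mean_split({"a": 1.0})


class TestEndToEndRecovery:
    def test_chain_recovers_well_separated_phenotypes(self):
        """With the phenotype signal well separated (3 pooled SD on resting
        HR and perceived risk, the only informative features), the selection
        confirms both carriers and k=2 clustering recovers the labels with
        >= 90% mean accuracy."""
        es, sd = 3.0, 13.0
        both, accs = 0, []
        seeds = range(8)
        for seed in seeds:
            spec = CohortSpec(
                n_participants=40,
                seed=seed,
                phenotype_mix=0.5,
                hr_rest_adherent=(72.5 - es * sd / 2, sd),
                hr_rest_nonadherent=(72.5 + es * sd / 2, sd),
                effect_sizes={"apq_risk_overactivity": es},
            )
            profiles, truth = generate_cohort(spec)
            table = profiles.copy()
            table["target"] = truth.outcomes["exercise_program_adherence"].to_numpy()
            report = shadow_feature_selection(
                table, "target", features=PROFILE_FEATURES, seed=seed
            )
            both += {"hr_rest_bpm", "apq_risk_overactivity"} <= set(report.confirmed)
            feats = report.confirmed or ["hr_rest_bpm", "apq_risk_overactivity"]
            cluster = kmeans_two(table, feats, seed=seed)
            lab = np.array(
                [1 if truth.labels[p] == ADHERENT else 2 for p in table.participant_id]
            )
            got = np.array([cluster.assignments[p] for p in table.participant_id])
            accs.append(max((got == lab).mean(), (got != lab).mean()))
        assert both >= 7
        assert np.mean(accs) >= 0.90
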