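"""Baseline-factor profiling: shadow-feature selection -> k=2 clustering.

Builds a well-separated synthetic cohort (the adherent phenotype sits 3
pooled SD lower on resting HR and perceived risk of over-activity), asks
the shadow-feature selector which baseline factors predict exercise
adherence, clusters on the selected factors, and compares the clusters with
the latent phenotype labels.
"""

import numpy as np

from wearadhere import (
    ADHERENT,
    CohortSpec,
    generate_cohort,
    kmeans_two,
    mean_split,
    shadow_feature_selection,
)
from wearadhere.synthetic import PROFILE_FEATURES

es, sd = 3.0, 13.0
spec = CohortSpec(
    n_participants=40,
    seed=1,
    phenotype_mix=0.5,
    hr_rest_adherent=(72.5 - es * sd / 2, sd),
    hr_rest_nonadherent=(72.5 + es * sd / 2, sd),
    effect_sizes={"apq_risk_overactivity": es},
)
profiles, truth = generate_cohort(spec)
table = profiles.copy()
table["target"] = truth.outcomes["exercise_program_adherence"].to_numpy()

report = shadow_feature_selection(table, "target", features=PROFILE_FEATURES, seed=1)
print(f"Confirmed features ({report.iterations} iterations): {report.confirmed}")
print(f"Rejected: {len(report.rejected)} of {len(report.status)}")

cluster = kmeans_two(table, report.confirmed, seed=1)
labels = np.array([1 if truth.labels[p] == ADHERENT else 2 for p in table.participant_id])
got = np.array([cluster.assignments[p] for p in table.participant_id])
accuracy = max((got == labels).mean(), (got != labels).mean())
print(f"k=2 clusters of sizes {len(cluster.group(1))}/{len(cluster.group(2))}, "
      f"converged in {cluster.iterations_to_convergence} iterations")
print(f"Agreement with latent phenotype: {100 * accuracy:.0f}%")

split = mean_split(dict(zip(table.participant_id, table.target)))
print(f"Mean split of the outcome at {split.mean:.2f}: "
      f"{len(split.group(1))} above / {len(split.group(2))} at-or-below")
print()
print("Only the two features that truly carry the phenotype emerge from the")
print("selection; clustering on them recovers the latent groups almost")
print("perfectly at this separation.")
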