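"""The normality-gated statistics toolkit on synthetic pre/post measurements.

Simulates a 10-person cohort whose six-minute-walk distance declines only
in the non-adherent phenotype, then runs the paired comparison, the
mean-split time x group mixed ANOVA, and a baseline correlation.
"""

import warnings

import numpy as np
import pandas as pd

from wearadhere import (
    CohortSpec,
    PairedSample,
    generate_cohort,
    mean_split,
    mixed_anova,
    paired_compare,
    pearson_r,
)

warnings.filterwarnings("ignore")
profiles, truth = generate_cohort(CohortSpec(n_participants=10, seed=3))
pre = profiles["sixmwt_distance_m"].to_numpy()
post = pre + truth.outcomes["sixmwt_change_m"].to_numpy()
ids = list(profiles.participant_id)

res = paired_compare(PairedSample(tuple(ids), tuple(pre), tuple(post)))
print(f"6-MWT pre vs post: {res.test_name}, statistic={res.statistic:.2f}, "
      f"df={res.df}, p={res.p_value:.3f}")
if res.ci95:
    print(f"  mean change {res.mean_difference:.1f} m "
          f"(95% CI {res.ci95[0]:.1f}, {res.ci95[1]:.1f})")

split = mean_split(dict(zip(ids, pre)))
print(f"Baseline mean split at {split.mean:.0f} m: "
      f"{len(split.group(1))} faster / {len(split.group(2))} slower")

# group by the latent phenotype; a real analysis would approximate these
# groups with the adherence clusters from the profiling chain
groups = [truth.labels[i] for i in ids]
long = pd.concat(
    [
        pd.DataFrame({"id": ids, "time": "pre", "value": pre, "group": groups}),
        pd.DataFrame({"id": ids, "time": "post", "value": post, "group": groups}),
    ]
)
anova = mixed_anova(long)
print(f"Time x group (adherence phenotype): "
      f"F{anova.interaction.df}={anova.interaction.statistic:.2f}, "
      f"p={anova.interaction.p_value:.3f}")
for eff in anova.simple_effects:
    print(f"  follow-up {eff.label}: {eff.test_name} p={eff.p_value:.3f}")

corr = pearson_r(profiles["age_yr"],
                 truth.outcomes["walking_program_adherence"].to_numpy())
print(f"Age vs walking adherence: r={corr.statistic:.2f}, p={corr.p_value:.3f}")
print()
print("The group-level pre/post change is flat, but the time x group")
print("interaction exposes the walk-test decline confined to the")
print("non-adherent phenotype — the subgroup pattern this machinery tests.")
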