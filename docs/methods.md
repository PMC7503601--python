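# Methods

This note records the models, counting rules, parameter choices and known
limitations behind `wearadhere`, in the order data flows through the
package.

## Physiology

Maximal heart rate uses the sedentary-adult regression HRmax = 211 −
0.8·age (beats/min; age in years, accepted over 18–110 with a warning
outside the 60–90 band the defaults target). The exercise zone is the
Karvonen form HR = HRrest + f·(HRmax − HRrest); the default band f ∈
[0.50, 0.80] encodes a moderate-intensity prescription. Cardiorespiratory
fitness is the linear six-minute-walk-test regression (see README for the
coefficients). Two deliberate choices:

- The regression's VO₂ and HR terms are interpreted as the *seated-rest*
  measurements taken alongside the walk test. Protocols differ on whether
  the HR term is resting or end-of-walk HR; the inputs are plain fields,
  so the other convention is a matter of what the caller passes.
- Outputs are never clamped. A non-positive VO₂max estimate sets an
  `implausible` flag but the linear model's value is reported as-is, so
  downstream users see the model's behavior rather than a silent repair.
- Relative fitness divides by current-visit body mass.

## Minute derivation

The wrist monitor is trusted for its per-minute walking seconds (0–60) and
minute-mean optical HR; no accelerometer processing happens here.

- **Walking bouts.** A bout is a maximal run of consecutive calendar
  minutes with any walking. The exclusion rule "shorter than 2 min ± 10 s"
  is implemented as a single 110 s threshold on a bout's summed walking
  seconds — the permissive reading of the tolerance band — configurable via
  `min_bout_seconds`. An intra-bout gap tolerance exists
  (`max_gap_minutes`) but defaults to 0: one idle minute ends a bout, the
  strictest reading. Gaps in the *recording* (unworn time) always end a
  bout.
- **Exercise minutes.** A minute counts iff its mean HR lies in the closed
  target zone; there is deliberately no minimum-bout filter (isolated
  in-zone minutes count), and minutes with missing HR never count. Closed
  bounds are the inclusive convention for a band quoted without boundary
  semantics.
- Wear-time gaps contribute nothing; no imputation anywhere.
- Walking and exercise tallies are independent by construction: HR never
  affects walking minutes and walking seconds never affect exercise
  minutes. Minutes inside a counted walking bout may also count as
  exercise if the HR is in zone; the two programs are scored separately.

## Adherence

Weeks are Monday-anchored; partial boundary weeks are scored but flagged
incomplete. Program adherence = qualifying days ÷ prescribed frequency,
where a qualifying day reaches the daily minute target whether or not it
was a planned day; volume adherence = weekly minutes ÷ (daily target ×
days/week). Both are uncapped fractions internally and percentages at the
interfaces. Per-day display states mirror the participant-facing progress
screen: check mark on a planned qualifying day, opaque check on an
unplanned one, and no extra reward past the daily target. A walking-only
prescription (used for participants contraindicated for the
higher-intensity program) simply reports the exercise metrics as missing.

## Synthetic cohorts and streams

The generator emulates a small older-adult cohort with two latent
adherence phenotypes so that every downstream stage can be tested against
known labels.

- **Baseline features** are drawn around published-style cohort summaries:
  age 73.8 ± 2.3 y, height 170 ± 11 cm, mass 81.6 ± 13.8 kg, 6-MWT
  508 ± 60 m, PCS-12 53.5 ± 3.2, MCS-12 58.4 ± 2.1, FSS 2.50 ± 0.77
  (1–7), ESE 62.7 ± 23.6 (0–100), pacing engagement 2.68 ± 0.92 and
  perceived risk of over-activity 2.45 ± 0.98 (1–5). Bounded scores are
  clipped to their instrument ranges; self-reported walking minutes
  (153 ± 180) use a lognormal matched to that mean/SD because the quantity
  is strongly right-skewed and non-negative.
- **Phenotype structure.** The adherent fraction defaults to 0.4 (the
  4-vs-6 split of the emulated cohort). Resting HR is specified per
  phenotype (65 ± 5 vs 78 ± 15 bpm — the subgroups differ in spread, not
  just location); other effects are pooled-SD shifts applied symmetrically
  around the feature mean, default 1 SD on perceived risk, with the
  adherent phenotype lower. Fitness estimates are *computed* from the
  drawn inputs via the 6-MWT regression, so they inherit a real
  correlation with resting HR — an all-relevant selector may legitimately
  flag them.
- **Latent outcomes** (per-phenotype normal draws): walking program
  adherence 0.85 ± 0.30 vs 0.30 ± 0.22, exercise program adherence
  1.75 ± 0.55 vs 0.55 ± 0.35 (clipped at 0), and a 6-MWT change of
  +5 ± 15 m vs −25 ± 15 m, encoding a fitness decline concentrated in the
  non-adherent phenotype. The change is emitted as an observable post
  measurement so pre/post analyses have real inputs.
- **Behavior model.** Per phenotype and program: a planned-day attempt
  probability, an unplanned-day probability, a truncated-normal session
  duration, and (exercise) a per-minute HR-zone fidelity. Defaults
  (adherent walking 0.90/0.50 × 35 ± 8 min; non-adherent 0.55/0.15 ×
  27 ± 9; adherent exercise 0.95/0.30 × 28 ± 6 at fidelity 0.9;
  non-adherent 0.50/0.10 × 18 ± 6 at 0.8) were chosen once so the scored
  cohort lands in the reported range of such interventions (walking
  program ~30–50%, exercise volume well above 100%). A cohort-shared
  bad-weather Bernoulli (p = 0.10 per day, winter setting) suppresses all
  sessions. Minute-mean HR is Gaussian noise (SD 4 bpm) around a
  session/rest setpoint; non-exercise minutes are kept strictly below the
  zone's lower bound so the exercise tally is interpretable.
- **Incidental exercise minutes.** Because the exercise tally has no
  minimum bout, real cohorts log large exercise volumes from brief HR
  excursions. A per-minute incidental-spike probability (0.030 adherent /
  0.015 non-adherent) reproduces that inflation; `BehaviorSpec.ideal()`
  zeroes it, along with every stochastic imperfection, for closed-loop
  testing.
- **What it does not emulate:** HR kinetics (no on/off transients),
  seasonality beyond the day-level weather coin, device artifacts other
  than random optical dropouts at rest (p = 0.02, non-session minutes
  only), within-week behavioral drift, and any link between baseline
  walk-test distance and phenotype. Passing tests therefore demonstrate
  correctness of the *pipeline*, not realism of any individual trajectory.

Ground truth (labels, latent outcomes, per-day true tallies) is emitted
alongside the streams; a test verifies the derived tallies equal the true
ones minute-for-minute even under imperfect behavior.

## Profiling

- **Shadow-feature selection.** Each iteration appends one permuted copy
  of every active feature (never fewer than five shadows — once most
  candidates are rejected the best-shadow bar would otherwise collapse and
  let stragglers drift upward), fits a random-forest regressor (100 trees,
  `max_features="sqrt"`), and scores a hit for each undecided feature
  whose importance exceeds the best shadow's. Hit counts are tested
  against Binomial(i, ½), two-sided at α = 0.01 with Bonferroni correction
  over candidates; the loop stops when nothing is tentative or at
  `max_iter = 50`. Impurity importance is the default — with shadows in
  the design matrix its optimistic bias cancels out of the comparison and
  it is an order of magnitude cheaper than permutation importance, which
  remains available (`importance="permutation"`). The median-vs-median
  tentative "rough fix" is opt-in (`rough_fix=True`) because forcing a
  decision sacrifices the binomial gate's false-positive control.
- **Null behavior, honestly stated.** On pure-noise designs most features
  are rejected quickly, but the luckiest feature — the top order statistic
  of the chance feature–target correlations, an effect that does not
  vanish with n — earns a spurious confirmation in roughly a fifth of
  datasets. This is inherent to comparing a fixed sample correlation
  against freshly permuted shadows; the test suite pins the measured rate
  rather than pretending it is zero.
- **Pilot-scale instability.** Below 20 rows a single run is unstable, so
  the pipeline reports per-feature confirmation frequencies across a seed
  sweep (default 10 seeds) instead of one verdict, and clusters on the
  features confirmed in a majority of sweeps.
- **Clustering.** k-means, k = 2 fixed, 10 k-means++ restarts keeping the
  lowest inertia, tolerance 1e-6, on z-scored selected features —
  questionnaire points and beats/min are incommensurate, and unstandardized
  distances would be dominated by the widest-ranged variable
  (`standardize=False` is available). Clusters are relabelled by centroid
  order so assignments are invariant to row order.
- **Mean split.** Group 1 strictly above the arithmetic mean, group 2 at
  or below; an all-equal input is returned flagged rather than raised.

A note on attainable recovery: with a d-SD pooled shift on each of two
features, the Bayes-optimal accuracy for recovering the phenotype from
those features is Φ(d·√2/2) — about 0.76 at d = 1 and 0.92 at d = 2. The
recovery test therefore exercises the chain at a 3-SD separation, where
near-perfect recovery is information-theoretically possible; at 1 SD no
clustering method can reach 90%.

## Statistics

- Normality gating uses the D'Agostino–Pearson K² omnibus test at
  α = 0.05; samples under its validity floor (n < 8) and zero-variance
  samples route to the non-parametric branch with a flag. The paired
  dispatch gates on the *differences*; the ANOVA dispatch gates per cell.
- Paired t results carry the mean difference with a 95% t-interval;
  all-zero differences return the degenerate (t = 0, p = 1) result.
- RM-ANOVA (pingouin backend) assesses sphericity (Mauchly) and reports
  Greenhouse–Geisser-corrected df and p when violated; any non-Gaussian
  cell switches the whole comparison to Friedman. With two levels the F is
  the squared paired t (verified in tests).
- The 2 × 2 mixed ANOVA (time within, group between) reports interaction,
  time and group effects; on a significant interaction (or on request) it
  adds simple main effects: between-group t at each time — Welch-corrected
  with fractional df when Levene rejects homogeneity — and the paired
  comparison within each group. Follow-ups are not multiplicity-corrected
  by default, matching common reporting practice in small cohorts; a
  zero-within-variance input returns null time/interaction results with
  the group effect computed on subject means.
- Pearson correlations report the two-tailed p from the t-transform with
  n − 2 df. Worth knowing for small samples: r = 0.67 at n = 7 has a
  two-tailed p of ~0.0997; the familiar-looking 0.049 at that r and n is
  the one-tailed value.
- Type-I calibration of the gated RM-ANOVA and of the mixed-model
  interaction is verified empirically (2000-replicate Gaussian nulls,
  acceptance suite).

## Orchestration

One `StudyConfig` (YAML or constructor) drives simulate → derive → adhere
→ profile → stats. The top-level seed fans out as `seed + stage_index` so
stages are reproducible in isolation; every run writes a manifest (config
hash stable under key reordering, package version, per-stage outputs and
timings), and a stage failure leaves earlier outputs intact while the
manifest records the failed stage. Adherence tables are emitted tidy
(participant, week, metric, percent); default problem sizes (10
participants, one baseline plus two intervention weeks, 15 h wear days)
keep a full run under a minute apart from the profiling seed sweep.

## Known limitations

- The behavior model is stationary within a run: no learning, fatigue, or
  feedback effects of the adherence display itself.
- Selection outcomes at pilot scale are seed-sensitive by nature; the
  frequency report makes that visible but cannot remove it.
- The generator's outcome distributions are simple per-phenotype normals;
  real adherence distributions are zero-inflated and heavier-tailed.
- Exercise minutes rely on minute-mean HR alone; the package has no way to
  distinguish genuine exertion from optical artifacts that land in zone.
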