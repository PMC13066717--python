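# Methods

## The measurement problem

Alcohol-use-disorder (AUD) pharmacotherapy trials measure efficacy almost
entirely through self-reported daily drinking collected with the timeline
follow-back (TLFB) calendar. The daily record has to be compressed into a
small number of regulatory endpoints, and the compression rules — which days
count, what a missing day means, where the category boundaries sit — are
exactly where analyses of different trials diverge. `tlfbtrials` implements
one fully specified, tested version of that compression and the predictor
analysis built on top of it, for harmonized multi-site trial data.

## Coordinates and windows

Study days are 0-based integers with the day of randomization/first dosing at
day 0. Screening sits at a negative day (`screening_day`, default −14 in the
generator); the pre-screening month occupies the 28 days before it; the
treatment period is `[0, 7·treatment_weeks]`. Five bundled presets cover
treatment lengths of 16, 26, 16, 13 and 12 weeks (with titration/taper weeks
carried as metadata inside the treatment length, not added to it).

Two assessment windows matter:

* **baseline**: the 28 days strictly before `screening_day`;
* **endpoint**: the 28 days ending at the final treatment day. This window is
  anchored strictly at the treatment end; whether it may straddle a taper week
  is not distinguished — the anchor day decides.

Window extraction always returns exactly the requested number of day records;
days absent from a calendar come back flagged missing, so "short" windows
cannot arise silently.

## WHO risk drinking levels

Mean daily grams of pure alcohol over a 28-day window (standard drink = 14 g,
configurable; all bundled designs are US trials) maps to an ordinal level:

| level      | male (g/day) | female (g/day) |
|------------|--------------|----------------|
| abstinent  | no drinking day | no drinking day |
| low        | (0, 40]      | (0, 20]        |
| medium     | (40, 60]     | (20, 40]       |
| high       | (60, 100]    | (40, 60]       |
| very high  | > 100        | > 60           |

Boundaries are half-open on the left and closed on the right ("up to 40 g" is
low risk), so ties go to the lower level; the female bands are the male bands
shifted one level. *Abstinent* requires a window with no drinking day at all,
not merely a mean that rounds to zero — this is what makes the two-level
reduction rule coherent for medium-risk baselines (they can only succeed by
reaching abstinence, with no special case in the code).

## Endpoints and missing data

Four binary outcomes per participant:

* **total abstinence** and **no heavy drinking** (heavy day: ≥ 5 standard
  drinks male / ≥ 4 female, the standard NIAAA definition, configurable) are
  computed over the *entire* treatment period with worst-case scenario
  imputation: an unreported day counts as a (heavy) drinking day. Both
  outcomes are therefore monotone under data deletion — removing an observed
  day can never turn a failure into a success.
* **WHO 2+ reduction**: endpoint level at least two ordinal codes below
  baseline. Under the default `strict` policy any missing day inside the
  endpoint window voids the measurement and is recoded to "no change"
  (failure). An `observed` policy (classify on the reported days only) is
  available behind a flag, default off, because the original handling of
  participants with scattered mid-study gaps is not documented.
* **research completer**: TLFB datum present on the final treatment day —
  completion, not abstinence.

**DSLD** (days since last drink) counts consecutive reported zero-drink days
backwards from day −1, stopping at the first drinking *or missing* day, and
capped at the observed history length (no extrapolation when the whole
history is abstinent). Interim screening-gap days participate automatically
because they are ordinary calendar days.

Baseline risk level is classified on the observed days of the baseline window
(the pre-study TLFB is collected retrospectively at screening and is complete
in practice); the endpoint window keeps the strict rule above. These two
policies are deliberately different and both are documented at the call site.

## Harmonization

Raw per-study instrument categories map to shared binary flags through
explicit dictionaries (married/cohabitating; employed full/part time; income
dichotomized at $60k — chosen as the closest-to-even split of the pooled
data; education at 12+ years; smoking at 10+ cigarettes/day; THC urine
screen). Unmapped categories raise with the offending value; recoding is
total on the declared dictionaries. Race/ethnicity becomes three
non-exclusive indicators (White, Black, Hispanic) entered simultaneously in
models; participants in none of the three are the implicit reference and
their count is logged. Whether Hispanic ethnicity overlaps the White/Black
flags in the original instruments is unknown; the generator draws it
independently.

Participants whose baseline level is low risk (or abstinent) are excluded —
a two-level reduction is unattainable — and the exclusion log reconciles
exactly (`input = retained + excluded`). Merging prefixes participant ids
with the study label so ids reused across trials cannot collide.

A documented inconsistency in the source material is preserved rather than
resolved: the placebo-only modelling subset is described as n = 610 in one
place and tabulated as 607 in another; this package simply takes whatever
rows are flagged `placebo`.

## Statistical stage

* Per-outcome **logistic regression** (statsmodels MLE) on: study indicators
  (first study as reference), placebo-vs-active (omitted in the placebo-only
  subset), baseline risk level with *medium* as reference, DSLD, age and the
  demographic flags. Per-coefficient Wald p-values; single likelihood-ratio
  p-values for the multi-level study and risk-level blocks (the source tables
  print one p per block without naming the test; LR is the package's choice).
  Complete-case within each model, with the dropped-row count reported.
  Non-convergence and (quasi-)separation are flagged on the fit, never
  silent; a one-class outcome is an error.
* **Bonferroni** gating at `alpha / m` for the four modelled outcomes
  (0.05/4 = 0.0125 by default).
* **ROC/Youden**: candidate thresholds are the midpoints between consecutive
  observed predictor values plus ±∞, so an integer predictor like DSLD yields
  half-integer operational cutoffs (e.g. 3.5 or 5.5 days). J = sensitivity +
  specificity − 1 is maximized with ties broken toward the smallest
  threshold; the tie-break uses a 1e−9 tolerance so float roundoff between
  mathematically equal J values cannot flip it. AUC comes from
  scikit-learn's `roc_auc_score`; the test suite independently checks it
  against trapezoidal integration of the coordinate table and checks the
  optimal cutoff against exhaustive search.
* **Contingency/group tests**: Pearson chi-squared without continuity
  correction; pooled-variance two-sample t for two groups (Welch behind a
  flag) and one-way ANOVA for more. Degenerate inputs (zero-variance groups,
  empty cells) are flagged, with two identical groups reported as t = 0,
  p = 1.

## The synthetic generator

The calendars this pipeline was designed for are controlled-access datasets,
so the package ships a generator whose defaults emulate their published
marginals: per-study sizes 594/346/130/221/200 (total 1491), placebo
fractions 0.25–0.53, baseline risk mixture 4.4% medium / 18.0% high / 77.6%
very high, per-study DSLD means 7.8/3.5/0.6/1.8/0.2 days, and a daily
dropout hazard of 0.0015 giving roughly 14% non-completion.

Design choices, with reasons:

* **Drinking process**: a first-order two-state (drink/abstain) Markov chain
  with lognormal grams on drinking days — the simplest process that produces
  both abstinence runs (needed for DSLD) and stable risk strata. Persistence
  is parametrized so the stationary drinking probability is exact
  (`p11 = π + ρ(1−π)`, `p01 = π(1−ρ)`, default ρ = 0.5); a stationary
  probability of zero is made absorbing so a pre-randomization binge cannot
  leak into a configured-abstinent treatment period.
* **Baseline exactness**: each participant draws a target mean-grams value
  uniformly inside the assigned stratum's sex-specific band (1 g inside the
  boundaries), and the baseline window's grams are rescaled to hit the target
  exactly, so the *derived* baseline level always equals the assigned
  stratum. This is what makes the mixture a controllable condition rather
  than an emergent one.
* **DSLD by construction**: the terminal run before day 0 is forced (zeros on
  the last `dsld` days, a drinking day just before), not rejection-sampled,
  keeping the very different per-study DSLD means directly controllable. The
  normal-draw/round/clip distribution reproduces the published means
  approximately (exactly for the weakly truncated studies).
* **Outcome law**: covariate effects (DSLD, age, baseline level, arm, study
  offsets) enter a logistic *sustained-response* propensity. A responder is
  fully abstinent through treatment and completes; a non-responder keeps
  drinking with a uniformly drawn reduction multiplier on both drinking-day
  probability and grams, and faces the geometric dropout hazard. Because
  response ⇔ total abstinence (a non-responder's chance of spontaneous
  100+-day abstinence is negligible), the derived abstinence endpoint follows
  the configured logistic law *exactly* — which is what makes coefficient
  recovery a well-posed test. The other endpoints are correlated consequences
  of the same latent response plus the reduction draw; with default settings
  their pooled rates land close to the published aggregates (≈ 10% abstinent,
  ≈ 17% no heavy day, ≈ 55% WHO 2+, ≈ 86% completers) without being fit to
  them per-study.
* **Reproducibility**: one global seed with per-participant substreams keyed
  by a (study, participant) counter, so deleting a participant or growing the
  cohort never shifts anyone else's draws; day-level recursion is vectorized
  across participants after the per-participant draws.

What the generator does **not** emulate: within-day drinking patterns,
site-level clustering, pharmacokinetics, correlated demographics, seasonal or
calendar effects, and instrument-specific reporting biases. Passing tests
therefore demonstrate that the *pipeline arithmetic and inference machinery*
are correct under a controlled data law, not that the published effect sizes
would be recovered from the real calendars.

## Numerical and problem-size choices

* Coefficient recovery runs 100 replicates of a 5,000-participant five-study
  trial (study sizes scaled proportionally) against the configured DSLD
  log-odds of 0.15; the mean estimate's relative bias is required to be under
  10% (observed ≈ 1%).
* Wald 95% interval coverage uses 500 replicates of n = 2,000 drawn directly
  from the logistic covariate/outcome law (no calendars), with the accepted
  band [0.90, 0.98].
* Oracle equivalence sweeps: the risk classifier against an interval-lookup
  oracle on a 0.1 g grid for both sexes; the Youden cutoff against exhaustive
  search on 1,000 random instances of up to 200 points; chi-squared against
  the closed form on random 2×2 tables; DSLD against a per-day backward scan
  on 1,000 random gap-ridden calendars.
* Logistic fits use Newton iterations (statsmodels defaults, `maxiter=200`);
  standard errors above 10³ downgrade a formally converged fit to flagged.

## Known limitations

* The strict endpoint-window rule is the harshest defensible reading; real
  analyses may have classified on observed days (the `observed` policy).
* The generator's demographic covariates are mutually independent, so
  demographic coefficients in recovery runs are true zeros rather than
  realistic confounded effects.
* Group t statistics computed from rounded summary statistics of the source
  tables are not exactly reproducible (pooled and Welch variants both
  provided); this package always computes from participant-level data.
* No multiple imputation, mixed-effects site modelling, or interaction terms.
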