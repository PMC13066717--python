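# tlfbtrials

Drinking-endpoint derivation and predictor analysis for multi-site alcohol
use disorder (AUD) pharmacotherapy trials.

AUD trial efficacy rests on daily self-reported drinking collected with the
timeline follow-back (TLFB) calendar. This package turns those calendars into
the FDA-guided binary endpoints, harmonizes per-study baseline tables into
one analysis dataset, and runs the predictor-screening stage used to ask
which baseline characteristics (notably pre-randomization abstinence and
baseline drinking level) forecast trial outcomes — a question that matters
for controlling placebo response and type-II error in future trial designs.

## What it computes

For each participant, from the daily calendar (day 0 = randomization):

* **total abstinence** — no drinking day across the whole treatment period;
* **no heavy drinking day** — never ≥ 5 standard drinks (male) / ≥ 4
  (female); both use *worst-case scenario imputation* (an unreported day
  counts as a heavy drinking day);
* **WHO 2+ risk-level reduction** — the WHO risk drinking level (RDL) over
  the final 28 treatment days at least two ordinal levels below the
  baseline level (28 days before screening); a missing endpoint window is
  recoded to "no change". Levels for males: low ≤ 40 g/day < medium ≤ 60 <
  high ≤ 100 < very high; female bands are one level lower; *abstinent*
  requires zero drinking days;
* **research completer** — TLFB datum present on the final treatment day;
* **DSLD** — consecutive reported abstinent days immediately before day 0.

The analysis stage fits per-outcome logistic models
`logit P(Y=1) = β₀ + β·(study, arm, baseline RDL, DSLD, age, demographics)`
with Wald tests gated at the Bonferroni threshold α/m (0.05/4 = 0.0125),
locates operational DSLD cutoffs by maximizing Youden's
J = sensitivity + specificity − 1 over half-integer thresholds, and produces
contingency (Pearson χ², no continuity correction) and group-difference
(t/ANOVA) reports.

Because the source trial datasets are controlled-access, a synthetic
multi-study generator with known ground truth (logistic response law, forced
DSLD runs, configurable dropout hazard) stands in for them; every stage is
tested against it and against independent oracles. See `docs/methods.md` for
the model and its assumptions.

## Worked example

```python
import tlfbtrials as t
from tlfbtrials.pipeline import harmonize_tables

cfg = t.scale_sample_sizes(t.SimulationConfig(), 1491)   # five studies, pooled n
sim = t.simulate_trial(cfg, seed=42)
ep = t.derive_endpoint_table(sim.calendars(), sim.sex_by_id(), sim.study_configs())
table, log = harmonize_tables(sim.baseline, ep)

fit = t.fit_outcome_model(table, "abstinent")
print(fit.summary_frame().loc[["dsld", "age"]].round(3))

roc = t.roc_youden(table["dsld"].to_numpy(), table["abstinent"].astype(bool).to_numpy())
print(f"AUC = {roc.auc:.3f}; optimal cutoff = {roc.optimal_cutoff}")
print(t.cutoff_table(table, roc.optimal_cutoff).table.round(3))
```

prints

```
      beta     se      p  ci_low  ci_high  significant
dsld  0.142  0.021  0.000   0.101    0.183         True
age   0.013  0.008  0.108  -0.003    0.029        False
AUC = 0.691; optimal cutoff = 6.5
           n_low  pct_low  n_high  pct_high    chi2      p  significant
outcome
abstinent     80    7.333      95     23.75  76.150  0.000         True
no_heavy     170   15.582     128     32.00  49.334  0.000         True
who2plus     601   55.087     260     65.00  11.788  0.001         True
completer    934   85.610     350     87.50   0.875  0.350        False
```

Reading: the generator was configured with a DSLD log-odds of 0.15 on the
abstinence response, and the fitted coefficient is 0.142 (within one standard
error); participants above the Youden-optimal abstinence cutoff of 6.5 days
were abstinent at 23.8% versus 7.3% below it, significant at the corrected
threshold. Percentages are of each DSLD group.

The same flow is available from the shell:

```bash
tlfbtrials run-all --out runs/demo --seed 42        # simulate → derive → analyze
tlfbtrials simulate --out data/ --seed 1            # just the synthetic trial
tlfbtrials derive --tlfb data/tlfb.csv --baseline data/baseline.csv --out endpoints.csv
tlfbtrials analyze --table runs/demo/analysis_table.csv --outcome who2plus --subset placebo
tlfbtrials roc --table runs/demo/analysis_table.csv --outcome abstinent
```

## Layout

```
src/tlfbtrials/
  tlfb.py        calendars, windows, WHO risk levels, study presets
  endpoints.py   the four outcomes + DSLD, worst-case imputation
  harmonize.py   category recoding, exclusions, multi-study merge
  analysis.py    logistic models, ROC/Youden, contingency, group tests
  simulate.py    synthetic trial generator with known truth
  io.py          CSV/JSON dialects with strict validation
  pipeline.py    end-to-end run + manifest
  cli.py         command-line interface (exit codes 0/1/2)
```
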