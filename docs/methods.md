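# Methods

## The projection model

The method treats forecasting as missing-data imputation on a sliding
window.  The observed panel holds seven biennial waves (2000–2012) of two
binary mobility outcomes (difficulty climbing one flight of stairs;
difficulty walking across a room), six ADL and six IADL items (1 = no
difficulty), five binary risk factors (current smoking, obesity, any
alcohol use, hypertension, vigorous physical activity), vital status,
and time-independent study, sex and education.  After the observed data
are completed, item batteries are collapsed to 0–6 sum scores
(0 = severe disability) and the items are dropped, so all projection
models condition on scores.

A projection step stacks two blocks that share window positions 1…7:

- the **training block**: the most recent complete seven-wave window
  (initially the imputed observed panel, then the previous step's
  completed survivor block);
- the **apply block**: survivors of the training block's newest wave,
  with the window slid one wave forward — position 7 is entirely missing
  except age (previous age + 2) and the time-independent variables.

Conditional models trained on the training block impute position 7 of
the apply block.  This operationalises the stationarity assumption that
variables change between adjacent waves with the same transition law
throughout; it is also what limits the horizon — each step consumes one
wave of history, so seven steps (2026) exhaust a seven-wave window.

### Imputation machinery

Conditional models are CART trees (sklearn `DecisionTree*`) used as
donor samplers: a case is routed to its terminal node and receives one
observed donor value drawn uniformly from that node.  Donor draws keep
every imputed value inside the variable's observed support, which is why
binary variables stay binary and scores stay in `{0,…,6}` without
clamping.  Binary and nominal targets use classification trees; scores
and other numerics use regression trees (the draw is still a donor
value).  Uniform donor draws are used rather than a Bayesian bootstrap
of the node; parameter uncertainty is carried by the bootstrap
replicates instead.

Predictor sets are chosen per target by a single selection tree: the
candidates appearing in at least one split are selected, and age, sex
and education at the anchor wave (2012) are forced into every model.
During selection only, missing candidate values are tolerated
(missing-as-own-category for categoricals, median fill for numerics);
imputation itself always sees complete designs.

The chained loop initialises missing cells from each variable's observed
marginal, then revisits targets in order of increasing missingness
fraction (ties by column order) for `n_chained_iters` sweeps, refitting
each model on the originally observed rows against the current completed
data.  One completed dataset is produced per bootstrap replicate; the
"multiple" in multiple imputation is supplied by the 120 replicates.

Candidate predictors for the observed-data models are restricted to the
target's wave or earlier (plus time-independent variables and the forced
set).  Combined with absorbing mortality — cells after death are missing
structurally and are never imputed — this guarantees every tree design
is complete: a row with an imputable missing cell at wave *w* is alive
through *w*, hence observed or initialised everywhere at waves ≤ *w*.

At projected waves, the step has a fixed causal order.  Phase 1 imputes
risk factors and the two scores (their candidate sets exclude the
contemporaneous outcomes and vital status); the scenario shift, if any,
is applied; phase 2 imputes the outcomes (which may condition on the
just-modified scores) and finally vital status.  The mortality model is
a discrete-time hazard trained on rows alive at the previous position,
conditioning on lagged history plus the forced demographics only —
individuals who die at the new wave have no substantive values there, so
contemporaneous mortality predictors are unidentifiable.  A consequence
worth noting: the intervention influences projected mortality only with
a one-wave lag.  Imputed death is absorbing and masks the row's
substantive values at that wave.

### Bootstrap and summaries

Sampling variability is handled by the Rao–Wu rescaled bootstrap with
equal weights: `m = n − 1` draws with replacement within each study
stratum, which makes the naive bootstrap variance consistent under
simple random sampling.  All scenarios within a replicate share the
replicate's observed-data imputation and predictor selection, and the
random streams of the projection steps are keyed by (replicate, step,
phase) — not by scenario — so scenario contrasts are paired down to the
random numbers and isolate the intervention effect.  A null intervention
(effect size 0) is exactly scenario 0: the shift operator is skipped,
its draws live on dedicated per-target streams, and the two-phase order
is identical in every scenario.

Point estimates are replicate means; predictive variances are replicate
variances; 95% credible intervals are the 2.5th/97.5th percentiles of
the replicate distribution (assumption-free given the ensemble), with a
normal approximation (mean ± 1.96 SD) available by flag.  Contrasts are
within-replicate paired differences.  Selection proportions — the share
of replicates in which a candidate entered a target's final model — are
reported at or above 10%; forced predictors are flagged separately since
they are 100% by construction.  Pooled ("ALL") estimates weight
individuals equally across studies, matching the unweighted bootstrap.
Headline prevalences are restricted to survivors aged ≥ 76, the minimum
attainable age in 2026 for a cohort aged ≥ 50 in 2000.

## The scenarios

The intervention evidence enters as a standardised mean difference of
1.12 (moderate physical activity vs none, on self-reported ADL/IADL
measures).  It is transformed to the absolute score scale by the
study-specific SD of the score at baseline (2000), and applied once, at
the 2014 wave, to individuals whose (possibly just-imputed) vigorous
physical activity at 2014 is "no": the score is replaced by a draw from
`N(score + 1.12·SD, SD)`, truncated to `[0, 6]` (values below 0 coded 0,
above 6 coded 6; never rounded — downstream trees accept continuous
predictors).  Scenario 1 shifts IADL; scenario 2 shifts IADL and ADL.
The ADL shift is scaled by the ADL baseline SD; a flag
(`adl_sd_from_iadl`) exposes the alternative of scaling it by the IADL
SD, since the procedure's labelling of that SD is ambiguous.  The effect
is applied once and persists only through whatever the transition models
propagate; uncertainty in the effect size itself is not propagated.
Eligibility is evaluated at the intervention wave by default; a config
switch anchors it at the last observed wave instead.

## The synthetic cohort

The generator emulates the features the method's validity rests on, with
closed-form oracles:

- a latent disability process (default three states good/limited/severe)
  following a first-order Markov chain (defaults: baseline
  (0.70, 0.22, 0.08); rows (0.85, 0.12, 0.03), (0.25, 0.60, 0.15),
  (0.02, 0.18, 0.80) per 2-year wave);
- items conditionally independent given the latent state (P(no
  difficulty) 0.97/0.78/0.40 by state), outcomes depending on state and
  age band, risk factors with their own persistence/onset dynamics;
- per-wave mortality on the log-odds scale (intercept −9.74, +0.09 per
  year of age, state offsets 0/0.8/1.8 — roughly 2% per wave for a
  60-year-old in good state, 11% when severe), absorbing, with
  substantive values masked from the death wave onward;
- missingness: whole-wave structural rules reproducing the real layout
  (the ELSA-like study starts in 2002; the Finnish-like study lacks
  2002–2008 and has its single follow-up split across 2010/2012 by a
  seeded fair coin; one ADL item is never asked in the HRS-like study
  and one IADL item never in the Finnish-like study), 12% independent
  wave non-response, and 2% item-level missingness.

Default sample sizes are the harmonised analysis dataset's
(9,765 / 10,815 / 4,402; N = 24,982).  Test and driver runs use smaller
cohorts and replicate counts chosen as sensible desk-scale problem
sizes: the Markov-recovery check uses n = 5,000 with 30 replicates and
three projection steps, the reproducibility check n = 2,000 with 10
replicates and two scenarios, and the analysis drivers n = 3,200 with 12
replicates to the full 2026 horizon.

`analytic_prevalence` computes the exact outcome prevalence among
survivors by forward recursion over (latent state × alive), integrated
over the uniform baseline-age distribution, for any wave index —
including beyond the observed grid.  It is the recovery target for the
central property: scenario-0 projections of a stationary binary Markov
outcome must track the analytic forward recursion at every projected
wave.  In that check the Monte-Carlo tolerance combines two layers of
randomness — the spread across bootstrap replicates and the binomial
error of the single synthetic base cohort (which is what the bootstrap
SD estimates) — since all replicates share one base draw.

What the generator does **not** emulate: refreshment samples and partner
recruitment, survey design weights, informative (outcome-dependent)
non-response, calendar-time trends in the transition law (the generated
chain is exactly stationary, which the real world need not be),
measurement error in harmonisation, and realistic marginal prevalences
of any specific country.  Passing tests therefore demonstrate that the
machinery is correct under its own assumptions — stationary first-order
dynamics, ignorable non-response — not that those assumptions hold in
real cohort data.  An optional post-processing helper reproduces the
disclosure-control age top-coding of one source study (ages > 90 coded
99); it is off by default because it deliberately breaks the
deterministic age arithmetic.

## Numerical and design choices

- CART controls default to `min_leaf = 5`, `complexity = 1e-4`
  (minimum impurity decrease), unlimited depth — the conventional
  defaults of tree-based chained-equations imputation; `min_leaf ≥ 2`
  is enforced so a terminal node always has donors.
- `n_chained_iters` defaults to 5; the fast end-to-end tests and the
  drivers use 2–3 sweeps.
- Selection uses one tree per target (no cross-validation); selection is
  run once per replicate on the imputed observed window and the specs
  are reused with shifted wave positions at every step, which keeps
  selection proportions comparable across replicates.  A degenerate
  target (constant among donors) simply yields a stump and constant
  draws.
- Categorical encodings are fixed (education low/medium/high → 0/1/2;
  other categoricals by sorted label) and shared between training and
  apply rows, so leaf routing is consistent.
- Every random stream is derived from one master seed plus named keys
  (module, replicate, step, phase), so any replicate or step is
  independently reproducible and full runs are bit-identical under a
  repeated seed.  Tree fits use a fixed `random_state`.
- A replicate that fails aborts the whole run with the replicate index
  attached; silently skipping replicates would bias the ensemble.
- Missing vital status in the observed data is resolved before the main
  chained pass: deterministic death if already dead, otherwise a CART
  draw on the forced demographics among rows alive at the previous
  wave; baseline participants are alive by construction.

## Known limitations

- The stationarity assumption is untestable from the window itself; the
  projection inherits any secular trend violation.
- Selection trees with the default (very small) complexity penalty are
  deep, so many predictors reach high selection proportions on synthetic
  data; raising `complexity` prunes the reported sets.
- The intervention cannot affect mortality at the wave it is applied
  (lagged-only hazard predictors; see above).
- Horizon is capped by the window width; projecting past it would
  require refreshment samples, which are out of scope.
- Credible intervals are percentile intervals of a 120-point ensemble;
  their tails are accordingly coarse, and no small-sample correction is
  applied.
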