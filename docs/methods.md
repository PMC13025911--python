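# Methods

`wardwatch` predicts post-ICU-discharge deterioration — unplanned ICU
readmission or death within 7 days of transfer to a general ward — from
daily-gridded, heavily missing clinical time series. This note documents the
models, the synthetic study conditions, the numerical choices, and what the
packaged experiments do and do not establish.

## Cohort and endpoint

The unit of analysis is one continuous ICU stay. Stays are kept when the
patient was an adult (age ≥ 18 at admission), stayed at least 24 h, survived
the ICU, and was discharged to a general ward; every removal is counted in an
audit that partitions the exclusions. Planned surgical returns to the ICU are
not outcome events: each planned return interval is concatenated with its
parent stay (union time range, merged events, recomputed length of stay)
*before* filtering and labeling. The endpoint label is 1 iff an unplanned ICU
readmission or a death occurs in `(t_out, t_out + 7 days]` — we fix the
window as a closed right endpoint at exactly 7 × 24 h, since "within seven
days" does not specify the boundary.

## Daily tensorization

Day bins are 24-hour windows anchored at ICU admission, so a stay of length
L days yields `T = ceil(L)` bins deterministically. Numeric channels average
all in-bin measurements; treatment channels flag any in-bin positive event.
A bin is *missing* only when it contains no measurement (the alternative
reading — a day is missing when any scheduled measurement is absent — would
discard the very partial observations the decay models exist to use). Where
the mask `M` is 0, the value matrix holds NaN as a sentinel; consumers must
branch on `M`, never on the sentinel. The elapsed-time matrix follows the
daily-grid recursion `Delta[0,d] = 0`, `Delta[t,d] = 1` if `M[t-1,d] = 1`
else `Delta[t-1,d] + 1`.

Channels are retained when their pooled missing rate over the *training*
stay-days is strictly below 50%. Numeric channels and age are z-scored with
training-split statistics under the population (divide-by-n) variance
convention — either convention works statistically, but one must be fixed
for bit-exact tests. Binary treatments and sex pass through. Baseline
(non-decay) models receive forward-filled values, with the channel's global
mean where no prior observation exists; last-day snapshots for the
non-temporal learners are `(age, sex, final-day filled values, LOS)`.

## Recurrent models

All recurrent variants share one numpy forward/backward engine with a single
32-unit tanh hidden layer and a prediction head mapping
`(hidden state at day t) ⊕ (age, sex)` to a logit, so prefix trajectories
(a risk estimate after every day) come from one forward pass, and the
stay-level risk is the final day's trajectory value.

* **rnn / gru** consume fill-imputed dense inputs.
* **gru_d** adds (i) per-channel input decay
  `γx = exp(−max(0, w δ + b))` blending the last observation toward the
  global mean, (ii) full-rank hidden-state decay `ĥ = γh ⊙ h`, and (iii) the
  observation mask as an additional gate input. A channel missing with no
  history falls back to the global mean — the classical formulation's
  implicit assumption that the first step is observed.
* **gru_d_pp** replaces that fallback with a trainable per-channel default
  `x0`, blended by the same decay gate with elapsed time measured from stay
  start. The no-history rule sits behind a small strategy switch
  (`no_history ∈ {"trainable", "global_mean", None}`) so an alternative rule
  can be swapped in without touching the cell.

Decay outputs are confined to (0, 1] by construction; with decays pinned to
one, masks fully observed, and mask weights zeroed, both decay variants are
bit-identical to the plain GRU — a property the test suite asserts at 1e-10.
Gradients are analytic backprop through time, validated against central
finite differences at 1e-4 relative tolerance.

**Training.** Binary cross-entropy on the final-day logit; adaptive moment
estimation; early stopping when validation loss has not decreased for 20
consecutive epochs, with a stratified 10% of the training stays as the
selection split and the best-validation-loss epoch's weights returned.
Class imbalance (~7% positives) is handled by plain BCE; an optional
positive-class weight exists but is off by default. The output bias is
initialized to the log-odds of the training prevalence ("prior
initialization"): without it the first epochs mostly re-learn the base rate,
and the small selection split can hand its loss minimum to a barely trained
model. `TrainConfig` defaults to lr 1e-3 / batch 64 / max 500 epochs; the
packaged experiment configurations use lr 5e-4 capped at 150 epochs (3e-4
and 100 epochs for warm-started fine-tuning, the usual guard against
catastrophic forgetting); early stopping fires well before either cap in
practice. Initialization is
fan-in-scaled uniform, zero biases, `x0 = 0` (the normalized global mean),
all fixed by seed; training is deterministic given the seed.

**Baselines.** Logistic regression, decision tree, and random forest at
scikit-learn defaults, and gradient boosting at 1000 rounds / eta 0.01 /
depth 6, all on last-day snapshots. The recurrent fill baselines (rnn, gru)
consume filled values only — whether masks should also be fed to them is
left at the conservative default of "no". An LSTM baseline is deliberately
absent: the package's recurrent core implements the decay family, and a
bespoke LSTM would add maintenance surface without touching any claim the
package makes.

## SWIFT comparator

The five-component integer score (admission source, ICU LOS, last GCS,
PaO2/FiO2, PaCO2; range 0–64) ships as versioned configuration
(`gajic-2008`), since the components are standard but deployments may need
local cut-points. Extraction forward-fills each component to discharge and
flags provenance per component: `measured` (final-day), `carried-forward`,
`proxy` (SpO2/FiO2 substituted when no arterial gas exists — untransformed,
with its own bin set obtained by passing the P/F cut-points through the
standard linear S/F correspondence), or `unavailable`, which scores the
lowest-risk bin rather than excluding the stay. FiO2 defaults to room air
(0.21) when never recorded, also flagged.

## Evaluation

AUROC is the tie-aware pairwise probability (mid-rank computation); AUPR is
average precision. Cross-validation is stratified at the stay level (at ~7%
prevalence, unstratified folds risk positive-free test sets) with the
variable filter, normalization statistics, and global means fitted inside
each training split. The DeLong comparison uses the fast mid-rank
structural-components algorithm, two-sided normal approximation; identical
rankings return a degenerate flag with p = 1. The operating threshold
maximizes Youden's J, breaking ties toward the higher threshold (higher
specificity). Trajectory summaries align stays at admission or discharge and
report per-offset group means with normal-approximation 95% bands; an offset
contributed by a single stay is flagged degenerate. The
baseline-characteristics table reports median (IQR) + Mann–Whitney U
(exact for tie-free groups of ≤50, asymptotic with tie correction otherwise)
for numeric variables and count (%) + Fisher's exact for binary ones.

## Shapley attribution

Attribution is channel-level (a 26-variable display needs one number per
variable, not per variable-day): a coalition keeps a subset of channels at
their actual series; channels outside it take the reference's series *and
observation pattern*, with `Delta` rebuilt from the hybrid mask. The default
reference is the all-global-mean stay on the stay's own grid (every channel
observed daily at its global mean; zero in normalized units) — defining the
reference on the stay's own grid makes per-stay efficiency exact. Values are
estimated on the logit scale by antithetic permutation sampling; each
permutation walk telescopes, so efficiency (values summing to
`f(x) − f(reference)`) holds exactly and sampling error affects only the
per-channel split. An exact subset-enumeration evaluator (tractable to
D ≈ 15) is the estimator's normative definition and its test oracle.

## Synthetic study conditions

Real cohorts for this problem are credentialed or private, so the package
ships a generator that emulates the statistical structure the pipeline
assumes, and all quantitative claims are made under these conditions:

* **Latent state.** Two independent per-day AR(1) factors with stationary
  unit variance and autocorrelation 0.7: *acuity* (mean shifted by
  0.15 · standardized age) and *reserve/frailty*. AR(1) is the simplest
  process with the longitudinal autocorrelation the decay models exploit.
* **Channels.** 23 time-varying channels mirror a daily ICU collection
  panel: 6 binary treatments (threshold functions of acuity, never missing),
  6 physiologic signals (1–3 samples/day), 9 labs, GCS, SAS. Numeric values
  are linear readouts `base + scale·(w·s + w_f·f + noise)` with clinically
  plausible bases/scales and noise SD ≈ 0.6–0.95. Roughly seven channels
  (temperature, urine output, hemoglobin, platelets, BUN, creatinine, SAS)
  also load on frailty. With age, sex, and LOS the modeling set has 26
  variables.
* **Missingness.** Per-channel rates 0.20–0.60 (numeric-channel mean ≈ 0.4
  realized); treatments fully observed. Four labs are MNAR (observation
  probability is a logistic function of the standardized day value — sicker
  values are measured more often — with the intercept solved by quadrature
  so the marginal rate equals the configured rate); the rest are MCAR. Three
  labs (WBC, BUN, creatinine) are structurally unobserved on day 1,
  exercising the no-history path; one decoy lab (lactate) at 60% missingness
  exists to be dropped by the <50% filter. Blood-gas channels (PaO2, PaCO2,
  FiO2, ~70–75% missing) are emitted only for SWIFT extraction.
* **Outcome.** Logistic in the discharge-day latent risk
  `1.3·acuity + 0.4·frailty` with intercept −3.35, giving ≈ 6.7% prevalence
  (the closed-form rate under the stationary risk distribution is exposed
  and tested). Positive stays emit a death (30%) or an unplanned readmission
  (70%) within 7 days.
* **Plants.** Exclusion categories (2% under-18, 4% under-24 h, 5% ICU
  death, 4% specialized-unit transfer) are assigned by exact count, not
  sampled; 5% of kept stays get a planned, flagged return interval.
* **External site.** The site-shift preset moves channel baselines by
  ±0.35 channel-SD, inflates lab missingness ~15%, ages the population, and
  — decisively — shifts the outcome weights from acuity (1.3 → 1.0) toward
  frailty (0.4 → 1.3). A source-trained model has mostly learned the acuity
  direction, so it transfers with a genuine performance drop that site data
  gradually repairs; marginal shifts alone leave ranking performance intact
  and produce no learning curve, which is unrealistic for cross-hospital
  transfer.

**What the generator does not emulate:** pharmacology, unit harmonization,
sub-daily dynamics, multi-ICU transfer graphs, documentation artifacts,
informative discharge timing, or outcome mechanisms beyond a logistic link
on latent state. Passing experiments therefore establish that the pipeline
recovers plantable structure under realistic missingness — not clinical
performance on any real cohort.

## Packaged experiments and problem sizes

The experiments (`wardwatch.experiments`) are shared verbatim by the test
suite and the reproduction script. Sizes were chosen as the smallest at
which each phenomenon is stably measurable:

* *Signal recovery*: n = 2000 stays, 10 training seeds, 85/15 stratified
  splits. The trained model's mean test AUROC is compared with the latent
  oracle evaluated **on the same test folds** — pairing removes
  fold-composition noise from the gap. For calibration: an exact Kalman
  smoother using the true generator loadings (the information ceiling given
  the observations) sits ≈ 0.02 AUROC below the latent oracle under these
  conditions, so a trained-model gap of ≈ 0.04 means the network is within
  ≈ 0.02 of the best any observation-based predictor could do.
* *Imputation ordering*: n = 1000, the three variants on shared splits and
  seeds (paired comparison), 10 seeds.
* *Fine-tuning*: source and site cohorts of n = 2000; fixed 40% site test
  and 10% selection sets; nested training subsets at 10–50% so the learning
  curve is monotone in data rather than split noise; 10 fine-tuning seeds
  around one pretrained model.
* *DeLong calibration*: 2000 null replicates at n = 300, prevalence 0.1.

BLAS is pinned to a single thread in test and script entry points: batched
matmul reduction order otherwise varies with thread count, which can flip
early-stopping epoch selection and break bit-reproducibility.

## Known limitations

* The no-history mechanism is one defensible realization (trainable default
  under the shared decay gate); other rules fit behind the same interface.
* Trajectories are prefix forward passes of one final-day-trained model, not
  models retrained per horizon; early-day risk estimates are therefore
  extrapolations of the discharge-day objective.
* The SWIFT point table is transcribed configuration; deployments should
  verify it against their local standard before clinical use.
* Attribution is channel-level and reference-dependent; day-resolved
  attribution and alternative background sets are out of scope.
* With ~90 positive stays per training split, run-to-run variation in
  early-stopping selection remains the dominant noise source in the trained
  model's test AUROC (±0.02–0.04 per seed); the packaged experiments
  average over 10 seeds for this reason.
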