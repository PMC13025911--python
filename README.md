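# wardwatch

Missing-data-aware recurrent prediction of patient deterioration after ICU
discharge, for researchers studying ICU-to-ward transition safety and for
methodologists working on clinical time series with informative missingness.

The transfer from intensive care to a general ward is a high-risk handoff:
discharge too early and the patient returns (or dies); discharge too late
and ICU beds are wasted. `wardwatch` implements the full study pipeline for
predicting the composite endpoint *unplanned ICU readmission or death within
7 days of ward transfer* from daily clinical time series:

* **Cohort tooling** — adult / ≥24 h / survived / ward-discharge filters with
  an exact exclusion audit; planned surgical ICU returns merged into one
  continuous stay; closed 7-day endpoint labeling.
* **Tensorization** — admission-anchored daily bins producing the triple
  (values `X`, observation mask `M`, days-since-last-observation `Δ`),
  a strict <50% missing-rate variable filter, and leakage-safe
  normalization.
* **Recurrent classifiers with learned decay imputation** — GRU-D, where a
  missing channel's last observation decays toward the global mean via
  `γ_t = exp(−max(0, W δ_t + b))` and the hidden state decays likewise, and
  **GRU-D++**, which additionally learns a per-channel default for channels
  with *no* history in the stay (relaxing GRU-D's observed-first-step
  assumption). Plain RNN/GRU on fill-imputed inputs and
  LR/DT/RF/XGBoost on last-day snapshots serve as baselines. The
  forward/backward engine is pure numpy with analytic BPTT gradients.
* **SWIFT comparator** — the Stability and Workload Index for Transfer
  (admission source, ICU LOS, last GCS, PaO2/FiO2, PaCO2; 0–64 points) with
  forward-filled components, the SpO2/FiO2 proxy, and provenance flags.
* **Evaluation** — tie-aware AUROC / average precision, stratified k-fold CV
  with per-fold preprocessing, the fast structural-components DeLong test,
  Youden-threshold selection, per-day risk-trajectory summaries, and
  median/IQR + Mann–Whitney / Fisher baseline-characteristics tables.
* **Attribution** — channel-level Shapley values by antithetic permutation
  sampling on the logit scale, with an exact enumeration evaluator at small
  channel counts.
* **Synthetic ICU-stay generator** — real cohorts for this task are
  credentialed or private, so a seeded generator emulates the assumed
  structure (two latent AR(1) severity factors, 26 variables, 0–60%
  per-channel MCAR/MNAR missingness, planted exclusions, planned returns,
  a distribution-shifted "external hospital" preset) and makes every stage
  testable end-to-end. Generated records carry their latent truth, so every
  trained model can be compared against the Bayes-score oracle.

## Worked example

```python
import numpy as np
from wardwatch.synthetic import default_config, generate_cohort, oracle_auroc
from wardwatch.cohort import prepare_cohort
from wardwatch.preprocess import prepare_split
from wardwatch.models.training import TrainConfig, train, predict, stratified_split
from wardwatch.evaluation import auroc, aupr, delong_test
from wardwatch.swift import swift_auroc

config = default_config(n_stays=2000, seed=7)
kept, labels, audit = prepare_cohort(generate_cohort(config))
labels = np.array(labels)

rng = np.random.default_rng(0)
tr, te = stratified_split(labels, 0.25, rng)
train_t, test_t, stats, channels = prepare_split(
    [kept[i] for i in tr], labels[tr], [kept[i] for i in te], labels[te],
    config.channels)

params, log = train("gru_d_pp", train_t,
                    TrainConfig(learning_rate=5e-4, max_epochs=150, seed=0),
                    stats)
risk = predict(params, "gru_d_pp", test_t, stats)
sw = swift_auroc([kept[i] for i in te], labels[te])
dl = delong_test(risk, sw["scores"], labels[te])
```

Output (printed by the snippet above with the obvious `print` calls):

```
kept 1700/2000 stays, exclusions {'missing_metadata': 0, 'age_lt_18': 40,
  'los_lt_24h': 80, 'icu_death': 100, 'not_ward_discharge': 80}
deterioration prevalence: 0.069
23 channels kept by the <50% filter
stopped after epoch 27, best epoch 7
GRU-D++  AUROC 0.818  AUPR 0.228
SWIFT    AUROC 0.679  AUPR 0.109
DeLong GRU-D++ vs SWIFT: z=3.79, p=1.5e-04
latent-risk oracle AUROC 0.807
```

Reading it: the planted exclusion counts come back exactly (they are
assigned, not sampled); prevalence matches the generator's closed-form
expectation (~7%); the 60%-missing decoy lab is the one channel dropped by
the filter; the trained decay model reaches the neighborhood of the latent
oracle on this test fold and clearly outperforms the SWIFT comparator
(paired DeLong p ≈ 1.5e-4) — the qualitative picture such models show on
real ICU cohorts.

There is also a CLI for shell-driven use (`wardwatch simulate | preprocess |
train | predict | swift | evaluate | compare | attribute`); each subcommand
is a thin wrapper over the functions above.

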