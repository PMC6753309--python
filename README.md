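# wmbind — does working-memory capacity limit items, or bindings?

`wmbind` is an analysis pipeline for n-alternative forced-choice (n-AFC)
word-list experiments that separate **item memory** (knowing *which* words
were in the current list) from **binding memory** (knowing which word occupied
*which* list position). The signature of a capacity limit is the set-size
effect — performance falls as the number of list words N grows — and the
question is where that effect lands. The package is aimed at cognitive
modellers who want the full chain — design, simulation, measurement models,
capacity estimates, Bayes factors — as reusable, tested code.

The response set of each trial contains the target, `RSS_List − 1` other words
from the current list, and `RSS_New` new words, so errors are diagnostic:
other-list confusions are binding failures, new-word choices are item
failures. Two measurement models decompose the three response-category
frequencies:

* a discrete-state **multinomial process tree** (MPT) with binding probability
  `Pb` and item probability `Pi`:
  `p_correct = Pb + (1−Pb)(Pi/RSS_List + (1−Pi)/RSS)`, etc.;
* a continuous-strength **memory measurement model** (MMM) with activations
  `B`, `B+A`, `B+A+C` for new / other-list / target candidates, combined by
  Luce's choice rule with weights (1, RSS_List−1, RSS_New); the across-set-size
  mean of group-level `C` is fixed to 10 for identifiability.

Both are fitted as hierarchical Bayesian models (custom adaptive
Metropolis-within-Gibbs, 4 chains, split-R̂/ESS gates) with linear effects of
mean-centered set size on each memory parameter. On top sit discrete-capacity
estimates `K = N(P(correct) − g)/(1 − g)` under competing guessing assumptions
(g = 1/RSS vs 1/RSS_List vs 1/N for recall), and a hierarchical logistic
regression of accuracy with bridge-sampled Bayes factors for set size,
RSS_List and RSS_New (Cauchy(0, .353) priors on standardized effects, with a
prior-scale sensitivity analysis).

A fully seeded synthetic-experiment generator reproduces the design — set
sizes 2/4/6/8 × nine response-set compositions plus recall, 28-cell blocks,
three-session schedules, large (1198-word) vs small (16-word) pools — and
generates responses from either model's generative process with known
parameters, so every stage is testable end to end without any data download.

## Worked example

Simulate an experiment whose ground truth has a negative set-size slope on
binding only, then fit the MPT:

```python
import numpy as np
from wmbind import GroundTruth, MPTParams, MCMCConfig, simulate_dataset, fit_mpt

truth = GroundTruth(group=MPTParams(pb_intercept=0.6, pb_slope=-0.35,
                                    pi_intercept=2.0, pi_slope=0.0),
                    n_subjects=20, seed=11)
trials = simulate_dataset(truth, words=False)     # 13,640 trials
fit = fit_mpt(trials, MCMCConfig(seed=5))
print(fit.hdi("mu_pb_slope"), fit.hdi("mu_pi_slope"))
```

Output from this exact run:

```
(-0.4729688301508427, -0.30502747471143243) (-0.1258723583709656, 0.12282636310382912)
```

The binding slope's 95% HDI lies entirely below zero (truth −0.35 recovered),
while the item slope's HDI spans zero (truth 0) — the dissociation the design
is built to detect. The same check for the MMM recovers `C` slope −2 with a
negative-only HDI and an `A` slope HDI spanning zero, with the group-level `C`
averaging exactly 10 across set sizes.

The numbered drivers under `analysis/` run the full story on two synthetic
experiments (large-pool vs small-pool) and write tidy tables to
`results/analysis/`: `01` simulation, `02` descriptive category proportions
(the set-size effect is carried almost entirely by other-list errors),
`03` both measurement-model fits (binding slopes negative, item slopes ~0,
baseline `B` higher in the small-pool experiment), `04` capacity estimates
(binding-limit K is far more consistent across RSS_List strata than
item-limit K), `05` Bayes factors with sensitivity, `06` parameter recovery
across replicates. A `wmbind` CLI exposes the same stages
(`simulate`, `fit-mpt`, `fit-mmm`, `kest`, `bf`, `recover`, `report`).

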