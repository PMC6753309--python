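# Methods

This package analyses n-alternative forced-choice (n-AFC) tests of memory for
word lists, separating *item memory* (which words were in the current list)
from *binding memory* (which word occupied the probed list position). It
implements the experimental design, a synthetic-data generator, two
measurement models fitted as hierarchical Bayesian models, discrete-capacity
(K) estimation, and a Bayes-factor descriptive analysis. This note documents
the models, the defaults, and the design choices that were genuinely open.

## Experimental design

Memory set sizes N ∈ {2, 4, 6, 8} are partially crossed with nine response-set
compositions, coded [RSS_List, RSS_New]: [1,1], [2,0], [2,2], [4,0], [4,4],
[6,0], [6,4], [8,0], [8,4], plus a recall test per set size. A composition is
feasible only when RSS_List ≤ N, leaving 3 + 5 + 7 + 9 = 24 n-AFC cells and 4
recall cells (28 in total). Each test block presents all 28 cells in random
order; a standard run is three sessions with 7, 8 and 8 test blocks, preceded
by 28 practice trials (session 1) or 5 warm-up trials (later sessions).
Practice/warm-up trials are stored with `analyze=False` rather than discarded,
so their exclusion is an explicit, reproducible analysis step.

List candidates entering the response set are ranked by positional distance
from the probed position and the nearest RSS_List taken; this keeps the mean
lure distance constant across set sizes, so the set-size effect is not diluted
by increasingly distant (less confusable) lures. Open details resolved here:
distance ties are broken uniformly at random (avoids an earlier/later-position
bias); the probed position is uniform on 1..N; warm-up trials are drawn with
replacement.

Word materials are synthetic tokens. The large pool (default 1198 tokens)
samples without replacement *across* trials and is reinstated in full only on
exhaustion, so a "new" word is genuinely unfamiliar. The small pool is exactly
16 tokens per participant, reinstated after every trial, so "new" words are
highly familiar. Pool sizes are configurable.

## Measurement models

Both models map parameters to the probabilities of the three observable
response categories — correct, other-list word, new word — in each cell.

**Discrete-state multinomial process tree (MPT).** With probability `Pb` the
item-position binding is intact and the response is correct. Otherwise item
memory is available with probability `Pi`, in which case guessing is uniform
over the RSS_List candidates from the current list; with neither source,
guessing is uniform over all RSS = RSS_List + RSS_New candidates:

    p_correct = Pb + (1-Pb)(Pi/RSS_List + (1-Pi)/RSS)
    p_other   = (1-Pb)(RSS_List-1)(Pi/RSS_List + (1-Pi)/RSS)
    p_new     = (1-Pb)(1-Pi) RSS_New/RSS

**Continuous-strength memory measurement model (MMM).** Activations
B (baseline, all candidates), B+A (list words), B+A+C (the word bound to the
probed position) enter Luce's choice rule with category weights
(1, RSS_List−1, RSS_New). Luce's rule is scale-free, so one quantity must pin
the scale: the across-set-size mean of group-level C is fixed to 10, and B is
estimated freely so that it can absorb the familiarity of "new" words (higher
in the small-pool design).

**Hierarchy and set-size effects.** Each subject carries an intercept and a
linear slope on mean-centered set size for each memory parameter. Scales:
logit for Pb and Pi (keeps probabilities in [0,1] at every set size); log for
B and A (positivity). C is linear on the *natural* scale: with mean-centered
set size, the fixed group intercept then equals the across-condition mean
exactly, which is what the identifiability constraint asserts; a log-scale C
would only satisfy the constraint approximately. Negative subject-level C
values at an observed set size get zero posterior density (truncation).
Subject parameters are normal around group means; hyperpriors are diffuse
normals on group means (SD 1.5–3 by parameter) and half-normals on
between-subject SDs (scale 0.5–3, wider for C's intercept spread). Recall
trials are excluded from both model fits; the models address the 24 n-AFC
cells.

**Sampling.** Adaptive Metropolis-within-Gibbs, exploiting the model
structure: component-wise random-walk updates of subject parameters vectorized
across subjects (conditionally independent given the group level), conjugate
Gibbs draws for group means, log-scale random walks for group SDs, and two
joint moves that repair the slow directions of hierarchical posteriors — a
(mean, subjects) translation and a (SD, subjects) rescaling that traverses the
funnel. Proposal scales adapt during warmup (targets 0.44 component-wise,
0.234 joint) with diminishing adaptation, then freeze. Defaults: 4 chains,
2000 warmup + 2000 kept draws. Convergence gates: split-R̂ ≤ 1.01 and bulk
ESS ≥ 400 per group-level parameter (ArviZ); violations are reported as
warnings on a flagged summary, not silently ignored. On paper-scale data
(20 subjects × 552 n-AFC trials) a fit takes ~20 s; occasionally the
weakest-identified SD parameter sits slightly below the ESS gate, which the
summary flags.

**Posterior predictives.** For a subsample of posterior draws, category
counts are simulated at each subject × cell's observed trial total; the
predictive mean and central 95% interval are reported next to observed
proportions with a coverage flag. Cells without new candidates predict
p_new = 0 exactly; predictive proportions sum to 1 per cell.

## Synthetic-data generator

The generator inverts either measurement model: subject parameters are drawn
from the group distributions on the transformed scales above (MMM draws are
redrawn until C ≥ 0 at all set sizes), and each trial's category is drawn from
the analytic cell probabilities. One run seed spawns an independent child
stream per subject, so any subject can be re-simulated in isolation,
identically. Word-level sampling (pools, lure positions, concrete choices) is
optional; category-only generation is vectorized per design cell for large
simulations.

Default ground truth — the study conditions for all recovery checks — is 20
subjects, three-session schedule, a clearly negative set-size slope on binding
(−0.35 per item on the logit of Pb; −2 per item on C) and a zero slope on the
item parameter, with moderate between-subject SDs (0.5 on logit intercepts,
0.15 on logit slopes; 0.4 on log A and log B, 2.0 and 0.5 on C's intercept
and slope). These values produce accuracy falling from ~.88 (N=2) to ~.45
(N=8) with new-word rates ~1–5%, the qualitative regime of the task.

Recall is generated as an effective N-AFC: with the small pool, a 16-AFC over
the pool (the current list as effective response set); with the large pool,
an N-AFC over the list, with an optional redintegration-failure probability
(default 0 — identity recovery from degraded traces is not modelled). What
the generator does *not* emulate: response times, serial-position effects
within a list, typing errors in recall (exact-token scoring), fatigue or
session effects, and any similarity structure among words. Passing recovery
tests therefore show that the estimation machinery is faithful to these
generative assumptions, not that the models are true of human data.

## Capacity estimates

K = N·(P(correct) − g)/(1 − g), with the guessing probability g set by the
assumed limit: g = 1/RSS if capacity limits all item information, g =
1/RSS_List if it limits only bindings (item memory restricts the effective
response set), and g = 1/N for recall under the binding-limit reading with
item memory assumed perfect. K is computed per subject × (N, RSS_List,
RSS_New) cell — under the item limit g differs across RSS_New within an
(N, RSS_List) stratum — then averaged over RSS_New. Negative K values
(performance below the assumed chance level) are reported as computed, to
keep averages unbiased. Strata with RSS_List = 1 are excluded under the
binding limit (g would be 1). Note the algebra: K is decreasing in g for
P(correct) < 1, so the binding-limit K is at most the item-limit K in any
cell with new candidates; the diagnostic contrast is *consistency across
strata*, not magnitude.

Condition means carry 95% within-subject confidence intervals: Cousineau
subject-centering (subtract the subject mean, add the grand mean), Morey's
√(J/(J−1)) bias correction for J conditions, and t intervals with
n_subjects − 1 degrees of freedom. Missing cells are an error; imputation is
out of scope.

## Descriptive Bayes factors

Accuracy counts per subject × n-AFC cell enter a binomial logistic model with
fixed main effects of set size, RSS_List and RSS_New, a random subject
intercept, and random slopes for the three main effects and their three
two-way interactions (interactions appear only in the random part; the fixed
part carries the effects under test). Predictors are centered and scaled by
2 SD over the design cells, so coefficients are standardized effect sizes;
they receive Cauchy(0, 0.353) priors (intercept: Cauchy(0, 2.5)), and the
seven random-effect SDs half-Cauchy priors with the same 0.353 scale. The
standardization is recorded and invertible. This default standardization is
an approximation chosen here; it is configurable where a different
standardized-effect-size convention is preferred.

Evidence for a predictor is BF = p(y | full)/p(y | without that fixed effect),
both marginal likelihoods estimated by iterative optimal bridge sampling with
a moment-matched multivariate-normal proposal fitted to half of the posterior
draws. Bridging runs in the non-centered parameterization (u/σ, log σ), which
flattens the scale funnel and makes the posterior near-Gaussian; the marginal
likelihood is invariant to the reparameterization. Each estimate is repeated
(default 3×) with fresh proposal draws; a spread above 0.1 on the log scale
triggers a warning. The estimator is validated against adaptive quadrature on
a one-parameter model (agreement ~10⁻³ on the log scale, gate 2%). The
sensitivity analysis re-fits and re-bridges over a grid of Cauchy scales
(default 0.25–3.0, including the default scale) and reports the BF range.

## Problem sizes and numerical choices

Recovery and acceptance checks run at the design's own scale: 20 subjects,
23 analyzed blocks (552 n-AFC trials per subject). Monte-Carlo validation of
the category probabilities uses 10⁶ draws per parameter × composition cell
(total-variation gate 0.005). Unit-level fits in the test suite use reduced
chains/iterations — they check machinery and calibration, not publication
posteriors. The recovery study in `analysis/06` uses 5 replicates per model;
across them the binding-slope HDI is entirely negative in every replicate,
the item-slope HDI always spans zero, and the probability-scale bias of Pb is
~0.02. Degenerate inputs are rejected early: fits require ≥2 subjects and ≥2
set sizes (slopes are unidentifiable otherwise); empty categories (weight 0)
contribute no likelihood term; a constant predictor yields a zero
standardized column (prior-dominated coefficient) rather than a division by
zero.

## Known limitations

* The samplers are random-walk based; for much larger designs a
  gradient-based sampler would scale better. Convergence gates make the
  trade-off visible rather than hidden.
* Bridge-sampling accuracy degrades if the posterior is far from Gaussian in
  the non-centered parameterization; the repeated-estimate spread is the
  built-in diagnostic.
* B is hierarchical (one per subject with a group mean); a single shared B
  per dataset is not currently exposed as a config switch.
* Model-based capacity estimates (e.g., K derived from MPT posteriors) are
  deliberately not implemented; only the direct formula.
* Real-data use requires mapping the source columns onto the canonical trial
  schema; misspelling-tolerant recall scoring is not provided (exact match
  only) and must be handled upstream.
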