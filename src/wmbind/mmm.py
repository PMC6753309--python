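"""Continuous-strength memory measurement model (MMM) with Luce's choice rule.

Every response candidate carries an activation: baseline ``b`` for all
candidates, plus item-memory strength ``a`` for words from the current list,
plus binding strength ``c`` for the one word bound to the probed position:

    A_correct = b + a + c      A_other = b + a      A_new = b

Choice follows Luce's rule over candidates, which at the category level means
weighting each category's activation by its number of candidates
(1, rss_list - 1, rss_new) and normalizing.

The rule is scale-free — multiplying (b, a, c) by any positive constant leaves
all probabilities unchanged — so one quantity must pin the scale. Here the
across-set-size mean of the group-level binding strength C is fixed to a
constant (default 10): with C modelled as linear in mean-centered set size,
fixing the group intercept at the constant makes the across-condition mean
equal it exactly, and condition effects on binding appear as deviations from
the constant. Baseline ``b`` is estimated freely, which lets it absorb how
familiar the "new" words are (small re-used pools make new words less new).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchical import (
    CellData,
    HierarchicalSpec,
    MCMCConfig,
    PosteriorSummary,
    posterior_predictive,
    prepare_cells,
    run_hierarchical,
)

#: Across-set-size mean of group-level binding strength; pins the Luce scale.
C_CONSTRAINT = 10.0


def mmm_category_probs(b, a, c, rss_list, rss_new):
    """Category probabilities (correct, other_list, new) under Luce's rule.

    Broadcasts over arrays; final axis indexes the categories. Activations
    must be admissible (b > 0, a >= 0, c >= 0); inadmissible entries raise.
    """
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    rss_list = np.asarray(rss_list)
    rss_new = np.asarray(rss_new)
    if np.any(b <= 0) or np.any(a < 0) or np.any(c < 0):
        raise ValueError("need b > 0, a >= 0, c >= 0")
    if np.any(rss_list < 1) or np.any(rss_new < 0):
        raise ValueError("need rss_list >= 1 and rss_new >= 0")
    w_correct = 1.0 * (b + a + c)
    w_other = (rss_list - 1) * (b + a)
    w_new = rss_new * b
    total = w_correct + w_other + w_new
    return np.stack(np.broadcast_arrays(w_correct / total, w_other / total, w_new / total), axis=-1)


def simulate_mmm_choices(b, a, c, rss_list, rss_new, n, rng):
    """Brute-force draw of ``n`` trials by Luce sampling over candidates.

    Builds the candidate-level activation vector (one target, rss_list - 1
    list lures, rss_new new words) and samples candidates with probability
    proportional to activation, returning counts per category. Independent
    generative cross-check of :func:`mmm_category_probs`.
    """
    acts = np.concatenate([
        [b + a + c],
        np.full(rss_list - 1, b + a),
        np.full(rss_new, b),
    ])
    choice = rng.choice(len(acts), size=n, p=acts / acts.sum())
    correct = (choice == 0).sum()
    other = ((choice >= 1) & (choice < rss_list)).sum()
    return np.array([correct, other, n - correct - other])


@dataclass
class MMMParams:
    """Ground-truth or point parameters.

    ``log_b`` and the item-strength intercept/slope live on the log scale
    (guaranteeing positivity); binding strength C is linear in mean-centered
    set size on the natural scale so that the fixed intercept is exactly the
    across-set-size mean.
    """

    log_b: float
    a_intercept: float      # log scale
    a_slope: float          # log scale, per item
    c_intercept: float = C_CONSTRAINT
    c_slope: float = 0.0    # natural scale, per item

    def at_set_size(self, set_size, center: float = 5.0):
        x = np.asarray(set_size, dtype=float) - center
        b = np.exp(self.log_b) * np.ones_like(x)
        a = np.exp(self.a_intercept + self.a_slope * x)
        c = self.c_intercept + self.c_slope * x
        return b, a, c


def _mmm_cell_probs(theta: np.ndarray, cells: CellData) -> np.ndarray:
    """Map theta (S, 5) to cell probabilities (S, n_cells, 3).

    theta columns: log_b, a_intercept, a_slope, c_intercept, c_slope.
    Rows where binding strength goes negative at any observed set size are
    returned as NaN, which the engine treats as zero posterior density.
    """
    x = cells.centered_set_size
    b = np.exp(theta[:, [0]]) * np.ones_like(x)
    a = np.exp(theta[:, [1]] + theta[:, [2]] * x)
    c = theta[:, [3]] + theta[:, [4]] * x
    w_correct = b + a + c
    w_other = (cells.rss_list - 1) * (b + a)
    w_new = cells.rss_new * b
    total = w_correct + w_other + w_new
    probs = np.stack([w_correct / total, w_other / total, w_new / total], axis=-1)
    invalid = (c < 0).any(axis=1)
    probs[invalid] = np.nan
    return probs


def make_mmm_spec(c_constraint: float = C_CONSTRAINT) -> HierarchicalSpec:
    """Hierarchical spec with the group-level C intercept pinned."""
    return HierarchicalSpec(
        name="mmm",
        param_names=("log_b", "a_intercept", "a_slope", "c_intercept", "c_slope"),
        cell_probs=_mmm_cell_probs,
        prior_mean_loc=(0.0, 0.0, 0.0, c_constraint, 0.0),
        prior_mean_scale=(2.0, 2.0, 1.0, 1.0, 2.0),
        sd_scale=(1.0, 1.0, 0.5, 3.0, 1.5),
        fixed_mean={"c_intercept": c_constraint},
    )


def fit_mmm(
    data: pd.DataFrame,
    config: MCMCConfig | None = None,
    c_constraint: float = C_CONSTRAINT,
) -> PosteriorSummary:
    """Hierarchical Bayesian fit of the MMM to trial-level n-AFC data.

    Same data contract as :func:`wmbind.mpt.fit_mpt`. The group-level C
    intercept is fixed at ``c_constraint``; by construction the across-set-size
    mean of the reported group-level C equals the constraint exactly. Returns
    posterior summaries including per-set-size group means of A and C and the
    baseline B.
    """
    config = config or MCMCConfig()
    cells = prepare_cells(data)
    spec = make_mmm_spec(c_constraint)
    summary = run_hierarchical(spec, cells, config)
    draws = summary.group_draws
    rows = []
    set_sizes = np.unique(cells.set_sizes)
    for n in set_sizes:
        x = n - cells.center
        a = np.exp(draws["mu_a_intercept"] + draws["mu_a_slope"] * x)
        c = c_constraint + draws["mu_c_slope"] * x
        for label, vals in (("A", a), ("C", c)):
            lo, hi = np.quantile(vals, [0.025, 0.975])
            rows.append(dict(parameter=label, set_size=int(n), mean=vals.mean(),
                             hdi_lower=lo, hdi_upper=hi))
    b = np.exp(draws["mu_log_b"])
    lo, hi = np.quantile(b, [0.025, 0.975])
    rows.append(dict(parameter="B", set_size=0, mean=b.mean(), hdi_lower=lo, hdi_upper=hi))
    summary.condition_means = pd.DataFrame(rows)
    return summary


def group_c_by_set_size(fit: PosteriorSummary, set_sizes=(2, 4, 6, 8),
                        c_constraint: float = C_CONSTRAINT) -> np.ndarray:
    """Posterior-mean group-level binding strength C at each set size."""
    slope = fit.group_draws["mu_c_slope"].mean()
    x = np.asarray(set_sizes, dtype=float) - fit.center
    return c_constraint + slope * x


def mmm_posterior_predictive(fit: PosteriorSummary, data: pd.DataFrame, n_draws: int = 500,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Posterior-predictive category proportions per subject x condition cell."""
    return posterior_predictive(make_mmm_spec(), fit, prepare_cells(data),
                                n_draws=n_draws, rng=rng)
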