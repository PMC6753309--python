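"""Discrete-state multinomial process tree (MPT) for n-AFC list memory.

The tree has two latent memory states. With probability ``pb`` the
item-position binding at the probed position is intact and the correct word is
chosen outright. Otherwise, with probability ``pi`` item memory is available:
the chooser restricts guessing to the response candidates that come from the
current list (uniformly over the ``rss_list`` list candidates). With
probability ``(1-pb)(1-pi)`` neither source is available and the guess is
uniform over the full response set of ``rss = rss_list + rss_new`` candidates.

Collapsing branches into the three observable categories (correct word, other
list word, new word):

    p_correct = pb + (1-pb) * (pi/rss_list + (1-pi)/rss)
    p_other   = (1-pb) * (rss_list-1) * (pi/rss_list + (1-pi)/rss)
    p_new     = (1-pb) * (1-pi) * rss_new/rss

In the hierarchical fit, each subject carries an intercept and a linear slope
on mean-centered memory set size for logit(pb) and logit(pi); group-level
normal distributions tie subjects together, and the group slope posteriors
answer whether set size degrades binding memory, item memory, or both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierarchical import (
    CellData,
    HierarchicalSpec,
    MCMCConfig,
    PosteriorSummary,
    posterior_predictive,
    prepare_cells,
    run_hierarchical,
)


def mpt_category_probs(pb, pi, rss_list, rss_new):
    """Analytic category probabilities (correct, other_list, new) of the tree.

    Broadcasts over array inputs; the final axis of the result indexes the
    three categories. Raises if any probability parameter lies outside [0, 1].
    """
    pb = np.asarray(pb, dtype=float)
    pi = np.asarray(pi, dtype=float)
    rss_list = np.asarray(rss_list)
    rss_new = np.asarray(rss_new)
    if np.any((pb < 0) | (pb > 1)) or np.any((pi < 0) | (pi > 1)):
        raise ValueError("pb and pi must lie in [0, 1]")
    if np.any(rss_list < 1) or np.any(rss_new < 0):
        raise ValueError("need rss_list >= 1 and rss_new >= 0")
    rss = rss_list + rss_new
    guess_correct = pi / rss_list + (1 - pi) / rss
    p_correct = pb + (1 - pb) * guess_correct
    p_other = (1 - pb) * (rss_list - 1) * guess_correct
    p_new = (1 - pb) * (1 - pi) * rss_new / rss
    return np.stack(np.broadcast_arrays(p_correct, p_other, p_new), axis=-1)


def simulate_mpt_branches(pb, pi, rss_list, rss_new, n, rng):
    """Brute-force draw of ``n`` trials by walking the branch process.

    Samples the latent binding and item states as Bernoulli variables and then
    guesses uniformly over the appropriate candidate set, returning counts of
    (correct, other_list, new). Serves as a generative cross-check of
    :func:`mpt_category_probs`; the two must agree in distribution.
    """
    rss = rss_list + rss_new
    binding = rng.random(n) < pb
    item = rng.random(n) < pi
    # candidate index: 0 = target, 1..rss_list-1 = list lures, rest = new
    guess_list = rng.integers(0, rss_list, size=n)
    guess_any = rng.integers(0, rss, size=n)
    choice = np.where(binding, 0, np.where(item, guess_list, guess_any))
    correct = (choice == 0).sum()
    other = ((choice >= 1) & (choice < rss_list)).sum()
    new = (choice >= rss_list).sum()
    return np.array([correct, other, new])


@dataclass
class MPTParams:
    """Ground-truth or point parameters on the logit scale.

    ``pb_intercept``/``pi_intercept`` are logits at the mean set size;
    the slopes are per-item changes in the logit with memory set size.
    """

    pb_intercept: float
    pb_slope: float
    pi_intercept: float
    pi_slope: float

    def at_set_size(self, set_size, center: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(set_size, dtype=float) - center
        return (
            expit(self.pb_intercept + self.pb_slope * x),
            expit(self.pi_intercept + self.pi_slope * x),
        )


def _mpt_cell_probs(theta: np.ndarray, cells: CellData) -> np.ndarray:
    """Map subject parameter matrix (S, 4) to cell probabilities (S, n_cells, 3).

    theta columns: pb intercept, pb slope, pi intercept, pi slope (logit scale).
    """
    x = cells.centered_set_size  # (n_cells,)
    pb = expit(theta[:, [0]] + theta[:, [1]] * x)
    pi = expit(theta[:, [2]] + theta[:, [3]] * x)
    return mpt_category_probs(pb, pi, cells.rss_list, cells.rss_new)


MPT_SPEC = HierarchicalSpec(
    name="mpt",
    param_names=("pb_intercept", "pb_slope", "pi_intercept", "pi_slope"),
    cell_probs=_mpt_cell_probs,
    prior_mean_loc=(0.0, 0.0, 0.0, 0.0),
    prior_mean_scale=(3.0, 1.5, 3.0, 1.5),
    sd_scale=(1.0, 0.5, 1.0, 0.5),
)


def fit_mpt(data: pd.DataFrame, config: MCMCConfig | None = None) -> PosteriorSummary:
    """Hierarchical Bayesian fit of the MPT to trial-level n-AFC data.

    ``data`` is the canonical trial table (one row per trial); recall trials
    and trials flagged ``analyze=False`` are excluded. The likelihood is
    multinomial over (correct, other_list, new) counts per subject x condition
    cell. Returns a :class:`PosteriorSummary` with group-level intercept and
    slope posteriors on the logit scale, back-transformed per-set-size group
    means of Pb and Pi, subject-level estimates and convergence diagnostics.
    """
    config = config or MCMCConfig()
    cells = prepare_cells(data)
    summary = run_hierarchical(MPT_SPEC, cells, config)
    # back-transformed group means of Pb and Pi per set size
    draws = summary.group_draws
    rows = []
    for n in np.unique(cells.set_sizes):
        x = n - cells.center
        for label, ic, sl in (("Pb", "pb_intercept", "pb_slope"), ("Pi", "pi_intercept", "pi_slope")):
            vals = expit(draws[f"mu_{ic}"] + draws[f"mu_{sl}"] * x)
            lo, hi = np.quantile(vals, [0.025, 0.975])
            rows.append(dict(parameter=label, set_size=int(n), mean=vals.mean(),
                             hdi_lower=lo, hdi_upper=hi))
    summary.condition_means = pd.DataFrame(rows)
    return summary


def mpt_posterior_predictive(fit: PosteriorSummary, data: pd.DataFrame, n_draws: int = 500,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Posterior-predictive category proportions per subject x condition cell."""
    return posterior_predictive(MPT_SPEC, fit, prepare_cells(data), n_draws=n_draws, rng=rng)
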