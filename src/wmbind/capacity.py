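"""Discrete-capacity estimates K under competing guessing assumptions.

If memory holds a discrete number of items, capacity can be expressed as

    K = N * (P(correct) - g) / (1 - g)

where N is the memory set size, P(correct) the proportion correct, and g the
probability of guessing the correct response when memory fails. What g should
be depends on what the capacity limit is assumed to limit:

* item limit: memory failure leaves no information at all, so guessing is
  uniform over the full response set — g = 1/RSS;
* binding limit: only the item-position binding is lost; item memory still
  restricts guessing to the list candidates — g = 1/RSS_List;
* recall (binding limit, item memory assumed perfect): the effective response
  set is the memory list itself — g = 1/N.

If the binding-limit reading is right, K computed with g = 1/RSS_List should
agree across response-set compositions, while the item-limit K diverges.

Negative K (performance below the assumed chance level) is reported as
computed, not clipped, so that averages remain unbiased.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ASSUMPTIONS = ("item_limit", "binding_limit", "recall")


def estimate_k(p_correct, n, g):
    """K = N (P(correct) - g)/(1 - g); broadcasts over array inputs."""
    p_correct = np.asarray(p_correct, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((p_correct < 0) | (p_correct > 1)):
        raise ValueError("p_correct must lie in [0, 1]")
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("guessing probability g must lie in (0, 1)")
    return n * (p_correct - g) / (1 - g)


def k_by_condition(data: pd.DataFrame, assumption: str) -> pd.DataFrame:
    """Per-subject K estimates stratified by set size and RSS_List.

    For the n-AFC assumptions, the proportion correct is aggregated per
    subject x (N, rss_list, rss_new) cell and converted with that cell's g
    (g = 1/RSS differs across rss_new under the item limit), then averaged
    over rss_new to one K per (subject, N, rss_list) stratum. The ``recall``
    assumption uses the recall trials with g = 1/N (rss_list reported as 0).
    Strata where g would reach 1 (rss_list = 1 under the binding limit) are
    excluded; empty strata are simply absent.

    Returns a tidy frame: subject, set_size, rss_list, assumption, g
    (trial-weighted mean over the aggregated cells), p_correct, n_trials, k.
    """
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"assumption must be one of {ASSUMPTIONS}")
    df = data
    if "analyze" in df.columns:
        df = df[df["analyze"]]
    if assumption == "recall":
        df = df[df["is_recall"].astype(bool)]
    else:
        df = df[~df["is_recall"].astype(bool)]
        if assumption == "binding_limit":
            n_drop = int((df["rss_list"] == 1).sum())
            if n_drop:
                logger.info("binding_limit: dropping %d trials with rss_list=1 (g would be 1)",
                            n_drop)
            df = df[df["rss_list"] > 1]
    if df.empty:
        raise ValueError(f"no trials available for assumption {assumption!r}")

    grouped = (
        df.assign(correct=df["response_category"].eq("correct"))
        .groupby(["subject", "set_size", "rss_list", "rss_new"], as_index=False)
        .agg(p_correct=("correct", "mean"), n_trials=("correct", "size"))
    )
    n = grouped["set_size"].to_numpy(dtype=float)
    if assumption == "item_limit":
        g = 1.0 / (grouped["rss_list"] + grouped["rss_new"])
    elif assumption == "binding_limit":
        g = 1.0 / grouped["rss_list"]
    else:
        g = 1.0 / grouped["set_size"]
    grouped["g"] = np.asarray(g, dtype=float)
    grouped["k"] = estimate_k(grouped["p_correct"], n, grouped["g"])

    def _wmean(frame, col):
        return np.average(frame[col], weights=frame["n_trials"])

    out = (
        grouped.groupby(["subject", "set_size", "rss_list"])
        .apply(lambda f: pd.Series({
            "g": _wmean(f, "g"),
            "p_correct": _wmean(f, "p_correct"),
            "n_trials": f["n_trials"].sum(),
            "k": np.mean(f["k"]),
        }), include_groups=False)
        .reset_index()
    )
    out["assumption"] = assumption
    if assumption == "recall":
        out["rss_list"] = 0
    return out[["subject", "set_size", "rss_list", "assumption", "g",
                "p_correct", "n_trials", "k"]]


def within_subject_ci(matrix: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Within-subject confidence intervals for condition means.

    ``matrix`` is subjects x conditions (complete, no missing cells). Applies
    Cousineau subject-centering — subtract each subject's mean, add the grand
    mean — which removes pure between-subject variance, then the Morey
    bias correction sqrt(J/(J-1)) for J conditions, and t-based intervals with
    n_subjects - 1 degrees of freedom.

    Returns one row per condition: mean, ci_lower, ci_upper, half_width.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing cells; imputation is out of scope")
    n_subj, n_cond = matrix.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_cond < 2:
        raise ValueError("within-subject correction undefined for a single condition")
    values = matrix.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True) + values.mean()
    morey = np.sqrt(n_cond / (n_cond - 1))
    sd = centered.std(axis=0, ddof=1) * morey
    sem = sd / np.sqrt(n_subj)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n_subj - 1)
    mean = values.mean(axis=0)
    half = tcrit * sem
    return pd.DataFrame({
        "condition": list(matrix.columns),
        "mean": mean,
        "ci_lower": mean - half,
        "ci_upper": mean + half,
        "half_width": half,
    })


def k_summary(k_table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Condition-level mean K with within-subject CIs from a k_by_condition table."""
    wide = k_table.pivot_table(index="subject", columns=["set_size", "rss_list"],
                               values="k")
    if wide.isna().any().any():
        # subjects missing a stratum cannot enter the within-subject correction
        wide = wide.dropna(axis=0)
    ci = within_subject_ci(wide, level=level)
    ci[["set_size", "rss_list"]] = pd.DataFrame(ci["condition"].tolist(), index=ci.index)
    ci["assumption"] = k_table["assumption"].iloc[0]
    return ci.drop(columns=["condition"])
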