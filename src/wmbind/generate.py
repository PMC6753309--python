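"""Synthetic trial-level data from known ground truth.

Generates responses for the full experimental design from either measurement
model's generative process, so that every downstream stage (descriptive
analysis, model fits, capacity estimation, Bayes factors) can be exercised and
validated against known parameters without any external data.

Subject-level parameters are drawn from group-level normal distributions on
the models' transformed scales (logit for the MPT probabilities, log for the
MMM's B and A, natural scale for C around the fixed constraint), then each
trial's response category is drawn from the analytic category probabilities at
that subject's parameters and that trial's response-set composition.

Recall trials are generated as an effective N-AFC: with a small re-used pool
the whole pool acts as the nominal response set (16-AFC with the current list
as the effective set); with a large pool the effective response set is the
current list itself, optionally thinned by a redintegration-failure
probability (default 0 — identity recovery is not modelled).

Seeding: one global seed spawns an independent child stream per subject, so
subjects can be simulated in any order (or in isolation) with identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_SMALL_POOL,
    Condition,
    TrialSpec,
    WordPool,
    build_schedule,
    sample_trial_words,
)
from .mpt import MPTParams, mpt_category_probs
from .mmm import MMMParams, mmm_category_probs

CATEGORIES = ("correct", "other_list", "new")

#: Default between-subject SDs on the transformed scales.
DEFAULT_SD_MPT = {"pb_intercept": 0.5, "pb_slope": 0.15, "pi_intercept": 0.5, "pi_slope": 0.15}
DEFAULT_SD_MMM = {"log_b": 0.4, "a_intercept": 0.4, "a_slope": 0.1,
                  "c_intercept": 2.0, "c_slope": 0.5}


@dataclass
class GroundTruth:
    """Group-level generative parameters for a simulated experiment.

    ``group`` holds the group means (an :class:`~wmbind.mpt.MPTParams` or
    :class:`~wmbind.mmm.MMMParams`); ``sd`` the between-subject SDs per field
    on the same transformed scale. ``model`` is inferred from ``group``.
    """

    group: MPTParams | MMMParams
    sd: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 20
    seed: int = 0
    pool_mode: str = "large"
    recall_failure_prob: float = 0.0

    @property
    def model(self) -> str:
        return "mpt" if isinstance(self.group, MPTParams) else "mmm"

    def __post_init__(self) -> None:
        if not isinstance(self.group, (MPTParams, MMMParams)):
            raise ValueError("group must be MPTParams or MMMParams")
        defaults = DEFAULT_SD_MPT if self.model == "mpt" else DEFAULT_SD_MMM
        unknown = set(self.sd) - set(defaults)
        if unknown:
            raise ValueError(f"unknown sd fields: {sorted(unknown)}")
        self.sd = {**defaults, **self.sd}
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("between-subject SDs must be nonnegative")
        if not 0 <= self.recall_failure_prob <= 1:
            raise ValueError("recall_failure_prob must be a probability")


def draw_subject_params(truth: GroundTruth, rng: np.random.Generator,
                        set_sizes=(2, 4, 6, 8), center: float = 5.0):
    """Draw one subject's parameters from the group distribution.

    MMM draws are redrawn until binding strength is nonnegative at every
    set size (truncation matching the fitted model's constraint).
    """
    g = truth.group
    fields = list(truth.sd)
    for _ in range(1000):
        vals = {f: getattr(g, f) + truth.sd[f] * rng.standard_normal() for f in fields}
        params = type(g)(**vals)
        if truth.model == "mmm":
            _, _, c = params.at_set_size(np.asarray(set_sizes), center)
            if np.any(c < 0):
                continue
        return params
    raise RuntimeError("could not draw valid subject parameters (check ground truth)")


def _category_probs(params, condition_row, center: float, pool_size: int,
                    pool_mode: str) -> np.ndarray:
    """Analytic (correct, other_list, new) probabilities for one design cell."""
    n = condition_row.set_size
    if condition_row.is_recall:
        # effective composition of the recall test
        rl, rn = (n, pool_size - n) if pool_mode == "small" else (n, 0)
    else:
        rl, rn = condition_row.rss_list, condition_row.rss_new
    if isinstance(params, MPTParams):
        pb, pi = params.at_set_size(n, center)
        return mpt_category_probs(pb, pi, rl, rn)
    b, a, c = params.at_set_size(np.asarray([float(n)]), center)
    return mmm_category_probs(b[0], a[0], c[0], rl, rn)


def categorize_response(trial: TrialSpec, chosen_word: str,
                        pool: WordPool | None = None) -> str:
    """Map a chosen word to its response category.

    n-AFC: membership label of the chosen candidate (a choice outside the
    response set is a data error). Recall: exact-token match against the
    current list (target -> correct, other position -> other_list); anything
    else — a pool word not in the list, or an unknown token — is ``new``.
    """
    if trial.condition.is_recall:
        if chosen_word == trial.target:
            return "correct"
        if chosen_word in trial.list_words:
            return "other_list"
        return "new"
    label = trial.response_set.get(chosen_word)
    if label is None:
        raise ValueError(f"response {chosen_word!r} is not in the trial's response set")
    return {"target": "correct", "list_lure": "other_list", "new": "new"}[label]


def simulate_dataset(
    truth: GroundTruth,
    schedule: pd.DataFrame | None = None,
    words: bool = True,
) -> pd.DataFrame:
    """Simulate the full experiment for all subjects in the ground truth.

    ``schedule`` is a per-subject trial plan from
    :func:`wmbind.design.build_schedule`; if omitted, each subject gets an
    independent plan at the standard three-session schedule. With
    ``words=False`` the word-level sampling is skipped (response categories
    only), which is faster and sufficient for model fitting.

    Returns the canonical tidy trial table, one row per trial.
    """
    if schedule is not None and schedule.empty:
        raise ValueError("schedule must be non-empty")
    pool_size = DEFAULT_SMALL_POOL if truth.pool_mode == "small" else WordPool(mode="large").size
    records: list[dict] = []
    frames: list[pd.DataFrame] = []
    for s in range(truth.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=(s,)))
        params = draw_subject_params(truth, rng)
        plan = schedule if schedule is not None else build_schedule(rng=rng)
        set_sizes = np.unique(plan["set_size"])
        center = float(np.mean(set_sizes))
        pool = WordPool(mode=truth.pool_mode)
        prob_cache: dict[tuple, np.ndarray] = {}
        if not words:
            # fast path: draw all categories per design cell at once
            sub = plan.reset_index(drop=True).copy()
            keys = list(zip(sub["set_size"], sub["rss_list"], sub["rss_new"],
                            sub["is_recall"]))
            sub["_key"] = keys
            cats = np.empty(len(sub), dtype=object)
            for key, idx in sub.groupby("_key", sort=True).groups.items():
                row = sub.loc[idx[0]]
                probs = _category_probs(params, row, center, pool_size, truth.pool_mode)
                draw = rng.choice(3, size=len(idx), p=probs)
                cats[sub.index.get_indexer(idx)] = [CATEGORIES[i] for i in draw]
            if truth.recall_failure_prob > 0:
                recall_mask = sub["is_recall"].to_numpy(dtype=bool)
                fail = rng.random(len(sub)) < truth.recall_failure_prob
                cats[recall_mask & fail] = "new"
            nafc = ~sub["is_recall"].to_numpy(dtype=bool)
            probe = rng.integers(1, sub["set_size"].to_numpy() + 1)
            frame = pd.DataFrame(dict(
                subject=s + 1,
                session=sub["session"].to_numpy(),
                block=sub["block"].to_numpy(),
                trial=sub["trial"].to_numpy(),
                set_size=sub["set_size"].to_numpy(),
                rss_list=np.where(nafc, sub["rss_list"], 0),
                rss_new=np.where(nafc, sub["rss_new"], 0),
                is_recall=sub["is_recall"].to_numpy(dtype=bool),
                analyze=sub["analyze"].to_numpy(dtype=bool),
                response_category=cats,
                probed_position=probe,
                response_word="",
            ))
            frames.append(frame)
            continue
        for row in plan.itertuples(index=False):
            key = (row.set_size, row.rss_list, row.rss_new, row.is_recall)
            if key not in prob_cache:
                prob_cache[key] = _category_probs(params, row, center, pool_size,
                                                 truth.pool_mode)
            probs = prob_cache[key]
            cat_idx = rng.choice(3, p=probs)
            category = CATEGORIES[cat_idx]
            if row.is_recall and truth.recall_failure_prob > 0:
                if rng.random() < truth.recall_failure_prob:
                    category = "new"  # redintegration failure: no list word produced
            rec = dict(
                subject=s + 1,
                session=row.session,
                block=row.block,
                trial=row.trial,
                set_size=row.set_size,
                rss_list=0 if row.is_recall else row.rss_list,
                rss_new=0 if row.is_recall else row.rss_new,
                is_recall=row.is_recall,
                analyze=row.analyze,
                response_category=category,
                probed_position=0,
                response_word="",
            )
            if words:
                cond_rl = row.rss_list if not row.is_recall else 0
                cond_rn = row.rss_new if not row.is_recall else 0
                cond = Condition(set_size=row.set_size, rss_list=cond_rl,
                                 rss_new=cond_rn, is_recall=bool(row.is_recall))
                spec = sample_trial_words(pool, cond, rng)
                rec["probed_position"] = spec.probed_position
                rec["response_word"] = _choose_word(spec, category, pool, rng)
            else:
                rec["probed_position"] = int(rng.integers(1, row.set_size + 1))
            records.append(rec)
    if records:
        frames.append(pd.DataFrame(records))
    return pd.concat(frames, ignore_index=True)[
        ["subject", "session", "block", "trial", "set_size", "rss_list", "rss_new",
         "is_recall", "analyze", "response_category", "probed_position", "response_word"]
    ]


def _choose_word(spec: TrialSpec, category: str, pool: WordPool,
                 rng: np.random.Generator) -> str:
    """Pick a concrete word consistent with the drawn response category."""
    if category == "correct":
        return spec.target
    if spec.condition.is_recall:
        if category == "other_list":
            others = [w for w in spec.list_words if w != spec.target]
            return others[rng.integers(len(others))]
        extra = [t for t in pool.tokens if t not in spec.list_words]
        return extra[rng.integers(len(extra))] if extra else "x-unknown"
    members = [w for w, lab in spec.response_set.items()
               if lab == {"other_list": "list_lure", "new": "new"}[category]]
    return members[rng.integers(len(members))]
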