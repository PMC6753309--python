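"""Experimental design: conditions, word pools, response sets, trial schedules.

The task is an n-alternative forced-choice (n-AFC) test of memory for word
lists. On each trial a list of N words (N in {2, 4, 6, 8}) is presented, one
word per list position; a randomly chosen position is probed and the
participant selects the word that occupied it from a response set composed of
``rss_list`` words from the current list (always including the target) and
``rss_new`` words not in the list. A tenth test condition replaces the choice
display with typed recall.

Crossing set size with the nine feasible response-set compositions leaves some
cells structurally empty (a composition requires rss_list <= N), giving
3 + 5 + 7 + 9 = 24 n-AFC cells plus one recall cell per set size: 28 in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The nine response-set compositions, coded [rss_list, rss_new], in canonical order.
RSS_COMPOSITIONS: tuple[tuple[int, int], ...] = (
    (1, 1), (2, 0), (2, 2), (4, 0), (4, 4), (6, 0), (6, 4), (8, 0), (8, 4),
)

#: Memory set sizes used in the design.
SET_SIZES: tuple[int, ...] = (2, 4, 6, 8)

DEFAULT_LARGE_POOL = 1198
DEFAULT_SMALL_POOL = 16


@dataclass(frozen=True)
class Condition:
    """One design cell: a memory set size plus a test condition.

    For n-AFC cells the test condition is the response-set composition
    ``[rss_list, rss_new]``; for recall cells ``is_recall`` is set and the
    composition fields are ignored (stored as 0).
    """

    set_size: int
    rss_list: int = 0
    rss_new: int = 0
    is_recall: bool = False

    def __post_init__(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValueError(f"set_size must be one of {SET_SIZES}, got {self.set_size}")
        if not self.is_recall:
            if (self.rss_list, self.rss_new) not in RSS_COMPOSITIONS:
                raise ValueError(
                    f"[{self.rss_list},{self.rss_new}] is not a valid response-set composition"
                )
            if self.rss_list > self.set_size:
                raise ValueError(
                    f"rss_list={self.rss_list} infeasible at set_size={self.set_size}"
                )

    @property
    def rss(self) -> int:
        """Total response-set size (n-AFC cells only)."""
        return self.rss_list + self.rss_new


def enumerate_conditions() -> list[Condition]:
    """Enumerate all 28 feasible design cells in deterministic order.

    Order: set size ascending; within a set size, the n-AFC compositions in
    canonical order followed by the recall cell. Per-set-size n-AFC counts are
    3 (N=2), 5 (N=4), 7 (N=6) and 9 (N=8).
    """
    cells: list[Condition] = []
    for n in SET_SIZES:
        for rl, rn in RSS_COMPOSITIONS:
            if rl <= n:
                cells.append(Condition(set_size=n, rss_list=rl, rss_new=rn))
        cells.append(Condition(set_size=n, is_recall=True))
    return cells


def select_list_lures(
    list_length: int,
    probed_position: int,
    rss_list: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Choose the list positions entering the response set, nearest-first.

    List items are ranked by absolute positional distance to the probed
    position and the first ``rss_list`` positions are taken (the probed
    position itself, at distance 0, is always first). Distance ties — a
    neighbour on either side — are broken uniformly at random. Ranking by
    distance keeps the mean lure distance from growing with set size, which
    would otherwise dilute the set-size effect because confusions concentrate
    on near neighbours.

    Returns a 1-based position array of length ``rss_list`` whose first
    element is the probed position.
    """
    if not 1 <= probed_position <= list_length:
        raise ValueError(f"probed_position {probed_position} outside 1..{list_length}")
    if rss_list > list_length:
        raise ValueError(f"rss_list={rss_list} exceeds list length {list_length}")
    if rng is None:
        rng = np.random.default_rng()
    positions = np.arange(1, list_length + 1)
    dist = np.abs(positions - probed_position)
    # random tie-break: sort by (distance, random key)
    order = np.lexsort((rng.random(list_length), dist))
    return positions[order][:rss_list]


@dataclass
class WordPool:
    """A pool of word tokens with the sampling semantics of the two experiments.

    * ``large`` mode: tokens are drawn without replacement *across* trials;
      only when the pool is exhausted is it reinstated in full, so a token
      reappears only after every other token has been used.
    * ``small`` mode: a per-participant pool of exactly 16 tokens, reinstated
      after every trial, so the same words recur constantly.

    Tokens are synthetic identifiers (``w0000`` ...), standing in for the
    word materials of the original design.
    """

    mode: str = "large"
    size: int | None = None
    tokens_init: list[str] | None = None
    _tokens: list[str] = field(init=False, repr=False)
    _remaining: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("large", "small"):
            raise ValueError("mode must be 'large' or 'small'")
        if self.tokens_init is not None:
            if len(set(self.tokens_init)) != len(self.tokens_init):
                raise ValueError("pool tokens must be unique")
            self.size = len(self.tokens_init)
        elif self.size is None:
            self.size = DEFAULT_LARGE_POOL if self.mode == "large" else DEFAULT_SMALL_POOL
        if self.mode == "small" and self.size != DEFAULT_SMALL_POOL:
            raise ValueError("small-pool mode uses exactly 16 tokens")
        self._tokens = (
            list(self.tokens_init)
            if self.tokens_init is not None
            else [f"w{i:04d}" for i in range(self.size)]
        )
        self._remaining = list(self._tokens)

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    def draw(self, n: int, rng: np.random.Generator, exclude: set[str] | None = None) -> list[str]:
        """Draw ``n`` distinct tokens under the pool's replacement policy.

        ``exclude`` holds tokens already drawn on the current trial, kept
        disjoint even across a reinstatement boundary.
        """
        exclude = set() if exclude is None else set(exclude)
        if n > self.size - len(exclude):
            raise ValueError("pool too small for requested draw")
        drawn: list[str] = []
        while len(drawn) < n:
            candidates = [t for t in self._remaining if t not in exclude]
            if not candidates:
                self._remaining = list(self._tokens)  # reinstate in full
                continue
            k = min(n - len(drawn), len(candidates))
            picks = rng.choice(len(candidates), size=k, replace=False)
            for i in picks:
                tok = candidates[i]
                drawn.append(tok)
                exclude.add(tok)
                self._remaining.remove(tok)
        return drawn

    def end_trial(self) -> None:
        """Apply the per-trial replacement policy (small mode reinstates)."""
        if self.mode == "small":
            self._remaining = list(self._tokens)


@dataclass
class TrialSpec:
    """A fully specified trial before the response is generated.

    ``response_set`` maps token -> membership label in
    {"target", "list_lure", "new"}; it is empty for recall trials.
    """

    condition: Condition
    list_words: list[str]
    probed_position: int
    response_set: dict[str, str]

    @property
    def target(self) -> str:
        return self.list_words[self.probed_position - 1]


def sample_trial_words(
    pool: WordPool, condition: Condition, rng: np.random.Generator
) -> TrialSpec:
    """Draw list words, probe position, lure positions and new words for a trial.

    The probed position is uniform over 1..N. List lures come from
    :func:`select_list_lures`; new words continue the pool's no-replacement
    stream and are disjoint from the list words within the trial.
    """
    n = condition.set_size
    list_words = pool.draw(n, rng)
    probed = int(rng.integers(1, n + 1))
    response_set: dict[str, str] = {}
    if not condition.is_recall:
        lure_positions = select_list_lures(n, probed, condition.rss_list, rng)
        for pos in lure_positions:
            word = list_words[pos - 1]
            response_set[word] = "target" if pos == probed else "list_lure"
        for word in pool.draw(condition.rss_new, rng, exclude=set(list_words)):
            response_set[word] = "new"
    pool.end_trial()
    return TrialSpec(
        condition=condition,
        list_words=list_words,
        probed_position=probed,
        response_set=response_set,
    )


def build_schedule(
    n_sessions: int = 3,
    blocks_per_session: tuple[int, ...] = (7, 8, 8),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the trial schedule for one participant.

    Session 1 opens with 28 practice trials (one per design cell, shuffled);
    later sessions open with 5 warm-up trials drawn at random (with
    replacement) from the 28 cells. Every test block is a fresh random
    permutation of the 28 cells. Practice and warm-up trials carry
    ``analyze=False`` so the analysis stages can reproduce their exclusion.

    Returns a tidy frame with columns session, block, trial, set_size,
    rss_list, rss_new, is_recall, analyze (block 0 = practice/warm-up).
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(blocks_per_session) != n_sessions:
        raise ValueError("blocks_per_session must have one entry per session")
    cells = enumerate_conditions()
    rows: list[dict] = []

    def add(cond: Condition, session: int, block: int, trial: int, analyze: bool) -> None:
        rows.append(
            dict(
                session=session,
                block=block,
                trial=trial,
                set_size=cond.set_size,
                rss_list=cond.rss_list,
                rss_new=cond.rss_new,
                is_recall=cond.is_recall,
                analyze=analyze,
            )
        )

    for session in range(1, n_sessions + 1):
        trial = 1
        if session == 1:
            for i in rng.permutation(len(cells)):
                add(cells[i], session, 0, trial, False)
                trial += 1
        else:
            for i in rng.integers(0, len(cells), size=5):
                add(cells[i], session, 0, trial, False)
                trial += 1
        for block in range(1, blocks_per_session[session - 1] + 1):
            for i in rng.permutation(len(cells)):
                add(cells[i], session, block, trial, True)
                trial += 1
    return pd.DataFrame(rows)
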