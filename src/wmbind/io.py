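"""Canonical file schemas, configuration and run plumbing.

The trial table is a tidy CSV with one row per trial:

    subject, session, block, trial, set_size, rss_list, rss_new, is_recall,
    probed_position, analyze, response_category[, response_word]

``response_category`` is one of correct / other_list / new. ``analyze`` marks
trials entering the analysis (practice and warm-up trials are stored but
flagged False). All stage seeds are derived deterministically from one run
seed via seed-sequence spawning.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "subject", "session", "block", "trial", "set_size", "rss_list", "rss_new",
    "is_recall", "probed_position", "analyze", "response_category",
]
VALID_CATEGORIES = {"correct", "other_list", "new"}


class SchemaError(ValueError):
    """A trial table violating the documented schema; names offending rows."""


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a canonical trial CSV."""
    df = pd.read_csv(path)
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and per-row invariants; raises SchemaError with row numbers."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.copy()
    for col in ("is_recall", "analyze"):
        df[col] = df[col].astype(bool)
    bad = ~df["response_category"].isin(VALID_CATEGORIES)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise SchemaError(f"invalid response_category at rows {rows}")
    nafc = ~df["is_recall"]
    bad = nafc & (df["rss_list"] > df["set_size"])
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise SchemaError(f"rss_list exceeds set_size at rows {rows}")
    bad = nafc & df["response_category"].eq("new") & (df["rss_new"] < 1)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise SchemaError(f"'new' response without new candidates at rows {rows}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table; round-trips through read_trials unchanged."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; loadable from YAML."""

    seed: int = 1
    pool_mode: str = "large"
    n_subjects: int = 20
    n_sessions: int = 3
    blocks_per_session: tuple[int, ...] = (7, 8, 8)
    generative_model: str = "mpt"
    truth: dict = field(default_factory=dict)   # overrides for GroundTruth group/sd
    mcmc: dict = field(default_factory=dict)    # MCMCConfig overrides
    bf: dict = field(default_factory=dict)      # BFConfig overrides
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "blocks_per_session" in raw:
            raw["blocks_per_session"] = tuple(raw["blocks_per_session"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["blocks_per_session"] = list(self.blocks_per_session)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """A deterministic child seed for a named pipeline stage."""
        key = sum(ord(ch) * (i + 1) for i, ch in enumerate(stage)) % (2**31)
        return np.random.SeedSequence(self.seed, spawn_key=(key,))
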