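"""Simulate the two synthetic experiments (large-pool and small-pool).

Both experiments run 20 subjects through the standard three-session schedule
(28 practice trials, then 7 + 8 + 8 test blocks of 28 trials, one per design
cell). Ground truth follows the continuous-strength model with a strong
negative set-size slope on binding strength C and no slope on item strength A;
the experiments differ in baseline activation B, which is higher in the
small-pool version where the "new" words are re-used and familiar.

Writes results/analysis/trials_large.csv and trials_small.csv.
"""

import warnings
from pathlib import Path

import numpy as np

from wmbind.generate import GroundTruth, simulate_dataset
from wmbind.io import write_trials
from wmbind.mmm import MMMParams

warnings.filterwarnings("ignore")
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
# trial-level tables are bulky intermediates; they live outside results/
TRIALS = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
SEED = 20240901

TRUTHS = {
    "large": GroundTruth(
        group=MMMParams(log_b=np.log(0.15), a_intercept=np.log(4.0), a_slope=0.0,
                        c_intercept=10.0, c_slope=-2.0),
        n_subjects=20, seed=SEED, pool_mode="large",
    ),
    "small": GroundTruth(
        group=MMMParams(log_b=np.log(1.0), a_intercept=np.log(4.0), a_slope=0.0,
                        c_intercept=10.0, c_slope=-2.0),
        n_subjects=20, seed=SEED + 1, pool_mode="small",
    ),
}


def main() -> None:
    for name, truth in TRUTHS.items():
        trials = simulate_dataset(truth, words=False)
        path = TRIALS / f"trials_{name}.csv"
        write_trials(trials, path)
        acc = trials.loc[trials.analyze & ~trials.is_recall, "response_category"].eq("correct").mean()
        print(f"{name}-pool experiment: {len(trials)} trials, "
              f"n-AFC accuracy {acc:.3f} -> {path}")


if __name__ == "__main__":
    main()
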