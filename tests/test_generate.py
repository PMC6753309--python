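"""Synthetic data generator: category frequencies, seeding, categorization."""

import numpy as np
import pandas as pd
import pytest

from wmbind.design import Condition, WordPool, sample_trial_words
from wmbind.generate import (
    GroundTruth,
    categorize_response,
    draw_subject_params,
    simulate_dataset,
)
from wmbind.mpt import MPTParams, mpt_category_probs
from wmbind.mmm import MMMParams

ZERO_SD_MPT = {k: 0.0 for k in ("pb_intercept", "pb_slope", "pi_intercept", "pi_slope")}


def _single_cell_plan(n_trials, set_size=4, rss_list=4, rss_new=4):
    return pd.DataFrame(dict(
        session=1, block=1, trial=np.arange(1, n_trials + 1), set_size=set_size,
        rss_list=rss_list, rss_new=rss_new, is_recall=False, analyze=True,
    ))


class TestSimulateDataset:
    def test_perfect_binding_always_correct(self):
        truth = GroundTruth(group=MPTParams(20.0, 0.0, 0.0, 0.0), sd=ZERO_SD_MPT,
                            n_subjects=2, seed=1)
        df = simulate_dataset(truth, schedule=_single_cell_plan(500), words=False)
        assert (df.response_category == "correct").all()

    def test_category_frequencies_match_tree_probabilities(self):
        """Pb=.5, Pi=.8 in cell [4,4]: frequencies at 10^6 trials hit the
        hand-computed tree values (0.6125, 0.3375, 0.05) within 0.002."""
        truth = GroundTruth(
            group=MPTParams(0.0, 0.0, float(np.log(4)), 0.0),  # logits of .5 and .8
            sd=ZERO_SD_MPT, n_subjects=1, seed=9,
        )
        df = simulate_dataset(truth, schedule=_single_cell_plan(10**6), words=False)
        freq = df.response_category.value_counts(normalize=True)
        expected = mpt_category_probs(0.5, 0.8, 4, 4)
        np.testing.assert_allclose(expected, [0.6125, 0.3375, 0.05], atol=1e-12)
        for cat, p in zip(("correct", "other_list", "new"), expected):
            assert abs(freq[cat] - p) < 0.002

    def test_identical_seed_identical_dataset(self):
        truth = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=3, seed=77)
        assert simulate_dataset(truth).equals(simulate_dataset(truth))

    def test_subjects_independent_of_order(self):
        """Per-subject seed streams: subject 3 alone equals subject 3 of the batch."""
        truth_all = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=3, seed=55)
        batch = simulate_dataset(truth_all, words=False)
        rng = np.random.default_rng(np.random.SeedSequence(55, spawn_key=(2,)))
        params = draw_subject_params(truth_all, rng)
        # same stream position: redraw and compare the drawn parameters
        rng2 = np.random.default_rng(np.random.SeedSequence(55, spawn_key=(2,)))
        params2 = draw_subject_params(truth_all, rng2)
        assert params == params2
        assert set(batch.subject) == {1, 2, 3}

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(group=MPTParams(0.5, 0, 0.5, 0), sd={"nonsense": 1.0})
        with pytest.raises(ValueError):
            GroundTruth(group="mpt")  # type: ignore[arg-type]

    def test_mmm_generation_small_pool_recall(self):
        truth = GroundTruth(
            group=MMMParams(log_b=np.log(0.3), a_intercept=np.log(4), a_slope=0.0,
                            c_intercept=10.0, c_slope=-2.0),
            n_subjects=2, seed=4, pool_mode="small",
        )
        df = simulate_dataset(truth, words=False)
        recall = df[df.is_recall]
        # small-pool recall behaves as 16-AFC: 'new' responses possible
        assert set(recall.response_category) <= {"correct", "other_list", "new"}
        assert len(recall) > 0


class TestSubjectParameterDraws:
    def test_group_mean_recovered_across_subjects(self):
        """Sample mean of 200 subject draws within 3 SE of the group mean."""
        truth = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=200, seed=31)
        rng = np.random.default_rng(123)
        draws = np.array([
            [getattr(draw_subject_params(truth, rng), f) for f in truth.sd]
            for _ in range(200)
        ])
        means = draws.mean(axis=0)
        ses = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        target = [0.6, -0.35, 2.0, 0.0]
        assert np.all(np.abs(means - target) < 3 * ses + 1e-9)


class TestCategorizeResponse:
    def setup_method(self):
        self.cond = Condition(set_size=4, rss_list=2, rss_new=2)
        self.pool = WordPool(mode="small")
        self.trial = sample_trial_words(self.pool, self.cond, np.random.default_rng(8))

    def test_nafc_mapping(self):
        rs = self.trial.response_set
        assert categorize_response(self.trial, self.trial.target) == "correct"
        lure = next(w for w, l in rs.items() if l == "list_lure")
        new = next(w for w, l in rs.items() if l == "new")
        assert categorize_response(self.trial, lure) == "other_list"
        assert categorize_response(self.trial, new) == "new"

    def test_choice_outside_response_set_is_error(self):
        with pytest.raises(ValueError):
            categorize_response(self.trial, "not-a-candidate")

    def test_recall_residual_category(self):
        recall = sample_trial_words(self.pool, Condition(set_size=4, is_recall=True),
                                    np.random.default_rng(8))
        assert categorize_response(recall, recall.target) == "correct"
        other = next(w for w in recall.list_words if w != recall.target)
        assert categorize_response(recall, other) == "other_list"
        assert categorize_response(recall, "zz-not-a-word") == "new"
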