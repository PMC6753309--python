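"""Capacity estimation K and within-subject confidence intervals."""

import numpy as np
import pandas as pd
import pytest

from wmbind.capacity import estimate_k, k_by_condition, k_summary, within_subject_ci
from wmbind.generate import GroundTruth, simulate_dataset
from wmbind.mpt import MPTParams


def _trials(rows):
    base = dict(session=1, block=1, trial=1, is_recall=False, analyze=True,
                probed_position=1)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestEstimateK:
    def test_perfect_memory_gives_n(self):
        for g in (0.1, 0.5, 0.9):
            assert estimate_k(1.0, 8, g) == pytest.approx(8.0)

    def test_chance_performance_gives_zero(self):
        for n, g in ((8, 1 / 8), (4, 0.25), (6, 1 / 3)):
            assert estimate_k(g, n, g) == pytest.approx(0.0)

    def test_spot_value(self):
        assert estimate_k(0.5, 8, 1 / 8) == pytest.approx(24 / 7)

    def test_below_chance_is_negative_not_clipped(self):
        assert estimate_k(0.05, 8, 1 / 8) < 0

    def test_invalid_g_raises(self):
        with pytest.raises(ValueError):
            estimate_k(0.5, 8, 1.0)
        with pytest.raises(ValueError):
            estimate_k(1.5, 8, 0.2)


class TestKByCondition:
    def test_all_correct_gives_k_equal_n(self):
        rows = []
        for subj in (1, 2):
            for n, rl, rn in ((4, 2, 2), (8, 4, 4), (8, 8, 0)):
                rows += [dict(subject=subj, set_size=n, rss_list=rl, rss_new=rn,
                              response_category="correct")] * 10
        df = _trials(rows)
        for assumption in ("item_limit", "binding_limit"):
            out = k_by_condition(df, assumption)
            np.testing.assert_allclose(out["k"], out["set_size"])

    def test_recall_at_chance_gives_zero(self):
        rows = []
        for subj in (1, 2):
            rows += [dict(subject=subj, set_size=4, rss_list=0, rss_new=0,
                          is_recall=True, response_category="correct")] * 1
            rows += [dict(subject=subj, set_size=4, rss_list=0, rss_new=0,
                          is_recall=True, response_category="other_list")] * 3
        out = k_by_condition(_trials(rows), "recall")
        np.testing.assert_allclose(out["k"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["g"], 0.25)

    def test_binding_limit_drops_single_candidate_strata(self):
        rows = [dict(subject=s, set_size=4, rss_list=1, rss_new=1,
                     response_category="correct") for s in (1, 2)]
        rows += [dict(subject=s, set_size=4, rss_list=2, rss_new=2,
                      response_category="correct") for s in (1, 2)]
        out = k_by_condition(_trials(rows), "binding_limit")
        assert (out["rss_list"] > 1).all()

    def test_binding_k_below_item_k_with_new_words(self):
        """K = N(p-g)/(1-g) is decreasing in g for p < 1; with rss_new > 0 the
        binding-limit chance level 1/RSS_List exceeds 1/RSS, so the
        binding-limit K is at most the item-limit K (equal only at p = 1)."""
        truth = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=5, seed=17)
        df = simulate_dataset(truth, words=False)
        df = df[df.rss_new > 0]
        item = k_by_condition(df, "item_limit").set_index(["subject", "set_size", "rss_list"])
        bind = k_by_condition(df, "binding_limit").set_index(["subject", "set_size", "rss_list"])
        joined = item.join(bind, lsuffix="_item", rsuffix="_bind", how="inner")
        assert (joined["k_bind"] <= joined["k_item"] + 1e-9).all()

    def test_binding_limit_converges_across_strata_when_items_perfect(self):
        """With item memory perfect and bindings limited, binding-limit K is
        roughly flat over RSS_List while item-limit K diverges."""
        truth = GroundTruth(group=MPTParams(0.2, 0.0, 12.0, 0.0),
                            sd={"pi_intercept": 0.0, "pi_slope": 0.0},
                            n_subjects=12, seed=23)
        df = simulate_dataset(truth, words=False)
        df = df[df.set_size == 8]
        item = k_by_condition(df, "item_limit").groupby("rss_list")["k"].mean()
        bind = k_by_condition(df, "binding_limit").groupby("rss_list")["k"].mean()
        assert item.max() - item.min() > 2 * (bind.max() - bind.min())

    def test_invariant_to_subject_relabeling_and_order(self):
        truth = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=3, seed=29)
        df = simulate_dataset(truth, words=False)
        shuffled = df.sample(frac=1.0, random_state=1)
        relabeled = shuffled.assign(subject=shuffled.subject.map({1: "c", 2: "a", 3: "b"}))
        a = k_by_condition(df, "item_limit").groupby(["set_size", "rss_list"])["k"].mean()
        b = k_by_condition(relabeled, "item_limit").groupby(["set_size", "rss_list"])["k"].mean()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestWithinSubjectCI:
    def test_pure_between_subject_shift_gives_zero_width(self):
        m = pd.DataFrame([[0.2, 0.5, 0.8], [0.4, 0.7, 1.0]], columns=list("abc"))
        out = within_subject_ci(m)
        np.testing.assert_allclose(out["half_width"], 0.0, atol=1e-12)

    def test_single_condition_is_error(self):
        with pytest.raises(ValueError):
            within_subject_ci(pd.DataFrame({"a": [0.1, 0.2, 0.3]}))

    def test_missing_cells_rejected(self):
        m = pd.DataFrame([[0.2, np.nan], [0.4, 0.7]])
        with pytest.raises(ValueError):
            within_subject_ci(m)

    def test_centering_preserves_condition_means(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((10, 4)), columns=list("wxyz"))
        out = within_subject_ci(m)
        np.testing.assert_allclose(out["mean"], m.mean(axis=0), atol=1e-12)

    def test_summary_pipeline(self):
        truth = GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=4, seed=37)
        df = simulate_dataset(truth, words=False)
        table = k_by_condition(df, "binding_limit")
        out = k_summary(table)
        assert {"mean", "ci_lower", "ci_upper", "set_size", "rss_list"} <= set(out.columns)
        assert (out["ci_upper"] >= out["ci_lower"]).all()
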