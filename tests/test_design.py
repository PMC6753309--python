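"""Design enumeration, lure selection, word pools and scheduling."""

from collections import Counter

import numpy as np
import pytest

from wmbind.design import (
    RSS_COMPOSITIONS,
    Condition,
    WordPool,
    build_schedule,
    enumerate_conditions,
    sample_trial_words,
    select_list_lures,
)


class TestEnumeration:
    def test_counts(self):
        cells = enumerate_conditions()
        nafc = [c for c in cells if not c.is_recall]
        assert len(cells) == 28
        assert len(nafc) == 24
        assert Counter(c.set_size for c in nafc) == {2: 3, 4: 5, 6: 7, 8: 9}
        assert sum(c.is_recall for c in cells) == 4

    def test_set_size_two_cells(self):
        cells = [c for c in enumerate_conditions() if c.set_size == 2 and not c.is_recall]
        assert [(c.rss_list, c.rss_new) for c in cells] == [(1, 1), (2, 0), (2, 2)]

    def test_feasibility_by_construction(self):
        for c in enumerate_conditions():
            if not c.is_recall:
                assert c.rss_list <= c.set_size
                assert (c.rss_list, c.rss_new) in RSS_COMPOSITIONS

    def test_deterministic_order(self):
        assert enumerate_conditions() == enumerate_conditions()

    def test_infeasible_condition_rejected(self):
        with pytest.raises(ValueError):
            Condition(set_size=4, rss_list=6, rss_new=4)
        with pytest.raises(ValueError):
            Condition(set_size=4, rss_list=3, rss_new=0)  # not a listed composition


class TestLureSelection:
    @pytest.mark.parametrize(
        "length,probe,rss_list,expected",
        [(6, 1, 3, {1, 2, 3}), (2, 1, 2, {1, 2}), (6, 6, 2, {6, 5}), (5, 3, 1, {3})],
    )
    def test_forced_orderings(self, length, probe, rss_list, expected):
        rng = np.random.default_rng(0)
        got = select_list_lures(length, probe, rss_list, rng)
        assert set(got.tolist()) == expected
        assert got[0] == probe

    def test_tie_broken_uniformly(self):
        """(6, 3, 4): positions {3,2,4} forced, the tie {1,5} split 50/50."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(10_000):
            got = set(select_list_lures(6, 3, 4, rng).tolist())
            assert {2, 3, 4} <= got
            hits += 1 in got
        assert abs(hits / 10_000 - 0.5) < 0.02

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            select_list_lures(4, 2, 5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            select_list_lures(4, 5, 2, np.random.default_rng(0))

    def test_mean_distance_not_increasing_with_set_size(self):
        """Distance ranking decouples lure distance from list length."""
        rng = np.random.default_rng(11)
        rss_list = 2
        means = []
        for n in (2, 4, 6, 8):
            dists = []
            for _ in range(2000):
                probe = int(rng.integers(1, n + 1))
                got = select_list_lures(n, probe, rss_list, rng)
                dists.extend(abs(p - probe) for p in got[1:])
            means.append(np.mean(dists))
        # nearest-neighbour selection keeps mean distance flat (~1) at all N
        assert max(means) - min(means) < 0.1


class TestWordPool:
    def test_small_pool_has_sixteen_tokens(self):
        assert len(WordPool(mode="small").tokens) == 16
        with pytest.raises(ValueError):
            WordPool(mode="small", size=20)

    def test_small_pool_reinstated_each_trial(self):
        pool = WordPool(mode="small")
        rng = np.random.default_rng(3)
        first = pool.draw(12, rng)
        assert len(set(first)) == 12
        pool.end_trial()
        assert len(pool.draw(16, rng)) == 16  # full pool available again

    def test_large_pool_no_reuse_until_exhausted(self):
        pool = WordPool(mode="large", size=30)
        rng = np.random.default_rng(4)
        seen = []
        for _ in range(3):  # 3 x 10 = the full pool
            seen.extend(pool.draw(10, rng))
            pool.end_trial()
        assert len(set(seen)) == 30
        more = pool.draw(10, rng)  # reinstated: draws repeat earlier tokens
        assert set(more) <= set(seen)

    def test_within_trial_disjoint_across_reinstatement(self):
        pool = WordPool(mode="large", size=10)
        rng = np.random.default_rng(5)
        pool.draw(8, rng)
        pool.end_trial()
        trial = pool.draw(3, rng)  # 2 remaining + 1 past the boundary
        assert len(set(trial)) == 3


class TestTrialSampling:
    def test_trial_words_disjoint(self):
        cond = Condition(set_size=8, rss_list=8, rss_new=4)
        pool = WordPool(mode="small")
        spec = sample_trial_words(pool, cond, np.random.default_rng(6))
        assert len(spec.list_words) == 8
        assert len(spec.response_set) == 12
        labels = Counter(spec.response_set.values())
        assert labels == {"target": 1, "list_lure": 7, "new": 4}
        assert set(w for w, l in spec.response_set.items() if l != "new") <= set(spec.list_words)

    def test_seeded_determinism(self):
        cond = Condition(set_size=4, rss_list=4, rss_new=4)
        a = sample_trial_words(WordPool(), cond, np.random.default_rng(9))
        b = sample_trial_words(WordPool(), cond, np.random.default_rng(9))
        assert a == b


class TestSchedule:
    def test_standard_session_structure(self):
        sched = build_schedule(rng=np.random.default_rng(10))
        s1 = sched[sched.session == 1]
        assert (~s1[s1.block == 0].analyze).all() and len(s1[s1.block == 0]) == 28
        assert len(s1[s1.block > 0]) == 7 * 28
        for s in (2, 3):
            ss = sched[sched.session == s]
            assert len(ss[ss.block == 0]) == 5
            assert len(ss[ss.block > 0]) == 8 * 28
        assert sched.analyze.sum() == (7 + 8 + 8) * 28

    def test_practice_covers_every_cell_once(self):
        sched = build_schedule(rng=np.random.default_rng(12))
        practice = sched[(sched.session == 1) & (sched.block == 0)]
        assert len(practice.drop_duplicates(["set_size", "rss_list", "rss_new", "is_recall"])) == 28

    def test_each_block_is_a_permutation_of_cells(self):
        sched = build_schedule(rng=np.random.default_rng(13))
        for (_, _), block in sched[sched.block > 0].groupby(["session", "block"]):
            assert len(block) == 28
            assert len(block.drop_duplicates(["set_size", "rss_list", "rss_new", "is_recall"])) == 28
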