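import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bksim.evaluation import (
    aggregate_delta_ef,
    delta_ef,
    ef_max,
    enrichment_factor,
    evaluate_screen,
    sign_test,
    subset_size,
    win_loss,
)
from bksim.screening import RankedScreen, RankEntry
from bksim.similarity import SimilarityConfig


def make_screen(flags, query_id="q"):
    """Screen with the given active flags in rank order; similarities
    strictly decreasing so ranks are unambiguous."""
    n = len(flags)
    entries = tuple(
        RankEntry(
            rank=k + 1,
            mol_id=f"m{k}",
            sim_base=1.0 - k / n,
            sim_bind_fp=0.0,
            sim_ext=1.0 - k / n,
            is_active=bool(f),
        )
        for k, f in enumerate(flags)
    )
    return RankedScreen(query_id=query_id, entries=entries,
                        config=SimilarityConfig(alpha=0.0))


class TestEnrichmentFactor:
    def test_half_the_actives_in_top_decile(self):
        flags = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 85
        ef, n_sub, n_act = enrichment_factor(make_screen(flags), 10.0)
        assert (n_sub, n_act) == (10, 5)
        assert ef == pytest.approx(5.0)

    def test_background_rate_gives_one(self):
        flags = [1] + [0] * 9 + [1] * 9 + [0] * 81
        ef, _, _ = enrichment_factor(make_screen(flags), 10.0)
        assert ef == pytest.approx(1.0)

    def test_all_actives_on_top_is_maximal(self):
        flags = [1] * 10 + [0] * 90
        ef, _, _ = enrichment_factor(make_screen(flags), 10.0)
        assert ef == pytest.approx(10.0) == pytest.approx(ef_max(10, 100, 10.0))

    def test_no_actives_rejected(self):
        with pytest.raises(ValueError, match="no actives"):
            enrichment_factor(make_screen([0] * 10), 10.0)

    def test_subset_never_empty(self):
        assert subset_size(50, 1.0) == 1  # floor would give 0

    def test_moving_active_down_never_raises_ef(self):
        flags = [1, 0, 1, 0, 1] + [0] * 15
        base_ef = enrichment_factor(make_screen(flags), 20.0)[0]
        swapped = [1, 0, 1, 1, 0] + [0] * 15  # active moved up within subset
        assert enrichment_factor(make_screen(swapped), 20.0)[0] >= base_ef


class TestEfMax:
    def test_all_actives_fit(self):
        assert ef_max(10, 100, 10.0) == pytest.approx(10.0)

    def test_subset_smaller_than_actives(self):
        # 1% of 1277 compounds is 12 < 35 actives
        assert ef_max(35, 1277, 1.0) == pytest.approx(1277 / 35)

    def test_whole_database(self):
        assert ef_max(10, 100, 100.0) == pytest.approx(1.0)


class TestDeltaEf:
    def test_zero_at_optimum(self):
        assert delta_ef(10.0, 10.0) == 0.0
        assert delta_ef(1.0, 10.0) == 9.0

    def test_inconsistency_rejected(self):
        with pytest.raises(ValueError):
            delta_ef(11.0, 10.0)

    def test_perfect_ranking_zero_at_all_fractions(self):
        flags = [1] * 10 + [0] * 190
        rep = evaluate_screen(make_screen(flags), (1.0, 5.0, 10.0))
        assert all(f.delta_ef == 0.0 for f in rep.fractions)

    def test_bruteforce_top_prefix_optimality(self):
        """Delta_EF is 0 exactly when the top-N prefix holds as many
        actives as any N compounds could, over all small screens."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 30))
            flags = (rng.random(n) < 0.3).astype(int)
            if flags.sum() == 0:
                flags[int(rng.integers(n))] = 1
            screen = make_screen(list(flags))
            for frac in (10.0, 33.0, 50.0):
                n_sub = subset_size(n, frac)
                ef, _, n_act_sub = enrichment_factor(screen, frac)
                em = ef_max(int(flags.sum()), n, frac)
                optimal = n_act_sub == min(int(flags.sum()), n_sub)
                assert (delta_ef(ef, em) == 0.0) == optimal


class TestRandomRankingExpectation:
    def test_mean_ef_near_one_over_shuffles(self):
        rng = np.random.default_rng(42)
        flags = np.array([1] * 25 + [0] * 475)
        efs = []
        for _ in range(400):
            rng.shuffle(flags)
            efs.append(enrichment_factor(make_screen(list(flags)), 10.0)[0])
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)


class TestWinLoss:
    def test_examples(self):
        rec = win_loss([0, 5, 3], [1, 5, 2])
        assert (rec.wins, rec.draws, rec.losses) == (1, 1, 1)
        rec = win_loss([1.0, 1.0], [1.0, 1.0])
        assert rec.draws == 2 and rec.sign_test_p is None
        rec = win_loss([0.9, 0.8], [1.0, 0.9])
        assert rec.wins == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            win_loss([1.0], [1.0, 2.0])

    def test_aggregate(self):
        reps = [
            evaluate_screen(make_screen([1, 0, 0, 1] + [0] * 16), (25.0,))
            for _ in range(3)
        ]
        m, sd = aggregate_delta_ef(reps, 25.0)
        assert sd == 0.0 and m == reps[0].delta(25.0)


class TestSignTest:
    def test_printed_reference_values(self):
        assert sign_test(8, 2) == pytest.approx(0.109375)
        assert sign_test(9, 1) == pytest.approx(0.021484375)

    def test_symmetric_split_gives_one(self):
        assert sign_test(5, 5) == 1.0

    def test_closed_form(self):
        # min(1, 2 * P(X >= max(w, l))), X ~ Binomial(w + l, 1/2)
        for w, l in [(8, 2), (9, 1), (18, 7), (3, 3), (10, 0)]:
            n, k = w + l, max(w, l)
            tail = sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
            assert sign_test(w, l) == pytest.approx(min(1.0, 2 * tail))

    @given(w=st.integers(0, 30), l=st.integers(0, 30))
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_bounds(self, w, l):
        if w + l == 0:
            with pytest.raises(ValueError):
                sign_test(w, l)
        else:
            p = sign_test(w, l)
            assert 0.0 < p <= 1.0
            assert p == pytest.approx(sign_test(l, w))
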