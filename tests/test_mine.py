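"""MINE criterion scoring and panel-selection algorithms."""

from itertools import combinations

import numpy as np
import pytest

from minegwas.mine import (
    CandidatePool,
    _Scorer,
    compare_selectors,
    prediction_moments,
    score_subset,
    select_greedy,
    select_monte_carlo,
    select_nc3plus2,
    select_suboptimal,
)


def make_pool(n, p, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"A{i:02d}" for i in range(n)]
    return CandidatePool(labels, rng.normal(size=(n, p)))


def exhaustive_best(e, pool, p_a, criterion="covariance"):
    sc = _Scorer(e, pool, criterion)
    best = max(combinations(range(pool.size), p_a),
               key=lambda t: sc.logdet(list(t)))
    return list(best), sc.logdet(list(best))


class TestMoments:
    def test_degenerate_ensemble_factorizes(self, ensemble_factory):
        e = ensemble_factory(10, 3, samples=np.tile([1.0, 2.0, 3.0], (10, 1)))
        pool = make_pool(4, 3)
        first, second = prediction_moments(e, pool, pool.accession_ids[:2])
        assert np.allclose(second, np.outer(first, first))

    def test_two_member_arithmetic(self, ensemble_factory):
        # predictions {1, 3} -> E[G] = 2, E[G^2] = 5
        e = ensemble_factory(2, 1, samples=np.array([[1.0], [3.0]]))
        pool = CandidatePool(["x"], np.array([[1.0]]))
        first, second = prediction_moments(e, pool, ["x"])
        assert first[0] == pytest.approx(2.0)
        assert second[0, 0] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, ensemble_factory):
        e = ensemble_factory(5, 4, seed=3)
        pool = make_pool(3, 4, seed=4)
        subset = pool.accession_ids
        first, second = prediction_moments(e, pool, subset)
        preds = np.array([[x @ b for b in e.beta] for x in pool.X_cand])
        for k in range(3):
            assert first[k] == pytest.approx(preds[k].mean())
            for j in range(3):
                assert second[k, j] == pytest.approx(
                    np.mean(preds[k] * preds[j])
                )

    def test_unknown_label_raises(self, ensemble_factory):
        e = ensemble_factory(5, 2)
        pool = make_pool(3, 2)
        with pytest.raises(KeyError):
            prediction_moments(e, pool, ["nope"])


class TestScoreSubset:
    def test_single_candidate_correlation_logdet_zero(self, ensemble_factory):
        e = ensemble_factory(20, 3, seed=1)
        pool = make_pool(4, 3, seed=2)
        ms = score_subset(e, pool, [pool.accession_ids[0]], "correlation")
        assert np.allclose(ms.matrix, [[1.0]])
        assert ms.log_det == pytest.approx(0.0)

    def test_identical_members_hit_floor(self, ensemble_factory):
        e = ensemble_factory(10, 3, samples=np.tile([0.3, -1.0, 2.0], (10, 1)))
        pool = make_pool(4, 3)
        ms = score_subset(e, pool, pool.accession_ids[:2])
        assert np.allclose(ms.matrix, 0.0, atol=1e-12)
        assert ms.log_det < -20  # at the eigenvalue floor

    def test_zero_variance_correlation_rejected(self, ensemble_factory):
        e = ensemble_factory(10, 2, samples=np.tile([1.0, 1.0], (10, 1)))
        pool = make_pool(3, 2)
        with pytest.raises(ValueError, match="zero-variance"):
            score_subset(e, pool, pool.accession_ids[:2], "correlation")

    def test_permutation_invariance(self, ensemble_factory):
        e = ensemble_factory(30, 4, seed=5)
        pool = make_pool(6, 4, seed=6)
        s1 = score_subset(e, pool, ["A01", "A04", "A02"]).log_det
        s2 = score_subset(e, pool, ["A02", "A01", "A04"]).log_det
        assert s1 == pytest.approx(s2)

    @pytest.mark.parametrize("k", [5, 20, 50])
    def test_eigenvalue_logdet_matches_lu(self, rng, k):
        A = rng.normal(size=(k, 2 * k))
        P = A @ A.T / (2 * k)
        from minegwas.mine import _logdet_psd
        ld, _ = _logdet_psd(P)
        _, lu = np.linalg.slogdet(P)
        assert ld == pytest.approx(lu, rel=1e-8)


class TestSuboptimal:
    def test_top_tuple_equals_exhaustive(self, ensemble_factory):
        e = ensemble_factory(30, 4, seed=7)
        pool = make_pool(4, 4, seed=8)
        res = select_suboptimal(e, pool, p_t=3, p_a=3)
        best_idx, best_score = exhaustive_best(e, pool, 3)
        assert sorted(res.selected) == sorted(
            pool.accession_ids[i] for i in best_idx
        )
        assert res.final_score == pytest.approx(best_score)

    def test_matches_enumerate_sort_harvest_oracle(self, ensemble_factory):
        e = ensemble_factory(25, 5, seed=9)
        pool = make_pool(8, 5, seed=10)
        res = select_suboptimal(e, pool, p_t=2, p_a=4)
        sc = _Scorer(e, pool, "covariance")
        order = sorted(range(8), key=lambda i: pool.accession_ids[i])
        scored = sorted(
            ((sc.logdet(list(t)), t) for t in combinations(order, 2)),
            key=lambda x: -x[0],
        )
        picked, seen = [], set()
        for _, t in scored:
            for i in t:
                if i not in seen:
                    seen.add(i)
                    picked.append(pool.accession_ids[i])
                if len(picked) == 4:
                    break
            if len(picked) == 4:
                break
        assert res.selected == picked

    def test_total_tie_is_deterministic(self, ensemble_factory):
        e = ensemble_factory(15, 2, seed=11)
        pool = CandidatePool(["b", "a", "d", "c"], np.tile([0.5, 0.5], (4, 1)))
        r1 = select_suboptimal(e, pool, p_t=2, p_a=2)
        r2 = select_suboptimal(e, pool, p_t=2, p_a=2)
        assert r1.selected == r2.selected == ["a", "b"]

    def test_budget_guard(self, ensemble_factory):
        e = ensemble_factory(5, 2, seed=1)
        pool = make_pool(30, 2, seed=1)
        with pytest.raises(ValueError, match="budget"):
            select_suboptimal(e, pool, p_t=3, p_a=3, tuple_budget=100)


class TestMonteCarlo:
    def test_zero_swaps_returns_initial(self, ensemble_factory):
        e = ensemble_factory(20, 3, seed=13)
        pool = make_pool(10, 3, seed=14)
        res = select_monte_carlo(e, pool, p_a=3, m=0, seed=2)
        assert len(res.selected) == 3
        assert len(res.score_trace) == 1

    def test_finds_exhaustive_optimum_most_seeds(self, ensemble_factory):
        e = ensemble_factory(40, 5, seed=15)
        pool = make_pool(10, 5, seed=16)
        _, best_score = exhaustive_best(e, pool, 3)
        hits = sum(
            np.isclose(
                select_monte_carlo(e, pool, p_a=3, m=2_000, seed=s).final_score,
                best_score, rtol=1e-9,
            )
            for s in range(5)
        )
        assert hits >= 4

    def test_greedy_limit_trace_never_decreases_on_accepts(self, ensemble_factory):
        e = ensemble_factory(20, 3, seed=17)
        pool = make_pool(8, 3, seed=18)
        res = select_monte_carlo(e, pool, p_a=3, m=300, seed=0,
                                 temperature=1e-9)
        trace = np.asarray(res.score_trace)
        assert np.all(np.diff(trace) >= -1e-9)


class TestNc3Plus2:
    def test_per_round_brute_force_oracle(self, ensemble_factory):
        e = ensemble_factory(25, 4, seed=19)
        pool = make_pool(6, 4, seed=20)
        res = select_nc3plus2(e, pool, p_a=5)
        sc = _Scorer(e, pool, "covariance")
        order = sorted(range(6), key=lambda i: pool.accession_ids[i])
        triple = max(combinations(order, 3), key=lambda t: sc.logdet(list(t)))
        rest = [i for i in order if i not in triple]
        doublet = max(
            combinations(rest, 2),
            key=lambda t: sc.logdet(list(triple) + list(t)),
        )
        expected = [pool.accession_ids[i] for i in triple + doublet]
        assert res.selected == expected

    def test_panel_of_tuple_size_reduces_to_top_triple(self, ensemble_factory):
        e = ensemble_factory(25, 4, seed=21)
        pool = make_pool(7, 4, seed=22)
        res = select_nc3plus2(e, pool, p_a=3)
        top = select_suboptimal(e, pool, p_t=3, p_a=3)
        assert sorted(res.selected) == sorted(top.selected)


class TestGreedy:
    def test_one_step_lookahead_oracle(self, ensemble_factory):
        e = ensemble_factory(30, 4, seed=23)
        pool = make_pool(5, 4, seed=24)
        res = select_greedy(e, pool, p_a=4)
        sc = _Scorer(e, pool, "covariance")
        order = sorted(range(5), key=lambda i: pool.accession_ids[i])
        triple = list(max(combinations(order, 3),
                          key=lambda t: sc.logdet(list(t))))
        rest = [i for i in order if i not in triple]
        add = max(rest, key=lambda i: sc.logdet(triple + [i]))
        expected = [pool.accession_ids[i] for i in triple + [add]]
        assert res.selected == expected

    def test_panel_three_is_top_triple(self, ensemble_factory):
        e = ensemble_factory(30, 4, seed=25)
        pool = make_pool(8, 4, seed=26)
        g = select_greedy(e, pool, p_a=3)
        s = select_suboptimal(e, pool, p_t=3, p_a=3)
        assert sorted(g.selected) == sorted(s.selected)

    def test_near_optimal_across_random_ensembles(self, ensemble_factory):
        gaps = []
        for seed in range(20):
            e = ensemble_factory(30, 4, seed=100 + seed)
            pool = make_pool(9, 4, seed=200 + seed)
            sc = _Scorer(e, pool, "covariance")
            scores = [sc.logdet(list(t)) for t in combinations(range(9), 3)]
            lo, hi = min(scores), max(scores)
            g = select_greedy(e, pool, p_a=3)
            gaps.append((hi - g.final_score) / (hi - lo))
        assert max(gaps) <= 0.05


class TestCompareSelectors:
    def test_deterministic_selector_repeats_score(self, ensemble_factory):
        e = ensemble_factory(20, 3, seed=27)
        pool = make_pool(8, 3, seed=28)
        df = compare_selectors(
            e, pool, p_a=3, seeds=[0, 1, 2],
            selectors={
                "greedy": lambda s: select_greedy(e, pool, 3),
                "mc": lambda s: select_monte_carlo(e, pool, 3, m=100, seed=s),
            },
        )
        g = df[df.selector == "greedy"].log_det
        assert g.nunique() == 1

    def test_greedy_beats_random_baseline(self, ensemble_factory):
        e = ensemble_factory(40, 5, seed=29)
        pool = make_pool(12, 5, seed=30)
        sc = _Scorer(e, pool, "covariance")

        def random_panel(s):
            rng = np.random.default_rng(s)
            idx = list(rng.choice(12, size=4, replace=False))
            from minegwas.mine import SelectionResult
            return SelectionResult(
                [pool.accession_ids[i] for i in idx], [], "random",
                final_score=sc.logdet(idx),
            )

        df = compare_selectors(
            e, pool, p_a=4, seeds=list(range(10)),
            selectors={
                "greedy": lambda s: select_greedy(e, pool, 4),
                "random": random_panel,
            },
        )
        means = df.groupby("selector").log_det.mean()
        assert means["greedy"] >= means["random"]

    def test_no_selector_beats_exhaustive(self, ensemble_factory):
        e = ensemble_factory(25, 4, seed=31)
        pool = make_pool(8, 4, seed=32)
        _, best = exhaustive_best(e, pool, 3)
        for res in (
            select_greedy(e, pool, 3),
            select_monte_carlo(e, pool, 3, m=500, seed=0),
            select_nc3plus2(e, pool, 3),
            select_suboptimal(e, pool, p_t=3, p_a=3),
        ):
            assert res.final_score <= best + 1e-9
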