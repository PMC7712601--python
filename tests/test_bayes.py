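import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import betainc

from ctebayes.bayes import (
    BetaPosterior,
    UNIFORM_PRIOR,
    WinTally,
    bayes_factor,
    count_wins,
    credible_interval,
    select_optimal,
    select_worst,
    subgroup_results,
    summarize_tally,
    update_posterior,
)
from ctebayes.simulate import SimulationConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracle: plain double loop over pairs, written from the rules
# ---------------------------------------------------------------------------

def brute_force_tally(treated, untreated):
    gamma = n = 0
    for tt, te in treated:
        for ut, ue in untreated:
            if tt < ut:
                if te == 1:
                    n += 1  # treated death observed first: loss
            elif ut < tt:
                if ue == 1:
                    n += 1
                    gamma += 1  # untreated death first: win
            else:  # equal observed times
                if te != ue:
                    n += 1
                    if te == 0:
                        gamma += 1  # the death loses the tie
    return gamma, n


pair_lists = st.lists(
    st.tuples(st.integers(0, 15).map(float), st.integers(0, 1)),
    min_size=0, max_size=30,
)


class TestCountWins:
    def test_all_deaths_enumeration(self):
        tally = count_wins([(5, 1), (10, 1)], [(3, 1), (7, 1)])
        assert (tally.gamma, tally.n) == (3, 4)

    def test_censored_before_death_incomparable(self):
        tally = count_wins([(5, 0)], [(7, 1)])
        assert tally.n == 0
        assert tally.n_incomparable == 1

    def test_censored_after_death_wins(self):
        tally = count_wins([(9, 0)], [(3, 1)])
        assert (tally.gamma, tally.n) == (1, 1)

    def test_equal_times_death_loses(self):
        assert count_wins([(5, 0)], [(5, 1)]).gamma == 1
        assert count_wins([(5, 1)], [(5, 0)]).gamma == 0
        assert count_wins([(5, 1)], [(5, 1)]).n == 0  # double death tie
        assert count_wins([(5, 0)], [(5, 0)]).n == 0

    def test_empty_side_gives_zero(self):
        assert count_wins([], [(3, 1)]).n == 0
        assert count_wins([(3, 1)], []).n == 0

    @given(pair_lists, pair_lists)
    @settings(max_examples=200, deadline=None)
    def test_brute_force_oracle(self, treated, untreated):
        tally = count_wins(treated, untreated)
        gamma, n = brute_force_tally(treated, untreated)
        assert (tally.gamma, tally.n) == (gamma, n)
        assert tally.n + tally.n_incomparable == len(treated) * len(untreated)

    @given(pair_lists, pair_lists)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_swap_arms(self, a, b):
        t1 = count_wins(a, b)
        t2 = count_wins(b, a)
        assert t1.n == t2.n
        assert t2.gamma == t1.n - t1.gamma


class TestUpdatePosterior:
    def test_conjugate_update(self):
        post = update_posterior(UNIFORM_PRIOR, WinTally(0, gamma=3, n=10))
        assert (post.alpha, post.beta) == (4.0, 8.0)

    def test_no_data_returns_prior(self):
        post = update_posterior(UNIFORM_PRIOR, WinTally(0, gamma=0, n=0))
        assert (post.alpha, post.beta) == (1.0, 1.0)

    def test_all_wins(self):
        post = update_posterior(UNIFORM_PRIOR, WinTally(0, gamma=5, n=5))
        assert (post.alpha, post.beta) == (6.0, 1.0)
        assert post.mean == pytest.approx(6 / 7)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance_under_splitting(self, g1, extra1, g2, extra2):
        n1, n2 = g1 + extra1, g2 + extra2
        a = update_posterior(update_posterior(UNIFORM_PRIOR, WinTally(0, g1, n1)),
                             WinTally(0, g2, n2))
        b = update_posterior(UNIFORM_PRIOR, WinTally(0, g1 + g2, n1 + n2))
        assert (a.alpha, a.beta) == (b.alpha, b.beta)

    def test_tally_validation(self):
        with pytest.raises(ValueError):
            WinTally(0, gamma=5, n=3)


class TestCredibleInterval:
    def test_uniform_quantiles(self):
        lo, hi = credible_interval(BetaPosterior(1, 1), 0.95)
        assert (lo, hi) == pytest.approx((0.025, 0.975))

    def test_bisection_oracle_beta_4_8(self):
        # independent numeric inversion of the regularized incomplete beta
        def invert(q, a, b):
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = (lo + hi) / 2
                if betainc(a, b, mid) < q:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        lo, hi = credible_interval(BetaPosterior(4, 8), 0.95)
        assert lo == pytest.approx(invert(0.025, 4, 8), abs=1e-6)
        assert hi == pytest.approx(invert(0.975, 4, 8), abs=1e-6)

    def test_narrow_level_collapses_to_median(self):
        med = stats.beta.median(4, 8)
        lo, hi = credible_interval(BetaPosterior(4, 8), 1e-9)
        assert lo == pytest.approx(med, abs=1e-6)
        assert hi == pytest.approx(med, abs=1e-6)

    def test_bounds_monotone_in_gamma(self):
        n = 40
        los, his = [], []
        for g in range(n + 1):
            lo, hi = credible_interval(
                update_posterior(UNIFORM_PRIOR, WinTally(0, g, n)))
            los.append(lo)
            his.append(hi)
        assert np.all(np.diff(los) >= 0)
        assert np.all(np.diff(his) >= 0)

    def test_mean_inside_equal_tailed_bounds(self):
        for g, n in [(0, 10), (3, 10), (10, 10), (50, 200)]:
            res = summarize_tally(WinTally(0, g, n))
            assert res.ci_low <= res.mean <= res.ci_high


class TestBayesFactor:
    def test_no_data_is_one(self):
        assert bayes_factor(WinTally(0, 0, 0)) == 1.0

    def test_density_oracle_gamma3_n10(self):
        # BF = prior pdf(0.5) / Beta(4,8) pdf(0.5); log-gamma arithmetic oracle
        log_pdf = (3 * math.log(0.5) + 7 * math.log(0.5)
                   - (math.lgamma(4) + math.lgamma(8) - math.lgamma(12)))
        expected = 1.0 / math.exp(log_pdf)
        assert bayes_factor(WinTally(0, 3, 10)) == pytest.approx(expected, rel=1e-12)

    def test_balanced_data_favors_null(self):
        assert bayes_factor(WinTally(0, 100, 200)) < 1.0
        assert bayes_factor(WinTally(0, 500, 1000)) < bayes_factor(WinTally(0, 50, 100))

    def test_symmetry_under_arm_swap(self):
        a = bayes_factor(WinTally(0, 17, 60))
        b = bayes_factor(WinTally(0, 43, 60))
        assert a == pytest.approx(b, rel=1e-12)

    @given(st.integers(0, 200), st.data())
    @settings(max_examples=100, deadline=None)
    def test_savage_dickey_marginal_agreement(self, n, data):
        from ctebayes.bayes import _log_bf_marginal, _log_bf_savage_dickey
        g = data.draw(st.integers(0, n))
        tally = WinTally(0, g, n)
        sd = _log_bf_savage_dickey(tally, UNIFORM_PRIOR)
        ml = _log_bf_marginal(tally, UNIFORM_PRIOR)
        assert abs(sd - ml) <= 1e-10 * max(1.0, abs(sd))

    def test_huge_evidence_saturates_to_inf(self):
        assert bayes_factor(WinTally(0, 2000, 2000)) == math.inf


class TestSelection:
    def _result(self, key, gamma, n):
        return summarize_tally(WinTally(key, gamma, n))

    def test_no_qualifying_subgroup_returns_none(self):
        results = [self._result(k, 10, 20) for k in range(5)]
        assert select_optimal(results) is None

    def test_single_qualifier_selected(self):
        results = [self._result(0, 10, 20), self._result(7, 48, 50)]
        sel = select_optimal(results)
        assert sel is not None and sel.key == 7

    def test_min_n_guard(self):
        results = [self._result(3, 12, 12)]
        assert select_optimal(results, min_n=10).key == 3
        assert select_optimal(results, min_n=13) is None

    def test_worst_mirrors_optimal(self):
        results = [self._result(0, 2, 50), self._result(1, 25, 50)]
        sel = select_worst(results)
        assert sel is not None and sel.key == 0

    def test_empty_results(self):
        assert select_optimal([]) is None
        assert select_worst([]) is None

    def test_tie_break_larger_n_then_smaller_key(self):
        a = summarize_tally(WinTally(5, 40, 40))
        b = summarize_tally(WinTally(2, 40, 40))
        sel = select_optimal([a, b])
        assert sel.key == 2

    def test_planted_harmful_cell_recovered(self):
        hits = 0
        for seed in (101, 102, 103):
            cfg = SimulationConfig(
                n=5000, seed=seed, effect_map={1: math.log(3.0)},
                covariate_prevalences=(0.04,) + (0.002,) * 8,
                covariate_log_hazards=(0.1,) * 9, censor_rate=0.01,
            )
            results = subgroup_results(generate_cohort(cfg), "chemo")
            sel = select_worst(results, min_n=30)
            hits += (sel is not None and sel.key == 1)
        assert hits >= 2
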