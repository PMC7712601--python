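"""Per-subgroup win counting, conjugate Beta updating, Bayes factors, selection.

The treatment outcome in a stratum is the *win probability* Y: the chance
that a treated patient outlives an untreated one drawn from the same cell.
Comparable treated/untreated pairs give a binomial likelihood for Y, updated
against a Beta prior (uniform Beta(1,1) by default).  Cells are gated on the
Bayes factor against the no-effect point Y = 0.5 and ranked by their 95%
equal-tailed credible bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import betaln

from .cohort import Cohort, PatientRecord, stratify

__all__ = [
    "WinTally",
    "BetaPosterior",
    "SubgroupResult",
    "count_wins",
    "update_posterior",
    "credible_interval",
    "bayes_factor",
    "subgroup_results",
    "select_optimal",
    "select_worst",
    "UNIFORM_PRIOR",
]

#: Default minimum comparable-pair count for a cell to enter selection.
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(alpha, beta) distribution over the win probability Y."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def pdf(self, y: float) -> float:
        return float(stats.beta.pdf(y, self.alpha, self.beta))

    def logpdf(self, y: float) -> float:
        # explicit log-gamma form; independent of scipy's pdf path
        a, b = self.alpha, self.beta
        return (a - 1) * math.log(y) + (b - 1) * math.log1p(-y) - betaln(a, b)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


UNIFORM_PRIOR = BetaPosterior(1.0, 1.0)


@dataclass(frozen=True)
class WinTally:
    """Comparable-pair count n and treated-win count gamma for one cell."""

    key: int
    gamma: int
    n: int
    n_incomparable: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gamma <= self.n):
            raise ValueError("need 0 <= gamma <= n")
        if self.n_incomparable < 0:
            raise ValueError("n_incomparable must be non-negative")


def _times_events(records: Iterable) -> Tuple[np.ndarray, np.ndarray]:
    times, events = [], []
    for r in records:
        if isinstance(r, PatientRecord):
            times.append(r.time_months)
            events.append(r.event)
        else:
            t, e = r
            times.append(float(t))
            events.append(int(e))
    return np.asarray(times, dtype=float), np.asarray(events, dtype=int)


def count_wins(treated: Iterable, untreated: Iterable, key: int = 0) -> WinTally:
    """Tally comparable treated-vs-untreated pairs and treated wins.

    All treated x untreated pairs are formed.  A pair is comparable iff the
    shorter observed time ends in death; at equal times the pair is
    comparable only when exactly one is a death (the death loses).  The
    treated subject wins when it survives strictly longer than an untreated
    death, or is censored at/after the untreated death time.  Incomparable
    pairs are excluded from n and reported separately.

    Accepts patient records or plain (time, event) pairs; either side empty
    yields n = 0.
    """
    tt, te = _times_events(treated)
    ut, ue = _times_events(untreated)
    if tt.size == 0 or ut.size == 0:
        return WinTally(key=key, gamma=0, n=0, n_incomparable=0)

    T = tt[:, None]
    U = ut[None, :]
    TE = te[:, None].astype(bool)
    UE = ue[None, :].astype(bool)

    treated_shorter = (T < U) & TE            # treated dies first: loss
    untreated_shorter = (U < T) & UE          # untreated dies first: win
    tie_one_death = (T == U) & (TE ^ UE)      # the death loses at a tie
    comparable = treated_shorter | untreated_shorter | tie_one_death
    wins = untreated_shorter | (tie_one_death & ~TE)

    n = int(comparable.sum())
    return WinTally(
        key=key,
        gamma=int(wins.sum()),
        n=n,
        n_incomparable=int(tt.size * ut.size - n),
    )


def update_posterior(prior: BetaPosterior, tally: WinTally) -> BetaPosterior:
    """Conjugate update: Beta(a, b) + (gamma, n) -> Beta(a + gamma, b + n - gamma)."""
    return BetaPosterior(prior.alpha + tally.gamma, prior.beta + tally.n - tally.gamma)


def credible_interval(
    posterior: BetaPosterior, level: float = 0.95
) -> Tuple[float, float]:
    """Equal-tailed credible interval via inverse regularized incomplete beta."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    return (
        float(stats.beta.ppf(lo, posterior.alpha, posterior.beta)),
        float(stats.beta.ppf(1.0 - lo, posterior.alpha, posterior.beta)),
    )


def _log_bf_savage_dickey(tally: WinTally, prior: BetaPosterior) -> float:
    post = update_posterior(prior, tally)
    return prior.logpdf(0.5) - post.logpdf(0.5)


def _log_bf_marginal(tally: WinTally, prior: BetaPosterior) -> float:
    # log [ BetaBinom(gamma | n, a, b) / Binom(gamma | n, 1/2) ]; the binomial
    # coefficient cancels, leaving the beta-function ratio vs (1/2)^n
    a, b, g, n = prior.alpha, prior.beta, tally.gamma, tally.n
    log_ml1 = betaln(a + g, b + n - g) - betaln(a, b)
    log_ml0 = n * math.log(0.5)
    return float(log_ml1 - log_ml0)


def bayes_factor(tally: WinTally, prior: BetaPosterior = UNIFORM_PRIOR) -> float:
    """BF10 for a free win probability vs the point null Y = 0.5.

    Computed by the Savage-Dickey density ratio and cross-checked against the
    marginal-likelihood (beta-binomial vs fair binomial) formulation; the two
    must agree to 1e-10 in log space.  n = 0 returns BF = 1.
    """
    if tally.n == 0:
        return 1.0
    log_sd = _log_bf_savage_dickey(tally, prior)
    log_ml = _log_bf_marginal(tally, prior)
    # agreement to 1e-10 for n <= 200; the n-term admits float rounding that
    # grows with the magnitude of the intermediate log terms at huge n
    tol = max(1e-10 * max(1.0, abs(log_sd)), 1e-13 * tally.n)
    if abs(log_sd - log_ml) > tol:
        raise AssertionError(
            f"Bayes factor self-check failed: {log_sd} vs {log_ml}")
    try:
        return float(math.exp(log_sd))
    except OverflowError:
        return math.inf


@dataclass(frozen=True)
class SubgroupResult:
    """Posterior summaries and Bayes factor for one subgroup cell."""

    key: int
    tally: WinTally
    posterior: BetaPosterior
    mean: float
    ci_low: float
    ci_high: float
    bf: float


def summarize_tally(
    tally: WinTally,
    prior: BetaPosterior = UNIFORM_PRIOR,
    level: float = 0.95,
) -> SubgroupResult:
    post = update_posterior(prior, tally)
    lo, hi = credible_interval(post, level)
    return SubgroupResult(
        key=tally.key,
        tally=tally,
        posterior=post,
        mean=post.mean,
        ci_low=lo,
        ci_high=hi,
        bf=bayes_factor(tally, prior),
    )


def subgroup_results(
    cohort: Cohort,
    treatment: str,
    prior: BetaPosterior = UNIFORM_PRIOR,
    level: float = 0.95,
) -> List[SubgroupResult]:
    """Stratify, tally wins and summarize every non-empty subgroup cell."""
    cells = stratify(cohort, treatment)
    return [
        summarize_tally(count_wins(treated, untreated, key=key), prior, level)
        for key, (treated, untreated) in sorted(cells.items())
    ]


def _candidates(results, bf_threshold, min_n):
    return [r for r in results if r.bf > bf_threshold and r.tally.n >= min_n]


def select_optimal(
    results: Sequence[SubgroupResult],
    bf_threshold: float = 3.0,
    min_n: int = DEFAULT_MIN_N,
) -> Optional[SubgroupResult]:
    """Cell with the highest 95% lower credible bound among those with
    BF > threshold and lower bound above 0.5; ties broken by larger n, then
    smaller key.  None when no cell qualifies."""
    cands = [r for r in _candidates(results, bf_threshold, min_n) if r.ci_low > 0.5]
    if not cands:
        return None
    return max(cands, key=lambda r: (r.ci_low, r.tally.n, -r.key))


def select_worst(
    results: Sequence[SubgroupResult],
    bf_threshold: float = 3.0,
    min_n: int = DEFAULT_MIN_N,
) -> Optional[SubgroupResult]:
    """Mirror of :func:`select_optimal`: lowest upper bound below 0.5."""
    cands = [r for r in _candidates(results, bf_threshold, min_n) if r.ci_high < 0.5]
    if not cands:
        return None
    return min(cands, key=lambda r: (r.ci_high, -r.tally.n, r.key))
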