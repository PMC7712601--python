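"""Kaplan-Meier estimation, (stratified) log-rank test and O/E hazard ratio.

Ties follow the standard conventions: multiple deaths at one time use the
hypergeometric multi-death formula, and a censored time equal to a death time
counts as at-risk through that death time before removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "HazardRatioSummary",
    "kaplan_meier",
    "logrank",
    "hazard_ratio",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance.

    ``event_times`` are the distinct times with at least one death;
    ``survival[i]`` is S(t) just after ``event_times[i]``.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _as_arrays(times, events) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-D sequences")
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("negative times")
    if not np.all((e == 0) | (e == 1)):
        raise ValueError("events must be 0/1")
    return t, e


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod(1 - d_i/n_i)."""
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    death_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= dt).sum() for dt in death_times], dtype=float)
    deaths = np.array([((t == dt) & (e == 1)).sum() for dt in death_times], dtype=float)
    frac = 1.0 - deaths / n_at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * sum d/(n(n-d)); 0/0 guarded when S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_at_risk > deaths, deaths / (n_at_risk * (n_at_risk - deaths)), np.inf)
        gv = np.where(surv == 0.0, 0.0, surv ** 2 * np.cumsum(inc))
    return SurvivalCurve(
        event_times=death_times,
        survival=surv,
        at_risk=n_at_risk,
        deaths=deaths,
        greenwood_var=gv,
        n=t.size,
    )


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: Tuple[float, float]
    expected: Tuple[float, float]
    o_minus_e: float
    variance: float
    per_stratum: Optional[Dict[object, Tuple[float, float]]] = None


def _oe_components(t1, e1, t2, e2) -> Tuple[float, float, float, float]:
    """(O1, E1, O-E for group 1, hypergeometric variance) over pooled death times."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])
    o1 = e1_exp = oe = var = 0.0
    for dt in np.unique(t[e == 1]):
        at = t >= dt
        n = at.sum()
        n1 = (at & g).sum()
        dead = (t == dt) & (e == 1)
        d = dead.sum()
        d1 = (dead & g).sum()
        exp1 = d * n1 / n
        o1 += d1
        e1_exp += exp1
        oe += d1 - exp1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o1), float(e1_exp), float(oe), float(var)


def logrank(
    times1: Sequence[float],
    events1: Sequence[int],
    times2: Sequence[float],
    events2: Sequence[int],
    strata: Optional[Tuple[Sequence, Sequence]] = None,
) -> LogRankResult:
    """Two-sample log-rank test, optionally stratified.

    ``strata``, when given, is a pair of per-record stratum labels aligned
    with the two groups; O-E and variance are summed over strata before
    squaring, giving the stratified chi-square on 1 df.
    """
    t1, e1 = _as_arrays(times1, events1)
    t2, e2 = _as_arrays(times2, events2)

    per_stratum: Optional[Dict[object, Tuple[float, float]]] = None
    if strata is None:
        o1, exp1, oe, var = _oe_components(t1, e1, t2, e2)
        d_total = float(e1.sum() + e2.sum())
    else:
        s1 = np.asarray(strata[0])
        s2 = np.asarray(strata[1])
        if s1.shape != t1.shape or s2.shape != t2.shape:
            raise ValueError("stratum labels must align with the group arrays")
        o1 = exp1 = oe = var = 0.0
        per_stratum = {}
        for lab in np.unique(np.concatenate([s1, s2])):
            m1, m2 = s1 == lab, s2 == lab
            if not m1.any() or not m2.any():
                # one-armed stratum contributes no comparison
                continue
            so1, sexp1, soe, svar = _oe_components(t1[m1], e1[m1], t2[m2], e2[m2])
            o1 += so1
            exp1 += sexp1
            oe += soe
            var += svar
            per_stratum[lab] = (soe, svar)
        d_total = float(e1.sum() + e2.sum())

    if var == 0.0:
        warnings.warn("log-rank variance is zero (no informative deaths)")
        return LogRankResult(0.0, 1.0, (o1, d_total - o1), (exp1, d_total - exp1),
                             oe, 0.0, per_stratum)
    stat = oe ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(float(stat), p, (o1, d_total - o1),
                         (exp1, d_total - exp1), oe, var, per_stratum)


@dataclass
class HazardRatioSummary:
    hr: float
    ci_low: float
    ci_high: float
    defined: bool = True


def hazard_ratio(
    times1: Sequence[float],
    events1: Sequence[int],
    times2: Sequence[float],
    events2: Sequence[int],
    level: float = 0.95,
) -> HazardRatioSummary:
    """O/E (Mantel-Haenszel-type) hazard ratio of group 1 vs group 2.

    HR = (O1/E1)/(O2/E2) with log-scale CI using SE = sqrt(1/E1 + 1/E2).
    Flagged undefined when either arm has no observed or no expected deaths.
    """
    t1, e1 = _as_arrays(times1, events1)
    t2, e2 = _as_arrays(times2, events2)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no deaths in either group")
    o1, exp1, _, _ = _oe_components(t1, e1, t2, e2)
    d_total = float(e1.sum() + e2.sum())
    o2, exp2 = d_total - o1, d_total - exp1
    if exp1 <= 0 or exp2 <= 0 or o1 == 0 or o2 == 0:
        return HazardRatioSummary(np.nan, np.nan, np.nan, defined=False)
    hr = (o1 / exp1) / (o2 / exp2)
    se = np.sqrt(1.0 / exp1 + 1.0 / exp2)
    z = stats.norm.ppf(0.5 + level / 2)
    return HazardRatioSummary(
        hr=float(hr),
        ci_low=float(hr * np.exp(-z * se)),
        ci_high=float(hr * np.exp(z * se)),
        defined=True,
    )
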