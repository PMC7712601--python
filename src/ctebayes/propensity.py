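"""Propensity estimation, greedy caliper matching and balance diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import BIT_NAMES, Cohort, N_BITS, dichotomize

__all__ = [
    "PropensityModel",
    "MatchedSet",
    "fit_propensity",
    "match",
    "standardized_differences",
    "design_matrix",
]

_SCORE_TOL = 1e-8
_MAX_ITER = 100


def design_matrix(cohort: Cohort, treatment: str) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(X, y, ids): 9-bit covariate matrix, treatment labels, record ids."""
    X = np.empty((len(cohort), N_BITS), dtype=float)
    y = np.empty(len(cohort), dtype=float)
    ids: List[str] = []
    for i, r in enumerate(cohort):
        X[i] = dichotomize(r, treatment)
        y[i] = getattr(r, treatment)
        ids.append(r.id)
    return X, y, ids


@dataclass
class PropensityModel:
    """Logistic regression of treatment on the nine covariate bits."""

    intercept: float
    coefs: np.ndarray
    converged: bool
    n_iter: int
    diagnostic: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.coefs
        return 1.0 / (1.0 + np.exp(-eta))

    def scores(self, cohort: Cohort, treatment: str) -> np.ndarray:
        X, _, _ = design_matrix(cohort, treatment)
        return self.predict(X)


def _newton_logistic(X1: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool, int, str]:
    """Newton-Raphson MLE; returns last stable iterate on separation/singularity."""
    beta = np.zeros(X1.shape[1])
    diagnostic = ""
    for it in range(1, _MAX_ITER + 1):
        eta = X1 @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X1.T @ (y - p)
        if np.max(np.abs(g)) < _SCORE_TOL:
            return beta, True, it, ""
        w = p * (1.0 - p)
        H = (X1 * w[:, None]).T @ X1
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False, it, "singular information matrix (possible separation)"
        new = beta + step
        if not np.all(np.isfinite(new)) or np.max(np.abs(new)) > 1e3:
            return beta, False, it, "diverging estimates (perfect separation suspected)"
        beta = new
    return beta, False, _MAX_ITER, "score tolerance not reached in 100 iterations"


def fit_propensity(cohort: Cohort, treatment: str) -> PropensityModel:
    """Maximum-likelihood logistic fit of treatment assignment on the 9 bits.

    Raises if either treatment arm is empty.  Perfect separation is flagged
    as non-converged with a diagnostic, keeping the last stable iterate.
    """
    X, y, _ = design_matrix(cohort, treatment)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"one {treatment} arm is empty; cannot fit propensity model")
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    beta, converged, n_iter, diagnostic = _newton_logistic(X1, y)
    if not converged:
        warnings.warn(f"propensity fit did not converge: {diagnostic}")
    return PropensityModel(
        intercept=float(beta[0]),
        coefs=beta[1:].copy(),
        converged=converged,
        n_iter=n_iter,
        diagnostic=diagnostic,
    )


@dataclass
class MatchedSet:
    """1:1 matched pairs; each control used at most once."""

    pairs: List[Tuple[str, str]]
    caliper_used: float
    n_unmatched_treated: int
    pair_indices: List[Tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> List[str]:
        out: List[str] = []
        for t, c in self.pairs:
            out.extend((t, c))
        return out


def match(
    scores: Sequence[float],
    treatment_labels: Sequence[int],
    ids: Optional[Sequence[str]] = None,
    caliper_sd_mult: float = 0.2,
    seed: int = 0,
) -> MatchedSet:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity.

    The caliper is ``caliper_sd_mult`` times the SD of the logit score over
    all records (default 0.2).  Treated records are processed in descending
    score order; distance ties among controls are broken by a seeded shuffle.
    An empty matched set (no admissible control anywhere) is a warning, not
    an error.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(treatment_labels, dtype=int)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must align")
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("scores must lie strictly in (0, 1)")
    if ids is None:
        ids = [str(i) for i in range(s.size)]

    logit = np.log(s) - np.log1p(-s)
    sd = float(np.std(logit, ddof=1)) if s.size > 1 else 0.0
    caliper = caliper_sd_mult * sd

    rng = np.random.default_rng(seed)
    treated_idx = np.flatnonzero(lab == 1)
    control_idx = np.flatnonzero(lab == 0)
    # seeded shuffle first, then stable sort: equal scores end up in shuffled order
    treated_idx = rng.permutation(treated_idx)
    treated_idx = treated_idx[np.argsort(-s[treated_idx], kind="stable")]
    control_idx = rng.permutation(control_idx)

    available = np.ones(control_idx.size, dtype=bool)
    c_logit = logit[control_idx]
    pairs: List[Tuple[str, str]] = []
    pair_indices: List[Tuple[int, int]] = []
    unmatched = 0
    for t in treated_idx:
        if not available.any():
            unmatched += 1
            continue
        d = np.abs(c_logit - logit[t])
        d = np.where(available, d, np.inf)
        j = int(np.argmin(d))
        if d[j] <= caliper:
            available[j] = False
            c = int(control_idx[j])
            pairs.append((ids[t], ids[c]))
            pair_indices.append((int(t), c))
        else:
            unmatched += 1
    if not pairs:
        warnings.warn("no admissible matches within the caliper")
    return MatchedSet(pairs=pairs, caliper_used=float(caliper),
                      n_unmatched_treated=unmatched, pair_indices=pair_indices)


def _smd_binary(p1: float, p0: float) -> float:
    pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    if pooled == 0.0:
        return 0.0
    return (p1 - p0) / np.sqrt(pooled)


def standardized_differences(
    cohort: Cohort,
    treatment: str,
    matched: Optional[MatchedSet] = None,
) -> pd.DataFrame:
    """Standardized mean differences per covariate bit, before/after matching.

    For binary covariates with arm proportions p1, p0:
    SMD = (p1 - p0) / sqrt((p1(1-p1) + p0(1-p0)) / 2).
    """
    X, y, ids = design_matrix(cohort, treatment)
    out = pd.DataFrame(index=list(BIT_NAMES))
    t_mask, c_mask = y == 1, y == 0
    out["smd_unmatched"] = [
        _smd_binary(X[t_mask, j].mean(), X[c_mask, j].mean()) for j in range(N_BITS)
    ]
    if matched is not None and matched.pairs:
        id_to_row = {rid: i for i, rid in enumerate(ids)}
        ti = [id_to_row[t] for t, _ in matched.pairs]
        ci = [id_to_row[c] for _, c in matched.pairs]
        out["smd_matched"] = [
            _smd_binary(X[ti, j].mean(), X[ci, j].mean()) for j in range(N_BITS)
        ]
    return out
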