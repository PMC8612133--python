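"""Metacognitive bias, type-1 SDT, and maximum-likelihood meta-d'.

Metacognitive *bias* is simply the mean confidence rating over rated
trials.  Metacognitive *sensitivity* is measured with meta-d': the
type-1 sensitivity that an SDT-ideal observer would need in order to
produce the observed confidence data.  Under a Gaussian equal-variance
model the meta-level stimulus distributions sit at +/- meta-d'/2 and
the type-1 criterion c is carried over at the scaled position
c' = c * (meta-d' / d').  The free parameters are meta-d' itself and
2(K-1) ordered type-2 criteria (K = number of confidence levels); they
are fitted by maximising the multinomial log-likelihood of the
confidence-level counts conditional on (stimulus, response).
Metacognitive *efficiency* is the ratio meta-d'/d': 1 for an observer
whose confidence uses all of the decision evidence, < 1 when
information is lost at the meta level.

meta-d' is theoretically bounded below by zero but the unbounded ML fit
can return negative values through estimation error; they are retained
by default, with an optional clamp-to-zero variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .staircase import InsufficientDataError

__all__ = [
    "ConfidenceCounts",
    "MetaDFit",
    "EstimabilityError",
    "mean_confidence",
    "bin_confidence",
    "counts_from_trials",
    "fit_type1_sdt",
    "fit_meta_d",
    "estimable",
    "clamp_negative_meta_d",
]


class EstimabilityError(ValueError):
    """Raised when the confidence data cannot support a meta-d' fit."""


@dataclass(frozen=True)
class ConfidenceCounts:
    """Confidence-level counts per (stimulus, response) cell.

    ``counts`` has shape (2, 2, K): stimulus (S1, S2) x response
    (R1, R2) x confidence level (1..K).  By convention S2/R2 is the
    'majority is side B' class; d' is sign-symmetric under relabeling.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape[:2] != (2, 2) or c.ndim != 3 or c.shape[2] < 2:
            raise ValueError("counts must have shape (2, 2, K) with K >= 2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_levels(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def padded(self, pad: float | None = None) -> np.ndarray:
        """Counts with Hautus-style padding (default 1/(2K) per cell)."""
        if pad is None:
            pad = 1.0 / (2.0 * self.n_levels)
        return self.counts + pad


@dataclass(frozen=True)
class MetaDFit:
    """Result of a type-1 + type-2 SDT fit."""

    d_prime: float
    criterion: float
    meta_d: float
    efficiency: float
    type2_criteria_r1: tuple[float, ...]
    type2_criteria_r2: tuple[float, ...]
    log_likelihood: float
    converged: bool


def mean_confidence(trials: pd.DataFrame) -> float:
    """Metacognitive bias: mean first confidence over rated (main) trials."""
    rated = trials.loc[
        (trials["phase"] == "main") & trials["confidence1"].notna(),
        "confidence1",
    ]
    if rated.empty:
        raise InsufficientDataError("no rated trials")
    return float(rated.astype(float).mean())


def bin_confidence(ratings, n_levels: int = 6) -> np.ndarray:
    """Discretise ratings in [0, 1] into 1..K equal-width levels.

    Bins are right-closed at 1: level = ceil(rating * K), clamped so
    0 maps to level 1 and 1 maps to level K.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 confidence levels")
    r = np.asarray(ratings, dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("ratings must lie in [0, 1]")
    levels = np.ceil(r * n_levels).astype(int)
    return np.clip(levels, 1, n_levels)


def counts_from_trials(trials: pd.DataFrame, n_levels: int = 6) -> ConfidenceCounts:
    """Tabulate main-phase trials into a (2, 2, K) confidence-count table."""
    main = trials[(trials["phase"] == "main") & trials["confidence1"].notna()]
    if main.empty:
        raise InsufficientDataError("no rated trials to tabulate")
    stim = (main["majority_side"] == "B").astype(int).to_numpy()
    resp = (main["choice1"] == "B").astype(int).to_numpy()
    level = bin_confidence(main["confidence1"].to_numpy(), n_levels)
    counts = np.zeros((2, 2, n_levels))
    np.add.at(counts, (stim, resp, level - 1), 1.0)
    return ConfidenceCounts(counts)


def fit_type1_sdt(
    counts: ConfidenceCounts, pad: float | None = None
) -> tuple[float, float]:
    """Type-1 d' and criterion c from the (padded) response counts.

    d' = z(H) - z(F), c = -(z(H) + z(F)) / 2 with H = P(R2|S2) and
    F = P(R2|S1).
    """
    c = counts.padded(pad)
    per_stim = c.sum(axis=2)  # (stimulus, response)
    if counts.counts.sum(axis=(1, 2)).min() <= 0:
        raise InsufficientDataError("both stimulus classes must be present")
    hit = per_stim[1, 1] / per_stim[1].sum()
    fa = per_stim[0, 1] / per_stim[0].sum()
    z_h, z_f = ndtri(hit), ndtri(fa)
    return float(z_h - z_f), float(-0.5 * (z_h + z_f))


def _criteria_from_increments(c_meta: float, u: np.ndarray, k: int):
    """Ordered type-2 criteria from log-increments around the scaled c."""
    inc_r1 = np.exp(u[: k - 1])
    inc_r2 = np.exp(u[k - 1 :])
    crit_r1 = c_meta - np.cumsum(inc_r1)  # decreasing below c_meta
    crit_r2 = c_meta + np.cumsum(inc_r2)  # increasing above c_meta
    return crit_r1, crit_r2


def type2_level_probabilities(
    meta_d: float,
    c_meta: float,
    crit_r1: np.ndarray,
    crit_r2: np.ndarray,
) -> np.ndarray:
    """P(confidence level | stimulus, response) under the meta-level model.

    Returns an array of shape (2, 2, K); each (stimulus, response) row
    sums to 1.
    """
    k = len(crit_r1) + 1
    probs = np.empty((2, 2, k))
    for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        # R1 side: boundaries c_meta > crit_r1[0] > ... > -inf
        edges = np.concatenate(([c_meta], crit_r1, [-np.inf]))
        cdf = ndtr(edges - mu)
        p_r1 = cdf[:-1] - cdf[1:]
        denom1 = ndtr(c_meta - mu)
        probs[s, 0] = p_r1 / max(denom1, 1e-300)
        # R2 side: boundaries c_meta < crit_r2[0] < ... < inf
        edges = np.concatenate(([c_meta], crit_r2, [np.inf]))
        cdf = ndtr(edges - mu)
        p_r2 = cdf[1:] - cdf[:-1]
        probs[s, 1] = p_r2 / max(1.0 - denom1, 1e-300)
    return probs


def _neg_log_likelihood(
    x: np.ndarray, padded: np.ndarray, d_prime: float, criterion: float
) -> float:
    k = padded.shape[2]
    meta_d = x[0]
    ratio = meta_d / d_prime if d_prime != 0 else 0.0
    c_meta = criterion * ratio
    crit_r1, crit_r2 = _criteria_from_increments(c_meta, x[1:], k)
    probs = type2_level_probabilities(meta_d, c_meta, crit_r1, crit_r2)
    return -float(np.sum(padded * np.log(np.clip(probs, 1e-12, None))))


def estimable(trials: pd.DataFrame, n_levels: int = 6) -> bool:
    """Whether a participant's confidence data supports a meta-d' fit.

    Participants who park their ratings on fewer than two distinct
    levels, or never use one of the two responses, carry no type-2
    signal; such participants are excluded from efficiency analyses.
    """
    main = trials[(trials["phase"] == "main") & trials["confidence1"].notna()]
    if main.empty:
        return False
    levels = bin_confidence(main["confidence1"].to_numpy(), n_levels)
    if len(np.unique(levels)) < 2:
        return False
    counts = counts_from_trials(trials, n_levels).counts
    # every stimulus class and every response must occur at least once
    if counts.sum(axis=(1, 2)).min() <= 0:
        return False
    if counts.sum(axis=(0, 2)).min() <= 0:
        return False
    return True


def fit_meta_d(
    counts: ConfidenceCounts,
    pad: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
    bound: float = 10.0,
) -> MetaDFit:
    """Maximum-likelihood meta-d' fit.

    Maximises the multinomial log-likelihood of the confidence-level
    counts conditional on (stimulus, response), holding d' and c at
    their type-1 estimates and scaling the criterion into the
    meta-level model.  Criteria are kept ordered by parameterising them
    as cumulative positive increments away from the scaled criterion;
    the optimiser is restarted from several feasible points and the
    best optimum kept.  Negative meta-d' is retained (see
    :func:`clamp_negative_meta_d` for the clamped variant).
    """
    k = counts.n_levels
    padded = counts.padded(pad)
    level_totals = counts.counts.sum(axis=(0, 1))
    if (level_totals > 0).sum() < 2:
        raise EstimabilityError(
            "confidence ratings occupy a single level; meta-d' unidentified"
        )
    d_prime, criterion = fit_type1_sdt(counts, pad)
    if abs(d_prime) < 1e-9:
        raise EstimabilityError("type-1 d' is zero; efficiency undefined")

    rng = np.random.default_rng(seed)
    base_inc = math.log(2.0 / k)
    starts = []
    meta_d_starts = [d_prime, 0.6 * d_prime, 1.4 * d_prime, 0.1, -0.3 * d_prime]
    for i in range(n_starts):
        md0 = meta_d_starts[i % len(meta_d_starts)]
        u0 = np.full(2 * (k - 1), base_inc)
        if i > 0:
            u0 = u0 + rng.normal(0.0, 0.3, size=u0.size)
        starts.append(np.concatenate(([md0], u0)))

    bounds = [(-bound, bound)] + [(-8.0, 3.0)] * (2 * (k - 1))
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_likelihood,
            x0,
            args=(padded, d_prime, criterion),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    meta_d = float(best.x[0])
    ratio = meta_d / d_prime
    c_meta = criterion * ratio
    crit_r1, crit_r2 = _criteria_from_increments(c_meta, best.x[1:], k)
    return MetaDFit(
        d_prime=d_prime,
        criterion=criterion,
        meta_d=meta_d,
        efficiency=meta_d / d_prime,
        type2_criteria_r1=tuple(float(v) for v in crit_r1),
        type2_criteria_r2=tuple(float(v) for v in crit_r2),
        log_likelihood=-float(best.fun),
        converged=any_converged,
    )


def clamp_negative_meta_d(fit: MetaDFit) -> MetaDFit:
    """Robustness variant: clamp negative meta-d' to zero.

    Returns a copy with meta_d = max(meta_d, 0) and the efficiency
    recomputed; non-negative fits are returned unchanged.
    """
    if fit.meta_d >= 0:
        return fit
    return replace(fit, meta_d=0.0, efficiency=0.0)
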