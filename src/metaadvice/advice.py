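"""Formula-defined advice-taking scores.

Two per-participant measures over advice trials:

* propensity to follow advice —
  P(switch | advisor disagreed) - P(switch | advisor agreed);
  the subtraction removes changes of mind unrelated to the advice.
* resistance to false advice —
  P(follow | initially incorrect & conflicting advice)
  - P(follow | initially correct & conflicting advice);
  positive means helpful conflicting advice is followed more than
  misleading conflicting advice, zero means no discrimination.

In a conflicting trial the advice is helpful exactly when the initial
choice was incorrect (a correct advisor names the majority side), so
"following" conflicting advice always means switching.  Participants
with an empty denominator get a missing score, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AdviceCellCounts",
    "advice_cell_counts",
    "propensity_score",
    "resistance_score",
    "standardize",
]


@dataclass(frozen=True)
class AdviceCellCounts:
    """Audit counts behind the two advice scores (advice trials only)."""

    n_disagree: int
    n_switch_given_disagree: int
    n_agree: int
    n_switch_given_agree: int
    n_incorrect_conflict: int
    n_follow_helpful: int
    n_correct_conflict: int
    n_follow_misleading: int

    def __post_init__(self) -> None:
        pairs = [
            (self.n_switch_given_disagree, self.n_disagree),
            (self.n_switch_given_agree, self.n_agree),
            (self.n_follow_helpful, self.n_incorrect_conflict),
            (self.n_follow_misleading, self.n_correct_conflict),
        ]
        for num, den in pairs:
            if num < 0 or den < 0 or num > den:
                raise ValueError("switch counts must be within denominators")


def advice_cell_counts(trials: pd.DataFrame) -> AdviceCellCounts:
    """Tabulate the advice trials of one participant into score cells.

    Helpful/misleading labels are derived from the participant's own
    initial accuracy on conflicting trials, not from the advisor's
    latent correctness flag.
    """
    adv = trials[trials["advice_given"].fillna(False).astype(bool)]
    agrees = adv["advice_agrees"].astype(bool)
    switched = adv["switched"].astype(bool)
    correct1 = adv["correct1"].astype(bool)

    disagree = ~agrees
    inc_conf = disagree & ~correct1  # conflicting & wrong -> advice helpful
    cor_conf = disagree & correct1  # conflicting & right -> advice misleading
    return AdviceCellCounts(
        n_disagree=int(disagree.sum()),
        n_switch_given_disagree=int((disagree & switched).sum()),
        n_agree=int(agrees.sum()),
        n_switch_given_agree=int((agrees & switched).sum()),
        n_incorrect_conflict=int(inc_conf.sum()),
        n_follow_helpful=int((inc_conf & switched).sum()),
        n_correct_conflict=int(cor_conf.sum()),
        n_follow_misleading=int((cor_conf & switched).sum()),
    )


def _ratio_difference(num1, den1, num2, den2) -> float:
    if den1 == 0 or den2 == 0:
        return math.nan
    return num1 / den1 - num2 / den2


def propensity_score(trials: pd.DataFrame) -> float:
    """Overall propensity to follow advice, in [-1, 1]; NaN if undefined."""
    c = advice_cell_counts(trials)
    return _ratio_difference(
        c.n_switch_given_disagree, c.n_disagree,
        c.n_switch_given_agree, c.n_agree,
    )


def resistance_score(trials: pd.DataFrame) -> float:
    """Resistance to false advice, in [-1, 1]; NaN if undefined."""
    c = advice_cell_counts(trials)
    return _ratio_difference(
        c.n_follow_helpful, c.n_incorrect_conflict,
        c.n_follow_misleading, c.n_correct_conflict,
    )


def standardize(values) -> np.ndarray:
    """z-score (sample SD, ddof=1) over non-missing entries; NaN preserved."""
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = np.std(v[mask], ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    out = np.full_like(v, np.nan)
    out[mask] = (v[mask] - v[mask].mean()) / sd
    return out
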