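"""2-down-1-up adaptive staircase on the alien-count difference.

The staircase controls the difference in counts between the two alien
colours so that a simulated (or replayed) observer converges near the
70.7% point of its psychometric function: two consecutive correct
responses make the discrimination harder (smaller difference), a single
error makes it easier (larger difference).  The fixed point is the
accuracy p satisfying p**2 = 0.5, i.e. sqrt(0.5) ~ 0.707.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class StaircaseConfigError(ValueError):
    """Raised when a staircase configuration violates its invariants."""


class InsufficientDataError(ValueError):
    """Raised when a summary is requested on an empty window."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the 2-down-1-up staircase.

    The difference is always measured in alien counts, so with
    ``total_aliens`` stimuli per display both colour counts
    ``(total +/- difference) / 2`` must be integers: the difference must
    share the parity of the total.
    """

    initial_difference: int = 20
    step_size: int = 2
    min_difference: int = 2
    max_difference: int = 66
    total_aliens: int = 68

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise StaircaseConfigError("step_size must be >= 1")
        if self.min_difference < 2:
            raise StaircaseConfigError("min_difference must be >= 2")
        if self.max_difference > self.total_aliens - 2:
            raise StaircaseConfigError(
                "max_difference must be <= total_aliens - 2"
            )
        if not (
            self.min_difference
            <= self.initial_difference
            <= self.max_difference
        ):
            raise StaircaseConfigError(
                "initial_difference must lie in "
                f"[{self.min_difference}, {self.max_difference}]"
            )
        parity = self.total_aliens % 2
        for name in ("initial_difference", "min_difference", "max_difference"):
            if getattr(self, name) % 2 != parity:
                raise StaircaseConfigError(
                    f"{name} must have the same parity as total_aliens"
                )


@dataclass(frozen=True)
class StaircaseState:
    """Current staircase position plus the full (difference, correct) history."""

    config: StaircaseConfig
    current_difference: int
    consecutive_correct: int = 0
    history: tuple[tuple[int, bool], ...] = field(default_factory=tuple)


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Return a fresh state at the configured initial difference."""
    return StaircaseState(
        config=config,
        current_difference=config.initial_difference,
    )


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial outcome under the 2-down-1-up rule.

    Two consecutive correct responses decrease the difference by one
    step; any error increases it by one step.  The difference is clamped
    to the configured bounds, and the two-correct counter resets on
    every difference change.
    """
    cfg = state.config
    delta = state.current_difference
    counter = state.consecutive_correct
    if correct:
        if counter >= 1:
            delta = max(delta - cfg.step_size, cfg.min_difference)
            counter = 0
        else:
            counter = 1
    else:
        delta = min(delta + cfg.step_size, cfg.max_difference)
        counter = 0
    return replace(
        state,
        current_difference=delta,
        consecutive_correct=counter,
        history=state.history + ((state.current_difference, bool(correct)),),
    )


def asymptotic_accuracy(
    history: "tuple[tuple[int, bool], ...] | list[tuple[int, bool]]",
    burn_in: int = 30,
) -> float:
    """Mean proportion correct over post-burn-in history entries.

    ``burn_in`` defaults to the 30 practice trials, which are excluded
    from all accuracy summaries.
    """
    window = list(history)[burn_in:]
    if not window:
        raise InsufficientDataError(
            "no trials remain after burn-in of "
            f"{burn_in} (history length {len(history)})"
        )
    return sum(1.0 for _, c in window if c) / len(window)
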