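"""Generative model of participants performing the advice-taking task.

A simulated participant is a signal-detection observer: on each trial
the displayed alien-count difference ``delta`` maps to a discriminability
``sensitivity_slope * delta`` and a noisy evidence sample decides the
choice.  Confidence is a logistic read-out of the same evidence
corrupted by additive meta-level noise, so ``meta_noise_sd = 0`` defines
the ideal metacognitive observer (fitted meta-d'/d' ~ 1) and larger
values degrade metacognitive efficiency without touching type-1
accuracy.  After the first choice, an advisor who is correct on a fixed
proportion of advice trials names a side, and the participant may
switch; the switch probability rises with (1 - confidence) when the
advice conflicts, scaled by an advice-trust weight.

Cohorts emulate a developmental study with three age groups (8-9,
12-13, 16-17 years): meta-level noise falls from childhood to early
adolescence and then plateaus, overall confidence peaks at 12-13 and is
higher in males, and advice trust falls with the same early-adolescent
plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staircase import (
    StaircaseConfig,
    init_staircase,
    update_staircase,
)

SIDES = ("A", "B")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant."""

    sensitivity_slope: float = 0.06  # d' per unit alien-count difference
    type1_criterion: float = 0.0
    meta_noise_sd: float = 0.5
    confidence_bias: float = 0.0
    confidence_gain: float = 1.5
    switch_baseline: float = 0.05
    switch_conflict_slope: float = 1.6
    advice_trust: float = 1.0
    age_years: float = 13.0
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.sensitivity_slope <= 0:
            raise ValueError("sensitivity_slope must be > 0")
        if self.meta_noise_sd < 0:
            raise ValueError("meta_noise_sd must be >= 0")
        if self.confidence_gain <= 0:
            raise ValueError("confidence_gain must be > 0")
        if not 0 <= self.switch_baseline <= 1:
            raise ValueError("switch_baseline must be in [0, 1]")
        if self.advice_trust < 0:
            raise ValueError("advice_trust must be >= 0")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


@dataclass(frozen=True)
class TaskConfig:
    """Trial-count and advisor parameters of one task session."""

    n_practice: int = 30
    n_main: int = 80
    advice_fraction: float = 0.5
    advisor_accuracy: float = 0.7

    def __post_init__(self) -> None:
        if self.n_practice < 0 or self.n_main < 1:
            raise ValueError("invalid trial counts")
        if not 0 <= self.advice_fraction <= 1:
            raise ValueError("advice_fraction must be in [0, 1]")
        if not 0 <= self.advisor_accuracy <= 1:
            raise ValueError("advisor_accuracy must be in [0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """One age group of a simulated cohort."""

    label: str
    age_low: float
    age_high: float
    n: int
    n_male: int

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 <= self.n_male <= self.n:
            raise ValueError("invalid group sizes")
        if self.age_low >= self.age_high:
            raise ValueError("age_low must be < age_high")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition plus the age/sex -> parameter maps.

    The default groups mirror a three-group developmental design:
    8-9 years (n=30, 11 male), 12-13 years (n=41, 19 male) and
    16-17 years (n=36, 15 male).  The parameter maps encode the
    qualitative developmental effects the generator is meant to
    produce; set the effect-size fields to zero for a null cohort.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("8-9", 8.89, 9.71, 30, 11),
        GroupSpec("12-13", 12.69, 13.70, 41, 19),
        GroupSpec("16-17", 16.71, 17.76, 36, 15),
    )
    # meta-level noise: falls linearly from age 8 to the age-12 plateau
    meta_noise_floor: float = 0.45
    meta_noise_childhood_extra: float = 1.85
    meta_noise_jitter_sd: float = 0.5
    # confidence bias: quadratic-like peak at early adolescence; male > female
    bias_base: float = 0.02
    bias_peak: float = 0.12
    bias_peak_age: float = 13.1
    bias_peak_width: float = 3.0
    bias_male_shift: float = 0.06
    bias_jitter_sd: float = 0.04
    # advice trust: early-adolescent-emergent decrease
    trust_floor: float = 0.6
    trust_childhood_extra: float = 0.45
    trust_jitter_sd: float = 0.1
    plateau_age: float = 12.0
    childhood_age: float = 8.0

    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def _emergent_ramp(age: float, spec: CohortSpec) -> float:
    """1 in childhood, falling to 0 at the plateau age, 0 after."""
    span = spec.plateau_age - spec.childhood_age
    return float(np.clip((spec.plateau_age - age) / span, 0.0, 1.0))


def draw_observer_params(
    spec: CohortSpec, age: float, sex: str, rng: np.random.Generator
) -> ObserverParams:
    """Sample one participant's generative parameters from the cohort maps."""
    ramp = _emergent_ramp(age, spec)
    meta_noise = max(
        0.0,
        spec.meta_noise_floor
        + spec.meta_noise_childhood_extra * ramp
        + rng.normal(0.0, spec.meta_noise_jitter_sd),
    )
    peak = math.exp(
        -((age - spec.bias_peak_age) ** 2) / (2.0 * spec.bias_peak_width**2)
    )
    bias = (
        spec.bias_base
        + spec.bias_peak * peak
        + (spec.bias_male_shift if sex == "male" else 0.0)
        + rng.normal(0.0, spec.bias_jitter_sd)
    )
    trust = max(
        0.0,
        spec.trust_floor
        + spec.trust_childhood_extra * ramp
        + rng.normal(0.0, spec.trust_jitter_sd),
    )
    return ObserverParams(
        meta_noise_sd=meta_noise,
        confidence_bias=bias,
        advice_trust=trust,
        age_years=age,
        sex=sex,
    )


def simulate_decision(
    params: ObserverParams, difference: int, rng: np.random.Generator
) -> tuple[str, str, float]:
    """One type-1 decision: returns (majority_side, choice, evidence).

    Evidence is a unit-variance normal centred at +d/2 when the majority
    is side B and -d/2 when it is side A, with d = slope * difference;
    the choice is the side of the evidence relative to the criterion.
    """
    majority = SIDES[rng.integers(2)]
    d = params.sensitivity_slope * difference
    mean = d / 2.0 if majority == "B" else -d / 2.0
    evidence = rng.normal(mean, 1.0)
    choice = "B" if evidence > params.type1_criterion else "A"
    return majority, choice, float(evidence)


def simulate_confidence(
    params: ObserverParams, evidence: float, rng: np.random.Generator
) -> float:
    """Confidence in [0, 1]: logistic of the meta-evidence distance.

    The meta-level re-reads the decision evidence through additive
    Gaussian noise; confidence grows with the distance of that noisy
    read-out from the type-1 criterion, is rescaled so zero distance
    maps to 0 ('total guess'), then shifted by the observer's bias and
    clipped to the unit interval.  The distance is divided by the
    standard deviation of the meta-level read-out, sqrt(1 + sd^2), so
    the observer is calibrated to its own noise scale and mean
    confidence stays comparable across noise levels (meta-level noise
    degrades confidence-accuracy coupling, not overall confidence).
    """
    meta_evidence = evidence + rng.normal(0.0, params.meta_noise_sd)
    dist = abs(meta_evidence - params.type1_criterion)
    dist /= math.sqrt(1.0 + params.meta_noise_sd**2)
    raw = 2.0 / (1.0 + math.exp(-params.confidence_gain * dist)) - 1.0
    return float(np.clip(raw + params.confidence_bias, 0.0, 1.0))


def schedule_advice(
    n_main: int,
    advice_fraction: float,
    advisor_accuracy: float,
    rng: np.random.Generator,
) -> list[tuple[bool, bool]]:
    """Per-main-trial advice plan: (advice_given, advice_correct).

    Exactly round(fraction * n_main) trials carry advice, chosen
    uniformly; on each, the advisor is independently correct with the
    given probability (names the true majority side when correct, the
    other side otherwise).
    """
    if not (0 <= advice_fraction <= 1 and 0 <= advisor_accuracy <= 1):
        raise ValueError("fractions must be in [0, 1]")
    n_advice = int(round(advice_fraction * n_main))
    advice_idx = set(rng.choice(n_main, size=n_advice, replace=False).tolist())
    plan = []
    for t in range(n_main):
        given = t in advice_idx
        correct = bool(rng.random() < advisor_accuracy) if given else False
        plan.append((given, correct))
    return plan


def simulate_post_advice(
    params: ObserverParams,
    confidence1: float,
    advice_agrees: bool,
    rng: np.random.Generator,
) -> bool:
    """Whether the participant switches after seeing the advice.

    Agreeing advice leaves only the baseline change-of-mind rate;
    conflicting advice adds a term proportional to (1 - confidence),
    weighted by trust in the advisor.
    """
    p = params.switch_baseline
    if not advice_agrees:
        p += (
            params.advice_trust
            * params.switch_conflict_slope
            * (1.0 - confidence1)
        )
    p = float(np.clip(p, 0.0, 1.0))
    return bool(rng.random() < p)


def simulate_participant(
    params: ObserverParams,
    task: TaskConfig | None = None,
    staircase: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "p000",
) -> list[dict]:
    """Simulate one full session; returns one dict per trial.

    Practice trials carry feedback and no confidence rating; main
    trials carry a confidence rating and, on scheduled trials, advice
    followed by a second choice and rating.  The staircase is updated
    after every type-1 decision, practice included.
    """
    task = task or TaskConfig()
    staircase = staircase or StaircaseConfig()
    rng = rng or np.random.default_rng()

    plan = schedule_advice(
        task.n_main, task.advice_fraction, task.advisor_accuracy, rng
    )
    state = init_staircase(staircase)
    records: list[dict] = []
    for t in range(task.n_practice + task.n_main):
        is_practice = t < task.n_practice
        delta = state.current_difference
        majority, choice1, evidence = simulate_decision(params, delta, rng)
        correct1 = choice1 == majority
        rec: dict = {
            "participant_id": participant_id,
            "trial_index": t,
            "phase": "practice" if is_practice else "main",
            "difference": delta,
            "majority_side": majority,
            "choice1": choice1,
            "correct1": correct1,
            "confidence1": None,
            "advice_given": False,
            "advice_choice": None,
            "advice_correct": None,
            "advice_agrees": None,
            "choice2": None,
            "switched": None,
            "confidence2": None,
            "feedback": "correct" if correct1 else "incorrect",
        }
        if not is_practice:
            rec["feedback"] = None
            conf1 = simulate_confidence(params, evidence, rng)
            rec["confidence1"] = conf1
            given, adv_correct = plan[t - task.n_practice]
            if given:
                advice_choice = (
                    majority
                    if adv_correct
                    else SIDES[1 - SIDES.index(majority)]
                )
                agrees = advice_choice == choice1
                switched = simulate_post_advice(params, conf1, agrees, rng)
                choice2 = (
                    SIDES[1 - SIDES.index(choice1)] if switched else choice1
                )
                conf2 = float(np.clip(conf1 + rng.normal(0.0, 0.05), 0.0, 1.0))
                rec.update(
                    advice_given=True,
                    advice_choice=advice_choice,
                    advice_correct=adv_correct,
                    advice_agrees=agrees,
                    choice2=choice2,
                    switched=switched,
                    confidence2=conf2,
                )
        state = update_staircase(state, correct1)
        records.append(rec)
    return records


def _participant_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # keyed on the participant index so cohorts of different sizes share
    # the per-participant streams they have in common
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_cohort(
    spec: CohortSpec | None = None,
    task: TaskConfig | None = None,
    staircase: StaircaseConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (participant table, trial table).

    Every participant gets an independent random stream derived from
    the master seed and their index, so the cohort is bit-reproducible.
    """
    spec = spec or CohortSpec()
    task = task or TaskConfig()
    staircase = staircase or StaircaseConfig()

    part_rows = []
    trial_rows = []
    index = 0
    for group in spec.groups:
        sexes = ["male"] * group.n_male + ["female"] * (group.n - group.n_male)
        for i in range(group.n):
            pid = f"p{index:03d}"
            rng = np.random.default_rng(_participant_seed(seed, index))
            age = float(rng.uniform(group.age_low, group.age_high))
            sex = sexes[i]
            params = draw_observer_params(spec, age, sex, rng)
            records = simulate_participant(
                params, task, staircase, rng, participant_id=pid
            )
            trial_rows.extend(records)
            part_rows.append(
                {
                    "participant_id": pid,
                    "group": group.label,
                    "age_years": age,
                    "sex": sex,
                    "meta_noise_sd": params.meta_noise_sd,
                    "confidence_bias": params.confidence_bias,
                    "advice_trust": params.advice_trust,
                }
            )
            index += 1
    participants = pd.DataFrame(part_rows)
    trials = pd.DataFrame(trial_rows)
    return participants, trials
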