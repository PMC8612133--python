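"""End-to-end analysis pipeline.

Orchestrates one full study analysis: simulate (or ingest) a cohort,
derive per-participant summaries (accuracy, metacognitive bias,
d', meta-d', efficiency, advice scores), standardise the advice scores
and efficiency, compare the seven age-trajectory models by BIC for each
of the four confidence/advice outcomes, run between-group tests, and
test whether metacognitive efficiency mediates the age effect on
resistance to false advice.  Every artifact records the master seed and
the run is bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .advice import advice_cell_counts, propensity_score, resistance_score, standardize
from .age_models import AgePredictors, ModelComparison, build_age_predictors, fit_candidates, group_tests
from .mediation import MediationResult, mediate, mediation_verdict
from .metacognition import (
    EstimabilityError,
    clamp_negative_meta_d,
    counts_from_trials,
    estimable,
    fit_meta_d,
    mean_confidence,
)
from .observer import CohortSpec, TaskConfig, generate_cohort
from .staircase import StaircaseConfig

logger = logging.getLogger("metaadvice")

OUTCOMES = ("mean_confidence", "efficiency", "propensity", "resistance")

TRIAL_COLUMNS = [
    "participant_id", "trial_index", "phase", "difference", "majority_side",
    "choice1", "correct1", "confidence1", "advice_given", "advice_choice",
    "advice_correct", "advice_agrees", "choice2", "switched", "confidence2",
    "feedback",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "simulate"  # or "ingest"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    task: TaskConfig = field(default_factory=TaskConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    n_bins: int = 6
    clamp_negative_metad: bool = False
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    trials_path: str | None = None
    participants_path: str | None = None


@dataclass
class PipelineResult:
    """The full report bundle of one run."""

    config: RunConfig
    participants: pd.DataFrame
    trials: pd.DataFrame
    summaries: pd.DataFrame
    model_comparisons: dict[str, ModelComparison]
    group_test_table: pd.DataFrame
    mediation: MediationResult
    verdict: str
    verdict_rationale: str


def summarize_participants(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    n_bins: int = 6,
    clamp_negative_metad: bool = False,
) -> pd.DataFrame:
    """Per-participant derived measures with exclusion flags.

    Participants whose confidence data cannot support a meta-d' fit
    (e.g. all ratings on one level) keep their accuracy and bias but
    carry missing efficiency and are excluded from efficiency analyses.
    The z-columns are standardised over participants with non-missing
    values.
    """
    rows = []
    for pid, ptrials in trials.groupby("participant_id", sort=True):
        main = ptrials[ptrials["phase"] == "main"]
        row: dict = {
            "participant_id": pid,
            "n_main": len(main),
            "accuracy": float(main["correct1"].astype(bool).mean()),
            "mean_confidence": mean_confidence(ptrials),
            "d_prime": np.nan,
            "meta_d": np.nan,
            "efficiency": np.nan,
            "excluded": False,
            "exclusion_reason": "",
        }
        if estimable(ptrials, n_bins):
            try:
                fit = fit_meta_d(counts_from_trials(ptrials, n_bins))
                if clamp_negative_metad:
                    fit = clamp_negative_meta_d(fit)
                row.update(
                    d_prime=fit.d_prime,
                    meta_d=fit.meta_d,
                    efficiency=fit.efficiency,
                )
            except EstimabilityError as err:
                row.update(excluded=True, exclusion_reason=str(err))
        else:
            row.update(
                excluded=True,
                exclusion_reason="confidence data not estimable",
            )
        cells = advice_cell_counts(ptrials)
        row["propensity"] = propensity_score(ptrials)
        row["resistance"] = resistance_score(ptrials)
        for f in dataclasses.fields(cells):
            row[f.name] = getattr(cells, f.name)
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.merge(
        participants[["participant_id", "group", "age_years", "sex"]],
        on="participant_id",
        how="left",
    )
    for col in ("efficiency", "propensity", "resistance"):
        out[f"{col}_z"] = standardize(out[col].to_numpy())
    return out


def _model_comparisons(
    summaries: pd.DataFrame, predictors: AgePredictors
) -> dict[str, ModelComparison]:
    outcome_cols = {
        "mean_confidence": "mean_confidence",
        "efficiency": "efficiency_z",
        "propensity": "propensity_z",
        "resistance": "resistance_z",
    }
    comparisons = {}
    for name, col in outcome_cols.items():
        comparisons[name] = fit_candidates(
            summaries[col].to_numpy(),
            predictors,
            summaries["sex"],
            outcome_name=name,
        )
        winner = comparisons[name].winner
        logger.info(
            "BIC winner for %s: %s (BIC=%.2f)",
            name, "+".join(winner.predictors), winner.bic,
        )
    return comparisons


def run_pipeline(config: RunConfig | None = None, out_dir: str | None = None) -> PipelineResult:
    """Run the full analysis and optionally write the report bundle."""
    config = config or RunConfig()
    if config.mode == "simulate":
        participants, trials = generate_cohort(
            config.cohort, config.task, config.staircase, seed=config.seed
        )
    elif config.mode == "ingest":
        trials = load_trial_table(config.trials_path)
        participants = pd.read_csv(config.participants_path)
    else:
        raise ValueError(f"unknown mode: {config.mode}")
    logger.info(
        "cohort: %d participants, %d trials",
        len(participants), len(trials),
    )

    summaries = summarize_participants(
        trials, participants, config.n_bins, config.clamp_negative_metad
    )
    logger.info(
        "staircase check: pooled main-phase accuracy %.3f; %d excluded",
        summaries["accuracy"].mean(), int(summaries["excluded"].sum()),
    )

    predictors = build_age_predictors(summaries["age_years"].to_numpy())
    summaries = summaries.assign(
        age_linear=predictors.linear,
        age_quadratic=predictors.quadratic,
        age_emergent=predictors.emergent,
    )
    comparisons = _model_comparisons(summaries, predictors)

    test_frames = [
        group_tests(summaries[col], summaries["group"], measure_name=col)
        for col in ("accuracy", "mean_confidence", "efficiency",
                    "propensity", "resistance")
    ]
    group_table = pd.concat(test_frames, ignore_index=True)

    med = mediate(
        summaries.assign(sex_code=(summaries["sex"] == "male").astype(float)),
        x="age_emergent",
        m="efficiency",
        y="resistance",
        covariates=["sex_code"],
        n_boot=config.n_boot,
        seed=config.seed,
        alpha=config.alpha,
    )
    verdict, rationale = mediation_verdict(med, config.alpha)
    logger.info("mediation verdict: %s (%s)", verdict, rationale)

    result = PipelineResult(
        config=config,
        participants=participants,
        trials=trials,
        summaries=summaries,
        model_comparisons=comparisons,
        group_test_table=group_table,
        mediation=med,
        verdict=verdict,
        verdict_rationale=rationale,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str) -> None:
    """Write the report bundle as CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.participants.to_csv(out / "participants.csv", index=False)
    result.trials.to_csv(out / "trials.csv", index=False)
    result.summaries.to_csv(out / "participant_summaries.csv", index=False)
    result.group_test_table.to_csv(out / "group_tests.csv", index=False)
    for name, comp in result.model_comparisons.items():
        comp.table().to_csv(out / f"model_comparison_{name}.csv", index=False)
    med = {
        "paths": {k: vars(v) for k, v in result.mediation.paths.items()},
        "n": result.mediation.n,
        "n_boot": result.mediation.n_boot,
        "seed": result.mediation.seed,
        "verdict": result.verdict,
        "rationale": result.verdict_rationale,
    }
    (out / "mediation.json").write_text(json.dumps(med, indent=2))
    manifest = {
        "package_version": __version__,
        "seed": result.config.seed,
        "mode": result.config.mode,
        "n_bins": result.config.n_bins,
        "n_boot": result.config.n_boot,
        "alpha": result.config.alpha,
        "clamp_negative_metad": result.config.clamp_negative_metad,
        "n_participants": int(len(result.participants)),
        "n_excluded": int(result.summaries["excluded"].sum()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# trial-table ingestion and validation


def load_trial_table(path) -> pd.DataFrame:
    """Read a trial table written by this pipeline, restoring dtypes."""
    df = pd.read_csv(path)
    errors = validate_trial_table(df)
    if errors:
        raise ValueError(
            "trial table failed validation:\n" + "\n".join(errors[:20])
        )
    return _normalize_trials(df)


def _normalize_trials(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bool_map = {"True": True, "False": False, True: True, False: False}
    for col in ("correct1", "advice_given"):
        df[col] = df[col].map(bool_map).astype(bool)
    for col in ("advice_correct", "advice_agrees", "switched"):
        df[col] = df[col].map(bool_map).astype(object)
        df[col] = df[col].where(df[col].notna(), None)
    for col in ("confidence1", "confidence2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def validate_trial_table(table) -> list[str]:
    """Schema, range and consistency checks on a trial table.

    Accepts a path or a DataFrame; returns a list of human-readable
    error strings (empty when valid), each naming the offending row.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table
    errors: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        return [f"header mismatch: missing columns {missing}"]
    df = _normalize_trials(df)

    for i, row in df.iterrows():
        where = f"row {i} (participant {row['participant_id']})"
        if row["phase"] not in ("practice", "main"):
            errors.append(f"{where}: bad phase {row['phase']!r}")
            continue
        if row["majority_side"] not in ("A", "B") or row["choice1"] not in ("A", "B"):
            errors.append(f"{where}: sides must be 'A' or 'B'")
        is_main = row["phase"] == "main"
        conf = row["confidence1"]
        if is_main:
            if pd.isna(conf) or not 0 <= conf <= 1:
                errors.append(f"{where}: confidence1 must be in [0, 1] on main trials")
        elif not pd.isna(conf):
            errors.append(f"{where}: confidence1 present on practice trial")
        if bool(row["correct1"]) != (row["choice1"] == row["majority_side"]):
            errors.append(f"{where}: correct1 inconsistent with choices")
        advice_fields = [row["advice_choice"], row["advice_correct"],
                         row["advice_agrees"], row["choice2"], row["switched"]]
        if row["advice_given"]:
            if any(pd.isna(v) if not isinstance(v, str) else v == ""
                   for v in advice_fields):
                errors.append(f"{where}: advice fields missing on advice trial")
            else:
                if bool(row["switched"]) != (row["choice2"] != row["choice1"]):
                    errors.append(f"{where}: switched inconsistent with choices")
                if bool(row["advice_agrees"]) != (row["advice_choice"] == row["choice1"]):
                    errors.append(f"{where}: advice_agrees inconsistent")
        else:
            if any((isinstance(v, str) and v != "") or
                   (not isinstance(v, str) and not pd.isna(v))
                   for v in advice_fields):
                errors.append(f"{where}: advice fields present without advice")
    return errors
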