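import numpy as np
import pandas as pd
import pytest

from metaadvice import (
    CohortSpec,
    GroupSpec,
    ObserverParams,
    TaskConfig,
    generate_cohort,
    simulate_participant,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced three-group cohort for fast pipeline-level tests."""
    spec = CohortSpec(
        groups=(
            GroupSpec("8-9", 8.89, 9.71, 10, 4),
            GroupSpec("12-13", 12.69, 13.70, 10, 5),
            GroupSpec("16-17", 16.71, 17.76, 10, 4),
        )
    )
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def one_session():
    """One simulated participant's trial records as a DataFrame."""
    params = ObserverParams(meta_noise_sd=0.4, age_years=13.0)
    recs = simulate_participant(
        params, rng=np.random.default_rng(5), participant_id="p000"
    )
    return pd.DataFrame(recs)


def simulate_rated_trials(params, n_trials, difference, seed):
    """Fixed-difficulty rated trials (no staircase) for SDT-level tests."""
    from metaadvice import simulate_confidence, simulate_decision

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trials):
        majority, choice, evidence = simulate_decision(
            params, difference, rng
        )
        conf = simulate_confidence(params, evidence, rng)
        rows.append(
            {
                "phase": "main",
                "majority_side": majority,
                "choice1": choice,
                "correct1": choice == majority,
                "confidence1": conf,
            }
        )
    return pd.DataFrame(rows)
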