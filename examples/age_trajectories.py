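"""Compare developmental trajectory models by BIC.

Builds the three transformed age predictors (linear, quadratic,
adolescent-emergent) for a synthetic cohort, generates an outcome with
a pure adolescent-emergent age effect, and fits the seven candidate
regressions (each with a sex covariate).  BIC should select the
generating trajectory.
"""

import numpy as np

from metaadvice import build_age_predictors, fit_candidates

rng = np.random.default_rng(3)
ages = np.concatenate(
    [
        rng.uniform(8.89, 9.71, 30),
        rng.uniform(12.69, 13.70, 41),
        rng.uniform(16.71, 17.76, 36),
    ]
)
preds = build_age_predictors(ages)
sex = rng.integers(0, 2, len(ages))
signal = (preds.emergent - preds.emergent.mean()) / preds.emergent.std(ddof=1)
outcome = 0.4 * signal + rng.normal(0, 1, len(ages))

comp = fit_candidates(outcome, preds, sex, outcome_name="demo")
table = comp.table()[["model", "k", "bic", "delta_bic", "winner"]]
print(table.round(2).to_string(index=False))
print(
    f"\nwinner: {'+'.join(comp.winner.predictors)} "
    f"(beta_emergent={comp.winner.params.get('emergent', float('nan')):.3f})\n"
    "The emergent predictor changes through childhood and plateaus at\n"
    "age 12, so selecting it indicates an effect that appears by early\n"
    "adolescence and then stays flat."
)
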