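"""Fit meta-d' for an ideal and a noisy metacognitive observer.

Simulates rated trials for two observers that differ only in meta-level
noise, fits type-1 SDT and maximum-likelihood meta-d', and prints the
efficiency ratio meta-d'/d'.  The ideal observer (zero meta noise)
should recover efficiency ~ 1; meta-level noise pushes it below 1
without touching type-1 accuracy.
"""

import numpy as np
import pandas as pd

from metaadvice import (
    ObserverParams,
    counts_from_trials,
    fit_meta_d,
    simulate_confidence,
    simulate_decision,
)


def rated_trials(meta_noise_sd, n=5000, difference=30, seed=0):
    params = ObserverParams(meta_noise_sd=meta_noise_sd)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        majority, choice, evidence = simulate_decision(params, difference, rng)
        rows.append(
            {
                "phase": "main",
                "majority_side": majority,
                "choice1": choice,
                "correct1": choice == majority,
                "confidence1": simulate_confidence(params, evidence, rng),
            }
        )
    return pd.DataFrame(rows)


for noise in (0.0, 1.5):
    fit = fit_meta_d(counts_from_trials(rated_trials(noise), n_levels=6))
    print(
        f"meta_noise_sd={noise}: d'={fit.d_prime:.3f}  "
        f"meta-d'={fit.meta_d:.3f}  efficiency={fit.efficiency:.3f}"
    )
print(
    "\nEfficiency ~1 means confidence uses all the decision evidence;\n"
    "the noisy observer keeps the same d' but loses metacognitive\n"
    "information, so its meta-d' (and the ratio) drops."
)
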