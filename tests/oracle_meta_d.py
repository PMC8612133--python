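"""Independent grid-search oracle for the maximum-likelihood meta-d' fit.

Profiles the likelihood over meta-d' on a coarse-to-fine grid (down to
1e-4 resolution), optimising the 2(K-1) ordered type-2 criteria at each
grid point with Nelder-Mead under an absolute-increment parameterisation.
Shares nothing with the package's joint quasi-Newton fit beyond the
model definition itself.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def _oracle_nll(meta_d, incs, padded, d_prime, criterion):
    k = padded.shape[2]
    c_meta = criterion * meta_d / d_prime
    inc = np.abs(incs) + 1e-6
    crit_r1 = c_meta - np.cumsum(inc[: k - 1])
    crit_r2 = c_meta + np.cumsum(inc[k - 1 :])
    nll = 0.0
    for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        p_r1 = stats.norm.cdf(c_meta - mu)
        edges1 = np.concatenate(([c_meta], crit_r1, [-np.inf]))
        cdf1 = stats.norm.cdf(edges1 - mu)
        probs1 = (cdf1[:-1] - cdf1[1:]) / max(p_r1, 1e-300)
        edges2 = np.concatenate(([c_meta], crit_r2, [np.inf]))
        cdf2 = stats.norm.cdf(edges2 - mu)
        probs2 = (cdf2[1:] - cdf2[:-1]) / max(1.0 - p_r1, 1e-300)
        nll -= np.sum(padded[s, 0] * np.log(np.clip(probs1, 1e-12, None)))
        nll -= np.sum(padded[s, 1] * np.log(np.clip(probs2, 1e-12, None)))
    return nll


def _profile_nll(meta_d, padded, d_prime, criterion, x0=None, loose=False):
    k = padded.shape[2]
    if x0 is None:
        x0 = np.full(2 * (k - 1), 0.5)
    opts = (
        {"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600}
        if loose
        else {"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000}
    )
    res = optimize.minimize(
        lambda v: _oracle_nll(meta_d, v, padded, d_prime, criterion),
        x0,
        method="Nelder-Mead",
        options=opts,
    )
    return res.fun, res.x


def grid_meta_d(counts, span=(-5.0, 5.0)) -> float:
    """Best meta-d' by profile-likelihood grid search (1e-4 resolution)."""
    k = counts.n_levels
    padded = counts.padded()
    per_stim = padded.sum(axis=2)
    hit = per_stim[1, 1] / per_stim[1].sum()
    fa = per_stim[0, 1] / per_stim[0].sum()
    d_prime = stats.norm.ppf(hit) - stats.norm.ppf(fa)
    criterion = -0.5 * (stats.norm.ppf(hit) + stats.norm.ppf(fa))

    best_x = None

    def sweep(grid, x0, loose=False):
        nonlocal best_x
        best = (np.inf, grid[0])
        x = x0
        for md in grid:
            nll, x = _profile_nll(md, padded, d_prime, criterion, x, loose)
            if nll < best[0]:
                best = (nll, md)
                best_x = x.copy()
        return best[1]

    coarse = sweep(np.arange(span[0], span[1] + 1e-9, 0.05), None, loose=True)
    medium = sweep(np.arange(coarse - 0.08, coarse + 0.08, 2e-3), best_x)
    fine = sweep(np.arange(medium - 0.004, medium + 0.004, 1e-4), best_x)
    return float(fine)
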