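"""Three-variable path mediation with BCa bootstrap inference.

The model is the standard Baron-Kenny decomposition: X -> M -> Y with a
direct path, all fitted by OLS on complete cases (plus optional
covariates, carried in every regression):

* a — effect of X on M,
* b — effect of M on Y controlling for X,
* c — total effect of X on Y,
* c' — direct effect of X on Y controlling for M,
* ab — the indirect effect of X on Y through M.

For OLS with identical covariate sets the identity c = c' + a*b holds
exactly at the point estimates.  Inference on each path uses a
case-resampling bootstrap with bias-corrected and accelerated (BCa)
intervals: the bias correction z0 is the normal quantile of the
proportion of bootstrap estimates below the point estimate, and the
acceleration is the jackknife skewness term.  The two-sided p-value is
obtained by CI inversion — the smallest alpha at which the (1 - alpha)
BCa interval excludes zero — with a normal-approximation p (estimate /
bootstrap SE) reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathEstimate",
    "MediationResult",
    "fit_paths",
    "bca_bootstrap",
    "mediation_verdict",
    "mediate",
]

PATH_NAMES = ("a", "b", "c", "c_prime", "ab")


@dataclass(frozen=True)
class PathEstimate:
    """One mediation path with bootstrap inference."""

    estimate: float
    se: float
    z: float
    p: float
    p_normal: float
    ci_low: float
    ci_high: float
    alpha: float


@dataclass(frozen=True)
class MediationResult:
    """Point estimates and BCa bootstrap inference for all five paths."""

    paths: dict[str, PathEstimate]
    n: int
    n_boot: int
    seed: int
    degenerate: bool

    def __getitem__(self, name: str) -> PathEstimate:
        return self.paths[name]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"path": name, **vars(est)}
                for name, est in self.paths.items()
            ]
        )


def _ols_coef(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _complete_cases(x, m, y, covariates):
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = ~(
        np.isnan(x) | np.isnan(m) | np.isnan(y) | np.isnan(cov).any(axis=1)
    )
    return x[keep], m[keep], y[keep], cov[keep]


def _path_point_estimates(x, m, y, cov) -> dict[str, float]:
    n = len(x)
    ones = np.ones((n, 1))
    design_x = np.hstack([ones, x[:, None], cov])
    design_xm = np.hstack([ones, x[:, None], m[:, None], cov])
    for name, d in (("X+cov", design_x), ("X+M+cov", design_xm)):
        if np.linalg.matrix_rank(d) < d.shape[1]:
            raise ValueError(f"collinear design matrix in regression on {name}")
    a = _ols_coef(m, design_x)[1]
    coef_y = _ols_coef(y, design_xm)
    c_prime, b = coef_y[1], coef_y[2]
    c = _ols_coef(y, design_x)[1]
    return {
        "a": float(a),
        "b": float(b),
        "c": float(c),
        "c_prime": float(c_prime),
        "ab": float(a * b),
    }


def fit_paths(x, m, y, covariates=None) -> dict[str, float]:
    """OLS point estimates of the five mediation paths on complete cases."""
    x, m, y, cov = _complete_cases(x, m, y, covariates)
    if len(x) < 10:
        raise ValueError("need at least 10 complete cases")
    return _path_point_estimates(x, m, y, cov)


def _batched_paths(x, m, y, cov, idx: np.ndarray) -> np.ndarray:
    """Path estimates (a, b, c, c', ab) for each row of resampled indices."""
    n_rep, n = idx.shape
    xb = x[idx]  # (n_rep, n)
    mb = m[idx]
    yb = y[idx]
    covb = cov[idx]  # (n_rep, n, p)
    ones = np.ones((n_rep, n, 1))
    dx = np.concatenate([ones, xb[..., None], covb], axis=2)
    dxm = np.concatenate([ones, xb[..., None], mb[..., None], covb], axis=2)

    def solve(design, target):
        gram = np.einsum("rnp,rnq->rpq", design, design)
        rhs = np.einsum("rnp,rn->rp", design, target)
        return np.linalg.solve(gram, rhs[..., None])[..., 0]

    a = solve(dx, mb)[:, 1]
    coef_y = solve(dxm, yb)
    c_prime, b = coef_y[:, 1], coef_y[:, 2]
    c = solve(dx, yb)[:, 1]
    out = np.empty((n_rep, 5))
    out[:, 0] = a
    out[:, 1] = b
    out[:, 2] = c
    out[:, 3] = c_prime
    out[:, 4] = a * b
    return out


def _bca_interval(boot: np.ndarray, theta: float, jack: np.ndarray, alpha):
    """BCa endpoints for a scalar or vector of alpha levels."""
    scalar = np.isscalar(alpha)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    z0 = stats.norm.ppf(
        np.clip(np.mean(boot < theta), 1e-7, 1 - 1e-7)
    )
    jbar = jack.mean()
    num = np.sum((jbar - jack) ** 3)
    den = 6.0 * np.sum((jbar - jack) ** 2) ** 1.5
    accel = num / den if den > 0 else 0.0
    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)

    def adj(z):
        return stats.norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))

    lo = np.quantile(boot, np.clip(adj(z_lo), 0.0, 1.0))
    hi = np.quantile(boot, np.clip(adj(z_hi), 0.0, 1.0))
    if scalar:
        return float(lo[0]), float(hi[0])
    return lo, hi


def _invert_p(boot: np.ndarray, theta: float, jack: np.ndarray,
              grid_step: float = 1e-4) -> float:
    """Smallest alpha at which the (1 - alpha) BCa interval excludes 0."""
    if np.allclose(boot, boot[0]):
        return float(0.0 if theta != 0 else 1.0)
    alphas = np.arange(grid_step, 1.0, grid_step)
    lo, hi = _bca_interval(boot, theta, jack, alphas)
    excludes = (lo > 0) | (hi < 0)
    if not excludes.any():
        return 1.0
    return float(alphas[np.argmax(excludes)])


def bca_bootstrap(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Case-resampling bootstrap of all mediation paths with BCa intervals.

    Rows (cases) are resampled with replacement, covariates attached;
    each path gets a BCa confidence interval at the requested alpha and
    a two-sided p-value by CI inversion.  Deterministic for a fixed
    seed.
    """
    x, m, y, cov = _complete_cases(x, m, y, covariates)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    point = _path_point_estimates(x, m, y, cov)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _batched_paths(x, m, y, cov, idx)

    # jackknife for the acceleration constant
    jack_idx = np.array(
        [np.delete(np.arange(n), i) for i in range(n)]
    )
    jack = _batched_paths(x, m, y, cov, jack_idx)

    degenerate = False
    paths: dict[str, PathEstimate] = {}
    for j, name in enumerate(PATH_NAMES):
        theta = point[name]
        bj = boot[:, j]
        se = float(bj.std(ddof=1))
        if se == 0:
            degenerate = True
            z = np.inf if theta != 0 else 0.0
            p_norm = 0.0 if theta != 0 else 1.0
        else:
            z = theta / se
            p_norm = float(2.0 * stats.norm.sf(abs(z)))
        lo, hi = _bca_interval(bj, theta, jack[:, j], alpha)
        p = _invert_p(bj, theta, jack[:, j]) if se > 0 else p_norm
        paths[name] = PathEstimate(
            estimate=theta,
            se=se,
            z=float(z),
            p=p,
            p_normal=p_norm,
            ci_low=float(np.atleast_1d(lo)[0]),
            ci_high=float(np.atleast_1d(hi)[0]),
            alpha=alpha,
        )
    return MediationResult(
        paths=paths, n=n, n_boot=n_boot, seed=seed, degenerate=degenerate
    )


def mediation_verdict(
    result: MediationResult, alpha: float = 0.05
) -> tuple[str, str]:
    """Classify the mediation as 'full', 'partial' or 'none'.

    All of a, b and ab must be significant at alpha for any mediation
    claim; among those, the mediation is 'full' when the direct path c'
    is not significant and 'partial' when it is.
    """
    sig = {name: result[name].p < alpha for name in ("a", "b", "ab", "c_prime")}
    if not (sig["a"] and sig["b"] and sig["ab"]):
        missing = [k for k in ("a", "b", "ab") if not sig[k]]
        return "none", (
            "paths not significant at "
            f"alpha={alpha}: {', '.join(missing)}"
        )
    if not sig["c_prime"]:
        return "full", (
            "a, b and ab significant; direct path c' not significant "
            f"(p={result['c_prime'].p:.4g})"
        )
    return "partial", (
        "a, b and ab significant; direct path c' remains significant "
        f"(p={result['c_prime'].p:.4g})"
    )


def mediate(
    frame: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: "list[str] | None" = None,
    standardize_vars: bool = True,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Convenience front-end: mediation on named DataFrame columns.

    By default X, M and Y are standardised (z-scored over complete
    cases) before fitting, so the paths are reported as standardised
    coefficients; covariates are passed through unchanged.
    """
    cols = [x, m, y] + (covariates or [])
    data = frame[cols].astype(float)
    data = data.dropna()

    def _z(v):
        return (v - v.mean()) / v.std(ddof=1)

    xs = _z(data[x]) if standardize_vars else data[x]
    ms = _z(data[m]) if standardize_vars else data[m]
    ys = _z(data[y]) if standardize_vars else data[y]
    cov = data[covariates].to_numpy() if covariates else None
    return bca_bootstrap(
        xs.to_numpy(), ms.to_numpy(), ys.to_numpy(), cov,
        n_boot=n_boot, seed=seed, alpha=alpha,
    )
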