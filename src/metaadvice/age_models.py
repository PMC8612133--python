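"""Developmental age-trajectory models and group-level tests.

Three transformed age predictors are built from raw age in years:

* linear — z-scored raw age;
* quadratic — the square of the linear predictor (U-shaped, minimum at
  the sample mean age);
* adolescent-emergent — the quadratic predictor with every participant
  older than the plateau age (default 12) assigned the quadratic value
  evaluated at exactly that age.  The predictor therefore changes over
  childhood and is constant from early adolescence on; because it
  *decreases* towards the plateau, a negative fitted coefficient on it
  corresponds to an outcome that rises into adolescence and then
  flattens.

Each outcome is regressed on the seven non-empty subsets of these
predictors (always plus a sex covariate) by OLS, and candidates are
compared with BIC = k*ln(n) - 2*lnL, counting the intercept, the age
predictors, sex and the residual variance in k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AgePredictors",
    "CandidateFit",
    "ModelComparison",
    "build_age_predictors",
    "fit_candidates",
    "group_tests",
    "cohens_d",
    "CANDIDATE_SETS",
]

CANDIDATE_SETS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for r in (1, 2, 3)
    for combo in itertools.combinations(("linear", "quadratic", "emergent"), r)
)


@dataclass(frozen=True)
class AgePredictors:
    """The three age trajectories evaluated for a cohort."""

    linear: np.ndarray
    quadratic: np.ndarray
    emergent: np.ndarray
    plateau_age: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "linear": self.linear,
                "quadratic": self.quadratic,
                "emergent": self.emergent,
            }
        )


def build_age_predictors(
    ages_years, plateau_age: float = 12.0
) -> AgePredictors:
    """Build linear, quadratic and adolescent-emergent predictors.

    z-scoring uses the sample mean and SD (ddof=1) of the analysed
    cohort's raw ages.  The emergent predictor clamps raw age at the
    plateau before the quadratic transform, so all participants older
    than the plateau share the quadratic value at exactly that age.
    """
    ages = np.asarray(ages_years, dtype=float)
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least 2 distinct ages")
    mean, sd = ages.mean(), ages.std(ddof=1)
    linear = (ages - mean) / sd
    quadratic = linear**2
    clamped = np.minimum(ages, plateau_age)
    emergent = ((clamped - mean) / sd) ** 2
    return AgePredictors(linear, quadratic, emergent, plateau_age)


@dataclass(frozen=True)
class CandidateFit:
    """One fitted candidate model in the BIC comparison."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    log_likelihood: float
    bic: float
    n: int
    k: int
    r_squared: float


@dataclass(frozen=True)
class ModelComparison:
    """All seven candidates plus the BIC winner."""

    outcome: str
    candidates: tuple[CandidateFit, ...]
    winner_index: int

    @property
    def winner(self) -> CandidateFit:
        return self.candidates[self.winner_index]

    def table(self) -> pd.DataFrame:
        rows = []
        best = min(c.bic for c in self.candidates)
        for i, c in enumerate(self.candidates):
            rows.append(
                {
                    "model": "+".join(c.predictors),
                    "k": c.k,
                    "n": c.n,
                    "log_likelihood": c.log_likelihood,
                    "bic": c.bic,
                    "delta_bic": c.bic - best,
                    "winner": i == self.winner_index,
                    **{
                        f"beta_{name}": c.params.get(name, np.nan)
                        for name in ("linear", "quadratic", "emergent", "sex")
                    },
                }
            )
        return pd.DataFrame(rows)


def _encode_sex(sex) -> np.ndarray:
    s = pd.Series(sex)
    if s.dtype == object:
        return (s == "male").astype(float).to_numpy()
    return s.astype(float).to_numpy()


def fit_candidates(
    outcome,
    predictors: AgePredictors,
    sex,
    outcome_name: str = "outcome",
) -> ModelComparison:
    """OLS fit of the seven age models (each + sex), compared by BIC.

    Rows with a missing outcome are dropped from every candidate so the
    comparison uses an identical case set.  Sex is coded female=0,
    male=1; reported sex coefficients are male vs female.
    """
    y = np.asarray(outcome, dtype=float)
    frame = predictors.frame()
    frame["sex"] = _encode_sex(sex)
    keep = ~np.isnan(y)
    y = y[keep]
    frame = frame.loc[keep].reset_index(drop=True)
    n = len(y)

    fits = []
    for names in CANDIDATE_SETS:
        x = sm.add_constant(frame[list(names) + ["sex"]])
        if n < x.shape[1] + 2:
            raise ValueError("too few complete cases for model comparison")
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            continue  # rank-deficient candidate: excluded from comparison
        res = sm.OLS(y, x).fit()
        k = x.shape[1] + 1  # + residual variance
        # floor the residual variance so numerically perfect fits tie in
        # log-likelihood and BIC's complexity penalty decides between them
        sigma2 = max(res.ssr / n, 1e-12 * max(float(np.var(y)), 1e-300))
        llf = -0.5 * n * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0)
        bic = k * np.log(n) - 2.0 * llf
        fits.append(
            CandidateFit(
                predictors=names,
                params=res.params,
                bse=res.bse,
                pvalues=res.pvalues,
                log_likelihood=float(llf),
                bic=float(bic),
                n=n,
                k=k,
                r_squared=float(res.rsquared),
            )
        )
    if not fits:
        raise ValueError("no estimable candidate models")
    winner = int(np.argmin([f.bic for f in fits]))
    return ModelComparison(outcome_name, tuple(fits), winner)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled (ddof=1) standard deviation."""
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
        / (nx + ny - 2)
    )
    if pooled == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / pooled)


def group_tests(
    measure,
    groups,
    measure_name: str = "measure",
) -> pd.DataFrame:
    """Pairwise independent t-tests (with Cohen's d) plus one-way ANOVA.

    Returns a tidy table: one row per group pair plus an 'anova' row
    carrying F, its degrees of freedom, p, and partial eta-squared.
    Degenerate groups (fewer than 2 members) are skipped.
    """
    df = pd.DataFrame({"y": np.asarray(measure, dtype=float), "g": list(groups)})
    df = df.dropna()
    labels = [g for g in pd.unique(df["g"]) if (df["g"] == g).sum() >= 2]
    samples = {g: df.loc[df["g"] == g, "y"].to_numpy() for g in labels}

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        x, y = samples[g1], samples[g2]
        t, p = stats.ttest_ind(x, y)
        rows.append(
            {
                "measure": measure_name,
                "contrast": f"{g1} vs {g2}",
                "statistic": float(t),
                "df": len(x) + len(y) - 2,
                "p": float(p),
                "effect_size": cohens_d(x, y),
                "effect_size_name": "cohens_d",
                "n": len(x) + len(y),
            }
        )
    if len(labels) >= 2:
        arrays = [samples[g] for g in labels]
        f, p = stats.f_oneway(*arrays)
        grand = df.loc[df["g"].isin(labels), "y"].to_numpy()
        ss_total = np.sum((grand - grand.mean()) ** 2)
        ss_between = sum(
            len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays
        )
        eta_p = ss_between / ss_total if ss_total > 0 else 0.0
        rows.append(
            {
                "measure": measure_name,
                "contrast": "anova",
                "statistic": float(f),
                "df": (len(labels) - 1, len(grand) - len(labels)),
                "p": float(p),
                "effect_size": float(eta_p),
                "effect_size_name": "partial_eta_squared",
                "n": len(grand),
            }
        )
    return pd.DataFrame(rows)
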