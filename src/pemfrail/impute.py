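"""Fully-conditional-specification (FCS) multiple imputation and Rubin pooling.

Covariates with missing cells (physical demand in the motivating setting, a
job attribute measured at only a minority of plants) are imputed at the job
level: each incomplete variable is regressed on the other covariates plus
observed outcome summaries of the job — the injury count and log person-time
— and imputed values are drawn with both parameter and residual noise
(proper imputation).  Including the outcome in the imputation model is
standard practice for survival data: omitting it biases covariate-outcome
associations toward the null in the completed data.

Analyses are then run once per completed cohort and pooled with Rubin's
rules: pooled estimate = mean; total variance ``T = W + (1 + 1/m) * B`` with
``W`` the mean within-imputation variance and ``B`` the between-imputation
variance of the estimates; small-sample t reference with
``df = (m - 1) * (1 + W / ((1 + 1/m) * B))**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .simulate import _job_level_frame

OUTCOME_TERMS = ["n_events", "log_person_time"]


@dataclass
class ImputationSet:
    """m completed cohorts sharing all observed values."""

    m: int
    completed: list
    seed: int
    iterations: int

    def write(self, directory):
        """Persist as m cohort CSVs plus a manifest."""
        import json
        import os

        from .cohort import write_cohort

        os.makedirs(directory, exist_ok=True)
        paths = []
        for i, c in enumerate(self.completed):
            p = os.path.join(directory, f"imputation_{i + 1}.csv")
            write_cohort(c, p)
            paths.append(p)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump({"m": self.m, "seed": self.seed,
                       "iterations": self.iterations, "files": paths}, fh,
                      indent=2)


@dataclass
class PooledFit:
    """Rubin's-rules pooled inference across m fits of a common model."""

    m: int
    table: pd.DataFrame  # per coefficient: estimate, W, B, T, se, df, ci, p
    fits: list = field(default_factory=list)

    @property
    def coef_(self) -> pd.Series:
        return self.table["estimate"]

    @property
    def se_(self) -> pd.Series:
        return self.table["se"]

    def hazard_ratio_table(self) -> pd.DataFrame:
        """Pooled HR table over the coefficients the fits report as HRs."""
        rows = []
        for label, j in self.fits[0]._report_rows():
            name = self.fits[0].param_names_[j]
            r = self.table.loc[name]
            rows.append({
                "term": label,
                "hr": np.exp(r["estimate"]),
                "ci_low": np.exp(r["ci_low"]),
                "ci_high": np.exp(r["ci_high"]),
                "p": r["p"],
            })
        return pd.DataFrame(rows)


class FCSImputer(BaseEstimator):
    """Chained-equations imputer for job-level covariates.

    Parameters
    ----------
    m : int
        Number of completed data sets.
    iterations : int
        FCS cycles per imputation (with a single incomplete variable one
        cycle suffices; extra cycles are cheap and harmless).
    method : {'norm', 'pmm'}
        Continuous variables: Bayesian normal linear regression draws, or
        predictive-mean matching against observed donors.
    predictors : sequence of str or None
        Variables allowed in the imputation models; default all other
        covariates plus the outcome terms (n_events, log person-time).
    include_outcome : bool
        Keep the outcome summaries among the predictors.
    """

    def __init__(self, m=4, iterations=10, method="norm", predictors=None,
                 include_outcome=True, random_state=0):
        self.m = m
        self.iterations = iterations
        self.method = method
        self.predictors = predictors
        self.include_outcome = include_outcome
        self.random_state = random_state

    def fit_transform(self, cohort: Cohort) -> ImputationSet:
        self.imputation_set_ = fcs_impute(
            cohort, m=self.m, iterations=self.iterations, method=self.method,
            predictors=self.predictors, include_outcome=self.include_outcome,
            seed=self.random_state)
        return self.imputation_set_


def _draw_norm(rng, Xo, yo, Xm):
    """Proper Bayesian draw from a normal linear model; returns imputations."""
    n, p = Xo.shape
    XtX = Xo.T @ Xo
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return Xm @ beta + np.sqrt(sigma2) * rng.standard_normal(len(Xm)), Xm @ beta_hat

def _draw_logistic(rng, Xo, yo, Xm):
    import statsmodels.api as sm

    res = sm.Logit(yo, Xo).fit(disp=0)
    cov = np.asarray(res.cov_params())
    beta = rng.multivariate_normal(np.asarray(res.params), cov)
    p = 1.0 / (1.0 + np.exp(-(Xm @ beta)))
    return (rng.random(len(Xm)) < p).astype(float), p


def fcs_impute(cohort: Cohort, m=4, iterations=10, method="norm",
               predictors=None, include_outcome=True, seed=0) -> ImputationSet:
    """Impute missing covariates by chained equations; m completed cohorts.

    Missing cells are modeled at the job level (a job attribute is constant
    across a job's episodes).  A cohort without missing cells returns m
    identical copies.  Deterministic given the seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    jobs = _job_level_frame(cohort)
    incomplete = [c for c in cohort.covariates if jobs[c].isna().any()]
    if not incomplete:
        return ImputationSet(m=m, completed=[
            Cohort(cohort.data.copy(), list(cohort.covariates))
            for _ in range(m)], seed=seed, iterations=0)
    for c in incomplete:
        if jobs[c].isna().all():
            raise ValueError(f"covariate {c!r} has no observed values")

    base_predictors = predictors
    rng = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        work = jobs.copy()
        # initialize missing cells from observed draws
        for c in incomplete:
            obs = work[c].dropna().to_numpy()
            nmiss = int(work[c].isna().sum())
            work.loc[work[c].isna(), c] = rng.choice(obs, size=nmiss)
        for _cycle in range(max(iterations, 1)):
            for c in incomplete:
                preds = base_predictors
                if preds is None:
                    preds = [p for p in cohort.covariates if p != c]
                    if include_outcome:
                        preds = preds + OUTCOME_TERMS
                preds = [p for p in preds if p != c]
                miss_mask = jobs[c].isna().to_numpy()
                X = np.column_stack(
                    [np.ones(len(work))] + [work[p].to_numpy(float) for p in preds])
                yo = jobs.loc[~miss_mask, c].to_numpy(float)
                Xo, Xm = X[~miss_mask], X[miss_mask]
                binary = set(np.unique(yo)) <= {0.0, 1.0}
                if binary:
                    draws, _ = _draw_logistic(rng, Xo, yo, Xm)
                elif method == "pmm":
                    draws = _pmm(rng, Xo, yo, Xm)
                else:
                    draws, _ = _draw_norm(rng, Xo, yo, Xm)
                col = work[c].to_numpy(float)
                col[miss_mask] = draws
                work[c] = col
        data = cohort.data.copy()
        for c in incomplete:
            data[c] = work[c].reindex(data["job_id"]).to_numpy()
        completed.append(Cohort(data, list(cohort.covariates)))
    return ImputationSet(m=m, completed=completed, seed=seed,
                         iterations=max(iterations, 1))


def _pmm(rng, Xo, yo, Xm, k=5):
    """Predictive-mean matching: draw from the k observed nearest predictions."""
    imputed, fitted_m = _draw_norm(rng, Xo, yo, Xm)
    fitted_o = Xo @ (np.linalg.pinv(Xo.T @ Xo) @ (Xo.T @ yo))
    out = np.empty(len(Xm))
    order = np.argsort(fitted_o)
    fo_sorted, yo_sorted = fitted_o[order], yo[order]
    pos = np.searchsorted(fo_sorted, fitted_m)
    for i, p in enumerate(pos):
        lo = max(0, p - k)
        hi = min(len(yo_sorted), p + k)
        window = yo_sorted[lo:hi]
        out[i] = window[rng.integers(0, len(window))]
    return out


def pool_rubin(fits) -> PooledFit:
    """Pool m fits of the same model specification by Rubin's rules."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    names = list(fits[0].param_names_)
    for f in fits[1:]:
        if list(f.param_names_) != names:
            raise ValueError("fits have mismatched parameterizations")
    m = len(fits)
    Q = np.vstack([np.asarray(f.params_, float) for f in fits])
    U = np.vstack([np.asarray(f.se_, float) ** 2 for f in fits])
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    if m > 1:
        B = Q.var(axis=0, ddof=1)
    else:
        B = np.full_like(qbar, np.nan)
    T = W + (1.0 + 1.0 / m) * np.where(np.isnan(B), 0.0, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * B / W
        df = (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2
    df = np.where((B > 0) & np.isfinite(df), df, np.inf)
    se = np.sqrt(T)
    tcrit = np.where(np.isinf(df), stats.norm.ppf(0.975),
                     stats.t.ppf(0.975, np.where(np.isinf(df), 1e6, df)))
    z = qbar / se
    p = np.where(np.isinf(df), 2 * stats.norm.sf(np.abs(z)),
                 2 * stats.t.sf(np.abs(z), np.where(np.isinf(df), 1e6, df)))
    table = pd.DataFrame({
        "estimate": qbar, "W": W, "B": B, "T": T, "se": se, "df": df,
        "ci_low": qbar - tcrit * se, "ci_high": qbar + tcrit * se, "p": p,
    }, index=names)
    return PooledFit(m=m, table=table, fits=list(fits))
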