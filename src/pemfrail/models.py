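"""Parametric proportional-hazards models for recurrent events on the job clock.

Three baseline-hazard families, each with optional gamma frailty:

* exponential — constant baseline rate ``lam`` (the null: experience does not
  change the hazard);
* Weibull — ``h0(t) = lam * p * t**(p-1)``, shape ``p = 1`` recovering the
  exponential;
* piecewise exponential (PEM) — constant rate within each piece of a
  :class:`~pemfrail.cohort.PieceGrid`, free to jump at the cuts.

The independence log-likelihood over episodes ``(entry, exit]`` with event
indicator ``d`` and covariates ``x`` is::

    sum d*(log h0(exit) + x'beta) - exp(x'beta) * (H0(exit) - H0(entry))

where ``H0`` is the cumulative baseline hazard (left truncation at ``entry``
is handled by the difference).  With gamma frailty ``u ~ Gamma(1/theta,
theta)`` (mean 1, variance theta) shared across all of a subject's episodes,
the frailty is integrated out analytically, giving per subject ``i`` with
``d_i`` total events and covariate-adjusted cumulative hazard ``H_i``::

    sum_events (log h0 + x'beta)
    + lgamma(1/theta + d_i) - lgamma(1/theta) + d_i*log(theta)
    - (1/theta + d_i) * log(1 + theta*H_i)

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit(cohort)``, read fitted attributes with trailing underscores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

from .cohort import Cohort, PieceGrid


class MissingCovariateError(ValueError):
    """Raised when a model is fit on covariates with missing cells."""


class _EpisodeArrays:
    """Numeric views of a cohort used by the likelihoods."""

    def __init__(self, cohort: Cohort, covariates):
        d = cohort.data
        self.entry = d["entry"].to_numpy(float)
        self.exit = d["exit"].to_numpy(float)
        self.event = d["event"].to_numpy(float)
        if covariates:
            X = d[list(covariates)].to_numpy(float)
            if np.isnan(X).any():
                raise MissingCovariateError(
                    "covariates contain missing values; impute first "
                    "(see pemfrail.impute.fcs_impute) or run a complete-case subset"
                )
            self.X = X
        else:
            self.X = np.zeros((len(d), 0))
        codes, uniques = pd.factorize(d["subject_id"])
        self.subject = codes
        self.n_subjects = len(uniques)


class BaseHazardModel(BaseEstimator):
    """Shared fitting machinery; subclasses define the baseline family.

    Parameters
    ----------
    covariates : sequence of str
        Covariate columns entering the linear predictor ``x'beta``.
    frailty : bool
        Include a subject-level gamma frailty (variance ``theta``).
    theta_start : float
        Starting value for the frailty variance.
    gtol : float
        Gradient-norm convergence tolerance.
    """

    _family = None

    def __init__(self, covariates=(), frailty=False, theta_start=0.2,
                 gtol=1e-8, maxiter=1000):
        self.covariates = covariates
        self.frailty = frailty
        self.theta_start = theta_start
        self.gtol = gtol
        self.maxiter = maxiter

    # -- baseline family interface (parameters on log scale) -------------
    def _n_base(self) -> int:
        raise NotImplementedError

    def _base_param_names(self) -> list:
        raise NotImplementedError

    def _log_base_hazard(self, base, t):
        raise NotImplementedError

    def _cum_base_hazard(self, base, t):
        raise NotImplementedError

    def _base_start(self, arr: _EpisodeArrays):
        raise NotImplementedError

    def _dlog_base_hazard(self, base, t):
        """d log h0(t) / d base_params, shape (n, n_base)."""
        raise NotImplementedError

    def _dcum_base_hazard(self, base, t):
        """d H0(t) / d base_params, shape (n, n_base)."""
        raise NotImplementedError

    # -- likelihood -------------------------------------------------------
    def _loglik_arrays(self, params, arr: _EpisodeArrays, frailty: bool) -> float:
        nb = self._n_base()
        p = arr.X.shape[1]
        base = params[:nb]
        beta = params[nb:nb + p]
        eta = arr.X @ beta
        dH = (self._cum_base_hazard(base, arr.exit)
              - self._cum_base_hazard(base, arr.entry))
        ev = arr.event
        with np.errstate(divide="ignore", invalid="ignore"):
            log_h = self._log_base_hazard(base, arr.exit)
        event_part = float(np.sum(ev * (log_h + eta)))
        if not frailty:
            return event_part - float(np.sum(np.exp(eta) * dH))
        theta = float(np.exp(params[nb + p]))
        H_i = np.bincount(arr.subject, weights=np.exp(eta) * dH,
                          minlength=arr.n_subjects)
        d_i = np.bincount(arr.subject, weights=ev, minlength=arr.n_subjects)
        inv = 1.0 / theta
        subj_part = (special.gammaln(inv + d_i) - special.gammaln(inv)
                     + d_i * np.log(theta)
                     - (inv + d_i) * np.log1p(theta * H_i))
        return event_part + float(np.sum(subj_part))

    def _grad_arrays(self, params, arr: _EpisodeArrays, frailty: bool):
        """Analytic gradient of the log-likelihood in ``params``."""
        nb = self._n_base()
        p = arr.X.shape[1]
        base = params[:nb]
        beta = params[nb:nb + p]
        eta = arr.X @ beta
        e_eta = np.exp(eta)
        dH = (self._cum_base_hazard(base, arr.exit)
              - self._cum_base_hazard(base, arr.entry))
        ddH = (self._dcum_base_hazard(base, arr.exit)
               - self._dcum_base_hazard(base, arr.entry))
        dlogh = self._dlog_base_hazard(base, arr.exit)
        ev = arr.event

        if not frailty:
            w = e_eta  # multiplier on each episode's cumulative-hazard term
            g_theta = None
        else:
            theta = float(np.exp(params[nb + p]))
            inv = 1.0 / theta
            H_i = np.bincount(arr.subject, weights=e_eta * dH,
                              minlength=arr.n_subjects)
            d_i = np.bincount(arr.subject, weights=ev, minlength=arr.n_subjects)
            A_i = (inv + d_i) * theta / (1.0 + theta * H_i)
            w = A_i[arr.subject] * e_eta
            dtheta = (-(inv**2) * (special.digamma(inv + d_i) - special.digamma(inv))
                      + d_i * inv
                      + inv**2 * np.log1p(theta * H_i)
                      - (inv + d_i) * H_i / (1.0 + theta * H_i))
            g_theta = theta * float(np.sum(dtheta))

        g_base = ev @ dlogh - w @ ddH
        g_beta = arr.X.T @ (ev - w * dH)
        parts = [g_base, g_beta]
        if frailty:
            parts.append([g_theta])
        return np.concatenate(parts)

    def log_likelihood(self, cohort: Cohort, params=None, frailty=None) -> float:
        """Log-likelihood at ``params`` (fitted parameters if omitted).

        ``params`` layout: baseline parameters on the log scale, then the
        covariate coefficients ``beta``, then ``log(theta)`` if ``frailty``.
        """
        arr = _EpisodeArrays(cohort, self.covariates)
        if frailty is None:
            frailty = self.frailty
        if params is None:
            params = self.params_
        return self._loglik_arrays(np.asarray(params, float), arr, frailty)

    # -- fitting ----------------------------------------------------------
    def fit(self, cohort: Cohort):
        """Maximize the (independence or frailty-marginal) likelihood."""
        arr = _EpisodeArrays(cohort, self.covariates)
        nb, p = self._n_base(), arr.X.shape[1]
        self.n_events_ = int(arr.event.sum())
        self.n_subjects_ = arr.n_subjects
        self.person_time_ = float((arr.exit - arr.entry).sum())

        if self.n_events_ == 0:
            warnings.warn("no events in cohort: baseline rate at boundary (0)")
            k = nb + p + (1 if self.frailty else 0)
            self.params_ = np.full(k, -np.inf)
            self.params_[nb:nb + p] = 0.0
            self.loglik_ = 0.0
            self.converged_ = True
            self.cov_ = np.full((k, k), np.nan)
            self._finalize(arr)
            return self

        x0 = np.concatenate([self._base_start(arr), np.zeros(p)])
        x_ind, ok_ind = self._maximize(x0, arr, frailty=False)
        if self.frailty:
            x0 = np.concatenate([x_ind, [np.log(self.theta_start)]])
            x_opt, ok = self._maximize(x0, arr, frailty=True)
        else:
            x_opt, ok = x_ind, ok_ind
        self.params_ = x_opt
        self.loglik_ = self._loglik_arrays(x_opt, arr, self.frailty)
        self.converged_ = bool(ok)
        if not ok:
            warnings.warn(f"{type(self).__name__}: optimizer did not converge")
        H = numdiff.approx_fprime(
            x_opt, lambda q: -self._grad_arrays(q, arr, self.frailty),
            centered=True)
        H = (H + H.T) / 2.0
        try:
            self.cov_ = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            self.cov_ = np.full_like(H, np.nan)
        self._finalize(arr)
        return self

    def _maximize(self, x0, arr, frailty):
        res = optimize.minimize(
            lambda q: (-self._loglik_arrays(q, arr, frailty),
                       -self._grad_arrays(q, arr, frailty)),
            x0, method="BFGS", jac=True,
            options={"gtol": self.gtol, "maxiter": self.maxiter},
        )
        scale = max(1.0, abs(res.fun))
        ok = res.success or np.linalg.norm(res.jac) < 1e-5 * scale
        return res.x, ok

    def _finalize(self, arr):
        names = self._base_param_names() + list(self.covariates)
        if self.frailty:
            names = names + ["log_theta"]
        self.param_names_ = names
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov_))
        self.se_ = pd.Series(se, index=names)
        self.coef_ = pd.Series(self.params_, index=names)
        nb = self._n_base()
        p = arr.X.shape[1]
        self.beta_ = self.coef_.iloc[nb:nb + p]
        self.n_params_ = len(self.params_)
        if self.frailty:
            self.theta_ = float(np.exp(self.params_[-1]))
            self.theta_se_ = float(self.theta_ * se[-1])
        else:
            self.theta_ = 0.0
            self.theta_se_ = np.nan

    # -- reporting --------------------------------------------------------
    def _report_rows(self):
        """(label, index) pairs of coefficients reported as hazard ratios."""
        nb = self._n_base()
        return [(name, nb + j) for j, name in enumerate(self.covariates)]

    def hazard_ratio_table(self) -> pd.DataFrame:
        """HR = exp(coef), 95% Wald CI and p-value per reported coefficient.

        With frailty the HRs are conditional on the frailty (within-subject
        comparisons), not population-averaged.
        """
        rows = []
        for label, j in self._report_rows():
            b, s = self.params_[j], self.se_.iloc[j]
            z = b / s if s > 0 else np.nan
            rows.append({
                "term": label,
                "hr": np.exp(b),
                "ci_low": np.exp(b - 1.959963984540054 * s),
                "ci_high": np.exp(b + 1.959963984540054 * s),
                "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            })
        return pd.DataFrame(rows)

    def predict_survival(self, covariates=None, times=(), kind="conditional"):
        """Injury-free probability S(t | x) on a time grid.

        ``kind='conditional'`` gives ``exp(-H0(t) e^{x'beta})`` (frailty u=1);
        ``kind='population'`` gives the frailty-integrated curve
        ``(1 + theta*H0(t)*e^{x'beta})**(-1/theta)``.
        """
        times = np.asarray(times, float)
        if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
            raise ValueError("times must be nonnegative and increasing")
        covariates = covariates or {}
        unknown = set(covariates) - set(self.covariates)
        if unknown:
            raise KeyError(f"covariates not in fit: {sorted(unknown)}")
        eta = sum(self.beta_[k] * covariates.get(k, 0.0) for k in self.covariates)
        nb = self._n_base()
        H = self._cum_base_hazard(self.params_[:nb], times) * np.exp(eta)
        if kind == "conditional":
            return np.exp(-H)
        if kind == "population":
            if not self.frailty or self.theta_ <= 0:
                return np.exp(-H)
            return (1.0 + self.theta_ * H) ** (-1.0 / self.theta_)
        raise ValueError("kind must be 'conditional' or 'population'")


class ExponentialHazard(BaseHazardModel):
    """Constant baseline hazard ``lam`` — the null model (experience inert).

    Without covariates or frailty the MLE is closed form: ``lam = events /
    person-time``; the optimizer recovers it and the score vanishes there.
    """

    _family = "exponential"

    def _n_base(self):
        return 1

    def _base_param_names(self):
        return ["log_rate"]

    def _log_base_hazard(self, base, t):
        return np.full(np.shape(t), base[0])

    def _cum_base_hazard(self, base, t):
        return np.exp(base[0]) * np.asarray(t, float)

    def _base_start(self, arr):
        d, E = arr.event.sum(), (arr.exit - arr.entry).sum()
        return np.array([np.log(max(d, 0.5) / E)])

    def _dlog_base_hazard(self, base, t):
        return np.ones((np.size(t), 1))

    def _dcum_base_hazard(self, base, t):
        return self._cum_base_hazard(base, t)[:, None] if np.ndim(t) else \
            np.atleast_1d(self._cum_base_hazard(base, t))[:, None]

    @property
    def rate_(self) -> float:
        return float(np.exp(self.params_[0]))


class WeibullHazard(BaseHazardModel):
    """Weibull baseline ``h0(t) = lam * p * t**(p-1)`` (``H0 = lam * t**p``).

    Parameterized so shape ``p = 1`` is exactly the exponential model (some
    software calls this parameter the "scale"; here ``p`` multiplies the
    exponent of time).  ``p > 1``: rising hazard; ``p < 1``: falling.
    """

    _family = "weibull"

    def _n_base(self):
        return 2

    def _base_param_names(self):
        return ["log_rate", "log_shape"]

    def _log_base_hazard(self, base, t):
        log_lam, log_p = base
        p = np.exp(log_p)
        t = np.asarray(t, float)
        return log_lam + log_p + (p - 1.0) * np.log(t)

    def _cum_base_hazard(self, base, t):
        log_lam, log_p = base
        t = np.asarray(t, float)
        return np.exp(log_lam) * np.power(t, np.exp(log_p))

    def _base_start(self, arr):
        d, E = arr.event.sum(), (arr.exit - arr.entry).sum()
        return np.array([np.log(max(d, 0.5) / E), 0.0])

    def _dlog_base_hazard(self, base, t):
        p = np.exp(base[1])
        t = np.asarray(t, float)
        return np.column_stack([np.ones(t.size), 1.0 + p * np.log(t)])

    def _dcum_base_hazard(self, base, t):
        p = np.exp(base[1])
        t = np.asarray(t, float)
        H = self._cum_base_hazard(base, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            dlogp = np.where(t > 0, H * p * np.log(t), 0.0)
        return np.column_stack([H, dlogp])

    @property
    def shape_(self) -> float:
        return float(np.exp(self.params_[1]))


class PiecewiseExponentialHazard(BaseHazardModel):
    """K-piece exponential baseline: constant rate per piece, jumps at cuts.

    Parameterized as the log-rate of the *reference* piece (the last piece,
    the experienced period) plus one log hazard-ratio per earlier piece, so
    the two-piece "inexperienced period" effect is a single coefficient and
    appears directly in :meth:`hazard_ratio_table`.

    Parameters
    ----------
    cuts : sequence of float
        Cut points in months; ``cuts=[12]`` is the hypothesis-driven
        two-piece model.
    """

    _family = "pem"

    def __init__(self, cuts=(12.0,), covariates=(), frailty=False,
                 theta_start=0.2, gtol=1e-8, maxiter=1000):
        super().__init__(covariates=covariates, frailty=frailty,
                         theta_start=theta_start, gtol=gtol, maxiter=maxiter)
        self.cuts = cuts

    @property
    def grid(self) -> PieceGrid:
        return PieceGrid(tuple(self.cuts))

    def _n_base(self):
        return len(tuple(self.cuts)) + 1

    def _base_param_names(self):
        labels = self.grid.labels()
        return ["log_rate_ref"] + [f"logHR_piece_{lab}" for lab in labels[:-1]]

    def _log_lams(self, base):
        """Per-piece log rates; base = (log lam_ref, gamma_1..gamma_{K-1})."""
        return np.concatenate([base[0] + base[1:], [base[0]]])

    def _log_base_hazard(self, base, t):
        return self._log_lams(base)[self.grid.piece_of(t)]

    def _cum_base_hazard(self, base, t):
        lams = np.exp(self._log_lams(base))
        edges = self.grid.edges()
        t = np.atleast_1d(np.asarray(t, float))
        # time spent in each piece up to t
        width = np.clip(t[:, None] - edges[:-1][None, :], 0.0, None)
        cap = edges[1:] - edges[:-1]
        width = np.minimum(width, cap[None, :])
        return width @ lams

    def _base_start(self, arr):
        grid = self.grid
        edges = grid.edges()
        K = grid.n_pieces
        d_k = np.zeros(K)
        E_k = np.zeros(K)
        ev_piece = grid.piece_of(arr.exit)
        np.add.at(d_k, ev_piece, arr.event)
        for k in range(K):
            E_k[k] = np.maximum(
                0.0,
                np.minimum(arr.exit, edges[k + 1]) - np.maximum(arr.entry, edges[k]),
            ).sum()
        log_lam = np.log(np.maximum(d_k, 0.5) / np.maximum(E_k, 1e-12))
        return np.concatenate([[log_lam[-1]], log_lam[:-1] - log_lam[-1]])

    def _dlog_base_hazard(self, base, t):
        K = self._n_base()
        piece = self.grid.piece_of(t)
        out = np.zeros((piece.size, K))
        out[:, 0] = 1.0
        for k in range(K - 1):
            out[:, 1 + k] = piece == k
        return out

    def _dcum_base_hazard(self, base, t):
        lams = np.exp(self._log_lams(base))
        edges = self.grid.edges()
        t = np.atleast_1d(np.asarray(t, float))
        width = np.clip(t[:, None] - edges[:-1][None, :], 0.0, None)
        width = np.minimum(width, (edges[1:] - edges[:-1])[None, :])
        piece_H = width * lams[None, :]  # lam_k * time spent in piece k
        K = self._n_base()
        out = np.empty((t.size, K))
        out[:, 0] = piece_H.sum(axis=1)
        out[:, 1:] = piece_H[:, :-1]
        return out

    def _report_rows(self):
        labels = self.grid.labels()
        rows = [(f"piece {lab} vs {labels[-1]}", 1 + k)
                for k, lab in enumerate(labels[:-1])]
        nb = self._n_base()
        rows += [(name, nb + j) for j, name in enumerate(self.covariates)]
        return rows

    @property
    def piece_rates_(self) -> np.ndarray:
        return np.exp(self._log_lams(self.params_[: self._n_base()]))


def fit_pem_poisson(expanded: pd.DataFrame, covariate_names=(), cuts=(),
                    n_pieces=None) -> "PiecewiseExponentialHazard":
    """Fit a piecewise exponential model via its Poisson-GLM representation.

    Takes the long-format rows of :func:`~pemfrail.cohort.split_at_cuts`
    (each row carries at most one event) and runs a Poisson regression of
    events on piece dummies plus covariates with a log-exposure offset; the
    piece structure enters the parameter vector as dummy variables.  The
    returned log-likelihood is converted to the survival scale, which differs
    from the Poisson one by the parameter-free constant
    ``sum(events * log(exposure))``.

    Returns a :class:`PiecewiseExponentialHazard` with fitted attributes
    populated from the GLM; estimates agree with direct maximization.
    """
    import statsmodels.api as sm

    cuts = tuple(cuts)
    K = n_pieces if n_pieces is not None else len(cuts) + 1
    piece = expanded["piece"].to_numpy(int)
    present = np.unique(piece)
    dropped = sorted(set(range(K)) - set(present))
    if dropped:
        warnings.warn(f"pieces with zero exposure dropped: {dropped}")
    y = expanded["events"].to_numpy(float)
    offset = np.log(expanded["exposure"].to_numpy(float))
    model = PiecewiseExponentialHazard(cuts=cuts, covariates=tuple(covariate_names))
    pretty = (model._base_param_names() if len(cuts) + 1 == K
              else ["log_rate_ref"] + [f"logHR_piece_{k}" for k in range(K - 1)])
    cols = [np.ones(len(expanded))]
    names = [pretty[0]]
    for k in range(K - 1):
        if k in dropped:
            continue
        cols.append((piece == k).astype(float))
        names.append(pretty[1 + k])
    for c in covariate_names:
        cols.append(expanded[c].to_numpy(float))
        names.append(c)
    Xd = np.column_stack(cols)
    glm = sm.GLM(y, Xd, family=sm.families.Poisson(), offset=offset)
    res = glm.fit()

    n_base = 1 + (K - 1) - len(dropped)
    model.params_ = np.asarray(res.params)
    model.cov_ = np.asarray(res.cov_params())
    model.loglik_ = float(res.llf - np.sum(y * offset))
    model.converged_ = bool(res.converged)
    model.n_events_ = int(y.sum())
    model.n_subjects_ = expanded["subject_id"].nunique()
    model.person_time_ = float(expanded["exposure"].sum())
    model.param_names_ = names
    se = np.sqrt(np.diag(model.cov_))
    model.se_ = pd.Series(se, index=names)
    model.coef_ = pd.Series(model.params_, index=names)
    model.beta_ = model.coef_.iloc[n_base:]
    model.n_params_ = len(model.params_)
    model.theta_ = 0.0
    model.theta_se_ = np.nan
    return model


def fit_model(spec, cohort: Cohort) -> BaseHazardModel:
    """Fit a model given a family name or an estimator instance.

    ``spec`` may be an unfitted estimator, or one of the family names
    ``'exponential' | 'weibull' | 'pem'`` (pem defaults to ``cuts=[12]``).
    """
    if isinstance(spec, BaseHazardModel):
        return spec.fit(cohort)
    families = {
        "exponential": ExponentialHazard,
        "weibull": WeibullHazard,
        "pem": PiecewiseExponentialHazard,
    }
    return families[spec]().fit(cohort)


def loglik_independence(model: BaseHazardModel, params, cohort: Cohort) -> float:
    """Independence log-likelihood at ``params`` (log-scale baseline + beta)."""
    return model.log_likelihood(cohort, params=params, frailty=False)


def loglik_frailty(model: BaseHazardModel, params, theta: float, cohort: Cohort) -> float:
    """Gamma-frailty marginal log-likelihood; ``theta`` > 0 is the frailty variance."""
    if theta <= 0:
        raise ValueError("theta must be > 0; use loglik_independence for theta = 0")
    q = np.concatenate([np.asarray(params, float), [np.log(theta)]])
    return model.log_likelihood(cohort, params=q, frailty=True)
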