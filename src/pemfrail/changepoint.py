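"""Data-driven two-piece changepoint estimation by profile likelihood.

For each candidate cut ``tau`` the two-piece exponential model is fit by
maximum likelihood (independence likelihood; frailty enters only in final
full-cohort fits) and the candidate with the largest maximized
log-likelihood is the estimate.  Variability is assessed by an
employee-level bootstrap: workers are resampled with replacement — all of a
worker's jobs and episodes travel together — and the changepoint is
re-estimated on the same candidate grid in each replicate.

Note the likelihood-ratio statistic comparing the exponential model to the
two-piece model *at the estimated* cut does not have a chi-square(1) null
distribution (the cut is estimated, not fixed).  The selection pipeline
therefore estimates the cut on a learning set and tests on a held-out test
set, where the cut is fixed and standard LRT behavior applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, PieceGrid, split_at_cuts
from .models import fit_pem_poisson


@dataclass
class ChangepointEstimate:
    """Profile-likelihood changepoint estimate."""

    tau_hat: float
    profile: pd.DataFrame      # columns: tau, loglik, feasible
    candidates: np.ndarray

    def to_csv(self, path):
        self.profile.to_csv(path, index=False)


@dataclass
class BootstrapResult:
    """Employee-level bootstrap of the changepoint estimate."""

    B: int
    sample_size: int
    replicates: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))

    def summary(self) -> str:
        return f"tau_hat bootstrap (mean {self.mean:.2f}, SD {self.sd:.2f})"


def default_candidates(cohort: Cohort) -> np.ndarray:
    """Integer months from 1 to the 95th percentile of observed exit times."""
    hi = int(np.floor(np.percentile(cohort.data["exit"], 95)))
    return np.arange(1.0, max(hi, 2))


def _episode_stats(cohort: Cohort):
    d = cohort.data
    return (d["entry"].to_numpy(float), d["exit"].to_numpy(float),
            d["event"].to_numpy(float))


def _profile_closed_form(entry, exit_, event, candidates):
    """Maximized two-piece log-likelihood per candidate, no covariates.

    Per piece the MLE is d_k/E_k and the profile likelihood is
    ``sum_k d_k log(d_k/E_k) - d_k``, vectorized over candidates.
    """
    taus = np.asarray(candidates, float)[None, :]
    E1 = (np.minimum(exit_[:, None], taus) - np.minimum(entry[:, None], taus)).sum(0)
    d1 = (event[:, None] * (exit_[:, None] <= taus)).sum(0)
    E, d = (exit_ - entry).sum(), event.sum()
    E2, d2 = E - E1, d - d1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (np.where(d1 > 0, d1 * np.log(d1 / E1), 0.0)
              + np.where(d2 > 0, d2 * np.log(d2 / E2), 0.0) - d)
    return ll, d1, d2


class ChangepointEstimator(BaseEstimator):
    """Profile-likelihood estimator of the two-piece cut point.

    Parameters
    ----------
    candidates : array-like or None
        Candidate cuts in months; default integer months 1..95th percentile
        of exit times.
    covariates : sequence of str
        Adjustment covariates (fits route through the Poisson GLM).
    min_events : int
        Feasibility floor: candidates leaving fewer events on either side
        are excluded.
    """

    def __init__(self, candidates=None, covariates=(), min_events=5):
        self.candidates = candidates
        self.covariates = covariates
        self.min_events = min_events

    def fit(self, cohort: Cohort):
        est = profile_changepoint(
            cohort,
            candidates=self.candidates,
            covariates=self.covariates,
            min_events=self.min_events,
        )
        self.tau_hat_ = est.tau_hat
        self.profile_ = est.profile
        self.estimate_ = est
        return self

    def bootstrap(self, cohort: Cohort, B=400, sample_size=10_000, seed=0):
        return bootstrap_changepoint(
            cohort, candidates=self.candidates, B=B, sample_size=sample_size,
            seed=seed, covariates=self.covariates, min_events=self.min_events,
        )


def profile_changepoint(cohort: Cohort, candidates=None, covariates=(),
                        min_events=5) -> ChangepointEstimate:
    """Estimate the two-piece cut by maximizing the profile log-likelihood.

    Ties are broken toward the smaller candidate.  Raises ``ValueError`` if
    no candidate leaves at least ``min_events`` events on both sides.
    """
    if candidates is None:
        candidates = default_candidates(cohort)
    candidates = np.sort(np.asarray(candidates, float))
    if candidates.size == 0:
        raise ValueError("empty candidate grid")
    entry, exit_, event = _episode_stats(cohort)

    ll_cf, d1, d2 = _profile_closed_form(entry, exit_, event, candidates)
    feasible = (d1 >= min_events) & (d2 >= min_events)
    if not feasible.any():
        raise ValueError("no candidate leaves enough events on both sides")

    if len(covariates) == 0:
        ll = ll_cf
    else:
        ll = np.full(candidates.shape, -np.inf)
        for i, tau in enumerate(candidates):
            if not feasible[i]:
                continue
            expanded = split_at_cuts(cohort, PieceGrid((tau,)))
            fit = fit_pem_poisson(expanded, covariates, cuts=(tau,))
            ll[i] = fit.loglik_
    ll_masked = np.where(feasible, ll, -np.inf)
    best = int(np.argmax(ll_masked))  # argmax takes the first max -> smaller tau
    profile = pd.DataFrame({"tau": candidates, "loglik": ll,
                            "feasible": feasible})
    return ChangepointEstimate(tau_hat=float(candidates[best]),
                               profile=profile, candidates=candidates)


def bootstrap_changepoint(cohort: Cohort, candidates=None, B=400,
                          sample_size=10_000, seed=0, covariates=(),
                          min_events=5) -> BootstrapResult:
    """Employee-level bootstrap of the changepoint (resampling whole workers).

    ``B`` with-replacement samples of ``sample_size`` employees are drawn;
    the changepoint is re-estimated per replicate on the same candidate
    grid.  A worker drawn twice contributes all episodes twice.
    """
    if B < 2:
        raise ValueError("B must be >= 2 (otherwise the SD is undefined)")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if candidates is None:
        candidates = default_candidates(cohort)
    candidates = np.sort(np.asarray(candidates, float))
    rng = np.random.default_rng(seed)
    subjects = pd.unique(cohort.data["subject_id"])
    codes = pd.factorize(cohort.data["subject_id"])[0]

    if len(covariates) == 0:
        # per-subject sufficient statistics per candidate -> replicate totals
        entry, exit_, event = _episode_stats(cohort)
        taus = candidates[None, :]
        e1 = np.minimum(exit_[:, None], taus) - np.minimum(entry[:, None], taus)
        d1 = event[:, None] * (exit_[:, None] <= taus)
        n_s = len(subjects)
        E1s = np.zeros((n_s, len(candidates)))
        D1s = np.zeros((n_s, len(candidates)))
        np.add.at(E1s, codes, e1)
        np.add.at(D1s, codes, d1)
        Es = np.bincount(codes, weights=exit_ - entry, minlength=n_s)
        Ds = np.bincount(codes, weights=event, minlength=n_s)
        reps = np.empty(B)
        for b in range(B):
            counts = np.bincount(
                rng.integers(0, n_s, size=sample_size), minlength=n_s
            ).astype(float)
            E1 = counts @ E1s
            D1 = counts @ D1s
            E, d = counts @ Es, counts @ Ds
            E2, D2 = E - E1, d - D1
            feas = (D1 >= min_events) & (D2 >= min_events)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = (np.where(D1 > 0, D1 * np.log(D1 / E1), 0.0)
                      + np.where(D2 > 0, D2 * np.log(D2 / E2), 0.0) - d)
            ll_masked = np.where(feas, ll, -np.inf)
            if not feas.any():  # tiny resample: fall back to unconstrained argmax
                ll_masked = np.where(np.isfinite(ll), ll, -np.inf)
            reps[b] = candidates[int(np.argmax(ll_masked))]
    else:
        groups = cohort.data.groupby("subject_id", sort=False).indices
        idx_of = [groups[s] for s in subjects]
        reps = np.empty(B)
        for b in range(B):
            draw = rng.integers(0, len(subjects), size=sample_size)
            frames = []
            for r, si in enumerate(draw):
                sub = cohort.data.iloc[idx_of[si]].copy()
                sub["subject_id"] = f"rep{r}"
                frames.append(sub)
            boot = Cohort(pd.concat(frames, ignore_index=True),
                          list(cohort.covariates))
            est = profile_changepoint(boot, candidates, covariates, min_events)
            reps[b] = est.tau_hat
    return BootstrapResult(B=B, sample_size=sample_size, replicates=reps,
                           seed=seed)
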