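"""Learning/test partition, model comparison, KM diagnostics and the
end-to-end selection pipeline.

The comparison protocol, on a cohort split by employee into a learning set
(default two-thirds) and a test set:

1. partition the employees;
2. estimate the data-driven cut ``tau_hat`` on the learning set only;
3. bootstrap ``tau_hat`` from the learning set (employee-level resampling);
4. fit the exponential, Weibull, hypothesis-driven two-piece (cut at 12
   months) and data-driven two-piece (cut at ``tau_hat``) models on the
   held-out test set; compare nested pairs by LRT and non-nested pairs by
   BIC / Schwarz Bayes factors;
5. refit the two-piece models with gamma frailty on the full cohort —
   complete-case and, when a covariate has missing cells, a multiple
   imputation path pooled by Rubin's rules.

Because ``tau_hat`` never sees the test set, the test-set LRT against the
exponential null retains its standard chi-square behavior.  The two
two-piece models address different questions and are never compared to each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .changepoint import (BootstrapResult, ChangepointEstimate,
                          bootstrap_changepoint, profile_changepoint)
from .cohort import Cohort
from .models import (BaseHazardModel, ExponentialHazard,
                     PiecewiseExponentialHazard, WeibullHazard)


def split_learning_test(cohort: Cohort, learn_fraction=2.0 / 3.0, seed=0):
    """Partition by employee into (learning, test) cohorts; deterministic."""
    if not 0 < learn_fraction < 1:
        raise ValueError("learn_fraction must be in (0, 1)")
    subjects = np.sort(cohort.data["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 employees to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_learn = int(np.clip(round(learn_fraction * len(subjects)), 1,
                          len(subjects) - 1))
    learn_ids = subjects[perm[:n_learn]]
    test_ids = subjects[perm[n_learn:]]
    return cohort.subset_subjects(learn_ids), cohort.subset_subjects(test_ids)


def lrt(null_fit: BaseHazardModel, alt_fit: BaseHazardModel, tol=1e-6):
    """Likelihood-ratio test of a nested null against its alternative.

    Returns ``(statistic, df, p)``.  A higher null than alternative
    likelihood (beyond tolerance) signals a fitting failure and raises.
    """
    stat = 2.0 * (alt_fit.loglik_ - null_fit.loglik_)
    if stat < -tol * max(1.0, abs(null_fit.loglik_)):
        raise RuntimeError(
            f"alternative log-likelihood below null ({alt_fit.loglik_:.6f} < "
            f"{null_fit.loglik_:.6f}): fitting failure"
        )
    stat = max(stat, 0.0)
    df = alt_fit.n_params_ - null_fit.n_params_
    p = float(stats.chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return stat, df, p


def effective_n(fit_or_cohort, kind="events") -> int:
    if kind == "events":
        return int(fit_or_cohort.n_events_ if hasattr(fit_or_cohort, "n_events_")
                   else fit_or_cohort.n_events)
    if kind == "subjects":
        return int(fit_or_cohort.n_subjects_ if hasattr(fit_or_cohort, "n_subjects_")
                   else fit_or_cohort.n_subjects)
    if kind == "rows":
        return int(fit_or_cohort.n_episodes)
    raise ValueError("kind must be events|subjects|rows")


def bic(fit: BaseHazardModel, n: int) -> float:
    """Schwarz criterion  -2*loglik + n_params*log(n)  (smaller is better)."""
    return -2.0 * fit.loglik_ + fit.n_params_ * np.log(n)


def bayes_factor(fit_a: BaseHazardModel, fit_b: BaseHazardModel, n: int) -> float:
    """Schwarz approximation BF_ab = exp(-(BIC_a - BIC_b)/2) (evidence for a)."""
    return float(np.exp(-(bic(fit_a, n) - bic(fit_b, n)) / 2.0))


def km_curve(cohort: Cohort) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve on the job clock with left truncation.

    Returns a frame with ``time, survival, at_risk, events`` plus the
    ``(log_time, loglog)`` pairs of the Weibull diagnostic
    ``log(-log S(t))`` vs ``log t`` (a straight line of slope p under a
    Weibull baseline).
    """
    from lifelines import KaplanMeierFitter

    d = cohort.data
    km = KaplanMeierFitter()
    km.fit(durations=d["exit"], event_observed=d["event"], entry=d["entry"])
    sf = km.survival_function_.iloc[:, 0]
    ev = km.event_table
    out = pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "survival": sf.to_numpy(float),
        "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(float),
        "events": ev["observed"].reindex(sf.index).to_numpy(float),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_time"] = np.log(out["time"])
        out["loglog"] = np.log(-np.log(out["survival"]))
    return out


_NESTED = {("exponential", "weibull"), ("exponential", "pem")}
_FORBIDDEN = frozenset({frozenset({"pem_hypothesis", "pem_datadriven"})})


class ComparisonTable:
    """Fit statistics and pairwise comparisons across competing models.

    Nested pairs (exponential within Weibull or within any two-piece) are
    compared by LRT; non-nested pairs by Delta-BIC and Schwarz Bayes factor.
    The hypothesis-driven and data-driven two-piece models address different
    questions and the pair is refused.
    """

    def __init__(self, fits: dict, n: int):
        self.fits = dict(fits)
        self.n = n

    def _family(self, name):
        fit = self.fits[name]
        if isinstance(fit, PiecewiseExponentialHazard):
            return "pem"
        if isinstance(fit, WeibullHazard):
            return "weibull"
        return "exponential"

    def is_nested(self, null_name, alt_name) -> bool:
        return (self._family(null_name), self._family(alt_name)) in _NESTED

    def fit_stats(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            rows.append({"model": name, "n_params": fit.n_params_,
                         "loglik": fit.loglik_, "bic": bic(fit, self.n)})
        return pd.DataFrame(rows)

    def compare(self, name_a, name_b) -> dict:
        if frozenset({name_a, name_b}) in _FORBIDDEN:
            raise ValueError(
                "the hypothesis-driven and data-driven two-piece models address "
                "different hypotheses and are not compared"
            )
        out = {"a": name_a, "b": name_b}
        if self.is_nested(name_a, name_b):
            stat, df, p = lrt(self.fits[name_a], self.fits[name_b])
            out.update(kind="lrt", statistic=stat, df=df, p=p)
        elif self.is_nested(name_b, name_a):
            stat, df, p = lrt(self.fits[name_b], self.fits[name_a])
            out.update(kind="lrt", statistic=stat, df=df, p=p)
        else:
            dbic = bic(self.fits[name_a], self.n) - bic(self.fits[name_b], self.n)
            out.update(kind="bic", delta_bic=dbic,
                       bayes_factor=float(np.exp(-dbic / 2.0)))
        return out

    def all_pairs(self) -> pd.DataFrame:
        names = list(self.fits)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if frozenset({a, b}) in _FORBIDDEN:
                    rows.append({"a": a, "b": b, "kind": "not compared"})
                else:
                    rows.append(self.compare(a, b))
        return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    covariates: tuple = ()
    profile_covariates: tuple | None = None  # None: adjust the profile fits too
    learn_fraction: float = 2.0 / 3.0
    fixed_cut: float = 12.0
    candidates: tuple | None = None
    min_events: int = 5
    bootstrap_B: int = 400
    bootstrap_sample_size: int = 10_000
    bic_n: str = "events"
    frailty_final: bool = True
    mi_m: int = 4
    mi_iterations: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    changepoint: ChangepointEstimate
    bootstrap: BootstrapResult
    table: ComparisonTable
    test_fits: dict
    final_fits: dict
    log: dict = field(default_factory=dict)


def run_selection_pipeline(cohort: Cohort, config: PipelineConfig) -> PipelineResult:
    """Execute the five-step selection protocol (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("split", "bootstrap", "mi")}
    log = {"seeds": seeds, "config": config}

    # 1. partition by employee
    learn, test = split_learning_test(cohort, config.learn_fraction,
                                      seed=seeds["split"])
    log["n_learn"], log["n_test"] = learn.n_subjects, test.n_subjects

    cov = tuple(config.covariates)
    has_missing = cohort.has_missing()
    cc_learn = _complete_cases(learn, cov) if has_missing else learn
    cc_test = _complete_cases(test, cov) if has_missing else test

    # 2. data-driven cut on the learning set only
    prof_cov = cov if config.profile_covariates is None \
        else tuple(config.profile_covariates)
    cp = profile_changepoint(cc_learn, candidates=config.candidates,
                             covariates=prof_cov, min_events=config.min_events)

    # 3. bootstrap the cut from the learning set
    boot = bootstrap_changepoint(
        cc_learn, candidates=config.candidates, B=config.bootstrap_B,
        sample_size=config.bootstrap_sample_size, seed=seeds["bootstrap"],
        covariates=prof_cov, min_events=config.min_events)

    # 4. compare the four models on the held-out test set
    test_fits = {
        "exponential": ExponentialHazard(covariates=cov).fit(cc_test),
        "weibull": WeibullHazard(covariates=cov).fit(cc_test),
        "pem_hypothesis": PiecewiseExponentialHazard(
            cuts=(config.fixed_cut,), covariates=cov).fit(cc_test),
        "pem_datadriven": PiecewiseExponentialHazard(
            cuts=(cp.tau_hat,), covariates=cov).fit(cc_test),
    }
    table = ComparisonTable(test_fits, n=effective_n(
        test_fits["exponential"], config.bic_n))

    # 5. chosen models with frailty on the full cohort (CC and MI paths)
    final = {}
    for name, cut in (("pem_hypothesis", config.fixed_cut),
                      ("pem_datadriven", cp.tau_hat)):
        entry = {}
        cc_full = _complete_cases(cohort, cov) if has_missing else cohort
        entry["cc"] = PiecewiseExponentialHazard(
            cuts=(cut,), covariates=cov,
            frailty=config.frailty_final).fit(cc_full)
        if has_missing:
            from .impute import fcs_impute, pool_rubin
            imp = fcs_impute(cohort, m=config.mi_m,
                             iterations=config.mi_iterations, seed=seeds["mi"])
            fits = [PiecewiseExponentialHazard(
                cuts=(cut,), covariates=cov,
                frailty=config.frailty_final).fit(c)
                for c in imp.completed]
            entry["mi"] = pool_rubin(fits)
        final[name] = entry

    return PipelineResult(changepoint=cp, bootstrap=boot, table=table,
                          test_fits=test_fits, final_fits=final, log=log)


def _complete_cases(cohort: Cohort, covariates) -> Cohort:
    if not covariates:
        return cohort
    mask = cohort.data[list(covariates)].notna().all(axis=1)
    if mask.all():
        return cohort
    return Cohort(cohort.data.loc[mask].copy(), list(cohort.covariates))
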