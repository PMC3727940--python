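"""Synthetic occupational-injury cohorts with the structure the models assume.

The generator emulates an hourly-workforce event history: each worker holds
one or more jobs; on each job, recurrent acute injuries arrive with a
piecewise-constant baseline hazard on the months-on-the-job clock, scaled by
proportional covariate effects and a worker-level gamma frailty (mean 1,
variance ``theta``); observation on a job ends at the earliest of a
job-change clock, a termination clock, or the administrative horizon.
Missingness in the continuous physical-demand covariate can be injected
under an explicit missing-at-random (MAR) mechanism.

Default magnitudes mirror a large aluminum-manufacturing workforce: 78%
male, age ~ N(39.4, 11.3) years at job start, about 2.4 jobs per worker, a
baseline hazard that drops after 12 months of job experience (rate ratio
1.3), male hazard ratio 0.71, physical-demand HR 1.25 per unit, smelter
plant 1.25, union plant 1.15, frailty variance 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort, PieceGrid


def _default_covariates():
    # (kind, params, level): level "subject" or "job"
    return {
        "male": ("bernoulli", {"p": 0.78}, "subject"),
        "age": ("normal", {"mean": 39.4, "sd": 11.3}, "subject"),
        "union": ("bernoulli", {"p": 0.35}, "job"),
        "smelter": ("bernoulli", {"p": 0.30}, "job"),
        "physical_demand": ("demand", {"sd": 1.0, "union": 0.4, "smelter": 0.4}, "job"),
    }


def _default_beta():
    return {
        "male": np.log(0.71),
        "age": np.log(0.99),
        "union": np.log(1.15),
        "smelter": np.log(1.25),
        "physical_demand": np.log(1.25),
    }


@dataclass
class MARSpec:
    """Missing-at-random mechanism for one covariate, applied at the job level.

    The missingness probability is ``expit(intercept + sum coef * predictor)``
    where predictors are fully observed job-level quantities: other
    covariates, or the derived terms ``n_events`` (injuries observed on the
    job) and ``log_person_time``.  The intercept is calibrated so the mean
    probability equals ``target_fraction``.
    """

    variable: str = "physical_demand"
    coefficients: dict = field(default_factory=lambda: {"union": -1.5, "smelter": -1.5})
    target_fraction: float = 0.5

    def __post_init__(self):
        if not 0 <= self.target_fraction < 1:
            raise ValueError("target_fraction must be in [0, 1)")


@dataclass
class SimulationDesign:
    """Full specification of a synthetic cohort (all rates per person-month)."""

    n_subjects: int = 1000
    mean_extra_jobs: float = 1.36          # jobs per subject = 1 + Poisson(mean_extra_jobs)
    cuts: tuple = (12.0,)                  # true baseline changepoint(s), months
    piece_rates: tuple = (0.026, 0.020)    # events per person-month per piece
    beta: dict = field(default_factory=_default_beta)
    frailty_variance: float = 0.5
    covariate_generators: dict = field(default_factory=_default_covariates)
    job_change_rate: float = 1.0 / 24.0    # exponential clock, per month
    termination_rate: float = 1.0 / 60.0
    admin_horizon: float = 60.0            # months
    missingness: MARSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if any(not np.isfinite(r) or r < 0 for r in self.piece_rates):
            raise ValueError("piece rates must be finite and nonnegative")
        if self.frailty_variance < 0:
            raise ValueError("frailty_variance must be >= 0")
        if len(self.piece_rates) != len(tuple(self.cuts)) + 1:
            raise ValueError("need one rate per piece (len(cuts)+1)")
        unknown = set(self.beta) - set(self.covariate_generators)
        if unknown:
            raise ValueError(f"beta names without generators: {sorted(unknown)}")

    @property
    def grid(self) -> PieceGrid:
        return PieceGrid(tuple(self.cuts))


@dataclass
class TruthRecord:
    """The design echoed back plus the realized per-subject frailty draws."""

    design: SimulationDesign
    frailty: pd.Series

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self.design)
        d.pop("covariate_generators")
        rows = [("design." + k, repr(v)) for k, v in d.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


def _cum_baseline(design: SimulationDesign):
    edges = design.grid.edges()
    rates = np.asarray(design.piece_rates, float)
    cum_at_edges = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(edges[:-1]))]) \
        if len(rates) > 1 else np.array([0.0])
    return edges, rates, cum_at_edges


def _invert_cumhaz(h, edges, rates, cum_at_edges):
    """t such that H0(t) = h, for piecewise-constant rates (vectorized)."""
    k = np.clip(np.searchsorted(cum_at_edges, h, side="right") - 1, 0, len(rates) - 1)
    with np.errstate(divide="ignore"):
        t = edges[k] + (h - cum_at_edges[k]) / rates[k]
    return t


def simulate_cohort(design: SimulationDesign, seed=None):
    """Draw a cohort from the design; deterministic given the seed.

    Returns ``(Cohort, TruthRecord)``.  Event times come from inversion of
    the piecewise-constant cumulative hazard scaled by ``u * exp(x'beta)``;
    recurrent events follow the counting-process convention (risk resumes at
    the event time on the same job clock).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_subjects
    theta = design.frailty_variance
    frailty = (rng.gamma(1.0 / theta, theta, size=n) if theta > 0
               else np.ones(n))

    n_jobs = 1 + rng.poisson(design.mean_extra_jobs, size=n)
    total_jobs = int(n_jobs.sum())
    subj_of_job = np.repeat(np.arange(n), n_jobs)
    job_index = np.concatenate([np.arange(k) for k in n_jobs]) + 1

    # covariates
    cov_names = list(design.covariate_generators)
    cov = {}
    for name, (kind, pars, level) in design.covariate_generators.items():
        size = n if level == "subject" else total_jobs
        if kind == "bernoulli":
            v = rng.binomial(1, pars["p"], size=size).astype(float)
        elif kind == "normal":
            v = rng.normal(pars["mean"], pars["sd"], size=size)
        elif kind == "demand":
            # physical demand shifted upward in union / smelter plants
            v = rng.normal(0.0, pars["sd"], size=size)
            for flag in ("union", "smelter"):
                if flag in cov:
                    fv = cov[flag]
                    fv = fv if len(fv) == size else np.repeat(fv, n_jobs)
                    v = v + pars.get(flag, 0.0) * fv
        else:
            raise ValueError(f"unknown covariate generator kind {kind!r}")
        cov[name] = np.repeat(v, n_jobs) if level == "subject" else v

    # linear predictor and per-job hazard multiplier
    eta = np.zeros(total_jobs)
    for name, b in design.beta.items():
        x = cov[name]
        if name == "age":  # center age so the baseline rate is at the cohort mean
            x = x - design.covariate_generators["age"][1]["mean"]
        eta = eta + b * x
    mult = frailty[subj_of_job] * np.exp(eta)

    # censoring: earliest of job-change / termination clocks and admin horizon
    t_jc = rng.exponential(1.0 / design.job_change_rate, size=total_jobs) \
        if design.job_change_rate > 0 else np.full(total_jobs, np.inf)
    t_term = rng.exponential(1.0 / design.termination_rate, size=total_jobs) \
        if design.termination_rate > 0 else np.full(total_jobs, np.inf)
    c_time = np.minimum(np.minimum(t_jc, t_term), design.admin_horizon)
    reason = np.where(
        c_time == design.admin_horizon, "admin_end",
        np.where(t_jc <= t_term, "job_change", "termination"),
    )

    edges, rates, cum_edges = _cum_baseline(design)

    rows = []
    last_t = np.zeros(total_jobs)
    cum_h = np.zeros(total_jobs)
    alive = np.arange(total_jobs)
    while alive.size:
        cum_h[alive] += rng.exponential(1.0, size=alive.size)
        t_ev = _invert_cumhaz(cum_h[alive] / mult[alive], edges, rates, cum_edges)
        hit = t_ev <= c_time[alive]
        ev_jobs = alive[hit]
        rows.append((ev_jobs, last_t[ev_jobs], t_ev[hit], 1, "event"))
        last_t[ev_jobs] = t_ev[hit]
        done = alive[~hit]
        rows.append((done, last_t[done], c_time[done], 0, None))
        alive = ev_jobs
    parts = []
    for jobs, t0, t1, ev, rsn in rows:
        if len(jobs) == 0:
            continue
        parts.append(pd.DataFrame({
            "_job": jobs, "entry": t0, "exit": t1, "event": ev,
            "censor_reason": rsn if rsn is not None else reason[jobs],
        }))
    df = pd.concat(parts, ignore_index=True).sort_values(["_job", "entry"])
    jid = df["_job"].to_numpy()
    df.insert(0, "subject_id", [f"s{subj_of_job[j] + 1}" for j in jid])
    df.insert(1, "job_id", [f"s{subj_of_job[j] + 1}_j{job_index[j]}" for j in jid])
    for name in cov_names:
        df[name] = cov[name][jid]
    if "age" in df.columns:
        df["age"] = df["age"] - design.covariate_generators["age"][1]["mean"]
    df = df.drop(columns="_job").reset_index(drop=True)

    cohort = Cohort(df, cov_names)
    truth = TruthRecord(
        design=design,
        frailty=pd.Series(frailty, index=[f"s{i + 1}" for i in range(n)], name="frailty"),
    )
    if design.missingness is not None and design.missingness.target_fraction > 0:
        cohort = inject_missingness(cohort, design.missingness,
                                    seed=rng.integers(2**31 - 1))
    return cohort, truth


def simulate_weibull_cohort(n_subjects, rate=0.05, shape=1.5, censor_time=60.0,
                            seed=0) -> Cohort:
    """Single-spell cohort with Weibull baseline ``H0(t) = rate * t**shape``.

    One job per worker, first event only, administrative censoring — the
    minimal design for checking the Kaplan-Meier log(-log) diagnostic, whose
    points fall on a line of slope ``shape`` under this model.
    """
    rng = np.random.default_rng(seed)
    t = (rng.exponential(1.0, n_subjects) / rate) ** (1.0 / shape)
    event = (t <= censor_time).astype(int)
    exit_ = np.minimum(t, censor_time)
    df = pd.DataFrame({
        "subject_id": [f"s{i + 1}" for i in range(n_subjects)],
        "job_id": [f"s{i + 1}_j1" for i in range(n_subjects)],
        "entry": 0.0,
        "exit": exit_,
        "event": event,
        "censor_reason": np.where(event == 1, "event", "admin_end"),
    })
    return Cohort(df, [])


def _job_level_frame(cohort: Cohort) -> pd.DataFrame:
    """One row per job: covariates plus observed outcome summaries."""
    d = cohort.data.assign(_dur=lambda s: s["exit"] - s["entry"])
    g = d.groupby("job_id", sort=False)
    out = g[list(cohort.covariates)].first()
    out["n_events"] = g["event"].sum()
    out["log_person_time"] = np.log(g["_dur"].sum())
    out["subject_id"] = g["subject_id"].first()
    return out


def inject_missingness(cohort: Cohort, spec: MARSpec, seed=0) -> Cohort:
    """Blank a covariate under the MAR mechanism of ``spec`` (job level).

    The probability of missingness depends only on fully observed quantities;
    the intercept is calibrated (bisection) so the expected missing fraction
    equals the target.  Deterministic given the seed.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    if spec.target_fraction == 0:
        return cohort
    if spec.variable not in cohort.covariates:
        raise KeyError(f"covariate {spec.variable!r} not in cohort")
    jobs = _job_level_frame(cohort)
    lp = np.zeros(len(jobs))
    for name, coef in spec.coefficients.items():
        if name not in jobs.columns:
            raise KeyError(f"MAR predictor {name!r} not available")
        v = jobs[name].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"MAR predictor {name!r} has missing values")
        lp = lp + coef * v

    a = brentq(lambda a0: expit(a0 + lp).mean() - spec.target_fraction, -40, 40)
    rng = np.random.default_rng(seed)
    miss = rng.random(len(jobs)) < expit(a + lp)
    miss_jobs = set(jobs.index[miss])
    data = cohort.data.copy()
    data.loc[data["job_id"].isin(miss_jobs), spec.variable] = np.nan
    return Cohort(data, list(cohort.covariates))
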