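"""Counting-process cohort container, validation, episode splitting and crude rates.

A cohort is a table of at-risk *episodes* on the job clock: one row per
at-risk interval per job per worker.  Time is measured in months since the
start of the job.  Recurrent injuries follow the Andersen-Gill counting
process convention: after an event at time t the worker re-enters risk at t
on the same job clock, so a job contributes intervals
``(0, t1], (t1, t2], ..., (t_last, c]``.

CSV dialect (this package's own documented format — no standard exists for
counting-process cohorts):

    subject_id, job_id, entry_months, exit_months, event, censor_reason, <covariates...>

Missing covariate cells are empty; ``censor_reason`` is one of
``job_change, termination, death, admin_end, event, none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["subject_id", "job_id", "entry", "exit", "event", "censor_reason"]
CSV_COLUMN_MAP = {"entry_months": "entry", "exit_months": "exit"}
CENSOR_REASONS = frozenset(
    {"job_change", "termination", "death", "admin_end", "event", "none"}
)


class CohortValidationError(ValueError):
    """Raised when a cohort file or frame violates the episode invariants."""


@dataclass(frozen=True)
class PieceGrid:
    """Ordered cut points tau_1 < ... < tau_{K-1} defining K constant-hazard pieces.

    An empty grid is the single-piece (exponential) case.  Pieces are the
    half-open intervals ``(tau_{k-1}, tau_k]`` with tau_0 = 0 and tau_K = inf;
    an event exactly at a cut belongs to the earlier piece.
    """

    cuts: tuple = ()

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if any(c <= 0 for c in cuts):
            raise ValueError("cut points must be positive")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_pieces(self) -> int:
        return len(self.cuts) + 1

    def edges(self) -> np.ndarray:
        """Piece boundaries [0, tau_1, ..., tau_{K-1}, inf]."""
        return np.concatenate([[0.0], self.cuts, [np.inf]])

    def piece_of(self, t) -> np.ndarray:
        """0-based index of the piece containing each time (event-at-cut -> earlier piece)."""
        return np.searchsorted(np.asarray(self.cuts), np.asarray(t, dtype=float), side="left")

    def labels(self) -> list:
        e = self.edges()
        out = []
        for k in range(self.n_pieces):
            hi = "inf" if np.isinf(e[k + 1]) else f"{e[k + 1]:g}"
            out.append(f"({e[k]:g},{hi}]")
        return out


@dataclass
class Cohort:
    """Validated collection of episodes with a covariate schema.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per episode with the required columns plus covariates.
    covariates : list of str
        Ordered covariate names (columns of ``data``); may contain NaN.
    """

    data: pd.DataFrame
    covariates: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        absent = [c for c in self.covariates if c not in self.data.columns]
        if absent:
            raise CohortValidationError(f"covariates not in data: {absent}")
        self.data = self.data.reset_index(drop=True)
        problems = self.validate()
        if problems:
            raise CohortValidationError(
                "invalid cohort:\n" + "\n".join(problems[:20])
            )

    # -- basic summaries -------------------------------------------------
    @property
    def n_episodes(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def person_time(self) -> float:
        return float((self.data["exit"] - self.data["entry"]).sum())

    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def subset_subjects(self, ids) -> "Cohort":
        mask = self.data["subject_id"].isin(np.asarray(ids))
        return Cohort(self.data.loc[mask].copy(), list(self.covariates))

    def has_missing(self) -> bool:
        return bool(self.data[self.covariates].isna().any().any()) if self.covariates else False

    # -- validation ------------------------------------------------------
    def validate(self) -> list:
        """Report invariant violations (empty list iff the cohort is valid)."""
        d = self.data
        problems = []
        bad = d.index[~(d["entry"] >= 0)]
        for i in bad[:10]:
            problems.append(f"row {i}: entry < 0")
        bad = d.index[~(d["exit"] > d["entry"])]
        for i in bad[:10]:
            problems.append(f"row {i}: entry >= exit")
        bad = d.index[~d["event"].isin([0, 1])]
        for i in bad[:10]:
            problems.append(f"row {i}: event not in {{0,1}}")
        bad = d.index[~d["censor_reason"].isin(CENSOR_REASONS)]
        for i in bad[:10]:
            problems.append(f"row {i}: unknown censor_reason {d.loc[i, 'censor_reason']!r}")
        bad = d.index[(d["event"] == 1) & (d["censor_reason"] != "event")]
        for i in bad[:10]:
            problems.append(f"row {i}: event=1 but censor_reason={d.loc[i, 'censor_reason']!r}")
        # intervals within a (subject, job) must be disjoint
        g = d.sort_values(["subject_id", "job_id", "entry"])
        same = (g["subject_id"].values[1:] == g["subject_id"].values[:-1]) & (
            g["job_id"].values[1:] == g["job_id"].values[:-1]
        )
        overlap = same & (g["entry"].values[1:] < g["exit"].values[:-1])
        for i in np.flatnonzero(overlap)[:10]:
            problems.append(
                f"overlapping intervals for subject {g['subject_id'].values[i]!r} "
                f"job {g['job_id'].values[i]!r}"
            )
        return problems


def validate_cohort(cohort: Cohort) -> list:
    """Return the list of invariant violations (empty iff valid)."""
    return cohort.validate()


def read_cohort(path, covariates=None) -> Cohort:
    """Read a cohort CSV (see module docstring for the dialect).

    Parameters
    ----------
    path : str or path-like
    covariates : list of str, optional
        Covariate schema; defaults to every column after ``censor_reason``.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=CSV_COLUMN_MAP)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    return Cohort(df, list(covariates))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in the package dialect (missing cells empty)."""
    df = cohort.data[REQUIRED_COLUMNS + list(cohort.covariates)].copy()
    df = df.rename(columns={"entry": "entry_months", "exit": "exit_months"})
    df.to_csv(path, index=False)


def split_at_cuts(cohort: Cohort, grid: PieceGrid) -> pd.DataFrame:
    """Expand episodes into one row per (episode, piece) with exposure and events.

    Exposure and events are conserved exactly per episode.  Pieces are
    half-open ``(tau_{k-1}, tau_k]``; an event at time t goes to the piece
    containing t (event at a cut -> earlier piece).  With an empty grid this
    is the identity up to row typing.

    Returns a frame with columns ``subject_id, job_id, piece, exposure,
    events`` plus the cohort's covariates; ``piece`` is 0-based.
    """
    d = cohort.data
    edges = grid.edges()
    entry = d["entry"].to_numpy(float)
    exit_ = d["exit"].to_numpy(float)
    event = d["event"].to_numpy(int)
    event_piece = grid.piece_of(exit_)

    frames = []
    for k in range(grid.n_pieces):
        lo, hi = edges[k], edges[k + 1]
        exposure = np.minimum(exit_, hi) - np.maximum(entry, lo)
        keep = exposure > 0
        if not keep.any():
            continue
        sub = d.loc[keep, ["subject_id", "job_id"] + list(cohort.covariates)].copy()
        sub["piece"] = k
        sub["exposure"] = exposure[keep]
        sub["events"] = np.where(event_piece[keep] == k, event[keep], 0)
        sub["_row"] = np.flatnonzero(keep)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True).sort_values(["_row", "piece"])
    out = out.drop(columns="_row").reset_index(drop=True)
    cols = ["subject_id", "job_id", "piece", "exposure", "events"] + list(cohort.covariates)
    return out[cols]


def crude_rates(cohort: Cohort, bin_width: float, hours_per_month=None) -> pd.DataFrame:
    """Per-bin event counts, person-time and crude rates on the job clock.

    Rates are events per person-month; if ``hours_per_month`` is given a
    rate per 200,000 person-hours is added (the occupational-health
    convention, roughly 100 worker-years).  Bins with zero person-time get
    ``rate = NaN`` and ``undefined = True``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = cohort.data
    max_t = float(d["exit"].max())
    n_bins = int(np.ceil(max_t / bin_width))
    edges = np.arange(n_bins + 1) * float(bin_width)
    entry = d["entry"].to_numpy(float)
    exit_ = d["exit"].to_numpy(float)
    event = d["event"].to_numpy(int)
    # events go to the bin containing the exit time (bin (lo, hi] like pieces)
    ev_bin = np.clip(np.searchsorted(edges[1:-1], exit_, side="left"), 0, n_bins - 1)
    exposure = np.empty(n_bins)
    events = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        exposure[k] = np.maximum(
            0.0, np.minimum(exit_, edges[k + 1]) - np.maximum(entry, edges[k])
        ).sum()
    np.add.at(events, ev_bin, event)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(exposure > 0, events / exposure, np.nan)
    out = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "events": events,
            "person_months": exposure,
            "rate_per_person_month": rate,
            "undefined": exposure <= 0,
        }
    )
    if hours_per_month is not None:
        out["rate_per_200k_hours"] = rate / float(hours_per_month) * 200_000.0
    return out
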