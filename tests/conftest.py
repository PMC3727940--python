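import numpy as np
import pandas as pd
import pytest

from pemfrail import Cohort, SimulationDesign, simulate_cohort


def make_cohort(rows, covariates=()):
    """Build a cohort from (subject, job, entry, exit, event) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "job_id", "entry", "exit",
                                     "event"][: len(rows[0])])
    if "event" not in df.columns:
        df["event"] = 0
    df["censor_reason"] = np.where(df["event"] == 1, "event", "admin_end")
    return Cohort(df, list(covariates))


@pytest.fixture(scope="session")
def small_cohort():
    """500 workers, default design (two-piece truth, covariates, frailty)."""
    cohort, truth = simulate_cohort(SimulationDesign(n_subjects=500, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def plain_cohort():
    """No covariates, no frailty, constant hazard 0.03/month."""
    design = SimulationDesign(
        n_subjects=400, seed=11, cuts=(12.0,), piece_rates=(0.03, 0.03),
        beta={}, covariate_generators={}, frailty_variance=0.0)
    cohort, _ = simulate_cohort(design)
    return cohort
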