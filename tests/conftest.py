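"""Shared fixtures.

The full default-cohort run (simulate -> staircase -> fit) is expensive, so
it is computed once per session and shared by the round-trip and
diagnostic-ordering tests."""

import numpy as np
import pandas as pd
import pytest

from darkadapt import (
    CohortSpec,
    DACurveParams,
    cohort_truth_frame,
    fit_all_loci,
    generate_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def canonical_params() -> DACurveParams:
    return DACurveParams(ct=-0.5, t0=3.0, tau=1.0, S2=-0.25, CRB=10.0, tf=-2.0)


@pytest.fixture(scope="session")
def default_cohort_run():
    """Default synthetic cohort simulated and refitted end to end.

    Returns (truth_frame, outcomes) merged-ready; seeds follow the
    pipeline's own defaults (cohort seed, session seed = cohort seed + 1,
    fit seed = cohort seed).
    """
    spec = CohortSpec()
    subjects = generate_cohort(spec)
    truth = cohort_truth_frame(subjects)
    presentations = simulate_cohort(subjects, seed=spec.seed + 1, spec=spec)
    outcomes = fit_all_loci(presentations, seed=spec.seed)
    merged = outcomes.merge(
        truth, on=["subject_id", "eccentricity_deg"], suffixes=("", "_truth")
    )
    return truth, outcomes, merged


def random_valid_params(rng: np.random.Generator) -> DACurveParams:
    """Draw one physiologically plausible parameter set."""
    ct = rng.uniform(-1.0, 0.5)
    t0 = ct + rng.uniform(0.5, 3.5)
    tau = rng.uniform(0.3, 3.0)
    s2 = -rng.uniform(0.05, 0.6)
    crb = rng.uniform(2.0, 30.0)
    tf = ct - rng.uniform(0.2, 2.5)
    return DACurveParams(ct=ct, t0=t0, tau=tau, S2=s2, CRB=crb, tf=max(tf, -3.4))
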