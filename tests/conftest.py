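import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import statin_pgx as sp

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: all configured effects at their null value
NULL_EFFECTS = {
    "or_intolerance_high_burden": 1.0,
    "rrr_deescalation_high_burden": 1.0,
    "rrr_escalation_high_burden": 1.0,
    "hr_regimen_change_high_burden": 1.0,
    "rrr_deescalation_myopathy": 1.0,
}


def build_dataset(n=2000, seed=0, effects=None, followup=365, baseline=None):
    """Simulate a cohort and assemble the per-subject analysis table."""
    cfg = sp.SimConfig(
        n_subjects=n,
        seed=seed,
        effect_sizes=dict(effects) if effects else dict(NULL_EFFECTS),
        baseline_rates=dict(baseline) if baseline else {},
        followup_days=followup,
    )
    cohort = sp.simulate_cohort(cfg)
    courses = sp.derive_courses(cohort.dispensings, cfg.followup_days)
    flags = sp.phenotype_cohort(cohort.clinical, cohort.labs, courses)
    ds = (
        cohort.truth[["subject_id", "high_burden", "latent_myopathy",
                      "designated_intolerant", "designated_nonadherent"]]
        .merge(courses, on="subject_id")
        .merge(flags, on="subject_id")
    )
    return ds, cohort


@pytest.fixture
def null_effects():
    return dict(NULL_EFFECTS)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared n=1500 null cohort for invariant checks."""
    ds, cohort = build_dataset(n=1500, seed=42)
    return ds, cohort
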