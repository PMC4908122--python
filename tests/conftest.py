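import numpy as np
import pytest

from fearscr.paradigm import ParadigmConfig, PhaseName, generate_schedule
from fearscr.pipeline import cohort_endpoints
from fearscr.stats import group_by_time_interaction
from fearscr.synth import CohortSpec, small_paradigm, synthesize_cohort


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(ParadigmConfig(seed=42))


def null_cohort_spec(seed: int, n_per_group: int = 10) -> CohortSpec:
    """Conditioning-only cohort with no programmed group-by-time effect."""
    return CohortSpec(n_per_group=n_per_group, seed=seed, paradigm=small_paradigm(),
                      phases=(PhaseName.CONDITIONING,), nonresponder_rate=0.0,
                      effect_cr_interaction=0.0, make_fa_tables=False)


@pytest.fixture(scope="session")
def null_interaction_pvalues():
    """Interaction p-values from 1000 null cohorts (generate -> score ->
    endpoints -> test); shared between the type-I-error and uniformity
    checks."""
    ps = []
    for i in range(1000):
        spec = null_cohort_spec(seed=20_000 + i)
        ep = cohort_endpoints(synthesize_cohort(spec))
        ps.append(group_by_time_interaction(ep, "diff_cond_uS").pvalue)
    return np.asarray(ps)
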