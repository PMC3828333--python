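import numpy as np
import pandas as pd
import pytest

from cytostrat.panel_io import (
    global_nonzero_min,
    log10_view,
    resolve_censored,
    to_molar,
)
from cytostrat.subgrouping import cluster_rows
from cytostrat.synthetic_cohort import generate_cohort, vasst_like

#: seed for the canonical synthetic cohort used across the suite
COHORT_SEED = 1


@pytest.fixture(scope="session")
def vasst_cohort():
    """Full synthetic cohort: raw matrices, clinical, truth, molar views."""
    spec = vasst_like(seed=COHORT_SEED)
    baseline, late, clinical, truth = generate_cohort(spec)
    half_min = global_nonzero_min(baseline, late) / 2.0
    molar = {
        "baseline": to_molar(resolve_censored(baseline, zero_fill=half_min), spec.catalog),
        "24h": to_molar(resolve_censored(late, zero_fill=half_min), spec.catalog),
    }
    return {
        "spec": spec,
        "baseline": baseline,
        "late": late,
        "clinical": clinical,
        "truth": truth,
        "molar": molar,
    }


@pytest.fixture(scope="session")
def vasst_assignments(vasst_cohort):
    """Subgroup assignments clustered from the synthetic cohort."""
    return {
        "baseline": cluster_rows(log10_view(vasst_cohort["molar"]["baseline"]), k=3),
        "24h": cluster_rows(log10_view(vasst_cohort["molar"]["24h"]), k=2),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
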