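import numpy as np
import pandas as pd
import pytest

from stratmr import (
    CohortTable,
    DoseResponseSpec,
    VariantRecord,
    compute_grs,
    generate_cohort,
    simulate_variants,
)


@pytest.fixture(scope="session")
def variant_panel():
    """Default-scale instrument panel (83 loci)."""
    return simulate_variants(83, seed=2)


@pytest.fixture(scope="session")
def small_variants():
    return simulate_variants(12, seed=5)


@pytest.fixture(scope="session")
def linear_spec():
    return DoseResponseSpec(shape="linear", params={"slope": -0.3})


@pytest.fixture()
def scored_cohort_factory(variant_panel):
    """Build a cohort with its allele score attached as a 'grs' column."""

    def make(n, spec, seed):
        cohort = generate_cohort(n, variant_panel, spec, seed=seed)
        res = compute_grs(cohort.dosages, cohort.variants)
        cohort.phenotypes["grs"] = res.scores
        return cohort

    return make


def toy_cohort(exposure, outcome, score=None, **extra_columns):
    """Hand-built minimal cohort: integer exposures, one outcome, no covariates."""
    n = len(exposure)
    ph = pd.DataFrame(index=pd.RangeIndex(n, name="iid"))
    ph["latent_exposure"] = np.asarray(exposure, dtype=float)
    ph["reported_exposure"] = np.asarray(exposure, dtype=float)
    ph["y"] = np.asarray(outcome, dtype=float)
    if score is not None:
        ph["grs"] = np.asarray(score, dtype=float)
    for k, v in extra_columns.items():
        ph[k] = v
    ph["included"] = True
    dosages = pd.DataFrame(index=ph.index)
    return CohortTable(ph, dosages, [], ("y",))
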