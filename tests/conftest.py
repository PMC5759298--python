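import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from zwseeker import synthetic_data as sd
from zwseeker.io_formats import CohortPanel, VariantTable

settings.register_profile("ci", derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the default study conditions (seed 1)."""
    return sd.simulate_cohort(sd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for I/O and plumbing tests."""
    cfg = sd.SimulationConfig(
        seed=4, n_other_scaffolds=2, other_scaffold_length=20_000,
        snp_density=0.001, w_snp_count=30, n_multiallelic=5,
    )
    return cfg, sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def marker_templates():
    return sd.make_marker_fixture()


def make_panel(n_f, n_m, population="P1"):
    rows = [(f"f{i:02d}", "F", population) for i in range(n_f)]
    rows += [(f"m{i:02d}", "M", population) for i in range(n_m)]
    return CohortPanel(pd.DataFrame(rows, columns=["sample", "sex",
                                                   "population"]))


def make_table(sites, gt, ad, samples):
    """Small VariantTable from plain lists."""
    return VariantTable(
        sites=pd.DataFrame(sites, columns=["scaffold", "pos", "ref", "alts"]),
        gt=np.asarray(gt, dtype=np.int8),
        ad=np.asarray(ad, dtype=np.int32),
        samples=list(samples),
    )
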