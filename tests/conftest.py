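import numpy as np
import pandas as pd
import pytest

import episig as es
from episig.synthetic import (CohortDesign, make_cell_reference_panel,
                              make_manifest, simulate_null_cohort)


@pytest.fixture(scope="session")
def manifest_small():
    return make_manifest(300, n_chromosomes=4, mean_spacing=800.0, seed=11)


@pytest.fixture(scope="session")
def panel_small(manifest_small):
    return make_cell_reference_panel(manifest_small, n_cell_types=7,
                                     n_discriminating=60, seed=12)


@pytest.fixture(scope="session")
def null_cohort(manifest_small, panel_small):
    design = CohortDesign(group_sizes={"A": 6}, control_pool_size=30, seed=13)
    return simulate_null_cohort(design, manifest_small, panel_small)


@pytest.fixture(scope="session")
def study():
    """The default simulated study, shared read-only across tests."""
    return es.simulate_study(seed=1)


def toy_cohort(betas: np.ndarray, manifest: pd.DataFrame,
               groups=None, detection_p=None) -> es.MethylationCohort:
    """Assemble a small cohort around an explicit beta matrix."""
    n = betas.shape[1]
    ids = [f"t{i:02d}" for i in range(n)]
    samples = pd.DataFrame({
        "group": groups if groups is not None else ["control"] * n,
        "age": 10.0, "sex": "F", "batch": "b1", "array_type": "450k",
    }, index=pd.Index(ids, name="sample_id"))
    b = pd.DataFrame(betas, index=manifest.index, columns=ids)
    dp = None if detection_p is None else pd.DataFrame(
        detection_p, index=manifest.index, columns=ids)
    return es.MethylationCohort(b, samples, manifest, dp)
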