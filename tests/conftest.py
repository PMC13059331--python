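import numpy as np
import pandas as pd
import pytest

from citequant.preprocess import QC_METRIC_NAMES, AdtSample
from citequant.synthetic import DEFAULT_PANEL, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-condition cohort shared across read-only tests."""
    config = SyntheticConfig(n_patients=3, n_cells_per_sample=300, seed=123)
    return generate_cohort(config)


@pytest.fixture()
def qc_series():
    """A plausible QC metric vector with all 13 metrics."""
    rng = np.random.default_rng(0)
    return pd.Series(rng.uniform(10, 90, len(QC_METRIC_NAMES)), index=QC_METRIC_NAMES)


@pytest.fixture()
def toy_adt():
    """Tiny hand-made ADT sample: 4 cells x (3 antigens + 2 isotypes)."""
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(4, 5)),
        index=[f"c{i}" for i in range(4)],
        columns=["CD33", "CD34", "CD38", "iso1", "iso2"],
    )
    return AdtSample(sample_id="toy", counts=counts, isotype_controls=("iso1", "iso2"))
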