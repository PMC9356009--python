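import numpy as np
import pytest

from cytoarch import qc
from cytoarch.synth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort reused by read-only tests (do not mutate)."""
    cfg = SimConfig(
        n_children=80,
        batch_sizes=(14, 66),
        seed=11,
        n_null_snps=50,
        n_low_viability=3,
        n_inadequate=4,
        n_nonresponder=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_folds(small_cohort):
    """QC'd, batch-adjusted, media-normalized folds of the small cohort."""
    tensor, _, _, _ = small_cohort
    tensor = qc.floor_tensor_to_lod(tensor)
    tensor, _ = qc.apply_sample_exclusions(tensor)
    tensor = qc.adjust_batch(tensor, qc.estimate_batch_model(tensor))
    folds = qc.media_normalize(tensor)
    return folds.loc[folds.notna().any(axis=1)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
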