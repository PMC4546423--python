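import numpy as np
import pytest

from gbmalt import AcquisitionConfig, CohortConfig


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Default acquisition: 120 dynamics, 10 baseline, 3.22 s."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """Desk-scale cohort: 12 patients on a 20x20x6 grid, same structure
    (nested artifact causes, steroid/follow-up exclusions) as the default."""
    return CohortConfig(
        n_total=12, n_dsc_hemorrhage=8, n_dsc_skull_base=4,
        n_dwi_uninterp_skull_base=2, n_dwi_uninterp_hemorrhage=1,
        n_dce_uninterp=2, n_steroid=1, n_no_followup=0,
        n_recurrence_final=4, n_post_treatment_final=4,
        acquisition=AcquisitionConfig(grid_shape=(20, 20, 6)),
        lesion_radius_xy=3.0, lesion_radius_z=2.0,
    )


@pytest.fixture(scope="session")
def small_grid_full_cohort_kwargs() -> dict:
    """Full 71-patient accrual structure on a reduced 20x20x6 grid."""
    return dict(acquisition=AcquisitionConfig(grid_shape=(20, 20, 6)),
                lesion_radius_xy=3.0, lesion_radius_z=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
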