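import numpy as np
import pandas as pd
import pytest

from petdosim import (
    BiodistributionTable,
    OrganKineticsSpec,
    PipelineConfig,
    StudyDesign,
    sample_td_study,
)
from petdosim.synthetic import with_noiseless


@pytest.fixture(scope="session")
def kinetics_spec() -> OrganKineticsSpec:
    return OrganKineticsSpec()


@pytest.fixture(scope="session")
def noiseless_table(kinetics_spec) -> BiodistributionTable:
    return sample_td_study(kinetics_spec, with_noiseless(StudyDesign(seed=0)))


@pytest.fixture(scope="session")
def noisy_table(kinetics_spec) -> BiodistributionTable:
    return sample_td_study(kinetics_spec, StudyDesign(seed=1))


@pytest.fixture()
def ne_config() -> PipelineConfig:
    return PipelineConfig(extrapolate=False)


@pytest.fixture()
def small_biodist_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": ["m1", "m1", "m2"],
            "organ": ["liver", "brain", "liver"],
            "time_post_injection_min": [2.0, 2.0, 5.0],
            "sample_mass_g": [1.7, 0.45, 1.8],
            "measured_activity_bq": [1.0e5, 2.0e4, 8.0e4],
            "injected_activity_bq": [7.0e6, 7.0e6, 7.0e6],
            "counting_delay_min": [0.0, 0.0, 0.0],
            "body_weight_g": [35.0, 35.0, 35.0],
        }
    )


@pytest.fixture(autouse=True)
def _quiet_single_animal_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="single animal for")
        yield


def assert_close(got, want, rel=None, abs_=None):
    __tracebackhide__ = True
    np.testing.assert_allclose(got, want, rtol=rel or 0, atol=abs_ or 0)
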