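import numpy as np
import pytest
from hypothesis import settings

from clamrepro.sectioning import SectionPlan, sample_fields, section_gonad
from clamrepro.stereology import estimate_fecundity
from clamrepro.synthetic_gonad import GeneratorConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Generator configuration with gonads scaled down ~70-fold in volume
    (same occupancy targets and diameter distributions) so that whole
    pipeline runs stay fast in tests."""
    return GeneratorConfig(gv_slope_mm3_per_mm=0.25, gv_intercept_mm3=-3.5)


@pytest.fixture(scope="session")
def small_plan() -> SectionPlan:
    """Section plan with camera fields shrunk to fit the scaled-down
    gonad cross-sections."""
    return SectionPlan(field_width_um=300.0, field_height_um=225.0)


def run_specimen(gonad, plan, config, field_seed, **kwargs):
    """Section, field-sample and stereologically estimate one gonad."""
    table = section_gonad(gonad, plan)
    sampled = sample_fields(table, plan, seed=field_seed)
    return estimate_fecundity(sampled, config=config, **kwargs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
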