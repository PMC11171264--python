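import numpy as np
import pytest

from melaband import synthetic


@pytest.fixture(scope="session")
def default_slide():
    """The default simulated slide (rectangle tumor, 4-sd marker mixtures)."""
    cfg = synthetic.SlideSimConfig(seed=1)
    annotation, cells, truth = synthetic.generate_slide(cfg, slide_id="S1")
    return cfg, annotation, cells, truth


@pytest.fixture(scope="session")
def rect_annotation(default_slide):
    return default_slide[1]


@pytest.fixture(scope="session")
def planted_cohort():
    """n=400 cohort with a single standardized factor at beta = 0.7."""
    cfg = synthetic.CohortSimConfig(n_patients=400, beta={"f": 0.7}, seed=42)
    return synthetic.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
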