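import numpy as np
import pytest

from neurosubtype.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with a planted two-subtype structure: 40 controls,
    15 + 15 patients, 40 regions, strong effect in 8 of them."""
    cfg = GeneratorConfig(
        n_controls=40, n_subtype1=15, n_subtype2=15, n_regions=40,
        affected_regions=np.arange(1, 9), effect_size=1.5, seed=11,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default-size cohort (93 controls, 38 + 37 patients, 246 regions)."""
    cfg = GeneratorConfig(seed=5, effect_size=1.0)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth
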