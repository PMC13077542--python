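import numpy as np
import pandas as pd
import pytest

from pfas_semiquant.calibration import CalibrationFit, CalibrationSeries, Compound
from pfas_semiquant.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (50 compounds, 200 descriptors, seed 42)."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same study conditions with every noise source switched off."""
    cfg = GeneratorConfig(ie_noise_sd=0.0, area_noise_cv=0.0, intercept_scale=0.0, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def anchor_pair():
    """A compound/anchor pair with hand-checkable slopes and weights."""
    compound = Compound("PFX", "test analyte", 400.0)
    anchor = Compound("FHUEA", "anchor", 320.0)
    fit = CalibrationFit("PFX", 500.0, 0.0, 1.0)
    anchor_fit = CalibrationFit("FHUEA", 800.0, 0.0, 1.0)
    return compound, fit, anchor, anchor_fit


def make_series(compound_id="C1", slope=3.5, intercept=0.0, noise_sd=0.0, seed=0,
                levels=(0.2, 0.5, 1.0, 2.0, 5.0, 10.0)):
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    areas = intercept + slope * levels + rng.normal(0.0, noise_sd, len(levels))
    return CalibrationSeries(compound_id, levels, areas)
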