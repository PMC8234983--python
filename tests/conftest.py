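import numpy as np
import pytest
from hypothesis import settings

import pahunfold as pu

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chem_truth():
    """One representative chemical parameter set with its preset baselines."""
    preset = pu.PRESETS["PAHt_0.8uM_urea"]
    return preset.params  # (ChemThermoParams, SignalBaselines)


@pytest.fixture(scope="session")
def thermal_truth():
    preset = pu.PRESETS["PAHd_0.8uM_thermal"]
    return preset.params


@pytest.fixture(scope="session")
def noiseless_chem_curve(chem_truth):
    thermo, baselines = chem_truth
    return pu.simulate_chem_curve(thermo, baselines, noise=pu.NoiseModel(sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_thermal_curve(thermal_truth):
    thermo, baselines = thermal_truth
    return pu.simulate_thermal_curve(thermo, baselines, noise=pu.NoiseModel(sigma=0.0))


def replicate_curves(preset_name, seeds=(1, 2, 3), sigma=0.01):
    """Replicate noisy curves from a named preset, one seed each."""
    preset = pu.PRESETS[preset_name]
    thermo, baselines = preset.params
    sim = (pu.simulate_chem_curve if preset.family == "chemical"
           else pu.simulate_thermal_curve)
    return [sim(thermo, baselines, noise=pu.NoiseModel(sigma=sigma, seed=s))
            for s in seeds], thermo


@pytest.fixture(scope="session")
def fast_fit_config():
    return pu.FitConfig(multistart=2, seed=0)
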