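import numpy as np
import pytest

from seedtherm import (ExperimentDesign, SeedPopulationParams,
                       TreatmentFlags, simulate_experiment)


@pytest.fixture
def black_ar_params() -> SeedPopulationParams:
    """After-ripened black seedlot-#1 population (T_opt = 24 °C)."""
    return SeedPopulationParams(
        T_base=8.0, theta_cold_50=144.0, sigma_theta=35.0,
        T_c_50=35.0, sigma_Tc=2.5, theta_warm=99.0, p_viable=0.6)


@pytest.fixture
def clean_regime_params() -> SeedPopulationParams:
    """Fully viable population whose per-seed regime splits all fall in
    (23.2, 23.9) °C, so temperatures <= 21 are sub-optimal and >= 25
    supra-optimal for every percentile used in the tests."""
    return SeedPopulationParams(
        T_base=8.0, theta_cold_50=144.0, sigma_theta=30.0,
        T_c_50=35.0, sigma_Tc=2.0, theta_warm=99.0, p_viable=1.0)


@pytest.fixture
def small_experiment(black_ar_params):
    design = ExperimentDesign(
        temperatures=(16.0, 20.0, 24.0), n_dishes=2, seeds_per_dish=25,
        scoring_times=tuple(float(d) for d in range(1, 31)),
        treatment=TreatmentFlags(), rng_seed=42)
    return design, simulate_experiment(design, black_ar_params)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
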