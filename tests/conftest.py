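import numpy as np
import pytest

from aaflux import (
    ConcentrationSeries,
    EnrichmentSeries,
    Pool,
    SimulationConfig,
    Tracer,
    TrialConfig,
    simulate_trial,
)


@pytest.fixture(scope="session")
def trial_config():
    return TrialConfig(protein_dose_g=25.0)


@pytest.fixture(scope="session")
def oracle_sim_25g():
    """Noise-free simulated 25 g trial on a 1-min grid."""
    cfg = SimulationConfig(noise_cv_enrichment=0.0, noise_cv_concentration=0.0)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_sim_25g():
    cfg = SimulationConfig(seed=7)
    return simulate_trial(cfg)


@pytest.fixture
def flat_series():
    """Steady-state plasma series: flat concentration and enrichments."""
    times = np.arange(0.0, 721.0, 60.0)
    conc = ConcentrationSeries("phe", times, np.full_like(times, 60.0))
    e_iv = EnrichmentSeries(Tracer.D5_PHE, Pool.PLASMA, times, np.full_like(times, 7.5))
    e_oral = EnrichmentSeries(Tracer.C13_PHE, Pool.PLASMA, times, np.zeros_like(times))
    return conc, e_iv, e_oral
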