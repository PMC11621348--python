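import numpy as np
import pytest

from bradyglu.signal_io import AnalysisConfig
from bradyglu.synthetic_cohort import (
    CohortConfig,
    SimPatientParams,
    simulate_cohort,
    simulate_patient,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def one_day_record():
    """One simulated patient-day with a moderate bradycardia load."""
    params = SimPatientParams(brady_base_rate=0.5)
    record, truth = simulate_patient(params, days=1.0, seed=11, patient_id="P000")
    return record, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Three patients, one day each, null glucose-bradycardia coupling."""
    cfg = CohortConfig(days=1.0, brady_base_rate=0.5)
    return simulate_cohort(3, cfg, seed=7)


@pytest.fixture(scope="session")
def random_rr_windows():
    """Random realistic RR windows used by feature-oracle comparisons."""
    rng = np.random.default_rng(2024)
    windows = []
    for _ in range(100):
        n = int(rng.integers(40, 320))
        rr = rng.normal(rng.uniform(650, 1100), rng.uniform(15, 80), size=n)
        rr = np.clip(rr, 320, 2900)
        t0 = float(rng.uniform(0, 86400 - 300)) // 300 * 300
        times = t0 + np.cumsum(rr) / 1000.0
        windows.append((t0, times, rr))
    return windows
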