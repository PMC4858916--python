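import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from leisuregps.config import StudyConfig
from leisuregps.synth import SynthConfig, simulate_study


@pytest.fixture(scope="session")
def default_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def noise_free_study():
    """Small noise-free cohort: exact recovery expected everywhere."""
    return simulate_study(SynthConfig.noise_free(n_participants=6, seed=11, frac_low_wear=0.0))


@pytest.fixture(scope="session")
def noisy_study():
    """Default-condition cohort: 2.9-m noise, 5% dropout, pauses, under-reporting."""
    return simulate_study(SynthConfig(n_participants=20, seed=7))


def epochs_frame(speeds, pid="P1", start="2014-01-07 10:00:00", epoch_s=15, counts=500):
    """Build an aligned epoch frame from a raw speed array (NaN = no fix)."""
    import numpy as np

    speeds = np.asarray(speeds, dtype=float)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(speeds.size) * epoch_s, unit="s")
    has_fix = ~np.isnan(speeds)
    return pd.DataFrame({
        "participant_id": pid, "timestamp": ts,
        "lat": np.where(has_fix, 51.0, np.nan),
        "lon": np.where(has_fix, 3.7, np.nan),
        "speed_kmh": speeds, "counts": counts,
    })
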