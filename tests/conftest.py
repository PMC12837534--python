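from datetime import datetime

import pandas as pd
import pytest

from foalwatch.simulate import SynthConfig, generate_cohort


def records_frame(rows):
    """Build a validated-records frame from (mare, iso-timestamp, temp) triples."""
    return pd.DataFrame(
        {
            "mare_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows], format="ISO8601"),
            "temp_c": [float(r[2]) for r in rows],
        }
    )


def events_frame(pairs):
    return pd.DataFrame(
        {
            "mare_id": [p[0] for p in pairs],
            "foaling_time": pd.to_datetime([p[1] for p in pairs]),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 4-mare cohort with foalings, reused by read-only tests."""
    cfg = SynthConfig(n_mares=4, days=10, sample_interval_min=6.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def clean_config():
    """Noise-free, artifact-free, no-drop configuration: a pure circadian signal."""
    return SynthConfig(
        n_mares=2, days=5, sample_interval_min=15.0,
        drop_magnitude_c=0.0, artifact_rate_per_h=0.0, noise_sd_c=0.0,
        sensor_bias_c=0.0, seed=5,
    )
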