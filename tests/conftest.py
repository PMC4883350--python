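import numpy as np
import pandas as pd
import pytest

from ecgddd.simulate import CohortConfig, NoiseConfig, default_morphology, synthesize_record


@pytest.fixture(scope="session")
def noiseless_cfg() -> CohortConfig:
    return CohortConfig(
        n_subjects=2,
        record_minutes=1.0,
        seed=11,
        noise=NoiseConfig(baseline_amp_mV=0.0, powerline_amp_mV=0.0, white_sd_mV=0.0),
    )


@pytest.fixture(scope="session")
def noiseless_record(noiseless_cfg):
    return synthesize_record(noiseless_cfg, class_label=0, seed=123)


@pytest.fixture(scope="session")
def noisy_record():
    cfg = CohortConfig(n_subjects=1, record_minutes=2.0, seed=5)
    return synthesize_record(cfg, class_label=0, seed=321)


@pytest.fixture
def morphology():
    return default_morphology()


def make_beat_table(n_beats: int, rr_s: float = 0.85, p_amp: float = 0.15, r_amp: float = 1.1,
                    s_amp: float = -0.22, p_dur: float = 107.0, record: str = "rec0") -> pd.DataFrame:
    """Synthetic delineation table with constant beats (helper, not a fixture)."""
    return pd.DataFrame(
        {
            "record": record,
            "beat": np.arange(n_beats),
            "r_time_s": np.arange(n_beats) * rr_s,
            "P_amp": p_amp,
            "R_amp": r_amp,
            "S_amp": s_amp,
            "P_dur_ms": p_dur,
            "P_dur_var": 0.0,
            "core_valid": True,
        }
    )
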