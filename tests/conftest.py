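"""Shared fixtures: clean synthetic recordings with known geometry."""

import numpy as np
import pytest

from repolab import (SyntheticConfig, average_beat, detect_r_peaks,
                     generate_dipole, generate_record, segment_beats)


def make_clean_config(theta: float = 60.0, **kwargs) -> SyntheticConfig:
    """Noiseless, spread-free config: TCRT ground truth is exactly cos(theta)."""
    defaults = dict(theta=theta, qrs_loop_spread=0.0, t_loop_width=0.0,
                    noise_sd=0.0)
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    return make_clean_config()


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def clean_dipole(clean_config):
    return generate_dipole(clean_config)


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    return segment_beats(clean_record, detect_r_peaks(clean_record))


@pytest.fixture(scope="session")
def clean_average(clean_beats):
    return average_beat(clean_beats)


def analytic_energy(config: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form dipole energy |d(t)|^2 (t in seconds relative to an R
    centre), evaluated directly from the wave parameters — independent of
    the generation and decomposition code paths."""
    from repolab.synthetic_ecg import _wave_directions

    dirs = _wave_directions(config)
    d = np.zeros((3, t.size))
    for name, w in config.wave_params.items():
        g = np.exp(-0.5 * ((t - w.center_ms / 1000.0) / (w.width_ms / 1000.0)) ** 2)
        d += w.amplitude * np.outer(dirs[name], g)
    return np.sum(d ** 2, axis=0)
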