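import numpy as np
import pandas as pd
import pytest

from chronoerp.core import Epochs, make_equidistant_montage
from chronoerp.synthetic import SimConfig


@pytest.fixture(scope="session")
def montage16():
    return make_equidistant_montage(16)


@pytest.fixture(scope="session")
def montage60():
    return make_equidistant_montage(60)


@pytest.fixture
def noise_free_sim():
    """Study-condition config with noise and artifacts switched off."""
    return SimConfig(
        n_channels=16,
        pink_sd_uv=0.0, alpha_sd_uv=0.0, white_sd_uv=0.0,
        blink_rate=0.0, drift_rate=0.0, flatline_rate=0.0,
    )


def make_epochs(data, rate=256.0, lock="stimulus", t0_ms=None, ch_names=None,
                units_tag="µV", baseline_applied=False, meta=None):
    """Build a minimal Epochs object around a trials x channels x samples array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    if t0_ms is None:
        t0_ms = 0.0
    step = 1000.0 / rate
    times = t0_ms + np.arange(n_samp) * step
    if ch_names is None:
        ch_names = tuple(f"ch{i}" for i in range(n_ch))
    if meta is None:
        meta = pd.DataFrame({
            "trial_index": np.arange(n_trials),
            "rt_ms": np.full(n_trials, 1200.0),
            "category": ["correct"] * n_trials,
            "kept": [True] * n_trials,
        })
    return Epochs(data=data, times_ms=times, lock=lock, rate=rate,
                  ch_names=ch_names, trial_meta=meta,
                  baseline_applied=baseline_applied, units_tag=units_tag)


@pytest.fixture
def epochs_factory():
    return make_epochs
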