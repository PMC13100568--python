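import dataclasses

import numpy as np
import pytest

from oculoscope import presets, sim
from oculoscope.io import GazeConfig, Screen, generate_session


@pytest.fixture(scope="session")
def small_fig_s4():
    """300-trial-per-condition ERP simulation (shared; treat as read-only)."""
    cfg = presets.fig_s4(n_trials=300, seed=11)
    epochs, events = sim.simulate_experiment(cfg)
    return cfg, epochs, events


@pytest.fixture(scope="session")
def noiseless_fig_s4():
    cfg = dataclasses.replace(presets.fig_s4(n_trials=200, seed=3), noise_sd=0.0)
    epochs, events = sim.simulate_experiment(cfg)
    return cfg, epochs, events


@pytest.fixture(scope="session")
def tiny_session():
    """A 4-trial continuous session with EEG + gaze + events."""
    cfg = presets.fig_s4(n_trials=2, seed=5)
    gc = GazeConfig(screen=Screen(), blink_rate=0.05)
    eeg, gaze, events = generate_session(cfg, gc, seed=5)
    return eeg, gaze, events


def deterministic_dist(value, width=1e-6):
    """Truncated normal collapsed (numerically) onto a single value."""
    return sim.TruncatedNormal(mean=value, sd=width, lo=value - 5 * width,
                               hi=value + 5 * width)
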