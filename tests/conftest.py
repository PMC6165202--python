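"""Shared fixtures: montage and small simulated recordings.

Session-scoped simulations keep the suite fast; tests that need
different effect structure build their own configs.
"""

import dataclasses

import numpy as np
import pytest

import earbci as eb


@pytest.fixture(scope="session")
def montage():
    return eb.build_default_montage()


@pytest.fixture(scope="session")
def task_recording(montage):
    """One reduced session (10 MA + 10 LC) with default effects, preprocessed."""
    schedule = eb.generate_main_schedule(sessions=1, trials_per_cond=10, seed=42)
    rec = eb.simulate_recording(montage, schedule, eb.SimulationConfig(seed=42))
    return eb.downsample(eb.bandpass(rec), 200.0)


@pytest.fixture(scope="session")
def task_epochs(task_recording):
    return eb.baseline_correct(eb.extract_epochs(task_recording))


def roi_referenced(epochs, montage, roi):
    """Re-reference epochs for one region and restrict to its channels."""
    groups = montage.analysis_groups(include_scalp=True)
    if roi == "ear":
        data = eb.rereference_ear(epochs.data, epochs.channels,
                                  montage.ear_left, montage.ear_right)
    else:
        data = eb.rereference_car(epochs.data, epochs.channels, groups[roi])
    return dataclasses.replace(epochs, data=data).select_channels(groups[roi])


@pytest.fixture(scope="session")
def quiet_blink_world(montage):
    """Low-amplitude background with strong injected blinks, epoched.

    Background peak-to-peak stays far below the rejection threshold, so
    the blink-bearing trials are exactly the rejectable ones.  Returns
    (epochs, blink_times).
    """
    schedule = eb.generate_main_schedule(sessions=1, trials_per_cond=5, seed=7)
    sim = eb.SimulationConfig(seed=7, noise_scale=1.0, alpha_amplitude=2.0,
                              beta_gamma_amplitude=2.0)
    rec = eb.simulate_recording(montage, schedule, sim)
    rec, times = eb.inject_blinks(rec, rate=2.0, amplitude=300.0, seed=3)
    rec = eb.downsample(eb.bandpass(rec), 200.0)
    epochs = eb.baseline_correct(eb.extract_epochs(rec))
    return epochs, times
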