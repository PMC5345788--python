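"""Shared fixtures: small synthetic traces with known ground truth."""

import numpy as np
import pytest

from minikin.detect import SweepTrace
from minikin.simulate import EventKinetics, SimConfig, simulate_sweep


@pytest.fixture(scope="session")
def kinetics_mid():
    """Mid-range biexponential kinetics (tau_w = 24.8 ms)."""
    return EventKinetics.from_tau_w(24.8)


@pytest.fixture(scope="session")
def noiseless_sweep(kinetics_mid):
    """A noiseless, unfiltered sweep with ~80 injected events."""
    cfg = SimConfig(
        kinetics=kinetics_mid,
        event_rate=1.2,
        sweep_duration=70.0,
        noise_sd=0.0,
        filter_cutoff=None,
        seed=3,
    )
    return simulate_sweep(cfg)


@pytest.fixture(scope="session")
def noisy_sweep(kinetics_mid):
    """Default-noise, 2 kHz-filtered sweep (study acquisition conditions)."""
    cfg = SimConfig(
        kinetics=kinetics_mid,
        event_rate=1.2,
        sweep_duration=70.0,
        noise_sd=2.0,
        seed=3,
    )
    return simulate_sweep(cfg)


def make_mono_event_trace(
    amplitude=-50.0,
    tau_ms=20.0,
    fs=10_000.0,
    pre_s=2.0,
    post_s=2.0,
    baseline_pa=0.0,
    noise_sd=0.0,
    seed=0,
):
    """A single ideal monoexponential event (instantaneous rise) on a flat trace."""
    rng = np.random.default_rng(seed)
    n_pre, n_post = int(pre_s * fs), int(post_s * fs)
    t_ms = np.arange(n_post) * 1e3 / fs
    x = np.concatenate([np.zeros(n_pre), amplitude * np.exp(-t_ms / tau_ms)])
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, len(x))
    return SweepTrace(samples=x + baseline_pa, sampling_rate=fs), n_pre
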