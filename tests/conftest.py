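import numpy as np
import pytest

from headkin import (
    PulseSpec,
    SkullResponseSpec,
    default_machine_spec,
    simulate_machine_trace,
    simulate_skull_trace,
)
from headkin.traces import AngularRateTrace


@pytest.fixture
def machine_spec():
    return default_machine_spec()


@pytest.fixture
def clean_machine(machine_spec):
    """Noise-free machine trace in the targeted 250 rad/s regime."""
    return simulate_machine_trace(machine_spec, 25_000.0, seed=0, noise_sd=0.0)


@pytest.fixture
def clean_skull(machine_spec):
    """Noise-free triaxial skull trace with the default transfer response."""
    return simulate_skull_trace(
        machine_spec, SkullResponseSpec(noise_sd=0.0), 50_000.0, seed=0
    )


def make_trace(omega, fs=25_000.0, axis="machine"):
    omega = np.asarray(omega, dtype=float)
    t = np.arange(omega.size) / fs
    return AngularRateTrace(t, omega, axis)


def half_sine(peak, base_ms, fs=25_000.0, lead_ms=15.0, duration_ms=60.0):
    """Symmetric half-sine pulse trace built directly from its closed form."""
    n = int(round(duration_ms * 1e-3 * fs)) + 1
    t = np.arange(n) / fs
    tau = t * 1e3 - lead_ms
    y = np.where(
        (tau >= 0) & (tau <= base_ms), np.sin(np.pi * np.clip(tau, 0, base_ms) / base_ms), 0.0
    )
    return AngularRateTrace(t, peak * y, "machine")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
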