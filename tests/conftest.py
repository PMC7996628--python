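import numpy as np
import pytest

from frailtykit import AngularVelocitySeries, SyntheticParams


@pytest.fixture
def params():
    """Default synthetic subject (realistic jitter and noise)."""
    return SyntheticParams(seed=11)


@pytest.fixture
def clean_params():
    """Perfectly periodic, noiseless subject."""
    return SyntheticParams(
        seed=11,
        decay=0.0,
        period_jitter_cv=0.0,
        amplitude_jitter_cv=0.0,
        omega_noise_sd=0.0,
        keypoint_noise_sd=0.0,
    )


def sine_omega(amplitude=100.0, freq=1.0, rate=100.0, duration=20.0, phase=0.0):
    """ω = A·sin(2πft) on a uniform grid; first lobe positive (flexion)."""
    t = np.arange(int(round(duration * rate)) + 1) / rate
    t = t[t <= duration + 1e-12]
    return AngularVelocitySeries(
        t=t, omega=amplitude * np.sin(2 * np.pi * freq * t + phase), source="synthetic"
    )


@pytest.fixture
def make_sine():
    return sine_omega
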