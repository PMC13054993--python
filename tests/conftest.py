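import numpy as np
import pytest

from relaxmap.relaxation_models import (
    AcquisitionSchedule,
    BiParams,
    MonoParams,
    bi_decay,
    mono_decay,
)
from relaxmap.voxel_fitting import DecayCurve


@pytest.fixture
def cpmg40() -> AcquisitionSchedule:
    """Default multi-echo schedule: 40 echoes, 10-400 ms."""
    return AcquisitionSchedule.cpmg()


@pytest.fixture
def ir_schedule() -> AcquisitionSchedule:
    """Log-spaced inversion-recovery schedule, 1 ms - 5 s."""
    return AcquisitionSchedule.ir(np.geomspace(1.0, 5000.0, 10))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_mono_curve(schedule, s0=100.0, t2=50.0, noise_sd=0.0, seed=0):
    signal = mono_decay(MonoParams(s0, t2), schedule.times)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(
            0.0, noise_sd, signal.shape
        )
    return DecayCurve(schedule, signal)


def make_bi_curve(schedule, a1=50.0, a2=50.0, tf=20.0, ts=200.0,
                  noise_sd=0.0, seed=0):
    signal = bi_decay(BiParams(a1, a2, tf, ts), schedule.times)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(
            0.0, noise_sd, signal.shape
        )
    return DecayCurve(schedule, signal)
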