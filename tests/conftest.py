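import numpy as np
import pytest

from mrgating import (
    FieldSpec,
    GatingConfig,
    MotionTrace,
    apply_kinematics,
    generate_regular_trace,
    synthetic_static_field,
)


@pytest.fixture
def trace_10bpm():
    """Two minutes of regular 10 BPM cos^6 breathing, 30 mm amplitude."""
    return generate_regular_trace(10.0, 30.0, 3, 120.0, 100.0)


@pytest.fixture
def trace_10bpm_3d(trace_10bpm):
    return apply_kinematics(trace_10bpm)


@pytest.fixture
def latency_gate_cfg():
    """Displacement gating at z in [-5, +5] mm about the reference."""
    return GatingConfig(thresholds={"z": (-5.0, 5.0)})


@pytest.fixture
def window_gate_cfg():
    """Dosimetric gating window: z in [0, 15] mm of the 30 mm amplitude."""
    return GatingConfig(thresholds={"z": (0.0, 15.0)})


@pytest.fixture
def small_field():
    """Modest static field for convolution/gamma tests."""
    spec = FieldSpec(field_size=(40.0, 55.0), center=(0.0, 7.5))
    x = np.arange(-45.0, 45.1, 1.0)
    z = np.arange(-50.0, 60.1, 1.0)
    return synthetic_static_field(spec, x, z)


@pytest.fixture
def constant_motion():
    """Static 'motion' at z = 5 mm for 10 s."""
    t = np.arange(0, 1001) / 100.0
    return MotionTrace(t=t, z=np.full_like(t, 5.0), fs=100.0)
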