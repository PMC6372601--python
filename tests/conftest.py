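import numpy as np
import pytest

from sacburst import ModelParameters, StimulusProtocol, Trajectory


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    """Published defaults at the canonical working point (g_K=10, g_C=12)."""
    return ModelParameters()


def make_calcium_trace(C: np.ndarray, sample_dt: float = 100.0) -> Trajectory:
    """Build a trajectory carrying a prescribed calcium time course.

    Voltage and gating columns are filled with resting placeholders; only
    the calcium column matters for burst detection.
    """
    n = len(C)
    states = np.zeros((n, 5))
    states[:, 0] = -70.0
    states[:, 2] = C
    T = n * sample_dt
    return Trajectory(
        times=np.arange(n) * sample_dt,
        states=states,
        params=ModelParameters(),
        dt=0.5,
        seed=0,
        protocol=StimulusProtocol(((0.0, max(T, 1.0), 0.0),)),
        stride=int(sample_dt / 0.5),
    )
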