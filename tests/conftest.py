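import numpy as np
import pytest

from ulmkit import (AcquisitionParams, IQStack, SceneConfig, VesselSpec,
                    make_scene, simulate_iq)


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_params() -> AcquisitionParams:
    """Reduced grid constants for fast tests (same physics, ×10 upsampling)."""
    return AcquisitionParams(frames_per_acquisition=64, n_acquisitions=2)


@pytest.fixture()
def straight_vessel_scene(params):
    """One lateral plug-flow vessel at 5 mm/s, clean background."""
    cfg = SceneConfig(
        grid_shape=(32, 48),
        vessels=[VesselSpec(kind="straight", start=(800.0, 100.0),
                            end=(800.0, 2200.0), radius=15.0, peak_speed=5.0,
                            flow_sign=1, bubble_rate=3.0)],
        tissue_amplitude=0.0, noise_floor=0.0, seed=0)
    return make_scene(cfg, params)


@pytest.fixture()
def tissue_bubble_stack(params):
    """Slowly drifting tissue 30 dB above a few flowing bubbles, mild noise."""
    cfg = SceneConfig(
        grid_shape=(32, 32),
        vessels=[VesselSpec(kind="straight", start=(400.0, 100.0),
                            end=(400.0, 1400.0), radius=15.0, peak_speed=6.0,
                            flow_sign=1, bubble_rate=4.0),
                 VesselSpec(kind="straight", start=(1100.0, 100.0),
                            end=(1100.0, 1400.0), radius=15.0, peak_speed=6.0,
                            flow_sign=-1, bubble_rate=4.0)],
        tissue_amplitude=10 ** (30 / 20), tissue_motion_amplitude=12.0,
        noise_floor=1e-3, seed=3)
    scene = make_scene(cfg, params)
    stack, truth = simulate_iq(scene, params, n_frames=96, seed=4)
    return scene, stack, truth


def random_iq_stack(shape=(8, 8, 16), seed=0, params=None) -> IQStack:
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return IQStack(data=data.astype(np.complex64), params=params or AcquisitionParams())
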