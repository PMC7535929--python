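import numpy as np
import pytest
from hypothesis import settings

from bitetrack.calibration import Calibration
from bitetrack.synth import SceneConfig, generate_scene

settings.register_profile("suite", derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cal():
    return Calibration()  # 25 um/px, 25 fps


@pytest.fixture(scope="session")
def walking_scene():
    """Two straight-walking agents in separate bands: no crossings, no
    noise. Shared by tracking-recovery and determinism tests."""
    cfg = SceneConfig(
        n_agents=2,
        frame_size=(640, 640),
        noise_sd=0.0,
        seed=5,
        heading_jitter=0.0,
        behavior_program=[[("walking", 5.0)], [("walking", 5.0)]],
        init_positions=[[200, 160], [440, 480]],
        init_headings=[0.0, np.pi],
    )
    frames, gt = generate_scene(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def feeding_result(feeding_scene):
    """Full pipeline run on the two-agent feeding scene, using the known
    empty-substrate background (the agents barely move, so a temporal
    median would absorb them)."""
    from bitetrack.pipeline import PipelineConfig, run_pipeline

    cfg_scene, frames, gt = feeding_scene
    cfg = PipelineConfig(
        calibration=cfg_scene.cal, genus="aedes", shape_stride=2, seed=3
    )
    background = np.full(frames.shape[1:], cfg_scene.background_level)
    return run_pipeline(cfg, frames=frames, background=background), gt


@pytest.fixture(scope="session")
def feeding_scene():
    """One feeding and one walking-then-resting agent, noise-free, used for
    the end-to-end ground-truth recovery checks."""
    cfg = SceneConfig(
        n_agents=2,
        frame_size=(640, 640),
        fps=25.0,
        noise_sd=0.0,
        seed=11,
        heading_jitter=0.0,
        behavior_program=[
            [("stationary", 11.0), ("feeding", 9.0)],
            [("walking", 3.0), ("stationary", 17.0)],
        ],
        init_positions=[[180, 180], [440, 480]],
        init_headings=[0.0, 0.0],
    )
    frames, gt = generate_scene(cfg)
    return cfg, frames, gt
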