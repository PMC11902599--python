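import numpy as np
import pytest

import phytosfm as ps


@pytest.fixture(scope="session")
def small_scene() -> ps.SyntheticScene:
    """Compact plant scene shared by the fast tests."""
    return ps.make_scene(ps.SceneParams(height=360, width=480), seed=7)


@pytest.fixture(scope="session")
def small_pair(small_scene):
    """Rendered two-view pair (8 mm baseline ≈ 1° at 450 mm radius)."""
    return ps.render_views(small_scene, baseline=8.0)


@pytest.fixture(scope="session")
def small_config(small_scene) -> ps.PipelineConfig:
    return ps.PipelineConfig(intrinsics=ps.default_intrinsics(small_scene),
                             upsample_factor=1)


@pytest.fixture(scope="session")
def small_result(small_config, small_pair) -> ps.ReconstructionResult:
    va, vb = small_pair
    return ps.run_reconstruction(small_config, va.frames, vb.frames)


@pytest.fixture(scope="session")
def turntable_sequence():
    """Five-view 1°-grid turntable sweep plus a matching config."""
    import dataclasses
    scene = ps.make_scene(ps.SceneParams(height=300, width=400), seed=9)
    views = ps.render_sequence(scene, [0, 1, 2, 3, 4], turntable_radius=450.0)
    frames = [dataclasses.replace(v.frames, view_angle=float(a))
              for a, v in zip([0, 1, 2, 3, 4], views)]
    cfg = ps.PipelineConfig(intrinsics=ps.default_intrinsics(scene),
                            upsample_factor=1)
    return frames, cfg


def random_frames(seed: int = 0, shape=(16, 16), bit_depth: int = 8):
    rng = np.random.default_rng(seed)
    hi = 2**bit_depth - 1
    def img():
        return ps.IntensityImage(
            rng.integers(0, hi + 1, size=shape,
                         dtype=np.uint8 if bit_depth == 8 else np.uint16),
            bit_depth=bit_depth)
    return ps.SpectralFrameSet(red=img(), green=img(), blue=img())
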