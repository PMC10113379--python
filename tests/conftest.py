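"""Shared fixtures: small procedural textures and rendered stereo scenes.

Everything is generated at test time from seeds; the heavier quarter-scale
render with its dense disparity map is session-scoped so the expensive work
happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenostereo import (
    CameraIntrinsics,
    MatchConfig,
    PlantSpec,
    SceneSpec,
    compute_disparity_map,
    make_field_scene,
    render_stereo_pair,
)

QUARTER_SCALE = dict(altitude=4.1, baseline=0.81, focal=3000.0)
SMALL_SHAPE = (228, 342)  # 1/16 of the full sensor, for cheap unit tests
SMALL_FOCAL = 750.0


def textured_image(seed: int, shape=(96, 128), contrast=40.0) -> np.ndarray:
    """Band-limited random texture with enough local variance for ZNCC."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), 1.2)
    img = 128.0 + contrast * img / img.std()
    return img


@pytest.fixture(scope="session")
def intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(QUARTER_SCALE["focal"])


@pytest.fixture(scope="session")
def small_flat_pair():
    """Small flat-ground render, no perturbations."""
    scene = make_field_scene(SceneSpec(extent=(4.0, 3.0), texture_seed=7))
    return render_stereo_pair(
        scene,
        altitude=QUARTER_SCALE["altitude"],
        baseline=QUARTER_SCALE["baseline"],
        focal=SMALL_FOCAL,
        image_shape=SMALL_SHAPE,
        noise_seed=7,
    )


@pytest.fixture(scope="session")
def box_scene_pair():
    """Quarter-scale render of a flat field with one 0.57 m plant box."""
    scene = make_field_scene(
        SceneSpec(
            extent=(8.0, 4.0),
            texture_seed=11,
            plants=(PlantSpec((0.45, 0.45), 0.57, (0.05, 0.0), 12),),
        )
    )
    return render_stereo_pair(
        scene, noise_seed=11, **QUARTER_SCALE
    )


@pytest.fixture(scope="session")
def box_scene_disparity(box_scene_pair):
    """Dense disparity map of the box scene (span wide enough for the plant top)."""
    rp = box_scene_pair
    center = int(round(rp.ground_disparity)) + 50
    cfg = MatchConfig(search_center=center, search_span=256)
    return compute_disparity_map(
        rp.left, rp.right, cfg, baseline_m=rp.baseline, focal_px=rp.focal
    )
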