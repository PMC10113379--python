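"""Disparity-to-depth conversion, plant height, and resolution accounting.

For a rectified pair with baseline ``b`` (metres) and focal length ``f``
(pixels), a point with disparity ``d`` (pixels) lies at depth

    l = f b / d.

A plant's height is the depth difference between the surrounding ground and
its highest point,

    p_h = f b / d_g  -  f b / d_p,

with ``d_g`` the ground disparity and ``d_p`` the (larger) plant-top
disparity.  Because disparities are integer levels, the smallest detectable
depth change at level ``d`` is

    dl = f b / d - f b / (d + 1) = l_d / (d + 1),

which is what limits the height resolution: wide baselines push ``d`` up and
the per-level step down into the millimetre range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stereo import DisparityMap

__all__ = [
    "CameraIntrinsics",
    "HeightMeasurement",
    "depth_from_disparity",
    "plant_height",
    "depth_step_resolution",
    "per_level_height_resolution",
    "error_reduction",
    "measure_plant",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal length in pixels, optional principal point."""

    focal_length: float
    principal_point: tuple[float, float] | None = None  # (x, y), defaults to image centre

    def __post_init__(self) -> None:
        if not self.focal_length > 0:
            raise ValueError(f"focal length must be positive, got {self.focal_length}")


@dataclass(frozen=True)
class HeightMeasurement:
    """One plant-height reading taken from a disparity map region."""

    plant_height: float  # metres
    ground_disparity: float  # pixels
    plant_disparity: float  # pixels
    resolution_per_level: float  # metres of height per disparity level
    baseline: float  # metres

    def as_dict(self) -> dict:
        return {
            "height_m": self.plant_height,
            "d_g": self.ground_disparity,
            "d_p": self.plant_disparity,
            "resolution_m": self.resolution_per_level,
            "baseline_m": self.baseline,
        }


def depth_from_disparity(d: float, f: float, b: float) -> float:
    """Depth ``l = f b / d`` in metres; strictly decreasing in ``d``."""
    if d <= 0:
        raise ValueError(f"disparity must be positive, got {d}")
    if f <= 0 or b <= 0:
        raise ValueError("focal length and baseline must be positive")
    return f * b / d


def plant_height(d_g: float, d_p: float, f: float, b: float) -> float:
    """Plant height from the ground and plant-top disparities.

    Zero when the disparities coincide, positive when the plant top is nearer
    to the camera than the ground (``d_p > d_g``).
    """
    if d_g <= 0 or d_p <= 0:
        raise ValueError(f"disparities must be positive, got d_g={d_g}, d_p={d_p}")
    return depth_from_disparity(d_g, f, b) - depth_from_disparity(d_p, f, b)


def depth_step_resolution(l_d: float, d: float) -> float:
    """Depth change (metres) for a one-level disparity change at depth ``l_d``.

    Equals ``l_d / (d + 1)``, identically ``f b / d - f b / (d + 1)``.
    """
    if l_d <= 0 or d <= 0:
        raise ValueError(f"depth and disparity must be positive, got l={l_d}, d={d}")
    return l_d / (d + 1.0)


def per_level_height_resolution(true_height: float, d_g: float, d_p: float) -> float:
    """Height change per disparity level given a known height spanning d_p - d_g levels."""
    if true_height <= 0:
        raise ValueError(f"true height must be positive, got {true_height}")
    if d_p <= d_g:
        raise ValueError(f"plant disparity {d_p} must exceed ground disparity {d_g}")
    return true_height / (d_p - d_g)


def error_reduction(err_proposed: float, err_conventional: float) -> float:
    """Relative error reduction in percent against a reference method."""
    if err_conventional <= 0:
        raise ValueError("conventional error must be positive")
    return 100.0 * (err_conventional - err_proposed) / err_conventional


class MeasurementError(RuntimeError):
    """No usable pixels for a height reading — signals that a re-shoot is needed."""


def _supported_extremes(values: np.ndarray, support_fraction: float = 0.01) -> tuple[float, float]:
    """Lowest and highest disparity level backed by enough pixels.

    Bins the values to integer levels and returns the extreme levels holding
    at least ``support_fraction`` of the sample each, discarding thin smears
    of mismatches beyond the real surfaces.
    """
    v = np.rint(values).astype(np.int64)
    lo_level, hi_level = int(v.min()), int(v.max())
    counts = np.bincount(v - lo_level, minlength=hi_level - lo_level + 1).astype(float)
    need = max(1.0, support_fraction * len(v))
    ok = np.flatnonzero(counts >= need)
    if len(ok) == 0:
        return float(lo_level), float(hi_level)
    return float(lo_level + ok[0]), float(lo_level + ok[-1])


def measure_plant(
    dm: DisparityMap,
    region: tuple[int, int, int, int],
    intrinsics: CameraIntrinsics,
    baseline: float,
    plant_mask: np.ndarray | None = None,
    robust: bool = True,
    min_score: float | None = None,
) -> HeightMeasurement:
    """Measure a plant's height from a disparity-map region.

    Parameters
    ----------
    dm
        Disparity map of the rectified pair (left image as reference).
    region
        ``(x0, y0, x1, y1)`` rectangle in map coordinates (half-open).
    intrinsics, baseline
        Camera focal length (pixels) and GNSS baseline (metres).
    plant_mask
        Boolean mask over the full map marking plant pixels; ground pixels
        are the remaining valid pixels of the region.  When omitted, the
        region is split at the midpoint between its extreme disparities
        (plants are nearer, hence higher disparity).
    robust
        Take the highest / lowest *well-supported* disparity level instead
        of the raw max / min: a level counts only if it and its immediate
        neighbours hold at least 1% of the class's pixels.  Occlusion edges
        around a plant produce bands of confident but wrong matches smeared
        thinly over many levels; support filtering rejects them while the
        plant-top and ground plateaus pass easily.  Raw mode reproduces
        manual readings off a disparity image exactly.
    min_score
        Discard matches scoring below this ZNCC value before measuring; by
        default robust mode uses 0.75 when the map carries scores, which
        rejects the weak spurious matches that occlusion bands produce.
    """
    x0, y0, x1, y1 = region
    sub = dm.disparity[y0:y1, x0:x1].astype(float)
    sub_valid = dm.valid[y0:y1, x0:x1].copy()
    if min_score is None and robust and dm.score is not None:
        min_score = 0.75
    if min_score is not None and dm.score is not None:
        sub_valid &= dm.score[y0:y1, x0:x1] >= min_score
    if not sub_valid.any():
        raise MeasurementError("no valid disparities in region")
    vals = sub[sub_valid]
    if plant_mask is not None:
        pm = plant_mask[y0:y1, x0:x1] & sub_valid
        gm = ~plant_mask[y0:y1, x0:x1] & sub_valid
        if not gm.any():
            raise MeasurementError("region lacks valid ground pixels")
    else:
        if robust:
            lo, hi = _supported_extremes(vals)
        else:
            lo, hi = float(vals.min()), float(vals.max())
        split = 0.5 * (lo + hi)
        pm = sub_valid & (sub > split)
        gm = sub_valid & (sub <= split)
    if not pm.any() or (robust and pm.sum() < 0.02 * sub_valid.sum()):
        # flat region: no substantial nearer surface, measure ground only
        pm = gm
    if robust:
        d_g = _supported_extremes(sub[gm])[0]
        d_p = _supported_extremes(sub[pm])[1]
    else:
        d_p = float(sub[pm].max())
        d_g = float(sub[gm].min())
    f = intrinsics.focal_length
    h = plant_height(d_g, d_p, f, baseline) if d_p > d_g else 0.0
    depth_g = depth_from_disparity(d_g, f, baseline)
    return HeightMeasurement(
        plant_height=h,
        ground_disparity=d_g,
        plant_disparity=d_p,
        resolution_per_level=depth_step_resolution(depth_g, d_g),
        baseline=baseline,
    )
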