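"""Dense block stereo matching by zero-mean normalized cross-correlation.

The matcher assumes a calibrated (rectified) pair: corresponding points lie
on the same image row, and the left image is the reference.  For each left
pixel an integer horizontal offset (disparity) is searched over a window of
candidates; the candidate maximizing the ZNCC of the two intensity windows
wins, ties going to the smallest disparity so results are deterministic.
ZNCC is invariant to positive affine intensity changes, which is what makes
block matching on naturally textured soil and canopy robust to exposure
differences between the two shots.

Pixels whose best score falls below the acceptance threshold, whose window
leaves the image, or whose neighbourhood is textureless (zero variance) are
marked invalid; they render black in the exported disparity image.

The dense path computes, per candidate disparity, windowed means, variances
and cross-terms with a box filter, which is algebraically the per-window
ZNCC evaluated at every pixel at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "MatchConfig",
    "DisparityMap",
    "OverlapError",
    "load_gray",
    "zncc_score",
    "match_pixel",
    "compute_disparity_map",
    "predict_search_center",
]

_VAR_EPS = 1e-12


class OverlapError(RuntimeError):
    """Image overlap below half the image width — matching refused, re-shoot."""


@dataclass(frozen=True)
class MatchConfig:
    """Block-matching parameters.

    ``window_radius`` gives a (2r+1)x(2r+1) correlation window;
    ``search_center``/``search_span`` bound the candidate disparities,
    typically centred on the GNSS-predicted ground disparity f*b/Z with a
    span of 128 levels.  With ``require_full_range`` (the default), pixels
    whose candidate range is truncated by the image border are treated as
    unmatched rather than risking a spurious best-of-a-partial-search; turn
    it off to accept any pixel with at least one testable candidate.
    """

    window_radius: int = 7
    zncc_accept_threshold: float = 0.6
    search_center: int = 64
    search_span: int = 128
    require_full_range: bool = True
    #: cross-check each left-reference match against the best match of its
    #: right-image partner (tolerance one level); occluded pixels and
    #: edge-fattening artefacts fail the check and render black
    lr_consistency: bool = True

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if not -1.0 < self.zncc_accept_threshold < 1.0:
            raise ValueError("zncc_accept_threshold must lie in (-1, 1)")
        if self.search_span < 1:
            raise ValueError("search_span must be >= 1")

    @property
    def search_min(self) -> int:
        return max(0, self.search_center - self.search_span // 2)

    @property
    def search_max(self) -> int:
        return self.search_center + self.search_span // 2


def predict_search_center(focal_px: float, baseline_m: float, altitude_m: float) -> int:
    """GNSS-informed prediction of the ground disparity, d = f b / Z."""
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    return int(round(focal_px * baseline_m / altitude_m))


@dataclass(frozen=True)
class DisparityMap:
    """Integer disparity per left-image pixel with an explicit validity mask."""

    disparity: np.ndarray  # non-negative offsets, reference = left image
    valid: np.ndarray  # bool, False where matching failed
    search_min: float
    search_max: float
    baseline_m: float | None = None
    focal_px: float | None = None
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.disparity.shape != self.valid.shape:
            raise ValueError("disparity and valid mask shapes differ")

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())

    def save(self, path: str | Path) -> None:
        """Write a 16-bit single-channel image (invalid = 0) plus a JSON sidecar."""
        path = Path(path)
        img = np.where(self.valid, np.rint(self.disparity), 0).astype(np.uint16)
        iio.imwrite(path, img)
        sidecar = {
            "search_min": float(self.search_min),
            "search_max": float(self.search_max),
            "baseline_m": self.baseline_m,
            "focal_px": self.focal_px,
            "valid_fraction": self.valid_fraction,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DisparityMap":
        path = Path(path)
        img = iio.imread(path).astype(np.int64)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            disparity=img.astype(float),
            valid=img > 0,
            search_min=meta["search_min"],
            search_max=meta["search_max"],
            baseline_m=meta.get("baseline_m"),
            focal_px=meta.get("focal_px"),
        )


def load_gray(path: str | Path) -> np.ndarray:
    """Read an image file as float64 grayscale (colour converted to luma)."""
    img = iio.imread(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        arr = arr @ np.array([0.299, 0.587, 0.114])
    return arr


def zncc_score(window_a: np.ndarray, window_b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape patches.

    Returns a score in [-1, 1]; NaN signals undefined (a zero-variance
    patch), which callers treat as a failed match.
    """
    a = np.asarray(window_a, dtype=np.float64)
    b = np.asarray(window_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sqrt((a * a).sum()))
    nb = float(np.sqrt((b * b).sum()))
    if na * na <= _VAR_EPS or nb * nb <= _VAR_EPS:
        return float("nan")
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0))


def match_pixel(
    left: np.ndarray,
    right: np.ndarray,
    x: int,
    y: int,
    cfg: MatchConfig,
) -> tuple[int, float] | None:
    """Match one left-image pixel against the right image along its row.

    Returns ``(disparity, score)`` for the best candidate in
    ``[search_min, search_max]``, or ``None`` when no candidate window fits,
    the texture is flat, or the best score misses the acceptance threshold.
    Ties break to the smallest disparity.
    """
    r = cfg.window_radius
    h, w = left.shape
    if not (r <= y < h - r and r <= x < w - r):
        return None
    if cfg.require_full_range and not (r <= x - cfg.search_max and x - cfg.search_min < w - r):
        return None
    patch_l = left[y - r : y + r + 1, x - r : x + r + 1]
    best: tuple[int, float] | None = None
    for d in range(cfg.search_min, cfg.search_max + 1):
        xr = x - d
        if not r <= xr < w - r:
            continue
        s = zncc_score(patch_l, right[y - r : y + r + 1, xr - r : xr + r + 1])
        if np.isnan(s):
            continue
        if best is None or s > best[1]:
            best = (d, s)
    if best is None or best[1] < cfg.zncc_accept_threshold:
        return None
    return best


def _window_stats(img: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    mean = uniform_filter(img, size, mode="constant")
    var = uniform_filter(img * img, size, mode="constant") - mean * mean
    return mean, np.sqrt(np.clip(var, 0.0, None))


def compute_disparity_map(
    left: np.ndarray,
    right: np.ndarray,
    cfg: MatchConfig,
    baseline_m: float | None = None,
    focal_px: float | None = None,
    check_overlap: bool = True,
) -> DisparityMap:
    """Dense ZNCC block matching of a rectified pair (left as reference).

    Equivalent pixel-for-pixel to running :func:`match_pixel` everywhere, but
    computed with box filters.  Refuses pairs whose predicted overlap is
    below half the image width: such a pair cannot be calibrated reliably and
    should be re-shot.
    """
    left = np.ascontiguousarray(left, dtype=np.float64)
    right = np.ascontiguousarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError("left/right shapes differ")
    h, w = left.shape
    # non-finite pixels (e.g. beyond a rectification border) poison any
    # window containing them: zero their intensity and kill those windows
    finite_l = np.isfinite(left)
    finite_r = np.isfinite(right)
    has_holes = not (finite_l.all() and finite_r.all())
    if has_holes:
        left = np.where(finite_l, left, 0.0)
        right = np.where(finite_r, right, 0.0)
    if check_overlap and cfg.search_center > w / 2:
        raise OverlapError(
            f"predicted disparity {cfg.search_center} px exceeds half the image "
            f"width ({w / 2:.0f} px): overlap ratio below 1/2, re-shoot the pair"
        )
    r = cfg.window_radius
    size = 2 * r + 1
    n = size * size
    mean_l, std_l = _window_stats(left, size)
    mean_r, std_r = _window_stats(right, size)
    if has_holes:
        ok_l = uniform_filter(finite_l.astype(np.float64), size, mode="constant") > 1.0 - 1e-9
        ok_r = uniform_filter(finite_r.astype(np.float64), size, mode="constant") > 1.0 - 1e-9
        std_l = np.where(ok_l, std_l, 0.0)  # zero variance -> window rejected
        std_r = np.where(ok_r, std_r, 0.0)

    best_score = np.full((h, w), -np.inf)
    best_d = np.zeros((h, w), dtype=np.int64)
    best_score_r = np.full((h, w), -np.inf)  # right image as reference
    best_d_r = np.zeros((h, w), dtype=np.int64)
    ys = np.zeros((h, w), dtype=bool)
    ys[r : h - r, :] = True

    for d in range(cfg.search_min, cfg.search_max + 1):
        if d >= w - 2 * r:
            break
        # column x of the left image against column x-d of the right image
        cross = np.full((h, w), np.nan)
        prod = left[:, d:] * right[:, : w - d]
        cross[:, d:] = uniform_filter(prod, size, mode="constant")[:, :]
        mr = np.full((h, w), np.nan)
        sr = np.full((h, w), np.nan)
        mr[:, d:] = mean_r[:, : w - d]
        sr[:, d:] = std_r[:, : w - d]
        cov = cross - mean_l * mr
        denom = std_l * sr
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > _VAR_EPS / n, cov / denom, -np.inf)
        score = np.clip(score, -1.0, 1.0, out=score, where=np.isfinite(score))
        # window must fit in both images
        ok = ys.copy()
        ok[:, : max(r, d + r)] = False
        ok[:, w - r :] = False
        score = np.where(ok, score, -np.inf)
        better = score > best_score  # strict: ties keep the smaller disparity
        best_score = np.where(better, score, best_score)
        best_d = np.where(better, d, best_d)
        if cfg.lr_consistency:
            # the same score belongs to right pixel x - d; track its best too
            sr = score[:, d:]
            br = sr > best_score_r[:, : w - d]
            best_score_r[:, : w - d] = np.where(br, sr, best_score_r[:, : w - d])
            best_d_r[:, : w - d] = np.where(br, d, best_d_r[:, : w - d])

    valid = np.isfinite(best_score) & (best_score >= cfg.zncc_accept_threshold)
    if cfg.lr_consistency:
        cols = np.clip(np.arange(w)[None, :] - best_d, 0, w - 1)
        partner_d = np.take_along_axis(best_d_r, cols, axis=1)
        valid &= np.abs(partner_d - best_d) <= 1
    if cfg.require_full_range:
        valid[:, : cfg.search_max + r] = False
        hi = w - r + cfg.search_min  # x - search_min must stay left of the border
        valid[:, hi:] = False
    return DisparityMap(
        disparity=np.where(valid, best_d, 0).astype(np.int64),
        valid=valid,
        search_min=cfg.search_min,
        search_max=cfg.search_max,
        baseline_m=baseline_m,
        focal_px=focal_px,
        score=np.where(valid, best_score, 0.0),
    )
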