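"""Two-phase in-flight calibration of a wide-baseline aerial image pair.

Because the baseline comes from two separate exposures during flight, the
pair must be rectified anew for every shot: the right image differs from the
left by small rotations about the vertical (gamma), the flight axis (beta),
and the cross axis (alpha), a vertical image shift (delta-y) and an altitude
scale change (delta-z), while the left image itself may be slightly tilted
against the ground.

The calibration matches *lines*, not isolated feature points.  A handful of
left-image scanlines ``y = C_i`` are matched by ZNCC into the right image;
the matched points of each scanline trace a least-squares line
``y = a_i x + b_i`` there (a line pair L_i/R_i).  The slopes and intercepts
of these lines carry the rotations:

* beta makes the slopes vary with the intercepts,
  ``beta = atan(f (a_i - a_j) / (b_i - b_j))``;
* gamma is the common slope, ``gamma = atan(a_i)``;
* alpha distorts the spacing of the (parallel) lines,
  ``alpha = atan(-f (b_i + b_k - 2 b_j) / (b_i b_j + b_j b_k + b_k b_i))``;
* delta-y and delta-z move/scale the intercepts onto the C_i.

Matching errors are eliminated in two stages: per-line robust fits drop bad
matched points, and rows inconsistent with the consensus transform are
dropped.  Because the three one-parameter solves interact (each overfits the
residual left by the others), the estimate-apply-correct cycle is iterated
until the sum of squared row residuals stops improving; the final increments
are the overfitting amounts.  The ground is assumed planar: the matched
points' depths are fitted by a least-squares plane ``z = a x + b y + c``,
which refines delta-y/delta-z and finally yields the left-image tilt
``beta_b = atan(a)``, ``alpha_b = atan(-b cos(beta_b))``.

All image coordinates inside this module are centred on the principal point
(x right, y down).  Angle sign convention: an alignment with parameters
(beta, gamma, alpha) applies the rotation ``Ry(beta) Rz(gamma) Rx(alpha)``
(right-handed about camera y, z, x; z along the optical axis toward the
ground) to the homogeneous pixel vector of the measured right image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import map_coordinates, uniform_filter
from skimage.feature import corner_harris, corner_peaks

from .height import CameraIntrinsics
from .stereo import MatchConfig

__all__ = [
    "CalibrationError",
    "ScanlineSpec",
    "LinePair",
    "GroundPlane",
    "CalibrationResult",
    "PairCalibration",
    "rotation_matrix",
    "apply_alignment",
    "phase1_rough_align",
    "match_scanlines",
    "solve_beta",
    "solve_gamma",
    "solve_alpha",
    "solve_alpha_rows",
    "solve_translation",
    "fit_ground_plane",
    "calibrate_pair",
]

MAX_ANGLE_RAD = 0.2  # wide-baseline nadir regime; larger recovered angles signal failure


class CalibrationError(RuntimeError):
    """Calibration cannot proceed or did not converge — re-shoot the pair."""


# ---------------------------------------------------------------------------
# geometry helpers (shared convention with the synthetic renderer)


def _ry(b: float) -> np.ndarray:
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(g: float) -> np.ndarray:
    c, s = np.cos(g), np.sin(g)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_matrix(beta: float, gamma: float, alpha: float) -> np.ndarray:
    """Composed alignment rotation ``Ry(beta) Rz(gamma) Rx(alpha)`` (radians)."""
    return _ry(beta) @ _rz(gamma) @ _rx(alpha)


def apply_alignment(
    x: np.ndarray,
    y: np.ndarray,
    focal: float,
    beta: float = 0.0,
    gamma: float = 0.0,
    alpha: float = 0.0,
    dy: float = 0.0,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map principal-point-centred pixel coordinates through a calibration.

    Rotates the homogeneous pixel vector by ``rotation_matrix``, reprojects,
    shifts y by ``-dy`` and scales both axes by ``scale`` about the centre.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = rotation_matrix(beta, gamma, alpha)
    p = np.stack([x, y, np.full_like(x, focal)])
    q = np.tensordot(r, p, axes=1)
    xr = focal * q[0] / q[2]
    yr = focal * q[1] / q[2]
    return scale * xr, scale * (yr - dy)


def invert_alignment(
    x: np.ndarray,
    y: np.ndarray,
    focal: float,
    beta: float = 0.0,
    gamma: float = 0.0,
    alpha: float = 0.0,
    dy: float = 0.0,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`apply_alignment` (rectified -> measured coordinates)."""
    x = np.asarray(x, dtype=float) / scale
    y = np.asarray(y, dtype=float) / scale + dy
    r = rotation_matrix(beta, gamma, alpha).T
    p = np.stack([x, y, np.full_like(x, focal)])
    q = np.tensordot(r, p, axes=1)
    return focal * q[0] / q[2], focal * q[1] / q[2]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ScanlineSpec:
    """Which left-image rows to match and how wide the right-image search band is.

    ``rows`` are 0-based image row indices, strictly increasing, at least
    three of them (the spacing criterion for alpha needs three intercepts).
    ``band_halfwidth`` is the +/- vertical search range S_R in the right
    image around the guided prediction.
    """

    rows: tuple[int, ...]
    band_halfwidth: int = 20

    def __post_init__(self) -> None:
        if len(self.rows) < 3:
            raise ValueError("need at least 3 scanline rows")
        if any(b <= a for a, b in zip(self.rows, self.rows[1:])):
            raise ValueError("rows must be strictly increasing")
        if self.band_halfwidth < 1:
            raise ValueError("band_halfwidth must be >= 1")

    @classmethod
    def evenly_spaced(
        cls, image_height: int, n_rows: int = 9, margin: int = 40, band_halfwidth: int = 20
    ) -> "ScanlineSpec":
        """``n_rows`` rows symmetric about the image centre row."""
        rows = np.linspace(margin, image_height - 1 - margin, n_rows)
        return cls(rows=tuple(int(round(r)) for r in rows), band_halfwidth=band_halfwidth)


@dataclass
class LinePair:
    """A left scanline L_i and its least-squares matched line R_i.

    Coordinates are centred on the principal point.  ``support`` holds the
    accepted matched points as columns (x_left, x_right, y_right).
    """

    left_row: float  # centred C_i
    right_slope: float  # a_i
    right_intercept: float  # centred b_i
    support: np.ndarray  # (n, 3)
    residual_rms: float

    def __post_init__(self) -> None:
        if self.support.shape[0] < 2:
            raise ValueError("a line pair needs at least 2 support points")


@dataclass(frozen=True)
class GroundPlane:
    """Least-squares ground plane z = a x + b y + c in left-camera metres."""

    a: float
    b: float
    c: float
    fit_rms: float


@dataclass
class CalibrationResult:
    """Recovered alignment of the right image plus left-image tilt.

    Angles are radians with the module's sign convention; ``overfit_*`` are
    the magnitudes of the final correction step (the residual overfitting
    when iteration stopped).
    """

    beta: float
    gamma: float
    alpha: float
    overfit_beta: float
    overfit_gamma: float
    overfit_alpha: float
    delta_y: float
    delta_z_scale: float
    left_tilt_betab: float
    left_tilt_alphab: float
    iterations: int
    final_sse: float
    sse_trace: list[float] = field(default_factory=list)
    rows_used: list[int] = field(default_factory=list)
    ground_plane: GroundPlane | None = None
    focal: float | None = None
    baseline_m: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "alpha"):
            if abs(getattr(self, name)) >= MAX_ANGLE_RAD:
                raise CalibrationError(
                    f"recovered |{name}| = {abs(getattr(self, name)):.3f} rad exceeds "
                    f"{MAX_ANGLE_RAD} rad: outside the small-rotation regime"
                )
        if not self.delta_z_scale > 0:
            raise CalibrationError("non-positive delta-z scale")

    def to_json(self) -> dict:
        return {
            "beta_deg": float(np.rad2deg(self.beta)),
            "gamma_deg": float(np.rad2deg(self.gamma)),
            "alpha_deg": float(np.rad2deg(self.alpha)),
            "overfit_deg": [
                float(np.rad2deg(self.overfit_beta)),
                float(np.rad2deg(self.overfit_gamma)),
                float(np.rad2deg(self.overfit_alpha)),
            ],
            "delta_y_px": float(self.delta_y),
            "scale": float(self.delta_z_scale),
            "left_tilt_deg": [
                float(np.rad2deg(self.left_tilt_betab)),
                float(np.rad2deg(self.left_tilt_alphab)),
            ],
            "iterations": self.iterations,
            "sse_trace": [float(s) for s in self.sse_trace],
            "rows_used": list(self.rows_used),
        }

    def summary(self) -> str:
        deg = np.rad2deg
        lines = [
            "Wide-baseline pair calibration",
            "=" * 46,
            f"{'rotation beta  (about y)':<30}{deg(self.beta):>10.4f} deg",
            f"{'rotation gamma (about z)':<30}{deg(self.gamma):>10.4f} deg",
            f"{'rotation alpha (about x)':<30}{deg(self.alpha):>10.4f} deg",
            f"{'vertical shift delta-y':<30}{self.delta_y:>10.3f} px",
            f"{'altitude scale delta-z':<30}{self.delta_z_scale:>10.5f}",
            f"{'left tilt beta_b':<30}{deg(self.left_tilt_betab):>10.4f} deg",
            f"{'left tilt alpha_b':<30}{deg(self.left_tilt_alphab):>10.4f} deg",
            f"{'iterations':<30}{self.iterations:>10d}",
            f"{'final SSE':<30}{self.final_sse:>10.4f} px^2",
            f"{'scanline rows used':<30}{len(self.rows_used):>10d}",
        ]
        if self.ground_plane is not None:
            gp = self.ground_plane
            lines.append(
                f"{'ground plane (a, b, c)':<30}"
                f"  {gp.a:+.5f}, {gp.b:+.5f}, {gp.c:.3f} m (rms {gp.fit_rms * 1e3:.1f} mm)"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# phase 1: rough z-rotation and scaling from corner matches


def _match_corners_zncc(
    left: np.ndarray,
    right: np.ndarray,
    corners: np.ndarray,
    dx_range: tuple[int, int],
    dy_half: int,
    radius: int,
    accept: float,
) -> tuple[np.ndarray, np.ndarray]:
    """ZNCC-match left-image corners into the right image. Returns (src, dst)."""
    h, w = left.shape
    src, dst = [], []
    for (y, x) in corners:
        y, x = int(y), int(x)
        if not (radius <= y < h - radius and radius <= x < w - radius):
            continue
        patch = left[y - radius : y + radius + 1, x - radius : x + radius + 1]
        if patch.std() < 1e-6:
            continue
        x_lo = max(radius, x - dx_range[1])
        x_hi = min(w - radius - 1, x - dx_range[0])
        y_lo = max(radius, y - dy_half)
        y_hi = min(h - radius - 1, y + dy_half)
        if x_hi < x_lo or y_hi < y_lo:
            continue
        region = right[y_lo - radius : y_hi + radius + 1, x_lo - radius : x_hi + radius + 1]
        win = sliding_window_view(region, (2 * radius + 1, 2 * radius + 1))
        pz = patch - patch.mean()
        pn = np.sqrt((pz * pz).sum())

        def zncc_at(view):
            wm = view.mean(axis=(2, 3), keepdims=True)
            wz = view - wm
            denom = np.sqrt((wz * wz).sum(axis=(2, 3)))
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.tensordot(wz, pz, axes=([2, 3], [0, 1])) / (denom * pn)
            return np.where(denom > 1e-9, s, -np.inf)

        # coarse stride-2 sweep, then a full-resolution local refinement:
        # the correlation peak of these window sizes is several pixels wide
        coarse = zncc_at(win[::2, ::2])
        cy_, cx_ = np.unravel_index(np.argmax(coarse), coarse.shape)
        iy0, ix0 = 2 * cy_, 2 * cx_
        sl_y = slice(max(0, iy0 - 2), min(win.shape[0], iy0 + 3))
        sl_x = slice(max(0, ix0 - 2), min(win.shape[1], ix0 + 3))
        fine = zncc_at(win[sl_y, sl_x])
        fy, fx = np.unravel_index(np.argmax(fine), fine.shape)
        iy, ix = sl_y.start + fy, sl_x.start + fx
        if fine[fy, fx] >= accept:
            src.append((x, y))
            dst.append((x_lo + ix, y_lo + iy))
    return np.asarray(src, dtype=float), np.asarray(dst, dtype=float)


def _rough_similarity(
    left: np.ndarray,
    right: np.ndarray,
    dx_range: tuple[int, int],
    dy_half: int = 130,
    radius: int = 7,
    accept: float = 0.75,
    max_corners: int = 60,
) -> tuple[float, float, float, float]:
    """Similarity transform left -> right from matched ground corners.

    Returns ``(rotation, scale, tx, ty)`` such that right ~ s R(theta) left + t
    in image coordinates.  The horizontal translation absorbs the (unknown
    but GNSS-bounded) mean disparity.
    """
    resp = corner_harris(left, sigma=2.0)
    corners = corner_peaks(resp, min_distance=20, num_peaks=max_corners, threshold_rel=1e-4)
    src, dst = _match_corners_zncc(left, right, corners, dx_range, dy_half, radius, accept)
    if len(src) < 4:
        raise CalibrationError(
            f"only {len(src)} corner matches found (need >= 4): insufficient ground texture"
        )
    # Similarity dst = s*R*src + t in complex form.  Corners on raised
    # plants carry a different disparity than ground corners, forming a
    # structured second mode that a plain robust fit can average into a
    # bogus scale; a deterministic two-point consensus search keeps only
    # the dominant (ground) mode before the final least squares.
    zs = src[:, 0] + 1j * src[:, 1]
    zd = dst[:, 0] + 1j * dst[:, 1]
    n = len(zs)
    best_inliers = None
    for i in range(n):
        for j in range(i + 1, n):
            dz = zs[j] - zs[i]
            if abs(dz) < 100.0:  # short spans give unstable scale/rotation
                continue
            m_ij = (zd[j] - zd[i]) / dz
            if not 0.9 < abs(m_ij) < 1.1:
                continue
            t_ij = zd[i] - m_ij * zs[i]
            inliers = np.abs(zd - (m_ij * zs + t_ij)) <= 2.0
            if best_inliers is None or inliers.sum() > best_inliers.sum():
                best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 4:
        raise CalibrationError("fewer than 4 consistent corner matches")
    keep = best_inliers
    for _ in range(2):
        zs0 = zs[keep] - zs[keep].mean()
        zd0 = zd[keep] - zd[keep].mean()
        m = np.vdot(zs0, zd0) / np.vdot(zs0, zs0)  # s * e^{i theta}
        t = zd[keep].mean() - m * zs[keep].mean()
        res = np.abs(zd - (m * zs + t))
        new_keep = res <= 2.0
        if new_keep.sum() < 4 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    theta = float(np.angle(m))
    s = float(abs(m))
    return theta, s, float(t.real), float(t.imag)


def phase1_rough_align(
    left: np.ndarray,
    right: np.ndarray,
    gnss_hint: float,
    focal: float | None = None,
    altitude_hint: float | None = None,
) -> tuple[float, float]:
    """Rough z-rotation and scaling of the right image from ground corners.

    ``gnss_hint`` is the baseline length in metres; with ``focal`` and
    ``altitude_hint`` it bounds the horizontal correspondence search to the
    predicted disparity neighbourhood, otherwise half the image width is
    searched.  Returns the *correction* ``(z_rotation, scale)`` to apply to
    the right image (the negatives of the estimated motion).
    """
    w = left.shape[1]
    if focal is not None and altitude_hint is not None:
        d0 = focal * gnss_hint / altitude_hint
        dx_range = (int(d0 - 0.15 * w), int(d0 + 0.15 * w))
    else:
        dx_range = (0, w // 2)
    theta, s, _, _ = _rough_similarity(left, right, dx_range)
    return -theta, 1.0 / s


# ---------------------------------------------------------------------------
# phase 2: scanline matching and the staged least-squares solves


def _cubic_weights(f: float) -> tuple[float, float, float, float]:
    # Catmull-Rom kernel taps at offsets -1, 0, +1, +2 for fraction f in [0, 1)
    f2 = f * f
    f3 = f2 * f
    return (
        -0.5 * f3 + f2 - 0.5 * f,
        1.5 * f3 - 2.5 * f2 + 1.0,
        -1.5 * f3 + 2.0 * f2 + 0.5 * f,
        0.5 * f3 - 0.5 * f2,
    )


def _shifted_window(block: np.ndarray, ty: float, tx: float) -> np.ndarray:
    """Separable Catmull-Rom shift of a 2-px-apron block by (ty, tx) in [-1, 1].

    Output is ``block.shape - 4``; cubic interpolation keeps the low-pass
    attenuation (hence sub-pixel matching bias) an order of magnitude below
    bilinear resampling.
    """
    jy = int(np.floor(ty))
    jx = int(np.floor(tx))
    fy = ty - jy
    fx = tx - jx
    h, w = block.shape
    wy = _cubic_weights(fy)
    wx = _cubic_weights(fx)
    # rows: output row i draws on block rows i + 2 + jy + {-1, 0, 1, 2}
    rows = sum(
        cy * block[2 + jy + k : h - 2 + jy + k, :] for k, cy in zip((-1, 0, 1, 2), wy)
    )
    return sum(
        cx * rows[:, 2 + jx + k : w - 2 + jx + k] for k, cx in zip((-1, 0, 1, 2), wx)
    )


def _subpixel_lk(
    region: np.ndarray,
    patch_block: np.ndarray,
    iy: int,
    ix: int,
    r: int,
    iters: int = 15,
) -> tuple[float, float]:
    """Joint (dx, dy) sub-pixel refinement of an integer ZNCC match.

    A symmetric Lucas-Kanade step: both windows are bilinearly shifted by
    half the current offset (left by -d/2, right by +d/2), so the low-pass
    attenuation of the interpolation is identical on both sides and its
    pixel-locking bias cancels to first order.  This matters because every
    point of a scanline shares the same fractional offset, so matching
    biases do not average out along a row.  Gain and offset differences are
    absorbed by normalizing both windows.  ``patch_block`` is the left patch
    with a 2-px apron; returns offsets clipped to [-1, 1].
    """
    h, w = region.shape
    size = 2 * r + 1
    if not (2 <= iy <= h - size - 3 and 2 <= ix <= w - size - 3):
        return 0.0, 0.0
    if patch_block.shape != (size + 6, size + 6):
        return 0.0, 0.0
    ox = oy = 0.0
    for _ in range(iters):
        uy, ux = oy / 2.0, ox / 2.0
        # left sampled at -d/2; keep a 1-px apron on the result for gradients
        lw = _shifted_window(patch_block, -uy, -ux)
        jy = int(np.floor(iy + uy))
        jx = int(np.floor(ix + ux))
        if jy < 3 or jx < 3 or jy + size + 3 > h or jx + size + 3 > w:
            break
        rblock = region[jy - 3 : jy + size + 3, jx - 3 : jx + size + 3]
        rw = _shifted_window(rblock, (iy + uy) - jy, (ix + ux) - jx)
        lwin = lw[1:-1, 1:-1]
        rwin = rw[1:-1, 1:-1]
        ls = lwin.std()
        rs = rwin.std()
        if ls <= 0 or rs <= 0:
            break
        res = (rwin - rwin.mean()) / rs - (lwin - lwin.mean()) / ls
        # symmetric gradient: d(res)/d(offset) ~ mean of both windows' gradients
        gx = 0.25 * ((rw[1:-1, 2:] - rw[1:-1, :-2]) / rs + (lw[1:-1, 2:] - lw[1:-1, :-2]) / ls)
        gy = 0.25 * ((rw[2:, 1:-1] - rw[:-2, 1:-1]) / rs + (lw[2:, 1:-1] - lw[:-2, 1:-1]) / ls)
        gxx = float((gx * gx).sum())
        gyy = float((gy * gy).sum())
        gxy = float((gx * gy).sum())
        det = gxx * gyy - gxy * gxy
        if not np.isfinite(det) or det <= 1e-12:
            break
        bx = float((res * gx).sum())
        by = float((res * gy).sum())
        dx = -(gyy * bx - gxy * by) / det
        dy = -(gxx * by - gxy * bx) / det
        if not (np.isfinite(dx) and np.isfinite(dy)):
            break
        ox = float(np.clip(ox + dx, -1.0, 1.0))
        oy = float(np.clip(oy + dy, -1.0, 1.0))
        if abs(dx) < 1e-3 and abs(dy) < 1e-3:
            break
    return ox, oy


def _robust_line_fit(
    x: np.ndarray, y: np.ndarray, mad_k: float = 2.5, passes: int = 2
) -> tuple[float, float, np.ndarray]:
    """Least-squares line y = a x + b with MAD-based outlier rejection.

    This is the first elimination stage: matched points far from the straight
    line the others agree on are dropped before the final fit.
    """
    keep = np.ones(len(x), dtype=bool)
    for _ in range(passes):
        a, b = np.polyfit(x[keep], y[keep], 1)
        res = y - (a * x + b)
        med = np.median(res[keep])
        mad = np.median(np.abs(res[keep] - med))
        if mad < 1e-9:
            break
        new_keep = np.abs(res - med) <= mad_k * 1.4826 * mad
        # never throw away more than half the points: a wildly tilted first
        # fit must not trigger a rejection death-spiral
        if new_keep.sum() < max(2, len(x) // 2) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    a, b = np.polyfit(x[keep], y[keep], 1)
    return float(a), float(b), keep


def match_scanlines(
    left: np.ndarray,
    right: np.ndarray,
    spec: ScanlineSpec,
    cfg: MatchConfig,
    guide: tuple[float, float, float, float] | None = None,
    sample_step: int = 4,
    min_points: int = 8,
    guided_halfwidth: int = 28,
) -> list[LinePair]:
    """Match left scanlines into the right image and fit the line pairs.

    For each sample point on a left row ``y = C_i``, ZNCC is evaluated over a
    horizontal disparity range and a vertical band C_i +/- S_R around the
    guided prediction (``guide`` is the phase-1 similarity ``(theta, s, tx,
    ty)``).  With a guide, the horizontal search shrinks to
    ``+/- guided_halfwidth`` around the predicted position, since phase 1
    already pins the mean disparity; without one the full configured
    disparity range is searched.  Accepted matches get symmetric
    Lucas-Kanade sub-pixel refinement in both axes; each row's points are
    fitted by a robust least-squares line.  Rows with fewer than
    ``min_points`` accepted points are dropped; fewer than 3 surviving rows
    is a calibration failure.
    """
    h, w = left.shape
    r = cfg.window_radius
    size = 2 * r + 1
    n_win = size * size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    band = spec.band_halfwidth
    half_dx = guided_halfwidth if guide is not None else (cfg.search_max - cfg.search_min) // 2 + 2
    pairs: list[LinePair] = []
    for row in spec.rows:
        if not (r <= row < h - r):
            continue
        xs = np.arange(cfg.search_max + r, w - r, sample_step)
        if guide is not None:
            theta, s, tx, ty = guide
            gxs = s * (np.cos(theta) * xs - np.sin(theta) * row) + tx
            gys = s * (np.sin(theta) * xs + np.cos(theta) * row) + ty
        else:
            gxs = xs - (cfg.search_min + cfg.search_max) / 2.0
            gys = np.full_like(xs, float(row), dtype=float)
        # one horizontal strip of the right image serves the whole row
        y_keep = (gys - band >= r) & (gys + band <= h - r - 1)
        if not y_keep.any():
            continue
        strip_lo = int(np.floor(gys[y_keep].min())) - band - r
        strip_hi = int(np.ceil(gys[y_keep].max())) + band + r
        strip = right[strip_lo : strip_hi + 1, :]
        finite = np.isfinite(strip)
        if not finite.all():
            # zero the holes and reject any window touching them (a NaN
            # would otherwise smear through the running-sum filters)
            strip = np.where(finite, strip, 0.0)
        win = sliding_window_view(strip, (size, size))  # indexed by window top-left
        mean_map = uniform_filter(strip, size, mode="constant")[r:-r or None, r:-r or None]
        sq_map = uniform_filter(strip * strip, size, mode="constant")[r:-r or None, r:-r or None]
        norm_map = np.sqrt(np.clip(sq_map - mean_map**2, 0.0, None) * n_win)
        if not finite.all():
            ok_win = (
                uniform_filter(finite.astype(np.float64), size, mode="constant")[
                    r:-r or None, r:-r or None
                ]
                > 1.0 - 1e-9
            )
            norm_map = np.where(ok_win, norm_map, 0.0)
        pts = []
        for x, gx, gy, ok in zip(xs, gxs, gys, y_keep):
            if not ok:
                continue
            x_lo = int(round(gx)) - half_dx
            x_hi = int(round(gx)) + half_dx
            y_lo = int(round(gy)) - band
            y_hi = int(round(gy)) + band
            # a clipped band means the true match may sit outside the right
            # image; matching there can only lock onto spurious texture
            if x_lo < r or x_hi > w - r - 1:
                continue
            patch = left[row - r : row + r + 1, x - r : x + r + 1]
            pz = patch - patch.mean()
            pn = np.sqrt((pz * pz).sum())
            if pn < 1e-6:
                continue
            sy = slice(y_lo - r - strip_lo, y_hi - r - strip_lo + 1)
            sx = slice(x_lo - r, x_hi - r + 1)
            cross = np.tensordot(win[sy, sx], pz, axes=([2, 3], [0, 1]))
            denom = norm_map[sy, sx] * pn
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(denom > 1e-9, cross / denom, -np.inf)
            iy, ix = np.unravel_index(np.argmax(score), score.shape)
            if not np.isfinite(score[iy, ix]) or score[iy, ix] < cfg.zncc_accept_threshold:
                continue
            if r + 3 <= x < w - r - 3 and r + 3 <= row < h - r - 3:
                patch_block = left[row - r - 3 : row + r + 4, x - r - 3 : x + r + 4]
                region = right[y_lo - r : y_hi + r + 1, x_lo - r : x_hi + r + 1]
                ox, oy = _subpixel_lk(region, patch_block, iy, ix, r)
            else:
                ox = oy = 0.0
            pts.append((x - cx, x_lo + ix + ox - cx, y_lo + iy + oy - cy))
        if len(pts) < max(2, min_points):
            continue
        pts_arr = np.asarray(pts)
        a, b, keep = _robust_line_fit(pts_arr[:, 1], pts_arr[:, 2])
        sup = pts_arr[keep]
        if len(sup) < 2:
            continue
        res = sup[:, 2] - (a * sup[:, 1] + b)
        pairs.append(
            LinePair(
                left_row=row - cy,
                right_slope=a,
                right_intercept=b,
                support=sup,
                residual_rms=float(np.sqrt(np.mean(res**2))),
            )
        )
    if len(pairs) < 3:
        raise CalibrationError(
            f"only {len(pairs)} scanlines matched (need >= 3): insufficient texture or overlap"
        )
    return pairs


def solve_beta(pairs: list[LinePair], focal: float) -> float:
    """Rotation about y from slope-vs-intercept variation of the line pairs.

    ``beta = atan(f (a_i - a_j) / (b_i - b_j))``; with more than two lines,
    the slope of the (delta-a vs delta-b) relation is solved by least squares
    over all index pairs.
    """
    if len(pairs) < 2:
        raise CalibrationError("solve_beta needs at least 2 line pairs")
    da, db = [], []
    for p, q in combinations(pairs, 2):
        da.append(p.right_slope - q.right_slope)
        db.append(p.right_intercept - q.right_intercept)
    da, db = np.asarray(da), np.asarray(db)
    denom = float((db * db).sum())
    if denom < 1e-12:
        raise CalibrationError("degenerate geometry: all line intercepts equal")
    return float(np.arctan(focal * float((da * db).sum()) / denom))


def solve_gamma(pairs: list[LinePair]) -> float:
    """Rotation about z that makes the line pairs parallel to the x-axis."""
    if not pairs:
        raise CalibrationError("solve_gamma needs at least 1 line pair")
    return float(np.arctan(np.mean([p.right_slope for p in pairs])))


def solve_alpha(b_i: float, b_j: float, b_k: float, focal: float) -> float:
    """Rotation about x from the spacing of three equally spaced line intercepts.

    ``alpha = atan(-f (b_i + b_k - 2 b_j) / (b_i b_j + b_j b_k + b_k b_i))``.
    Intercepts must be principal-point-centred and belong to equally spaced
    scanlines, the middle one near the image centre; the numerator vanishes
    when the spacing is already uniform.
    """
    denom = b_i * b_j + b_j * b_k + b_k * b_i
    if abs(denom) < 1e-9:
        raise CalibrationError("degenerate geometry: zero intercept-product sum")
    return float(np.arctan(-focal * (b_i + b_k - 2.0 * b_j) / denom))


def solve_alpha_rows(pairs: list[LinePair], focal: float) -> float:
    """Least-squares alpha over all line pairs via the spacing criterion.

    A leftover rotation about x bends the intercepts against the rows as
    ``b - C = f tan(a) + C^2 tan(a) / f`` (plus an affine part absorbed by
    the shift/scale solves); regressing ``b_i - C_i`` on ``[1, C_i,
    C_i^2/f]`` isolates ``tan(a)`` as the curvature coefficient.  This is
    the row-wise least-squares form of making all line spacings equal, and
    unlike second differences of row triples it is insensitive to rows
    dropped near the image border.
    """
    if len(pairs) < 3:
        raise CalibrationError("solve_alpha_rows needs at least 3 line pairs")
    rows = np.array([p.left_row for p in pairs])
    b = np.array([p.right_intercept for p in pairs])
    design = np.column_stack([np.ones_like(rows), rows, rows**2 / focal])
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("degenerate scanline geometry for the spacing criterion")
    coef, _, _, _ = np.linalg.lstsq(design, b - rows, rcond=None)
    return float(np.arctan(coef[2]))


def solve_translation(
    pairs: list[LinePair], rows: ScanlineSpec | None = None
) -> tuple[float, float]:
    """Vertical shift and altitude scale mapping the intercepts onto the rows.

    ``delta_y`` equalizes the mean of the intercepts with the mean of the
    C_i (the weight balance); the returned ``scale`` is the least-squares
    *correction* factor mapping the shifted intercepts onto the C_i about
    the image centre.  Zero spread of the C_i leaves the scale indeterminate.
    """
    if not pairs:
        raise CalibrationError("solve_translation needs line pairs")
    b = np.array([p.right_intercept for p in pairs])
    c = np.array([p.left_row for p in pairs])
    if np.ptp(c) < 1e-9:
        raise CalibrationError("zero spread of scanline rows: scale indeterminate")
    dy = float(b.mean() - c.mean())
    b2 = b - dy
    denom = float((b2 * b2).sum())
    if denom < 1e-12:
        raise CalibrationError("zero spread of intercepts: scale indeterminate")
    return dy, float((b2 * c).sum() / denom)


def fit_ground_plane(points: np.ndarray) -> GroundPlane:
    """Least-squares plane z = a x + b y + c through 3-D points (n, 3).

    Minimizes the squared vertical (z) distance; degenerate (collinear)
    support raises.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 3) array of points")
    a_mat = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(a_mat) < 3:
        raise CalibrationError("degenerate (collinear) support for plane fit")
    coef, _, _, _ = np.linalg.lstsq(a_mat, pts[:, 2], rcond=None)
    res = pts[:, 2] - a_mat @ coef
    return GroundPlane(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        fit_rms=float(np.sqrt(np.mean(res**2))),
    )


# ---------------------------------------------------------------------------
# the full two-phase calibration


class PairCalibration:
    """Calibration model for one wide-baseline image pair.

    Statsmodels-style fit object: construct from the data (the two grayscale
    images, intrinsics and the GNSS baseline), then :meth:`fit` runs phase 1
    (rough z-rotation/scale from corners) and the iterated phase-2 staged
    least squares, returning a :class:`CalibrationResult`.

    Parameters
    ----------
    left, right
        Grayscale images as 2-D float arrays, same shape.
    intrinsics
        Camera intrinsics (focal length in pixels).
    baseline_m
        GNSS-derived baseline length in metres.
    altitude_hint_m
        Rough flight altitude; bounds the correspondence searches.
    spec, cfg
        Scanline layout and ZNCC matching parameters.
    """

    def __init__(
        self,
        left: np.ndarray,
        right: np.ndarray,
        intrinsics: CameraIntrinsics,
        baseline_m: float,
        altitude_hint_m: float | None = None,
        spec: ScanlineSpec | None = None,
        cfg: MatchConfig | None = None,
    ) -> None:
        if left.shape != right.shape:
            raise ValueError("left/right image shapes differ")
        self.left = np.asarray(left, dtype=float)
        self.right = np.asarray(right, dtype=float)
        self.intrinsics = intrinsics
        self.baseline_m = float(baseline_m)
        self.altitude_hint_m = altitude_hint_m
        h, w = self.left.shape
        self.spec = spec or ScanlineSpec.evenly_spaced(h)
        f = intrinsics.focal_length
        if cfg is None:
            if altitude_hint_m is not None:
                center = int(round(f * baseline_m / altitude_hint_m))
            else:
                center = w // 4
            cfg = MatchConfig(search_center=center)
        self.cfg = cfg
        if cfg.search_center > w / 2:
            raise CalibrationError(
                f"predicted disparity {cfg.search_center} px exceeds half the image width: "
                "overlap ratio below 1/2, re-shoot the pair"
            )
        self._cx, self._cy = (w - 1) / 2.0, (h - 1) / 2.0

    # -- internals ---------------------------------------------------------

    def _transform_support(
        self,
        support: list[np.ndarray],
        beta: float,
        gamma: float,
        alpha: float,
        a_scale: float,
        a_off: float,
    ) -> list[np.ndarray]:
        """Apply the current alignment to each row's (x_l, x_r, y_r) support."""
        out = []
        f = self.intrinsics.focal_length
        for sup in support:
            xr, yr = apply_alignment(sup[:, 1], sup[:, 2], f, beta, gamma, alpha)
            out.append(np.column_stack([sup[:, 0], a_scale * xr, a_scale * yr + a_off]))
        return out

    @staticmethod
    def _fit_rows(rows_c: np.ndarray, support: list[np.ndarray]) -> list[LinePair]:
        pairs = []
        for c, sup in zip(rows_c, support):
            a, b = np.polyfit(sup[:, 1], sup[:, 2], 1)
            res = sup[:, 2] - (a * sup[:, 1] + b)
            pairs.append(
                LinePair(
                    left_row=float(c),
                    right_slope=float(a),
                    right_intercept=float(b),
                    support=sup,
                    residual_rms=float(np.sqrt(np.mean(res**2))),
                )
            )
        return pairs

    @staticmethod
    def _sse(pairs: list[LinePair]) -> float:
        return float(
            sum(((p.support[:, 2] - p.left_row) ** 2).sum() for p in pairs)
        )

    def _plane_from_support(self, pairs: list[LinePair]) -> tuple[GroundPlane, np.ndarray]:
        """Depths of the matched points from their disparities, then the LS plane.

        Matched points that landed on raised vegetation sit decimetres off
        the ground plane; two trimming passes drop them before the final
        least squares, keeping the plane (and the left-tilt it yields) a
        ground property.
        """
        f = self.intrinsics.focal_length
        xs, ys, zs = [], [], []
        for p in pairs:
            d = p.support[:, 0] - p.support[:, 1]
            ok = d > 1.0
            depth = f * self.baseline_m / d[ok]
            xs.append(p.support[ok, 0] * depth / f)
            ys.append(np.full(ok.sum(), p.left_row) * depth / f)
            zs.append(depth)
        pts = np.column_stack([np.concatenate(xs), np.concatenate(ys), np.concatenate(zs)])
        keep = np.ones(len(pts), dtype=bool)
        plane = fit_ground_plane(pts)
        for _ in range(2):
            res = pts[:, 2] - (plane.a * pts[:, 0] + plane.b * pts[:, 1] + plane.c)
            med = np.median(res[keep])
            mad = np.median(np.abs(res[keep] - med))
            if mad < 1e-9:
                break
            new_keep = np.abs(res - med) <= 3.0 * 1.4826 * mad
            if new_keep.sum() < max(3, len(pts) // 2) or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            plane = fit_ground_plane(pts[keep])
        return plane, pts[keep]

    # -- the fit -----------------------------------------------------------

    def fit(
        self,
        max_iter: int = 20,
        sse_change_tol: float = 0.01,
        sse_threshold: float | None = None,
        plane_rms_max: float | None = None,
    ) -> CalibrationResult:
        """Run the two-phase calibration.

        Iterates the staged solves (rotations, translation, plane-refined
        translation), measuring the leftover misalignment each pass and
        correcting the accumulated parameters by it, until the row SSE drops
        below ``sse_threshold`` or stops changing by more than
        ``sse_change_tol`` px^2.  Non-convergence raises with the SSE trace
        attached; ``plane_rms_max`` (metres) flags strongly non-planar
        scenes as failures.
        """
        f = self.intrinsics.focal_length
        # the GNSS hint bounds the disparity; uncalibrated rotations can
        # shift corners horizontally by up to ~f*tan(2 deg) on top of it
        slack = int(f * np.tan(np.deg2rad(2.0)))
        dx_range = (self.cfg.search_min - slack, self.cfg.search_max + slack)
        theta, s1, tx, ty = _rough_similarity(self.left, self.right, dx_range)
        raw = match_scanlines(self.left, self.right, self.spec, self.cfg, guide=(theta, s1, tx, ty))
        # first pass of the line-level elimination: a scanline crossing
        # raised vegetation picks up majority-wrong matches and its points
        # scatter far off any straight line; its own residual RMS exposes
        # that regardless of the (still unknown) alignment
        rms = np.array([p.residual_rms for p in raw])
        med_rms = float(np.median(rms))
        keep_rows = rms <= max(3.0 * med_rms, 0.5)
        if keep_rows.sum() >= 3:
            raw = [p for p, k in zip(raw, keep_rows) if k]
        rows_c = np.array([p.left_row for p in raw])
        support = [p.support for p in raw]

        beta = gamma = alpha = 0.0
        a_scale, a_off = 1.0, 0.0
        sse_trace: list[float] = []
        steps = (0.0, 0.0, 0.0)
        pairs = raw
        converged = False
        for it in range(1, max_iter + 1):
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            # the printed estimators measure the leftover motion; the applied
            # correction is its inverse (signs fixed by the rotation convention)
            db = -solve_beta(pairs, f)
            beta += db
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            dg = -solve_gamma(pairs)
            gamma += dg
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            da = solve_alpha_rows(pairs, f)
            alpha += da
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            dy_step, s_step = solve_translation(pairs)
            a_scale *= s_step
            a_off = s_step * (a_off - dy_step)
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            # plane refinement: re-solve the vertical shift/scale at point level
            plane, _ = self._plane_from_support(pairs)
            yl = np.concatenate([np.full(len(p.support), p.left_row) for p in pairs])
            yr = np.concatenate([p.support[:, 2] for p in pairs])
            a_mat = np.column_stack([yr, np.ones(len(yr))])
            coef, _, _, _ = np.linalg.lstsq(a_mat, yl, rcond=None)
            # compose the affine refinement y -> coef0*y + coef1 on top
            a_scale *= coef[0]
            a_off = coef[0] * a_off + coef[1]
            sup_t = self._transform_support(support, beta, gamma, alpha, a_scale, a_off)
            pairs = self._fit_rows(rows_c, sup_t)

            steps = (abs(db), abs(dg), abs(da))
            sse = self._sse(pairs)
            sse_trace.append(sse)

            # second elimination stage: drop lines inconsistent with the
            # consensus transform (their points scatter about their own fit)
            if it == 2 and len(pairs) > 3:
                row_rms = np.array([p.residual_rms for p in pairs])
                med = float(np.median(row_rms))
                keep = row_rms <= max(3.0 * med, 0.5)
                if 3 <= keep.sum() < len(pairs):
                    rows_c = rows_c[keep]
                    support = [s for s, k in zip(support, keep) if k]

            if sse_threshold is not None and sse < sse_threshold:
                converged = True
                break
            if len(sse_trace) >= 2 and abs(sse_trace[-2] - sse_trace[-1]) < sse_change_tol:
                converged = True
                break
        else:
            it = max_iter

        if not converged and sse_threshold is not None:
            raise CalibrationError(
                f"no convergence after {max_iter} iterations; SSE trace: "
                + ", ".join(f"{s:.2f}" for s in sse_trace)
            )

        plane, _ = self._plane_from_support(pairs)
        if plane_rms_max is not None and plane.fit_rms > plane_rms_max:
            raise CalibrationError(
                f"ground-plane fit RMS {plane.fit_rms:.3f} m exceeds {plane_rms_max} m: "
                "scene too far from planar"
            )
        betab = float(np.arctan(plane.a))
        alphab = float(np.arctan(-plane.b * np.cos(betab)))

        return CalibrationResult(
            beta=beta,
            gamma=gamma,
            alpha=alpha,
            overfit_beta=steps[0],
            overfit_gamma=steps[1],
            overfit_alpha=steps[2],
            delta_y=float(-a_off / a_scale),
            delta_z_scale=float(a_scale),
            left_tilt_betab=betab,
            left_tilt_alphab=alphab,
            iterations=it,
            final_sse=sse_trace[-1] if sse_trace else float("nan"),
            sse_trace=sse_trace,
            rows_used=[int(round(c + self._cy)) for c in rows_c],
            ground_plane=plane,
            focal=f,
            baseline_m=self.baseline_m,
            converged=converged or sse_threshold is None,
        )

    def rectify_right(self, result: CalibrationResult) -> np.ndarray:
        """Warp the right image into the rectified frame of ``result``."""
        h, w = self.right.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        xs, ys = invert_alignment(
            xx - self._cx,
            yy - self._cy,
            self.intrinsics.focal_length,
            result.beta,
            result.gamma,
            result.alpha,
            result.delta_y,
            result.delta_z_scale,
        )
        # NaN outside the source frame: correlation windows touching the
        # border become undefined and the matcher marks them invalid,
        # instead of latching onto the artificial black edge
        return map_coordinates(
            self.right, [ys + self._cy, xs + self._cx], order=1, mode="constant", cval=np.nan
        )


def calibrate_pair(
    left: np.ndarray,
    right: np.ndarray,
    baseline_m: float,
    intrinsics: CameraIntrinsics,
    spec: ScanlineSpec | None = None,
    cfg: MatchConfig | None = None,
    altitude_hint_m: float | None = None,
    **fit_kwargs,
) -> tuple[CalibrationResult, tuple[np.ndarray, np.ndarray]]:
    """Calibrate a pair and return the result plus the rectified images.

    Functional wrapper around :class:`PairCalibration`; the left image is
    the reference and is returned unchanged, the right image is warped into
    the common rectified frame, ready for dense stereo matching.
    """
    model = PairCalibration(
        left, right, intrinsics, baseline_m, altitude_hint_m=altitude_hint_m, spec=spec, cfg=cfg
    )
    result = model.fit(**fit_kwargs)
    return result, (model.left, model.rectify_right(result))
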