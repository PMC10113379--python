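"""Ground-truth synthetic stereo acquisitions of a textured field.

Renders the flight geometry of the wide-baseline acquisition: a near-flat,
soil-textured ground plane with box-shaped plant proxies of known height,
imaged by two pinhole cameras a commanded baseline apart at a commanded
altitude, with small inter-shot rotations, a small left-camera tilt, and
RTK-GNSS fixes rounded the way a shooting log prints them.  Every render
carries its full ground truth (poses, plane, per-plant heights, elevation
map), so each pipeline stage can be tested against a closed-form answer
without any real flight data.

World frame: x along the flight direction (image x), y the image-down
direction on the ground, z the depth below the camera plane (positive
toward the ground).  The left camera sits at ``(-b/2, 0, 0)``, the right at
``(+b/2, 0, 0)``; flat ground lies at ``z = altitude``.  Textures are
band-limited value noise (Gaussian-smoothed white noise), which gives the
local intensity variance ZNCC needs everywhere, like natural soil.

The right camera's commanded perturbation uses the calibration module's
alignment convention: a perfectly estimated calibration with exactly the
commanded parameters rectifies the pair.  Rendering supersamples 2x per
axis and box-downsamples to avoid aliasing biasing the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import apply_alignment, rotation_matrix
from .geodesy import GeoPosition, baseline_length

__all__ = [
    "PlantSpec",
    "SceneSpec",
    "Scene",
    "RenderedPair",
    "make_field_scene",
    "render_stereo_pair",
    "make_gnss_track",
]

DEFAULT_IMAGE_SHAPE = (912, 1368)  # quarter-scale of the 5472 x 3648 sensor


@dataclass(frozen=True)
class PlantSpec:
    """A box-shaped plant proxy: footprint (m), height (m), centre position (m)."""

    footprint: tuple[float, float]
    height: float
    position: tuple[float, float]
    albedo_texture_seed: int = 1

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("plant height must be >= 0")
        if min(self.footprint) <= 0:
            raise ValueError("plant footprint must be positive")

    def bounds(self) -> tuple[float, float, float, float]:
        (wx, wy), (px, py) = self.footprint, self.position
        return (px - wx / 2, px + wx / 2, py - wy / 2, py + wy / 2)


@dataclass(frozen=True)
class SceneSpec:
    """Procedural field: extent (m x m, centred on the origin), texture, plants."""

    extent: tuple[float, float] = (6.0, 4.0)
    texture_seed: int = 0
    texture_scale: float = 0.005  # metres per texel, soil-clod scale
    terrain_amplitude: float = 0.0  # metres of gentle undulation; 0 = flat
    plants: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        if min(self.extent) <= 0:
            raise ValueError("extent must be positive")


class _NoiseTexture:
    """Band-limited value noise sampled bilinearly with periodic wrap."""

    def __init__(self, seed: int, n: int, scale: float, mean: float, contrast: float):
        rng = np.random.default_rng(seed)
        g = gaussian_filter(rng.standard_normal((n, n)), sigma=1.2, mode="wrap")
        g = (g - g.mean()) / g.std()
        self.grid = (mean + contrast * g).astype(np.float32)
        self.scale = scale
        self.n = n

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = np.asarray(x, dtype=np.float32) * np.float32(1.0 / self.scale)
        v = np.asarray(y, dtype=np.float32) * np.float32(1.0 / self.scale)
        i0 = np.floor(u).astype(np.int32)
        j0 = np.floor(v).astype(np.int32)
        fu = u - i0
        fv = v - j0
        i0 %= self.n
        j0 %= self.n
        i1 = (i0 + 1) % self.n
        j1 = (j0 + 1) % self.n
        g = self.grid
        return (
            g[j0, i0] * (1 - fu) * (1 - fv)
            + g[j0, i1] * fu * (1 - fv)
            + g[j1, i0] * (1 - fu) * fv
            + g[j1, i1] * fu * fv
        )


@dataclass
class Scene:
    """A realized field scene: textures plus an elevation query."""

    spec: SceneSpec
    ground_texture: _NoiseTexture
    plant_textures: dict[int, _NoiseTexture]
    terrain: _NoiseTexture | None

    def terrain_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.terrain is None:
            return np.zeros_like(np.asarray(x, dtype=float))
        return self.terrain.sample(x, y)

    def elevation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Surface height above the z = altitude ground datum (metres)."""
        e = self.terrain_height(x, y)
        for p in self.spec.plants:
            x0, x1, y0, y1 = p.bounds()
            inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
            e = np.where(inside, p.height, e)
        return e


def make_field_scene(spec: SceneSpec) -> Scene:
    """Build the procedural textures of a field scene; deterministic per seed."""
    for i, p in enumerate(spec.plants):
        for q in spec.plants[i + 1 :]:
            a, b = p.bounds(), q.bounds()
            if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                raise ValueError(f"overlapping plant footprints: {p} and {q}")
    n = int(max(spec.extent) / spec.texture_scale) + 2
    n = min(n, 2048)
    ground = _NoiseTexture(spec.texture_seed, n, spec.texture_scale, mean=128.0, contrast=35.0)
    plants = {
        i: _NoiseTexture(p.albedo_texture_seed, 512, spec.texture_scale, mean=95.0, contrast=30.0)
        for i, p in enumerate(spec.plants)
    }
    terrain = None
    if spec.terrain_amplitude > 0:
        # long-wavelength undulation: ~1 m features
        terrain = _NoiseTexture(
            spec.texture_seed + 7919, 256, 1.0, mean=0.0, contrast=spec.terrain_amplitude
        )
    return Scene(spec=spec, ground_texture=ground, plant_textures=plants, terrain=terrain)


@dataclass
class RenderedPair:
    """A rendered stereo acquisition with full ground truth."""

    left: np.ndarray
    right: np.ndarray
    focal: float
    altitude: float
    baseline: float
    perturbations: dict[str, float]
    gnss: tuple[GeoPosition, GeoPosition]
    plane: tuple[float, float, float]  # z = a x + b y + c in left-camera metres
    plant_heights: tuple[float, ...]
    elevation_map: np.ndarray  # per left pixel, metres above ground datum
    plant_mask: np.ndarray  # per left pixel, True on plant tops
    scene: Scene = field(repr=False, default=None)

    @property
    def ground_disparity(self) -> float:
        """Analytic ground disparity f b / Z of the untilted geometry."""
        return self.focal * self.baseline / self.altitude


def _camera_rays(
    shape: tuple[int, int],
    focal: float,
    r_cam: np.ndarray,
    supersample: int,
    warp: tuple[float, float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    ss = supersample
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ys = ((np.arange(h * ss, dtype=np.float32) + 0.5) / ss - 0.5 - cy)[:, None]
    xs = ((np.arange(w * ss, dtype=np.float32) + 0.5) / ss - 0.5 - cx)[None, :]
    f32 = np.float32(focal)
    if warp is not None:
        # the commanded misalignment: the content a perfectly calibrated
        # correction with these parameters would map back onto the left frame
        beta, gamma, alpha, dy, scale = warp
        m = rotation_matrix(beta, gamma, alpha)
        xw = np.broadcast_to(xs, (h * ss, w * ss)).astype(np.float32)
        yw = np.broadcast_to(ys, (h * ss, w * ss)).astype(np.float32)
        qx = float(m[0, 0]) * xw + float(m[0, 1]) * yw + np.float32(float(m[0, 2]) * focal)
        qy = float(m[1, 0]) * xw + float(m[1, 1]) * yw + np.float32(float(m[1, 2]) * focal)
        qz = float(m[2, 0]) * xw + float(m[2, 1]) * yw + np.float32(float(m[2, 2]) * focal)
        xx = np.float32(scale) * f32 * qx / qz
        yy = np.float32(scale) * (f32 * qy / qz - np.float32(dy))
    else:
        xx, yy = xs, ys
    # ray direction (un-normalized; only the direction matters downstream)
    r = r_cam
    dx = float(r[0, 0]) * xx + float(r[0, 1]) * yy + np.float32(float(r[0, 2]) * focal)
    dy_ = float(r[1, 0]) * xx + float(r[1, 1]) * yy + np.float32(float(r[1, 2]) * focal)
    dz = float(r[2, 0]) * xx + float(r[2, 1]) * yy + np.float32(float(r[2, 2]) * focal)
    shape_full = (h * ss, w * ss)
    return (
        np.ascontiguousarray(np.broadcast_to(dx, shape_full)),
        np.ascontiguousarray(np.broadcast_to(dy_, shape_full)),
        np.ascontiguousarray(np.broadcast_to(dz, shape_full)),
    )


def _shade(
    scene: Scene,
    cam_pos: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    dz: np.ndarray,
    altitude: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cast rays against plant tops, side walls and (possibly undulating) ground.

    Visibility is resolved nearest-surface-first (tallest plant first), so a
    camera genuinely cannot see ground hidden behind a plant box: those rays
    hit the box wall instead, exactly where occlusion makes stereo matching
    fail on real crops.  Returns (intensity, elevation, plant_index).
    """
    shade = np.empty(dx.shape, dtype=np.float32)
    elev = np.zeros(dx.shape, dtype=np.float32)
    plant_idx = np.full(dx.shape, -1, dtype=np.int8)
    done = np.zeros(dx.shape, dtype=bool)

    order = sorted(
        range(len(scene.spec.plants)), key=lambda i: -scene.spec.plants[i].height
    )
    for i in order:
        p = scene.spec.plants[i]
        x0, x1, y0, y1 = p.bounds()
        t = (altitude - p.height - cam_pos[2]) / dz
        px = cam_pos[0] + t * dx
        py = cam_pos[1] + t * dy
        top = ~done & (px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)
        shade[top] = scene.plant_textures[i].sample(px[top], py[top])
        elev[top] = p.height
        plant_idx[top] = i
        done |= top
    # side walls: ray enters the footprint below the top plane
    for i in order:
        p = scene.spec.plants[i]
        x0, x1, y0, y1 = p.bounds()
        t = (altitude - cam_pos[2]) / dz
        gx = cam_pos[0] + t * dx
        gy = cam_pos[1] + t * dy
        wall = ~done & (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
        # flat, dim shading: walls carry almost no texture, matching fails there
        shade[wall] = 55.0
        elev[wall] = p.height / 2.0
        plant_idx[wall] = -2  # wall, not a measurable plant top
        done |= wall
    ground = ~done
    t = (altitude - cam_pos[2]) / dz
    gx = cam_pos[0] + t * dx
    gy = cam_pos[1] + t * dy
    if scene.terrain is not None:
        # one fixed-point pass is plenty for centimetre undulation at nadir
        for _ in range(2):
            e = scene.terrain_height(gx, gy)
            t = (altitude - e - cam_pos[2]) / dz
            gx = cam_pos[0] + t * dx
            gy = cam_pos[1] + t * dy
        elev[ground] = e[ground]
    shade[ground] = scene.ground_texture.sample(gx[ground], gy[ground])
    return shade, elev, plant_idx


def _downsample(img: np.ndarray, ss: int) -> np.ndarray:
    h, w = img.shape
    return img.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def make_gnss_track(
    start: GeoPosition,
    heading: float,
    spacing: float,
    n: int,
    rounding: tuple[int, int] | None = (8, 7),
) -> list[GeoPosition]:
    """Equally spaced GNSS fixes along a constant heading (degrees from north).

    ``rounding`` quantizes the printed coordinates like a shooting log
    (decimals of latitude, longitude); ``None`` keeps full precision.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n < 2:
        raise ValueError("need at least 2 fixes")
    from .geodesy import EARTH_RADIUS_M

    hd = np.deg2rad(heading)
    lat0 = np.deg2rad(start.latitude)
    dlat = spacing * np.cos(hd) / EARTH_RADIUS_M
    dlon = spacing * np.sin(hd) / (EARTH_RADIUS_M * np.cos(lat0))
    track = []
    for i in range(n):
        lat = start.latitude + np.rad2deg(dlat) * i
        lon = start.longitude + np.rad2deg(dlon) * i
        if rounding is not None:
            lat, lon = round(lat, rounding[0]), round(lon, rounding[1])
        track.append(GeoPosition(start.sequence_index + i, lat, lon, start.timestamp))
    return track


def render_stereo_pair(
    scene: Scene,
    altitude: float,
    baseline: float,
    perturbations: dict[str, float] | None = None,
    focal: float = 3000.0,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    supersample: int = 2,
    noise_sigma: float = 1.0,
    noise_seed: int = 0,
    gnss_start: GeoPosition = GeoPosition(1, 36.1141, 140.0992),
    gnss_rounding: tuple[int, int] | None = (8, 7),
) -> RenderedPair:
    """Render a nadir stereo pair over the scene with full ground truth.

    ``perturbations`` may set ``beta``, ``gamma``, ``alpha`` (radians,
    right-image rotations in the calibration convention), ``delta_y``
    (pixels), ``tilt_beta``/``tilt_alpha`` (radians, left-camera tilt).  The
    overlap must exceed half the image width or the render refuses, like the
    acquisition protocol does.
    """
    pert = {
        "beta": 0.0,
        "gamma": 0.0,
        "alpha": 0.0,
        "delta_y": 0.0,
        "tilt_beta": 0.0,
        "tilt_alpha": 0.0,
    }
    if perturbations:
        unknown = set(perturbations) - set(pert)
        if unknown:
            raise ValueError(f"unknown perturbations: {sorted(unknown)}")
        pert.update(perturbations)
    for k in ("beta", "gamma", "alpha", "tilt_beta", "tilt_alpha"):
        if abs(pert[k]) > np.deg2rad(2.0):
            raise ValueError(f"|{k}| exceeds 2 degrees: outside the gimbal regime")
    if altitude <= max((p.height for p in scene.spec.plants), default=0.0):
        raise ValueError("altitude must exceed the tallest plant")
    h, w = image_shape
    d_ground = focal * baseline / altitude
    if d_ground > w / 2:
        raise ValueError(
            f"ground disparity {d_ground:.0f} px exceeds half the image width: "
            "overlap ratio below 1/2, increase altitude or shrink the baseline"
        )

    r_left = rotation_matrix(pert["tilt_beta"], 0.0, pert["tilt_alpha"])
    cam_l = np.array([-baseline / 2.0, 0.0, 0.0])
    cam_r = np.array([+baseline / 2.0, 0.0, 0.0])

    dx, dy_, dz = _camera_rays((h, w), focal, r_left, supersample)
    shade_l, _, _ = _shade(scene, cam_l, dx, dy_, dz, altitude)
    # right camera: a perfect calibration with the commanded parameters
    # rectifies it onto the left frame, by construction
    warp = (pert["beta"], pert["gamma"], pert["alpha"], pert["delta_y"], 1.0)
    dx, dy_, dz = _camera_rays((h, w), focal, r_left, supersample, warp=warp)
    shade_r, _, _ = _shade(scene, cam_r, dx, dy_, dz, altitude)

    # truth channels at final resolution through the left camera
    dx1, dy1, dz1 = _camera_rays((h, w), focal, r_left, supersample=1)
    _, elev, pidx = _shade(scene, cam_l, dx1, dy1, dz1, altitude)

    rng = np.random.default_rng(noise_seed)
    left = _downsample(shade_l, supersample)
    right = _downsample(shade_r, supersample)
    if noise_sigma > 0:
        left = left + rng.normal(0.0, noise_sigma, left.shape)
        right = right + rng.normal(0.0, noise_sigma, right.shape)
    left = np.clip(left, 0.0, 255.0)
    right = np.clip(right, 0.0, 255.0)

    # flat-ground plane in left-camera coordinates from the left tilt
    r3 = r_left[2]
    plane = (-r3[0] / r3[2], -r3[1] / r3[2], altitude / r3[2])

    track = make_gnss_track(
        gnss_start, heading=90.0, spacing=baseline, n=2, rounding=gnss_rounding
    )
    return RenderedPair(
        left=left,
        right=right,
        focal=focal,
        altitude=altitude,
        baseline=baseline,
        perturbations=pert,
        gnss=(track[0], track[1]),
        plane=plane,
        plant_heights=tuple(p.height for p in scene.spec.plants),
        elevation_map=elev,
        plant_mask=pidx >= 0,
        scene=scene,
    )
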