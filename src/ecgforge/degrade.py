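"""Photographic degradation of clean ECG renders.

Simulates photographing a printed ECG with a 2.5-D image-space scene model:
the printed sheet is deformed by a smooth low-frequency mesh template (one
of 8: flat, sags, folds, ripples, twists, bumps), viewed through a
perspective camera (pitch/yaw tilt + distance), composited over one of 11
procedural workspace backgrounds in one of 4 orientations, lit by one or
more directional lights with an optional soft shadow, and finally textured
with stucci-style multi-octave value-noise turbulence ("holes and bumps").

Every stage is driven by a :class:`SceneConfig` and is bit-reproducible for
a fixed seed; the realized forward homography and displacement field are
returned so degraded pixels stay mapped to their clean-image origins.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

N_SHEETS = 8
N_WORKSPACES = 11
N_ORIENTATIONS = 4


class InvalidPoseError(ValueError):
    """Camera pose projects the sheet to (near-)zero area."""


@dataclass(frozen=True)
class LightConfig:
    """One directional light: gradient across the frame plus soft shadow."""

    direction: tuple[float, float] = (1.0, 0.0)   # unit vector in image plane
    intensity: float = 1.0                        # multiplicative gain at centre
    gradient_strength: float = 0.0                # gain swing across half-frame
    shadow_opacity: float = 0.0                   # 0..1 darkening inside shadow
    shadow_offset: float = 0.0                    # band position, -1..1 half-diagonals


@dataclass
class SceneConfig:
    """Full parameterization of one photographic degradation."""

    sheet_id: int = 0
    workspace_id: int = 0
    orientation_id: int = 0
    sheet_translation: tuple[float, float] = (0.0, 0.0)   # px
    sheet_rotation_deg: float = 0.0
    sheet_amplitude_px: float = 0.0          # mesh displacement amplitude
    camera_pitch_deg: float = 0.0
    camera_yaw_deg: float = 0.0
    camera_distance: float = 1.0             # 1.0 = unit magnification
    lights: tuple[LightConfig, ...] = (LightConfig(),)
    noise_size: float = 16.0                 # turbulence spatial scale, px
    noise_turbulence: float = 0.0            # 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sheet_id < N_SHEETS:
            raise ValueError(f"sheet_id must be 0..{N_SHEETS - 1}")
        if not 0 <= self.workspace_id < N_WORKSPACES:
            raise ValueError(f"workspace_id must be 0..{N_WORKSPACES - 1}")
        if not 0 <= self.orientation_id < N_ORIENTATIONS:
            raise ValueError(f"orientation_id must be 0..{N_ORIENTATIONS - 1}")
        if self.noise_size <= 0:
            raise ValueError("noise_size must be positive")
        if self.noise_turbulence < 0:
            raise ValueError("noise_turbulence must be non-negative")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["lights"] = [asdict(l) for l in self.lights]
        return d


@dataclass
class DegradationRecord:
    """The realized transform of one degradation, for paired supervision."""

    record_id: str
    config: dict
    homography: list[list[float]]            # clean -> degraded, 3x3
    displacement_rms_px: float
    displacement_max_px: float
    output_size: tuple[int, int]             # width, height

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def enumerate_scene_space() -> list[tuple[int, int, int]]:
    """All 352 (sheet_id, workspace_id, orientation_id) triples, lexicographic."""
    return [
        (s, w, o)
        for s in range(N_SHEETS)
        for w in range(N_WORKSPACES)
        for o in range(N_ORIENTATIONS)
    ]


def sample_scene_config(rng: np.random.Generator) -> SceneConfig:
    """Draw one scene uniformly over the discrete space, with continuous
    parameters from the documented default ranges (tilt <= 25 deg, sheet
    rotation <= 15 deg, light intensity 0.6-1.2, turbulence 0-2)."""
    azimuth = rng.uniform(0, 2 * np.pi)
    return SceneConfig(
        sheet_id=int(rng.integers(N_SHEETS)),
        workspace_id=int(rng.integers(N_WORKSPACES)),
        orientation_id=int(rng.integers(N_ORIENTATIONS)),
        sheet_translation=(float(rng.uniform(-20, 20)), float(rng.uniform(-20, 20))),
        sheet_rotation_deg=float(rng.uniform(-15, 15)),
        sheet_amplitude_px=float(rng.uniform(2, 12)),
        camera_pitch_deg=float(rng.uniform(-25, 25)),
        camera_yaw_deg=float(rng.uniform(-25, 25)),
        camera_distance=float(rng.uniform(1.05, 1.35)),
        lights=(
            LightConfig(
                direction=(float(np.cos(azimuth)), float(np.sin(azimuth))),
                intensity=float(rng.uniform(0.6, 1.2)),
                gradient_strength=float(rng.uniform(0.0, 0.25)),
                shadow_opacity=float(rng.uniform(0.0, 0.35)),
                shadow_offset=float(rng.uniform(-0.5, 0.5)),
            ),
        ),
        noise_size=float(rng.uniform(6, 32)),
        noise_turbulence=float(rng.uniform(0.0, 2.0)),
        seed=int(rng.integers(2**31 - 1)),
    )


# ---------------------------------------------------------------- geometry

def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Exact 3x3 homography from 4 point correspondences (direct linear
    transform, h33 fixed to 1)."""
    a = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i], b[2 * i + 1] = u, v
    try:
        h = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise InvalidPoseError("degenerate corner configuration") from exc
    return np.append(h, 1.0).reshape(3, 3)


def compute_homography(shape: tuple[int, int], config: SceneConfig) -> np.ndarray:
    """Forward 3x3 homography (clean px -> degraded px) for the camera pose.

    The sheet is rotated in-plane, tilted out of plane (pitch about x, yaw
    about y) and projected through a pinhole at distance ``2 * max(w, h)``;
    ``camera_distance`` 1.0 gives unit magnification at zero tilt.
    """
    h, w = shape[:2]
    if _is_identity_geometry(config):
        return np.eye(3)
    corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    centered = corners - [w / 2, h / 2]
    rot = np.deg2rad(config.sheet_rotation_deg)
    r2 = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    xy = centered @ r2.T
    pts = np.column_stack([xy, np.zeros(len(xy))])

    pitch = np.deg2rad(config.camera_pitch_deg)
    yaw = np.deg2rad(config.camera_yaw_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(pitch), -np.sin(pitch)],
                   [0, np.sin(pitch), np.cos(pitch)]])
    ry = np.array([[np.cos(yaw), 0, np.sin(yaw)],
                   [0, 1, 0],
                   [-np.sin(yaw), 0, np.cos(yaw)]])
    pts = pts @ (ry @ rx).T

    depth = 2.0 * max(w, h)
    denom = depth + pts[:, 2]
    if np.any(denom < 0.1 * depth):
        raise InvalidPoseError("sheet projects behind or through the camera")
    f = depth / config.camera_distance
    proj = f * pts[:, :2] / denom[:, None]
    center = np.array([w / 2 + config.sheet_translation[0],
                       h / 2 + config.sheet_translation[1]])

    # shrink about the sheet centre if the projection would leave the frame
    # (tiny margin absorbs round-off in the exact 4-point solve)
    margin = 0.01
    limits = np.array([w, h], dtype=float)
    scale = 1.0
    for p in proj:
        for ax in range(2):
            if p[ax] > 0:
                scale = min(scale, (limits[ax] - margin - center[ax]) / p[ax])
            elif p[ax] < 0:
                scale = min(scale, (margin - center[ax]) / p[ax])
    if scale <= 1e-3:
        raise InvalidPoseError("sheet cannot be fitted inside the frame")
    dst = proj * scale + center

    d1, d2 = dst[2] - dst[0], dst[3] - dst[1]
    area = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
    if area < 1e-3 * w * h:
        raise InvalidPoseError("sheet projects to near-zero area")
    return _dlt_homography(corners, dst)


def sheet_displacement(shape: tuple[int, int], config: SceneConfig) -> np.ndarray:
    """Smooth mesh displacement field (2, h, w) in px for the sheet template.

    Template 0 is flat; 1-7 are sags, folds, side bows, corner lifts,
    ripples, twists and a central bump, all scaled by ``sheet_amplitude_px``.
    """
    h, w = shape[:2]
    a = config.sheet_amplitude_px
    field = np.zeros((2, h, w), dtype=np.float32)
    if config.sheet_id == 0 or a == 0:
        return field
    yn, xn = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    sid = config.sheet_id
    if sid == 1:      # page sag
        field[1] = a * np.sin(np.pi * xn)
    elif sid == 2:    # S-fold
        field[1] = 0.5 * a * np.sin(2 * np.pi * xn)
    elif sid == 3:    # side bow
        field[0] = a * np.sin(np.pi * yn)
    elif sid == 4:    # corner lift
        field[1] = a * xn**2 * yn
    elif sid == 5:    # ripples
        field[1] = (a / 3.0) * np.sin(3 * np.pi * xn)
    elif sid == 6:    # twist
        field[0] = 0.5 * a * np.sin(2 * np.pi * yn)
        field[1] = 0.5 * a * np.sin(2 * np.pi * xn)
    elif sid == 7:    # central bump
        r2 = (xn - 0.5) ** 2 + (yn - 0.5) ** 2
        bump = np.exp(-8.0 * r2)
        field[0] = a * (xn - 0.5) * bump
        field[1] = a * (yn - 0.5) * bump
    return field


def _is_identity_geometry(config: SceneConfig) -> bool:
    return (
        config.camera_pitch_deg == 0 and config.camera_yaw_deg == 0
        and config.camera_distance == 1.0 and config.sheet_rotation_deg == 0
        and config.sheet_translation == (0.0, 0.0)
        and (config.sheet_id == 0 or config.sheet_amplitude_px == 0)
    )


def warp_sheet(
    image: np.ndarray, config: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warp a clean render into camera view.

    Returns (RGBA image, forward homography, displacement field).  Pixels
    outside the projected sheet have alpha 0.  The forward transform is the
    homography applied after the in-plane mesh displacement.
    """
    h, w = image.shape[:2]
    homography = compute_homography(image.shape, config)
    disp = sheet_displacement(image.shape, config)
    rgba = np.dstack([image, np.full((h, w), 255, dtype=np.uint8)])
    if _is_identity_geometry(config):
        return rgba, homography, disp

    h_inv = np.linalg.inv(homography)
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    denom = h_inv[2, 0] * xx + h_inv[2, 1] * yy + h_inv[2, 2]
    sx = (h_inv[0, 0] * xx + h_inv[0, 1] * yy + h_inv[0, 2]) / denom
    sy = (h_inv[1, 0] * xx + h_inv[1, 1] * yy + h_inv[1, 2]) / denom
    if np.any(disp):
        # first-order inversion of the small smooth displacement
        ix = np.clip(sy, 0, h - 1).astype(int), np.clip(sx, 0, w - 1).astype(int)
        sx = sx - disp[0][ix]
        sy = sy - disp[1][ix]
    coords = np.stack([sy, sx])
    out = np.empty_like(rgba)
    for c in range(4):
        out[..., c] = ndimage.map_coordinates(
            rgba[..., c].astype(np.float32), coords, order=1, mode="constant", cval=0.0,
        ).round().astype(np.uint8)
    return out, homography, disp


# ------------------------------------------------------------- appearance

def _value_noise(shape: tuple[int, int], cell: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothly interpolated lattice noise in [0, 1] with ~``cell`` px features."""
    h, w = shape
    gh, gw = int(np.ceil(h / cell)) + 2, int(np.ceil(w / cell)) + 2
    lattice = rng.random((gh, gw))
    yy, xx = np.meshgrid(np.arange(h) / cell, np.arange(w) / cell, indexing="ij")
    y0, x0 = yy.astype(int), xx.astype(int)
    fy, fx = yy - y0, xx - x0
    fy = fy * fy * (3 - 2 * fy)          # smoothstep
    fx = fx * fx * (3 - 2 * fx)
    v00 = lattice[y0, x0]
    v10 = lattice[y0 + 1, x0]
    v01 = lattice[y0, x0 + 1]
    v11 = lattice[y0 + 1, x0 + 1]
    return (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy + v11 * fx * fy)


def turbulence_field(
    shape: tuple[int, int], size: float, rng: np.random.Generator, octaves: int = 4,
) -> np.ndarray:
    """Multi-octave value-noise turbulence in [-1, 1] at spatial scale ``size``.

    The field is synthesized at half resolution and bilinearly upsampled;
    value noise is smooth at the octave cells used, so this changes nothing
    visible while halving the cost.
    """
    h, w = shape
    hs, ws = (h + 1) // 2, (w + 1) // 2
    total = np.zeros((hs, ws), dtype=np.float64)
    norm = 0.0
    for k in range(octaves):
        cell = max(size / 2 / 2**k, 1.5)
        amp = 0.5**k
        total += amp * _value_noise((hs, ws), cell, rng)
        norm += amp
    total = 2.0 * (total / norm) - 1.0
    return ndimage.zoom(total, (h / hs, w / ws), order=1, grid_mode=True, mode="nearest")


# base RGB and pattern family for the 11 workspace backgrounds
_WORKSPACES = [
    ((168, 116, 66), "wood"), ((190, 190, 195), "plain"), ((70, 92, 130), "fabric"),
    ((120, 84, 52), "wood"), ((220, 218, 210), "plain"), ((96, 120, 96), "fabric"),
    ((140, 100, 70), "wood"), ((60, 60, 65), "plain"), ((150, 130, 170), "fabric"),
    ((200, 170, 130), "wood"), ((245, 245, 245), "plain"),
]


def make_workspace_background(
    shape: tuple[int, int], workspace_id: int, orientation_id: int, seed: int,
) -> np.ndarray:
    """Procedural background texture, rotated by ``orientation_id`` * 90 deg."""
    h, w = shape
    side = max(h, w)
    rng = np.random.default_rng(
        (zlib.crc32(f"workspace/{workspace_id}".encode()) + seed) % 2**32
    )
    base, kind = _WORKSPACES[workspace_id]
    noise = turbulence_field((side, side), 24.0, rng, octaves=3)
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    if kind == "wood":
        pattern = 0.5 * np.sin(xx / 9.0 + 4.0 * noise) + 0.5 * noise
    elif kind == "fabric":
        pattern = 0.25 * (np.sin(xx / 3.0) + np.sin(yy / 3.0)) + 0.5 * noise
    else:
        pattern = 0.6 * noise
    tex = np.asarray(base, dtype=np.float64) * (1.0 + 0.18 * pattern[..., None])
    tex = np.rot90(tex, k=orientation_id, axes=(0, 1))
    tex = tex[:h, :w]
    return np.clip(np.rint(tex), 0, 255).astype(np.uint8)


def composite_workspace(sheet_rgba: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Alpha-composite the warped sheet over its workspace background."""
    h, w = sheet_rgba.shape[:2]
    alpha = sheet_rgba[..., 3:4].astype(np.float32) / 255.0
    if np.all(alpha == 1.0):
        return sheet_rgba[..., :3].copy()
    bg = make_workspace_background(
        (h, w), config.workspace_id, config.orientation_id, config.seed
    )
    out = sheet_rgba[..., :3].astype(np.float32) * alpha + bg.astype(np.float32) * (1 - alpha)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_lighting(image: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Directional illumination gradients plus an optional soft shadow band.

    The gain field is the mean over lights of
    ``intensity + gradient_strength * <projection on light direction>``;
    mean brightness is monotone in intensity, and a light at intensity 1
    with zero gradient and shadow leaves the image untouched.
    """
    lights = config.lights
    if all(l.intensity == 1.0 and l.gradient_strength == 0.0
           and l.shadow_opacity == 0.0 for l in lights):
        return image.copy()
    h, w = image.shape[:2]
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    px = (xx - w / 2) / (w / 2)
    py = (yy - h / 2) / (h / 2)
    gain = np.zeros((h, w), dtype=np.float32)
    shade = np.ones((h, w), dtype=np.float32)
    for l in lights:
        dx, dy = l.direction
        proj = px * dx + py * dy
        gain += l.intensity + l.gradient_strength * proj
        if l.shadow_opacity > 0:
            s = (proj - l.shadow_offset) / 0.08    # soft-edged half-plane
            mask = 1.0 / (1.0 + np.exp(-s))
            shade *= 1.0 - l.shadow_opacity * mask
    gain = np.clip(gain / len(lights), 0.0, 2.0) * shade
    out = image.astype(np.float32) * gain[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_stucci_noise(
    image: np.ndarray, noise_size: float, noise_turbulence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stucci-style texture: turbulence modulates intensity and displaces
    pixels sub-pixel-wise, producing stucco-like holes and bumps.

    Zero turbulence is the identity; for fixed seed the perturbation scale
    grows with turbulence.
    """
    if noise_size <= 0:
        raise ValueError("noise_size must be positive")
    if noise_turbulence < 0:
        raise ValueError("noise_turbulence must be non-negative")
    if noise_turbulence == 0:
        return image.copy()
    h, w = image.shape[:2]
    t_int = turbulence_field((h, w), noise_size, rng)
    t_dx = turbulence_field((h, w), noise_size, rng)
    t_dy = turbulence_field((h, w), noise_size, rng)
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    coords = np.stack([
        np.clip(yy + 1.2 * noise_turbulence * t_dy, 0, h - 1),
        np.clip(xx + 1.2 * noise_turbulence * t_dx, 0, w - 1),
    ])
    out = np.empty_like(image, dtype=np.float32)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            image[..., c].astype(np.float32), coords, order=1, mode="nearest"
        )
    out *= (1.0 + 0.12 * noise_turbulence * t_int)[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def degrade_image(
    clean_image: np.ndarray, manifest, config: SceneConfig,
) -> tuple[np.ndarray, DegradationRecord]:
    """Full degradation: warp -> composite -> lighting -> stucci noise.

    Deterministic per config (the config's own seed drives all stochastic
    texture).  Returns the degraded image and a :class:`DegradationRecord`
    linking it back to the clean render.
    """
    rgba, homography, disp = warp_sheet(clean_image, config)
    img = composite_workspace(rgba, config)
    img = apply_lighting(img, config)
    rng = np.random.default_rng(config.seed)
    img = apply_stucci_noise(img, config.noise_size, config.noise_turbulence, rng)
    mag = np.hypot(disp[0], disp[1])
    record = DegradationRecord(
        record_id=getattr(manifest, "record_id", ""),
        config=config.as_dict(),
        homography=homography.tolist(),
        displacement_rms_px=float(np.sqrt(np.mean(mag**2))),
        displacement_max_px=float(mag.max()),
        output_size=(img.shape[1], img.shape[0]),
    )
    return img, record
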