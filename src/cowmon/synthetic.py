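"""Parametric synthetic depth scenes with known ground truth.

The generator emulates the farm capture rig: a downward-looking depth
camera over a walkway, a static background (floor plus side walls) and a
cow-back surface translated along the walkway frame by frame.  Every
downstream stage (segmentation, curvedness, rolling-ball angularity,
spine fitting, volume integration) can therefore be tested against an
analytic ground truth without farm data.

Cow-back surface model
----------------------
The back is a superellipsoid cap over an elliptical footprint, raised on
a "base" so its flanks drop steeply the way a cow's sides do:

    s(x, y)   = |x / (L/2)|**e + |y / (W/2)|**e
    body(x,y) = H * (f + (1 - f) * (1 - s)**(1/e))      for s < 1

with length ``L``, width ``W``, maximum height ``H``, cap exponent ``e``
(2 = half-ellipsoid, large = slab) and base fraction ``f``.  Along the
central portion of the midline, the spine ridge forces the centreline
height to follow an exact metric parabola

    z(x) = H + p + a x**2 + b x

(prominence ``p`` = ``spine_prominence``, ``a`` = ``spine_arch_a``,
``b`` = ``spine_skew_b``); the ridge falls off as a Gaussian across the
body.  An arched (hunched) spine has ``a < 0``; a sound, slightly dipped
topline has ``a > 0``.  Hook, pin and vertebral protrusions are additive
Gaussian bumps whose amplitude grows and width shrinks with
``bump_sharpness``, so the rolling-ball angularity of the surface is
monotone in that single knob.

Rendering is perspective-consistent with the pinhole field-of-view model
used for metric rescaling: surface points are projected through the
camera and the per-pixel minimum depth is kept.  Gaussian depth noise
and missing-pixel dropout are applied last under seed control.  Default
shape parameters keep surface slopes below the ray-tangency limit, so
the whole back is visible from the camera and its volume is actually
recoverable from a single frame.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .depthio import (
    CameraGeometry,
    DepthFrame,
    SessionManifest,
    save_manifest,
    write_depth_frame,
)
from .errors import ValidationError

__all__ = [
    "CowShapeParams",
    "SceneParams",
    "generate_background",
    "generate_cow_frame",
    "generate_walk_sequence",
    "analytic_cow_volume",
    "write_session",
]


@dataclass(frozen=True)
class CowShapeParams:
    """Ground-truth shape of a synthetic cow back.

    Lengths in millimetres.  The default body is deliberately compact so
    the whole back fits inside the camera's field of view at back height
    (a full-size animal is only ever partially visible to an overhead
    camera at 2.3 m, which is fine for the pipeline but useless for
    volume ground-truth checks).
    """

    body_length: float = 950.0
    body_width: float = 520.0
    body_height: float = 1300.0
    #: Vertical-plane quadratic coefficient of the spine centreline (1/mm).
    #: Negative = arched (lame-looking), positive = dipped (sound topline).
    #: The default is a sound walking dip; note a scales as 1/length^2, so
    #: values on this compact fixture body are several times a full-size
    #: animal's.
    spine_arch_a: float = 7e-4
    spine_skew_b: float = 0.0
    #: Dimensionless >= 0; 0 gives a smooth back, larger values give
    #: sharper, taller hook/pin/vertebra protrusions (leaner animal).
    bump_sharpness: float = 1.0
    noise_sd: float = 3.0
    dropout_rate: float = 0.01
    seed: int = 0
    # --- secondary shape knobs -------------------------------------------
    cap_exponent: float = 2.0
    base_frac: float = 0.95
    spine_prominence: float = 30.0
    spine_sigma: float = 55.0
    #: Fraction of the half-length covered by the spine ridge; 1.0 runs
    #: the ridge out to the body ends (no interior cliff).
    ridge_frac: float = 1.0
    bump_base_amp: float = 8.0
    bump_base_sigma: float = 45.0

    def __post_init__(self) -> None:
        for name in ("body_length", "body_width", "body_height"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.bump_sharpness < 0:
            raise ValidationError("bump_sharpness must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.base_frac < 1:
            raise ValidationError("base_frac must be in [0, 1)")
        if not self.cap_exponent > 0:
            raise ValidationError("cap_exponent must be positive")

    def bump_sites(self) -> list[tuple[float, float, float, float]]:
        """(x, y, amplitude, sigma) of each protrusion in cow-local mm.

        Hooks sit wide at the rear, pins narrower and further back,
        plus three vertebral knobs along the midline.  The rear of the
        cow is on the -x side (it walks towards +x).
        """
        s = self.bump_sharpness
        if s == 0 or self.bump_base_amp == 0:
            return []
        a_len = self.body_length / 2.0
        b_wid = self.body_width / 2.0
        amp = self.bump_base_amp * s
        sig = self.bump_base_sigma / math.sqrt(1.0 + s)
        sites = [
            (-0.55 * a_len, +0.72 * b_wid, amp, sig),      # hooks
            (-0.55 * a_len, -0.72 * b_wid, amp, sig),
            (-0.85 * a_len, +0.32 * b_wid, amp, sig),      # pins
            (-0.85 * a_len, -0.32 * b_wid, amp, sig),
            (-0.40 * a_len, 0.0, 0.6 * amp, sig),          # vertebral knobs
            (0.0, 0.0, 0.6 * amp, sig),
            (+0.40 * a_len, 0.0, 0.6 * amp, sig),
        ]
        return sites


@dataclass(frozen=True)
class SceneParams:
    """Static scene: camera geometry, image raster, floor and side walls.

    The walls run along the walkway (the image x / column axis) and
    occupy ``wall_rows`` rows at the top and bottom of the frame.
    """

    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    shape: tuple[int, int] = (480, 640)
    floor_depth: float | None = None  # mm; default = camera mount height
    wall_depth: float | None = 1800.0
    wall_rows: int = 24

    def __post_init__(self) -> None:
        nr, nc = self.shape
        if nr < 1 or nc < 1:
            raise ValidationError("scene shape must be non-empty")
        if self.floor_depth is None:
            object.__setattr__(self, "floor_depth", self.geometry.floor_depth_mm)
        if not self.floor_depth > 0:
            raise ValidationError("floor_depth must be positive")

    def pixel_rays(self, rows=None, cols=None):
        """Per-pixel ray coefficients (kx*u, ky*v): ground mm per mm of depth."""
        nr, nc = self.shape
        if rows is None:
            rows = np.arange(nr)
        if cols is None:
            cols = np.arange(nc)
        kx = 2.0 * math.tan(math.radians(self.geometry.theta_horz_deg) / 2.0) / nc
        ky = 2.0 * math.tan(math.radians(self.geometry.theta_vert_deg) / 2.0) / nr
        u = (np.asarray(cols, dtype=np.float64) - (nc - 1) / 2.0) * kx
        v = (np.asarray(rows, dtype=np.float64) - (nr - 1) / 2.0) * ky
        return u, v


def elevation_field(
    cow: CowShapeParams, x, y, position_x: float = 0.0, position_y: float = 0.0
) -> np.ndarray:
    """Noiseless cow-back elevation above the floor (mm) at ground coords (x, y).

    ``x`` runs along the walkway.  Zero outside the body footprint.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xl = x - position_x
    yl = y - position_y
    a_len = cow.body_length / 2.0
    b_wid = cow.body_width / 2.0
    e = cow.cap_exponent
    if np.isinf(e):
        inside = (np.abs(xl) <= a_len) & (np.abs(yl) <= b_wid)
        cap = inside.astype(np.float64)
        cap_mid = (np.abs(xl) <= a_len).astype(np.float64)
    else:
        s = np.abs(xl / a_len) ** e + np.abs(yl / b_wid) ** e
        inside = s < 1.0
        cap = np.where(inside, np.clip(1.0 - s, 0.0, None) ** (1.0 / e), 0.0)
        s_mid = np.abs(xl / a_len) ** e
        cap_mid = np.where(s_mid < 1.0, np.clip(1.0 - s_mid, 0.0, None) ** (1.0 / e), 0.0)

    f = cow.base_frac
    body = cow.body_height * (f + (1.0 - f) * cap)
    elev = np.where(inside, body, 0.0)

    # Spine ridge: forces the midline to the exact parabola H + p + a x^2 + b x
    # over the central ridge span, with a Gaussian cross-profile.
    if cow.spine_prominence > 0:
        span = cow.ridge_frac * a_len
        in_span = np.abs(xl) <= span
        spine_line = (
            cow.body_height
            + cow.spine_prominence
            + cow.spine_arch_a * xl**2
            + cow.spine_skew_b * xl
        )
        body_mid = cow.body_height * (f + (1.0 - f) * cap_mid)
        ridge_amp = np.clip(spine_line - body_mid, 0.0, None)
        profile = np.exp(-(yl**2) / (2.0 * cow.spine_sigma**2))
        elev = elev + np.where(inside & in_span, ridge_amp * profile, 0.0)

    for bx, by, amp, sig in cow.bump_sites():
        bump = amp * np.exp(-(((xl - bx) ** 2) + (yl - by) ** 2) / (2.0 * sig**2))
        elev = elev + np.where(inside, bump, 0.0)
    return elev


def generate_background(scene: SceneParams) -> DepthFrame:
    """Depth frame of the empty scene: floor plus side-wall bands. Deterministic."""
    nr, nc = scene.shape
    depth = np.full((nr, nc), float(scene.floor_depth))
    if scene.wall_depth is not None and scene.wall_rows > 0:
        w = min(scene.wall_rows, nr)
        depth[:w, :] = scene.wall_depth
        depth[nr - w :, :] = scene.wall_depth
    return DepthFrame(depth=depth, frame_index=0)


def _max_elevation(cow: CowShapeParams) -> float:
    extra = max(0.0, cow.spine_arch_a) * (cow.ridge_frac * cow.body_length / 2.0) ** 2
    extra += abs(cow.spine_skew_b) * cow.ridge_frac * cow.body_length / 2.0
    bump = cow.bump_base_amp * cow.bump_sharpness
    return cow.body_height + cow.spine_prominence + extra + bump


def _render_cow_depth(scene: SceneParams, cow: CowShapeParams,
                      position_x: float, position_y: float) -> np.ndarray:
    """Perspective render of the cow surface: full-frame depth overlay.

    The noiseless elevation field is sampled on a fine metric grid (a few
    samples per pixel), each surface point is projected through the
    pinhole field-of-view model onto the raster, and the per-pixel
    minimum depth is kept.  For this camera-above geometry (the outward
    flanks are never visible from the centre mount) the splatted minimum
    is the first ray-surface intersection.  Pixels the body does not
    cover keep the floor depth.
    """
    nr, nc = scene.shape
    floor = float(scene.floor_depth)
    d_top = floor - _max_elevation(cow)
    if d_top <= 0:
        raise ValidationError("cow is taller than the camera mount")
    kx = 2.0 * math.tan(math.radians(scene.geometry.theta_horz_deg) / 2.0) / nc
    ky = 2.0 * math.tan(math.radians(scene.geometry.theta_vert_deg) / 2.0) / nr
    spacing = max(0.5, d_top * min(kx, ky) / 3.0)
    pad = 3.0 * cow.bump_base_sigma
    xs = np.arange(position_x - cow.body_length / 2 - pad,
                   position_x + cow.body_length / 2 + pad, spacing)
    ys = np.arange(position_y - cow.body_width / 2 - pad,
                   position_y + cow.body_width / 2 + pad, spacing)
    depth = np.full(nr * nc, floor)
    if xs.size == 0 or ys.size == 0:
        return depth.reshape(nr, nc)
    e = elevation_field(cow, xs[None, :], ys[:, None], position_x, position_y)
    yy, xx = np.nonzero(e > 0)
    if xx.size == 0:
        return depth.reshape(nr, nc)
    d_pt = floor - e[yy, xx]
    col = np.rint(xs[xx] / (d_pt * kx) + (nc - 1) / 2.0).astype(np.int64)
    row = np.rint(ys[yy] / (d_pt * ky) + (nr - 1) / 2.0).astype(np.int64)
    ok = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
    np.minimum.at(depth, row[ok] * nc + col[ok], d_pt[ok])
    return depth.reshape(nr, nc)


def generate_cow_frame(
    scene: SceneParams,
    cow: CowShapeParams,
    position_x: float = 0.0,
    position_y: float = 0.0,
    frame_index: int = 0,
    rng: np.random.Generator | None = None,
    extra_cows: tuple[tuple[CowShapeParams, float, float], ...] = (),
) -> DepthFrame:
    """Composite the cow onto the background at walkway position ``position_x`` (mm).

    Noise and dropout are applied to the whole frame, last, under seed
    control (``rng`` if given, else a generator seeded from ``cow.seed``).
    ``extra_cows`` allows a trailing animal for bunching fixtures.
    """
    _, fov_h = scene.geometry.fov_mm(scene.floor_depth - cow.body_height)
    if cow.body_width > fov_h:
        raise ValidationError(
            f"cow width {cow.body_width} mm exceeds the walkway FOV ({fov_h:.0f} mm)"
        )
    bg = generate_background(scene)
    depth = bg.depth.copy()
    for c, px, py in ((cow, position_x, position_y), *extra_cows):
        overlay = _render_cow_depth(scene, c, px, py)
        depth = np.minimum(depth, overlay)
    if cow.noise_sd > 0 or cow.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(cow.seed)
        if cow.noise_sd > 0:
            depth = depth + rng.normal(0.0, cow.noise_sd, size=depth.shape)
            np.clip(depth, 0.0, None, out=depth)
        if cow.dropout_rate > 0:
            drop = rng.random(depth.shape) < cow.dropout_rate
            depth[drop] = np.nan
    return DepthFrame(depth=depth, frame_index=frame_index)


def generate_walk_sequence(
    scene: SceneParams,
    cow: CowShapeParams,
    n_frames: int,
    step_mm: float,
    start_x: float | None = None,
    bunching: bool = False,
) -> list[DepthFrame]:
    """Render ``n_frames`` frames with the cow translated ``step_mm`` per frame.

    ``step_mm = 0`` gives a stationary sequence (for motion-gating tests).
    By default the trajectory is centred so the cow crosses the middle of
    the field of view mid-sequence.  With ``bunching=True`` a second,
    identical cow trails close behind, overlapping the imaged animal.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if start_x is None:
        start_x = -step_mm * (n_frames - 1) / 2.0
    rng = np.random.default_rng(cow.seed)
    frames = []
    for i in range(n_frames):
        px = start_x + i * step_mm
        extra = ()
        if bunching:
            extra = ((cow, px - 0.95 * cow.body_length, 0.0),)
        frames.append(
            generate_cow_frame(
                scene, cow, position_x=px, frame_index=i, rng=rng, extra_cows=extra
            )
        )
    return frames


def analytic_cow_volume(
    cow: CowShapeParams, floor_depth: float | None = None, spacing: float = 0.4
) -> float:
    """Ground-truth volume (m^3) of the solid between the noiseless back
    surface and the floor, by midpoint quadrature on a fine metric grid.

    ``spacing`` is the quadrature step in mm (default 0.4 mm, at least
    four times finer than the rendered pixel pitch).  ``floor_depth`` is accepted for
    interface symmetry; the elevation field does not depend on it.
    Deterministic.
    """
    del floor_depth
    pad = 3.0 * cow.bump_base_sigma + spacing
    a_len = cow.body_length / 2.0 + pad
    b_wid = cow.body_width / 2.0 + pad
    xs = np.arange(-a_len, a_len + spacing, spacing)
    ys = np.arange(-b_wid, b_wid + spacing, spacing)
    total = 0.0
    # Integrate in row blocks to bound memory.
    block = max(1, int(4e6 // xs.size))
    for i in range(0, ys.size, block):
        yy = ys[i : i + block]
        e = elevation_field(cow, xs[None, :], yy[:, None])
        total += float(e.sum())
    return total * spacing * spacing * 1e-9


def write_session(
    out_dir,
    scene: SceneParams,
    cow: CowShapeParams,
    n_frames: int,
    step_mm: float,
    cow_id: str = "cow-001",
    start_x: float | None = None,
    bunching: bool = False,
) -> SessionManifest:
    """Simulate a session and write it to ``out_dir``.

    Layout: ``background.png``, ``frames/NNNN.png``, ``manifest.txt`` and a
    ``ground_truth.json`` sidecar with the generating parameters, analytic
    volume and spine coefficients.
    """
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    write_depth_frame(generate_background(scene), out_dir / "background.png")
    frames = generate_walk_sequence(scene, cow, n_frames, step_mm, start_x, bunching)
    paths = []
    for i, fr in enumerate(frames):
        p = out_dir / "frames" / f"{i:04d}.png"
        write_depth_frame(fr, p)
        paths.append(p)
    manifest = SessionManifest(cow_id=cow_id, frame_paths=paths, dialect="png16mm")
    save_manifest(manifest, out_dir / "manifest.txt")
    truth = {
        "cow_id": cow_id,
        "params": {k: (None if v is None else v) for k, v in asdict(cow).items()},
        "scene": {
            "shape": list(scene.shape),
            "floor_depth": scene.floor_depth,
            "mount_height_m": scene.geometry.mount_height_m,
        },
        "analytic_volume_m3": analytic_cow_volume(cow),
        "spine": {"a": cow.spine_arch_a, "b": cow.spine_skew_b},
        "step_mm": step_mm,
        "n_frames": n_frames,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest
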