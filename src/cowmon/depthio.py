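"""Reading and writing of overhead depth frames and session manifests.

A depth frame is a rectangular grid of distances from the camera in
millimetres.  Two on-disk dialects are supported:

``png16mm``
    16-bit grayscale PNG, 1 unit = 1 mm, pixel value 0 reserved for
    missing data.  This matches Kinect-class sensors and keeps files
    viewable with standard tools.
``array``
    NumPy ``.npy`` float array with NaN marking missing pixels; lossless
    for non-integer data.

In memory, missing pixels are always NaN in a float64 array.

The camera geometry (mount height and lens angles) lives here too; the
physical field of view at a distance ``d`` from the camera is

    w = 2 d tan(theta_horz / 2),    h = 2 d tan(theta_vert / 2)

which is what converts pixel coordinates into millimetres downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, RangeError, ValidationError

__all__ = [
    "MISSING",
    "CameraGeometry",
    "DepthFrame",
    "SessionManifest",
    "read_depth_frame",
    "write_depth_frame",
    "load_manifest",
    "save_manifest",
]

#: In-memory missing-value code (the png16mm dialect stores it as pixel value 0).
MISSING = np.nan

_DIALECTS = ("png16mm", "array")

#: Default capture rate (frames per second) when timestamps are absent.
DEFAULT_FPS = 30.0


@dataclass(frozen=True)
class CameraGeometry:
    """Overhead camera mounting and lens parameters.

    Parameters
    ----------
    mount_height_m : float
        Height of the camera above the floor, metres.
    theta_horz_deg, theta_vert_deg : float
        Horizontal / vertical lens opening angles in degrees.  The
        defaults (58 and 45 degrees) are typical of Kinect-class depth
        cameras and give a ~2.5 m horizontal field of view from a 2.3 m
        mount.
    """

    mount_height_m: float = 2.3
    theta_horz_deg: float = 58.0
    theta_vert_deg: float = 45.0

    def __post_init__(self) -> None:
        if not self.mount_height_m > 0:
            raise ValidationError("mount_height_m must be positive")
        for name in ("theta_horz_deg", "theta_vert_deg"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValidationError(f"{name} must be in (0, 180), got {v}")

    @property
    def floor_depth_mm(self) -> float:
        """Distance from the camera to the floor, millimetres."""
        return self.mount_height_m * 1000.0

    def fov_mm(self, depth_mm):
        """Width and height (mm) of the field of view at distance ``depth_mm``."""
        w = 2.0 * depth_mm * math.tan(math.radians(self.theta_horz_deg) / 2.0)
        h = 2.0 * depth_mm * math.tan(math.radians(self.theta_vert_deg) / 2.0)
        return w, h


@dataclass
class DepthFrame:
    """One depth image: per-pixel distance from the camera in millimetres.

    ``depth`` is float64 with NaN for missing pixels; all non-missing
    values must be non-negative.
    """

    depth: np.ndarray
    frame_index: int = 0
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2 or self.depth.size == 0:
            raise ValidationError("depth grid must be 2-D and non-empty")
        finite = self.depth[np.isfinite(self.depth)]
        if finite.size and finite.min() < 0:
            raise ValidationError("non-missing depths must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.depth)


@dataclass
class SessionManifest:
    """One cow passage: an identifier plus an ordered list of frame files."""

    cow_id: str
    frame_paths: list[Path] = field(default_factory=list)
    dialect: str = "png16mm"

    def __post_init__(self) -> None:
        if not self.cow_id:
            raise ValidationError("manifest requires a cow_id")
        if len(self.frame_paths) < 1:
            raise ValidationError("manifest requires at least one frame")
        if self.dialect not in _DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        self.frame_paths = [Path(p) for p in self.frame_paths]

    def __len__(self) -> int:
        return len(self.frame_paths)


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def read_depth_frame(path, dialect: str = "png16mm", frame_index: int = 0) -> DepthFrame:
    """Read a depth frame from ``path``.

    For ``png16mm`` the file must be a single-channel 16-bit PNG; pixel
    value 0 maps to the missing code.  For ``array`` it must be a ``.npy``
    float array (NaN = missing).
    """
    _check_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "png16mm":
        try:
            raw = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"cannot read PNG {path}: {exc}") from exc
        if raw.dtype != np.uint16:
            raise FormatError(
                f"{path}: expected 16-bit grayscale PNG, got dtype {raw.dtype}"
            )
        if raw.ndim != 2:
            raise FormatError(f"{path}: expected single-channel image")
        depth = raw.astype(np.float64)
        depth[raw == 0] = MISSING
    else:
        try:
            depth = np.load(path, allow_pickle=False)
        except Exception as exc:
            raise FormatError(f"cannot read array file {path}: {exc}") from exc
        depth = np.asarray(depth, dtype=np.float64)
    return DepthFrame(depth=depth, frame_index=frame_index)


def write_depth_frame(frame: DepthFrame, path, dialect: str = "png16mm") -> None:
    """Write ``frame`` to ``path`` so that :func:`read_depth_frame` recovers it.

    png16mm rounds to integer millimetres; depths above 65535 mm raise a
    :class:`~cowmon.errors.RangeError` because they are not representable
    in 16 bits.
    """
    _check_dialect(dialect)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "png16mm":
        depth = frame.depth
        finite = depth[np.isfinite(depth)]
        if finite.size and finite.max() > 65535:
            raise RangeError(
                f"depth {finite.max():.0f} mm exceeds the 16-bit png16mm limit (65535 mm)"
            )
        coded = np.where(np.isfinite(depth), np.rint(depth), 0.0)
        iio.imwrite(path, coded.astype(np.uint16), extension=".png")
    else:
        np.save(path, frame.depth, allow_pickle=False)


def load_manifest(path) -> SessionManifest:
    """Parse a plain-text session manifest.

    Format: ``key: value`` lines for ``cow_id`` and optional ``dialect``,
    plus one ``frame: <relative path>`` line per frame, order preserved.
    Frame paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cow_id = None
    dialect = "png16mm"
    frames: list[Path] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "cow_id":
            cow_id = value
        elif key == "dialect":
            dialect = value
        elif key == "frame":
            frames.append(path.parent / value)
        else:
            raise ValidationError(f"{path}:{lineno}: unknown manifest key {key!r}")
    if cow_id is None:
        raise ValidationError(f"{path}: manifest is missing a cow_id")
    return SessionManifest(cow_id=cow_id, frame_paths=frames, dialect=dialect)


def save_manifest(manifest: SessionManifest, path) -> None:
    """Write ``manifest`` as plain text; frame paths stored relative to ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"cow_id: {manifest.cow_id}", f"dialect: {manifest.dialect}"]
    for p in manifest.frame_paths:
        try:
            rel = Path(p).relative_to(path.parent)
        except ValueError:
            rel = Path(p)
        lines.append(f"frame: {rel.as_posix()}")
    path.write_text("\n".join(lines) + "\n")


def load_session_frames(manifest: SessionManifest) -> list[DepthFrame]:
    """Read every frame listed in ``manifest``, in order."""
    return [
        read_depth_frame(p, dialect=manifest.dialect, frame_index=i)
        for i, p in enumerate(manifest.frame_paths)
    ]
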