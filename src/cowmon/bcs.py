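"""Body condition from rolling-ball angularity.

A grayscale morphological opening (erosion then dilation) with a
hemispherical structuring element is the digital analogue of rolling a
ball under the 3D back surface: the ball follows smooth, well-conditioned
flesh but cannot enter sharp bony protrusions (hooks, pins, vertebrae).
The mean positive residual between the surface and its opening -- the
material the ball could not reach -- is the angularity score: larger
means bonier, i.e. leaner.  A farm-specific linear calibration maps
angularity onto the 1-5 body condition scale (higher angularity, lower
condition, so the slope is negative by construction).

Numerical note: heights and the ball profile are quantised to 1/1024 mm
inside the opening so that the morphological identities (anti-extensivity
and idempotence) hold *exactly* in floating point; the quantisation is
three orders of magnitude below sensor noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, DegenerateInputError, ValidationError

__all__ = [
    "BallParams",
    "AngularityScore",
    "BcsCalibration",
    "rolling_ball_open",
    "angularity",
    "score_surface",
    "angularity_sweep",
    "fit_calibration",
    "predict_bcs",
]

_Q = 1024.0  # height quantum = 1/1024 (exact in binary floating point)
_BIG = float(2**30)  # out-of-mask sentinel; never constrains the ball


def _quantize(a: np.ndarray) -> np.ndarray:
    return np.round(a * _Q) / _Q


@dataclass(frozen=True)
class BallParams:
    """Rolling-ball structuring element.

    ``diameter_px`` is the ball diameter on the pixel grid (the default
    70 px discriminates well across the common condition range).  The
    structuring element is always odd-sized and at least 3 px.
    ``z_scale`` converts the ball's vertical profile into height units
    (mm per px); 1.0 applies the ball directly on the pixel grid, while
    passing the metric pixel pitch gives a physically spherical ball.
    """

    diameter_px: int = 70
    z_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_px < 2:
            raise ValidationError("ball diameter must be >= 2 px")
        if not self.z_scale > 0:
            raise ValidationError("z_scale must be positive")

    @property
    def radius_px(self) -> int:
        return self.diameter_px // 2

    def structure(self):
        """(heights, footprint) of the hemispherical structuring element."""
        r = self.radius_px
        ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
        rho2 = ii**2 + jj**2
        footprint = rho2 <= r**2
        heights = np.zeros_like(rho2, dtype=np.float64)
        heights[footprint] = np.sqrt(r**2 - rho2[footprint]) * self.z_scale
        return _quantize(heights), footprint


@dataclass
class AngularityScore:
    """Scalar angularity (mean positive opening residual, mm) plus the
    per-pixel residual map (NaN outside the mask)."""

    value: float
    residual_map: np.ndarray


@dataclass(frozen=True)
class BcsCalibration:
    """Linear angularity -> BCS map: ``bcs = slope * angularity + intercept``.

    Increased angularity means reduced condition, so ``slope < 0``.
    Predictions are clamped to the scoring range (1 = emaciated,
    5 = very obese).
    """

    slope: float
    intercept: float
    bcs_min: float = 1.0
    bcs_max: float = 5.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise CalibrationError(
                f"calibration slope must be negative (got {self.slope}); "
                "angularity rises as condition falls"
            )


def rolling_ball_open(
    height_map: np.ndarray, mask: np.ndarray | None = None,
    ball: BallParams | None = None,
) -> np.ndarray:
    """Grayscale opening of ``height_map`` with a hemispherical ball.

    Outside-mask pixels never constrain the ball (they are treated as
    unboundedly high), so the opening is evaluated on the cow surface
    alone.  The result is anti-extensive (``opened <= original``
    everywhere inside the mask, exactly) and idempotent (exactly).
    Returns the full-size opened map with original values outside the
    mask.  Raises when the ball footprint exceeds the mask bounding box.
    """
    if ball is None:
        ball = BallParams()
    h = np.asarray(height_map, dtype=np.float64)
    if mask is None:
        mask = np.isfinite(h)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(h)
    if not mask.any():
        raise DegenerateInputError("rolling_ball_open requires a non-empty mask")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    size = 2 * ball.radius_px + 1
    if rows[-1] - rows[0] + 1 < size or cols[-1] - cols[0] + 1 < size:
        raise DegenerateInputError(
            f"ball ({size} px) larger than the mask bounding box"
        )
    s, fp = ball.structure()
    pad = size
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = np.full((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), _BIG)
    sub_m = mask[r0:r1, c0:c1]
    sub_h = _quantize(np.where(sub_m, h[r0:r1, c0:c1], _BIG))
    crop[pad:-pad, pad:-pad] = np.where(sub_m, sub_h, _BIG)
    eroded = ndimage.grey_erosion(crop, structure=s, footprint=fp, mode="constant", cval=_BIG)
    opened = ndimage.grey_dilation(eroded, structure=s, footprint=fp, mode="constant", cval=-_BIG)
    out = _quantize(np.where(np.isfinite(h), h, np.nan))
    region = out[r0:r1, c0:c1]
    region[sub_m] = opened[pad:-pad, pad:-pad][sub_m]
    return out


def angularity(
    height_map: np.ndarray, opened: np.ndarray, mask: np.ndarray
) -> AngularityScore:
    """Reduce an opening residual to a scalar angularity.

    The residual map is ``original - opened`` (non-negative inside the
    mask); the score is its mean over the mask, in mm.  The mean is
    size-invariant, so cows of different footprint are comparable.
    """
    h = np.asarray(height_map, dtype=np.float64)
    opened = np.asarray(opened, dtype=np.float64)
    if h.shape != opened.shape:
        raise ValidationError("height map and opened map shapes differ")
    mask = np.asarray(mask, dtype=bool) & np.isfinite(h)
    if not mask.any():
        raise DegenerateInputError("angularity requires a non-empty mask")
    residual = np.where(mask, _quantize(h) - opened, np.nan)
    return AngularityScore(value=float(residual[mask].mean()), residual_map=residual)


def score_surface(
    height_map: np.ndarray, mask: np.ndarray, ball: BallParams | None = None
) -> AngularityScore:
    """Convenience: opening followed by angularity on one surface."""
    opened = rolling_ball_open(height_map, mask, ball)
    return angularity(height_map, opened, mask)


def angularity_sweep(
    height_map: np.ndarray, mask: np.ndarray, diameters_px
) -> dict[int, float]:
    """Angularity as a function of ball diameter (optional multi-ball scheme)."""
    return {
        int(d): score_surface(height_map, mask, BallParams(diameter_px=int(d))).value
        for d in diameters_px
    }


def fit_calibration(pairs) -> BcsCalibration:
    """Least-squares line through (angularity, manual BCS) pairs.

    Requires at least two pairs with distinct angularity and a negative
    fitted slope (angularity must fall as condition rises); otherwise a
    :class:`~cowmon.errors.CalibrationError` is raised.
    """
    pairs = list(pairs)
    ang = np.array([p[0] for p in pairs], dtype=np.float64)
    bcs = np.array([p[1] for p in pairs], dtype=np.float64)
    if np.unique(ang).size < 2:
        raise CalibrationError("need >= 2 pairs with distinct angularity")
    slope, intercept = np.polyfit(ang, bcs, 1)
    return BcsCalibration(slope=float(slope), intercept=float(intercept))


def predict_bcs(score, cal: BcsCalibration) -> float:
    """Map an angularity (or :class:`AngularityScore`) to a clamped BCS."""
    value = score.value if isinstance(score, AngularityScore) else float(score)
    bcs = cal.slope * value + cal.intercept
    return float(np.clip(bcs, cal.bcs_min, cal.bcs_max))
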