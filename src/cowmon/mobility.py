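"""Lameness from the arch of the walking cow's spine.

The spine shows up as a ridge of high curvedness along the body's major
axis.  Per frame, the ridge region of interest is the top-percentile
curvedness inside a central band; within each image column the highest
surface point is taken, and a quadratic ``a x^2 + b x + c`` is fitted to
those (metric x, height) points with x re-centred at the cow.  The
quadratic coefficient measures vertical spine curvature: with heights
measured upward, a hunched (arched) back gives ``a < 0`` and the gentle
dip of a sound walking topline gives ``a > 0``.

To compare animals of different size, the coefficient is reported as the
dimensionless arch statistic

    arch = -a * L^2 / H

(L = metric body length, H = mean spine height), so an arched back is
*positive* and a dipped one negative.  The per-session statistic is the
minimum of the per-frame arch values over frames in which the cow was
actually walking (stationary postures such as neck craning are gated
out): a cow is flagged lame when even its least-arched walking moment
stays at or above the decision threshold (default -0.3).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, SessionUnusableError
from .preprocess import CowSegment, CurvednessMap

__all__ = [
    "SpineCurve",
    "MobilityResult",
    "LAMENESS_THRESHOLD",
    "extract_spine_roi",
    "spine_points",
    "fit_spine",
    "normalised_arch",
    "is_moving",
    "session_statistic",
    "classify_lameness",
]

#: Default decision threshold on the session arch statistic.
LAMENESS_THRESHOLD = -0.3


@dataclass(frozen=True)
class SpineCurve:
    """Quadratic spine fit for one frame (metric mm, x centred on the cow)."""

    a: float
    b: float
    c: float
    n_points: int
    rms_residual: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise DegenerateInputError("a spine curve needs at least 3 points")
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise DegenerateInputError("spine coefficients must be finite")


@dataclass
class MobilityResult:
    """Per-session mobility outcome."""

    statistic: float
    lame: bool
    frames_used: int
    frames_discarded: int


def extract_spine_roi(
    cmap: CurvednessMap,
    segment: CowSegment,
    top_pct: float = 5.0,
    band_frac: float = 0.3,
    edge_margin_px: int = 10,
) -> np.ndarray:
    """Ridge region of interest: top-percentile curvedness pixels inside a
    central band around the major axis.

    ``band_frac`` is the half-width of the band as a fraction of the mask
    bounding-box height.  The mask is eroded by ``edge_margin_px`` first:
    the silhouette rim carries spuriously high curvedness (the body edge
    is a depth cliff) that would otherwise drag low points at the nose
    and tail into the spine fit.  Returns a boolean grid (a subset of the
    cow mask); empty when no ridge is present, in which case the caller
    discards the frame.
    """
    mask = segment.mask
    if edge_margin_px > 0:
        mask = ndimage.binary_erosion(mask, iterations=edge_margin_px)
        if not mask.any():
            return np.zeros_like(segment.mask)
    vals = cmap.values[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return np.zeros_like(mask)
    cut = np.percentile(vals, 100.0 - top_pct)
    rows = np.any(mask, axis=1).nonzero()[0]
    centroid_row = np.argwhere(mask).mean(axis=0)[0]
    half = band_frac * (rows[-1] - rows[0] + 1)
    rr = np.arange(mask.shape[0], dtype=np.float64)
    band = np.abs(rr - centroid_row)[:, None] <= half
    return mask & band & (cmap.values >= cut) & (cmap.values > 0)


def spine_points(roi: np.ndarray, segment: CowSegment, smooth_sigma: float = 2.0):
    """Highest point of each occupied ROI column, as (x mm, height mm).

    The height field is lightly denoised first (mask-aware Gaussian,
    ``smooth_sigma`` pixels): a per-column maximum is an extreme-value
    statistic, and without denoising its upward noise bias varies with
    how many ridge pixels each column holds, bending the fitted
    parabola.  Within a column, ties go to the smaller row index.
    Points are returned ordered by x.
    """
    roi = np.asarray(roi, dtype=bool)
    height = segment.height_map
    if smooth_sigma > 0:
        m = segment.mask & np.isfinite(height)
        num = ndimage.gaussian_filter(np.where(m, height, 0.0), smooth_sigma, mode="nearest")
        den = ndimage.gaussian_filter(m.astype(np.float64), smooth_sigma, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            height = np.where(m, num / np.maximum(den, 1e-9), height)
    h = np.where(roi & np.isfinite(height), height, -np.inf)
    cols = np.any(np.isfinite(h) & (h > -np.inf), axis=0).nonzero()[0]
    xs, hs = [], []
    for c in cols:
        r = int(np.argmax(h[:, c]))  # argmax returns the first (smallest row)
        xs.append(segment.x_mm[r, c])
        hs.append(height[r, c])
    xs = np.asarray(xs, dtype=np.float64)
    hs = np.asarray(hs, dtype=np.float64)
    order = np.argsort(xs, kind="stable")
    return xs[order], hs[order]


def fit_spine(
    x, height, x_center: float | None = None, trim_sigma: float | None = 2.5
) -> SpineCurve:
    """Least-squares quadratic through (x, height) points.

    ``x`` is re-centred at ``x_center`` (default: the mean of the points,
    a stand-in for the cow centroid) before fitting, so the linear term
    does not absorb arch magnitude and the quadratic coefficient is
    invariant to translation along the walkway.

    With ``trim_sigma`` set (the default), one trimmed refit discards
    points further than that many residual RMS from the first fit: where
    the ridge fades out near the nose and tail, noise can pull isolated
    crest points well off the spine line.  Noise-free data is never
    trimmed, so the fit remains exact on clean quadratics.
    """
    x = np.asarray(x, dtype=np.float64)
    height = np.asarray(height, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(height)
    x, height = x[ok], height[ok]
    if np.unique(x).size < 3:
        raise DegenerateInputError("spine fit needs >= 3 points with distinct x")
    if x_center is None:
        x_center = float(x.mean())
    xc = x - x_center

    def _ls(xv, hv):
        a, b, c = np.polyfit(xv, hv, 2)
        resid = hv - (a * xv**2 + b * xv + c)
        return a, b, c, resid

    a, b, c, resid = _ls(xc, height)
    rms = float(np.sqrt(np.mean(resid**2)))
    n = int(x.size)
    if trim_sigma is not None and rms > 1e-6:
        keep = np.abs(resid) <= trim_sigma * rms
        if 3 <= keep.sum() < n and np.unique(xc[keep]).size >= 3:
            a, b, c, resid = _ls(xc[keep], height[keep])
            rms = float(np.sqrt(np.mean(resid**2)))
            n = int(keep.sum())
    return SpineCurve(
        a=float(a), b=float(b), c=float(c), n_points=n, rms_residual=rms
    )


def normalised_arch(curve: SpineCurve, length_mm: float, mean_height_mm: float) -> float:
    """Dimensionless, size-invariant arch statistic ``-a * L^2 / H``.

    Positive for an arched (hunched) spine, negative for a dipped sound
    topline, zero when flat.
    """
    if not length_mm > 0 or not mean_height_mm > 0:
        raise DegenerateInputError("length and mean height must be positive")
    return -curve.a * length_mm**2 / mean_height_mm


def is_moving(segments, min_step_mm: float = 10.0) -> bool:
    """True when the cow is actually walking.

    Judged by the median per-frame displacement of the mask centroid
    along the walkway, in metric mm, across consecutive segments.
    """
    segments = list(segments)
    if len(segments) < 2:
        return False
    xs = np.array([s.centroid_x_mm for s in segments])
    steps = np.abs(np.diff(xs))
    return bool(np.median(steps) >= min_step_mm)


def session_statistic(arch_values) -> float:
    """Session mobility statistic: the minimum per-frame arch value.

    The minimum is the least-arched (most dipped) walking moment; sound
    cows reach well below the lameness threshold at some point of the
    passage, lame cows never do.
    """
    arch_values = [float(v) for v in arch_values]
    if len(arch_values) == 0:
        raise SessionUnusableError("no retained frames for the mobility statistic")
    return min(arch_values)


def classify_lameness(statistic: float, threshold: float = LAMENESS_THRESHOLD) -> bool:
    """A value of ``threshold`` (default -0.3) or greater flags a lame animal."""
    if not np.isfinite(statistic):
        raise DegenerateInputError("mobility statistic must be finite")
    return bool(statistic >= threshold)
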