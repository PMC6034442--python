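"""Depth-frame pre-processing: segmentation, curvedness, region
classification, alignment and metric rescaling.

The stages mirror the capture pipeline: the empty-scene background is
subtracted to expose the animal, near/area/range thresholds reject
spurious objects and low body parts (legs), the largest connected
component is kept, Koenderink curvedness highlights bony structure for
template matching and spine work, the body is rotated so its major axis
lies horizontally, and pixel coordinates are rescaled to millimetres
using the lens field-of-view model.
"""
from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.measure import regionprops
from skimage.transform import rotate as _sk_rotate

from .depthio import CameraGeometry, DepthFrame
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PreprocessParams",
    "CowSegment",
    "CurvednessMap",
    "RegionClass",
    "segment_cow",
    "largest_component",
    "curvedness",
    "match_region",
    "estimate_orientation",
    "rotate_to_major_axis",
    "metric_grid",
    "pixel_pitch",
    "pixel_areas",
    "make_templates",
    "default_templates",
]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable constants of the pre-processing stage (millimetres / pixels).

    Defaults follow the capture rig: objects are detected when closer
    than 1.5 m with at least 500 px of foreground; a 1.35 m range
    threshold removes legs and other low parts; the top 5% of curvedness
    values drive orientation estimation.
    """

    near_threshold: float = 1500.0
    min_area: int = 500
    range_threshold: float = 1350.0
    background_diff_min: float = 100.0
    curvedness_smooth_sigma: float = 5.0
    top_curvedness_pct: float = 5.0
    ncc_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")
        if not 0 < self.top_curvedness_pct <= 100:
            raise ValidationError("top_curvedness_pct must be in (0, 100]")
        if not -1 <= self.ncc_threshold <= 1:
            raise ValidationError("ncc_threshold must be a correlation in [-1, 1]")


@dataclass
class CowSegment:
    """A masked, metrically scaled cow-back surface.

    ``mask`` is a single 4-connected component; ``height_map`` is the
    per-pixel height above the local background (floor) in mm, filled
    inside the mask; ``depth`` is the per-pixel camera distance with
    in-mask holes inpainted.  ``x_mm``/``y_mm`` give each pixel's
    physical position from the field-of-view model evaluated at that
    pixel's own depth.
    """

    mask: np.ndarray
    height_map: np.ndarray
    depth: np.ndarray
    geometry: CameraGeometry
    orientation_deg: float = 0.0
    frame_index: int = 0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @functools.cached_property
    def _metric(self):
        return metric_grid(self.depth, self.geometry)

    @property
    def x_mm(self) -> np.ndarray:
        return self._metric[0]

    @property
    def y_mm(self) -> np.ndarray:
        return self._metric[1]

    @property
    def centroid_x_mm(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return float(np.nanmean(self.x_mm[self.mask]))

    def major_axis_length_mm(self) -> float:
        """Metric extent of the mask along the walkway (x) axis."""
        x = self.x_mm[self.mask]
        return float(np.nanmax(x) - np.nanmin(x))


@dataclass
class CurvednessMap:
    """Normalised Koenderink curvedness of a height field.

    ``values`` holds C / C_max in [0, 1] (zero outside the mask and
    everywhere when the surface is planar); ``raw`` the unnormalised
    curvedness sqrt(k1^2 + k2^2) in 1/length units of ``spacing``.
    """

    values: np.ndarray
    raw: np.ndarray
    cmax: float
    mask: np.ndarray


@dataclass(frozen=True)
class RegionClass:
    """Best template-match label: front, rear, front_and_rear or none."""

    label: str
    score: float


def metric_grid(depth, geometry: CameraGeometry):
    """Per-pixel physical (x, y) in mm, origin at the image centre.

    At a uniform depth ``d`` the full-image extent equals the field of
    view ``(w, h) = 2 d tan(theta / 2)``.  Non-positive or missing depths
    yield NaN coordinates.
    """
    depth = np.asarray(depth, dtype=np.float64)
    nr, nc = depth.shape
    kx = 2.0 * math.tan(math.radians(geometry.theta_horz_deg) / 2.0) / nc
    ky = 2.0 * math.tan(math.radians(geometry.theta_vert_deg) / 2.0) / nr
    d = np.where(depth > 0, depth, np.nan)
    cols = np.arange(nc) - (nc - 1) / 2.0
    rows = np.arange(nr) - (nr - 1) / 2.0
    x = d * (kx * cols)[None, :]
    y = d * (ky * rows)[:, None]
    return x, y


def pixel_pitch(depth, geometry: CameraGeometry):
    """Per-pixel metric size (dx, dy) in mm at each pixel's own depth."""
    depth = np.asarray(depth, dtype=np.float64)
    nr, nc = depth.shape
    kx = 2.0 * math.tan(math.radians(geometry.theta_horz_deg) / 2.0) / nc
    ky = 2.0 * math.tan(math.radians(geometry.theta_vert_deg) / 2.0) / nr
    d = np.where(depth > 0, depth, np.nan)
    return d * kx, d * ky


def _masked_partial(coord, mask, axis, fallback):
    """d(coord)/d(index) along ``axis`` from in-mask neighbours only.

    Central differences where both neighbours are in the mask, one-sided
    at the mask boundary (so the metric jump across the silhouette never
    leaks in), ``fallback`` where a pixel has no in-mask neighbour.
    """
    c = np.where(mask, coord, np.nan)
    fwd = np.full_like(c, np.nan)
    bwd = np.full_like(c, np.nan)
    sl_from, sl_to = [slice(None)] * 2, [slice(None)] * 2
    sl_from[axis], sl_to[axis] = slice(1, None), slice(None, -1)
    fwd[tuple(sl_to)] = c[tuple(sl_from)] - c[tuple(sl_to)]
    bwd[tuple(sl_from)] = c[tuple(sl_from)] - c[tuple(sl_to)]
    both = np.isfinite(fwd) & np.isfinite(bwd)
    out = np.where(both, (fwd + bwd) / 2.0, np.nan)
    out = np.where(~both & np.isfinite(fwd), fwd, out)
    out = np.where(~both & np.isfinite(bwd), bwd, out)
    return np.where(np.isfinite(out), out, fallback)


def pixel_areas(depth, mask, geometry: CameraGeometry, smooth_sigma: float = 1.0):
    """Physical ground-plane area (mm^2) covered by each in-mask pixel.

    Each pixel's metric position (x, y) comes from the field-of-view
    model at its own depth; the pixel's footprint is the parallelogram
    spanned by the local metric steps, i.e. the Jacobian determinant
    ``|dx/dcol * dy/drow - dx/drow * dy/dcol|``.  On a fronto-parallel
    plane this reduces exactly to the nominal pitch product
    ``(d kx)(d ky)``; on sloped, off-axis surface it carries the
    foreshortening the nominal product misses.  The depth field is
    lightly smoothed first so sensor noise does not alias into areas.
    """
    depth = np.asarray(depth, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if smooth_sigma > 0:
        # mask-aware smoothing: the floor depth beyond the silhouette
        # must not bleed into boundary pixels
        num = ndimage.gaussian_filter(np.where(mask, depth, 0.0), smooth_sigma, mode="nearest")
        den = ndimage.gaussian_filter(mask.astype(np.float64), smooth_sigma, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            depth = np.where(mask & (den > 1e-9), num / np.maximum(den, 1e-9), depth)
    x, y = metric_grid(depth, geometry)
    dx_nom, dy_nom = pixel_pitch(depth, geometry)
    x_c = _masked_partial(x, mask, 1, dx_nom)
    x_r = _masked_partial(x, mask, 0, 0.0)
    y_r = _masked_partial(y, mask, 0, dy_nom)
    y_c = _masked_partial(y, mask, 1, 0.0)
    return np.abs(x_c * y_r - x_r * y_c)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the maximal-area 4-connected component of ``mask``.

    Ties are broken towards the component whose first pixel comes
    earliest in scan (row-major) order.  An all-false mask is returned
    unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=FOUR_CONN)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    # ndimage.label assigns labels in scan order, so the smallest label
    # among equal-area components is the scan-order tie-break.
    best = int(np.flatnonzero(counts == counts.max())[0])
    return labels == best


def _masked_median_fill(values: np.ndarray, mask: np.ndarray, window: int = 5,
                        max_iter: int = 10) -> np.ndarray:
    """Fill NaNs inside ``mask`` with the median of valid window neighbours."""
    out = values.copy()
    half = window // 2
    for _ in range(max_iter):
        holes = mask & ~np.isfinite(out)
        if not holes.any():
            break
        stack = []
        for di in range(-half, half + 1):
            for dj in range(-half, half + 1):
                shifted = np.full_like(out, np.nan)
                src = out[
                    max(0, -di) : out.shape[0] - max(0, di),
                    max(0, -dj) : out.shape[1] - max(0, dj),
                ]
                shifted[
                    max(0, di) : out.shape[0] - max(0, -di),
                    max(0, dj) : out.shape[1] - max(0, -dj),
                ] = src
                stack.append(shifted)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(np.stack(stack), axis=0)
        out[holes] = med[holes]
    return out


def segment_cow(
    frame: DepthFrame,
    background: DepthFrame,
    params: PreprocessParams | None = None,
    geometry: CameraGeometry | None = None,
) -> CowSegment | None:
    """Segment the animal from one frame, or return None if nothing usable.

    A pixel is foreground when it is significantly closer than the
    background (one-sided difference >= ``background_diff_min``) and
    closer than ``near_threshold``.  Detection requires a connected
    foreground object of at least ``min_area`` pixels.  The range
    threshold then discards pixels further than ``range_threshold``
    (legs, low flanks), the largest 4-connected component is isolated,
    interior holes are filled and in-mask dropouts inpainted.
    """
    if params is None:
        params = PreprocessParams()
    f = frame.depth
    b = background.depth
    if f.shape != b.shape:
        raise ValidationError(f"frame shape {f.shape} != background shape {b.shape}")
    valid = np.isfinite(f) & np.isfinite(b)
    fg = valid & (b - f >= params.background_diff_min) & (f < params.near_threshold)
    detect = largest_component(fg)
    if detect.sum() < params.min_area:
        return None
    mask = largest_component(fg & (f < params.range_threshold))
    if mask.sum() < params.min_area:
        return None
    mask = ndimage.binary_fill_holes(mask, structure=FOUR_CONN)
    height = np.where(mask, b - f, np.nan)
    height = _masked_median_fill(height, mask)
    height = np.where(mask, np.clip(height, 0.0, None), np.nan)
    depth = np.where(np.isfinite(f), f, b)
    depth = np.where(mask, b - np.where(np.isfinite(height), height, 0.0), depth)
    if geometry is None:
        geometry = CameraGeometry()
    return CowSegment(
        mask=mask,
        height_map=height,
        depth=depth,
        geometry=geometry,
        frame_index=frame.frame_index,
    )


def _nearest_fill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend in-mask values to the whole grid by nearest neighbour."""
    if mask.all():
        return values
    idx = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def curvedness(
    height_map: np.ndarray,
    mask: np.ndarray | None = None,
    smooth_sigma: float = 5.0,
    spacing: float = 1.0,
) -> CurvednessMap:
    """Normalised curvedness of the Monge patch z = h(x, y).

    Principal curvatures are obtained from the mean (H) and Gaussian (K)
    curvature of the surface via ``k1,2 = H +/- sqrt(max(H^2 - K, 0))``,
    with derivatives estimated by Gaussian-derivative filtering at
    ``smooth_sigma`` pixels (raw depth is too noisy for direct second
    differences).  ``spacing`` is the grid step in the same units as the
    heights.  The map is normalised by its in-mask maximum; a planar
    patch (C_max = 0) yields all zeros.
    """
    h = np.asarray(height_map, dtype=np.float64)
    if mask is None:
        mask = np.isfinite(h)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(h)
    if not mask.any():
        raise DegenerateInputError("curvedness requires a non-empty mask")
    # Remove the mean height: the truncated derivative kernels have a tiny
    # residual sum that would otherwise couple to the absolute height, and
    # curvature is translation invariant anyway.
    h = h - h[mask].mean()
    h = _nearest_fill(np.where(mask, h, 0.0), mask)
    # Odd-reflection padding continues linear trends exactly, so an
    # inclined plane keeps zero curvature right up to the array edge.
    pad = int(np.ceil(6.0 * smooth_sigma)) + 1
    hp = np.pad(h, pad, mode="reflect", reflect_type="odd")

    def g(order):
        out = ndimage.gaussian_filter(
            hp, smooth_sigma, order=order, mode="nearest", truncate=6.0
        )
        return out[pad:-pad, pad:-pad]

    hy, hx = g((1, 0)) / spacing, g((0, 1)) / spacing
    hyy, hxx = g((2, 0)) / spacing**2, g((0, 2)) / spacing**2
    hxy = g((1, 1)) / spacing**2

    grad2 = hx**2 + hy**2
    K = (hxx * hyy - hxy**2) / (1.0 + grad2) ** 2
    Hm = ((1.0 + hx**2) * hyy - 2.0 * hx * hy * hxy + (1.0 + hy**2) * hxx) / (
        2.0 * (1.0 + grad2) ** 1.5
    )
    root = np.sqrt(np.clip(Hm**2 - K, 0.0, None))
    k1, k2 = Hm + root, Hm - root
    raw = np.sqrt(k1**2 + k2**2)
    raw = np.where(mask, raw, 0.0)
    cmax = float(raw[mask].max())
    # numerically flat surfaces (curvature radius > 1e6 grid steps) -> zeros
    if cmax <= 1e-6 / spacing:
        cmax = 0.0
        raw = np.zeros_like(raw)
    values = raw / cmax if cmax > 0 else np.zeros_like(raw)
    return CurvednessMap(values=values, raw=raw, cmax=cmax, mask=mask)


def match_region(
    cmap: CurvednessMap,
    templates: dict[str, np.ndarray],
    ncc_threshold: float = 0.5,
) -> RegionClass:
    """Classify the visible cow region by windowed zero-normalised
    cross-correlation of curvedness templates.

    Returns the best-scoring label, or ``none`` when the best score falls
    below ``ncc_threshold`` (including the all-background case).
    """
    if not templates:
        raise ValidationError("at least one template is required")
    image = cmap.values
    best_label, best_score = "none", -np.inf
    for label, tpl in templates.items():
        tpl = np.asarray(tpl, dtype=np.float64)
        if tpl.shape[0] > image.shape[0] or tpl.shape[1] > image.shape[1]:
            raise ValidationError(
                f"template {label!r} {tpl.shape} larger than image {image.shape}"
            )
        resp = match_template(image, tpl, pad_input=False)
        score = float(np.nan_to_num(resp, nan=0.0).max()) if resp.size else 0.0
        if score > best_score:
            best_label, best_score = label, score
    if not np.isfinite(best_score) or best_score < ncc_threshold:
        return RegionClass(label="none", score=max(best_score, -1.0))
    return RegionClass(label=best_label, score=best_score)


def _min_area_rect_angle(coords_rc: np.ndarray) -> float:
    """Major-axis angle (deg) of the minimum-area rectangle of pixel coords.

    Angle convention: 0 along image columns (the walkway axis), positive
    counter-clockwise as displayed (row axis pointing down), range
    (-90, 90].
    """
    from shapely import MultiPoint

    pts = MultiPoint([(float(c), float(r)) for r, c in coords_rc])
    rect = pts.minimum_rotated_rectangle
    if rect.geom_type == "Point":
        raise DegenerateInputError("cannot orient a single point")
    if rect.geom_type == "LineString":
        (x0, y0), (x1, y1) = rect.coords[0], rect.coords[-1]
        dx, dy = x1 - x0, y1 - y0
    else:
        xy = list(rect.exterior.coords)
        edges = [
            (xy[i + 1][0] - xy[i][0], xy[i + 1][1] - xy[i][1]) for i in range(4)
        ]
        dx, dy = max(edges, key=lambda e: e[0] ** 2 + e[1] ** 2)
    angle = math.degrees(math.atan2(-dy, dx))
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle == -90.0:
        angle = 90.0
    return angle


def estimate_orientation(cmap: CurvednessMap, top_pct: float = 5.0) -> float:
    """Orientation (degrees) of the high-curvedness ridge.

    Thresholds the curvedness map so only the top ``top_pct`` percent of
    in-mask values survive, takes the connected survivor region with the
    greatest major-axis length, and returns the major-axis angle of its
    minimum-area bounding rectangle, in (-90, 90].
    """
    vals = cmap.values[cmap.mask]
    vals = vals[vals > 0]
    if vals.size < 2:
        raise DegenerateInputError("not enough curvedness signal to orient")
    cut = np.percentile(vals, 100.0 - top_pct)
    surv = cmap.mask & (cmap.values >= cut) & (cmap.values > 0)
    if surv.sum() < 2:
        raise DegenerateInputError("fewer than 2 pixels survive the curvedness cut")
    labels, n = ndimage.label(surv, structure=np.ones((3, 3), dtype=bool))
    best_len, best_label = -1.0, None
    for prop in regionprops(labels):
        # strictly greater: earliest (smallest) label wins ties
        if prop.axis_major_length > best_len:
            best_len, best_label = prop.axis_major_length, prop.label
    coords = np.argwhere(labels == best_label)
    if coords.shape[0] < 2:
        raise DegenerateInputError("longest ridge region has fewer than 2 pixels")
    return _min_area_rect_angle(coords)


def rotate_to_major_axis(segment: CowSegment, angle: float) -> CowSegment:
    """Rotate the segment by ``-angle`` about the mask centroid so the
    major axis lies horizontally.

    Heights use mask-aware bilinear interpolation (values are weighted by
    the rotated mask coverage); the mask itself uses nearest neighbour.
    Pixels rotated in from outside are flagged missing.  ``angle = 0`` is
    an exact identity apart from the recorded orientation.
    """
    if angle == 0.0:
        return replace(segment, orientation_deg=segment.orientation_deg + 0.0)
    r, c = np.argwhere(segment.mask).mean(axis=0)
    center = (c, r)  # skimage uses (col, row)

    mask_f = segment.mask.astype(np.float64)
    mask_rot = _sk_rotate(mask_f, -angle, center=center, order=0, cval=0.0) > 0.5
    cov = _sk_rotate(mask_f, -angle, center=center, order=1, cval=0.0)
    num = _sk_rotate(
        np.where(segment.mask, segment.height_map, 0.0), -angle,
        center=center, order=1, cval=0.0, preserve_range=True,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        height = np.where(mask_rot & (cov > 1e-6), num / np.maximum(cov, 1e-6), np.nan)
    depth = _sk_rotate(
        segment.depth, -angle, center=center, order=1,
        cval=np.nan, preserve_range=True,
    )
    # inside the mask, use the same coverage-weighted scheme as heights so
    # border NaNs cannot bleed into an edge-touching mask
    depth_num = _sk_rotate(
        np.where(segment.mask, segment.depth, 0.0), -angle,
        center=center, order=1, cval=0.0, preserve_range=True,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.where(
            mask_rot & (cov > 1e-6), depth_num / np.maximum(cov, 1e-6), depth
        )
    # keep mask a single 4-connected component (rotation can shear off slivers)
    mask_rot = largest_component(mask_rot)
    height = np.where(mask_rot, height, np.nan)
    seg = CowSegment(
        mask=mask_rot,
        height_map=height,
        depth=depth,
        geometry=segment.geometry,
        orientation_deg=segment.orientation_deg + angle,
        frame_index=segment.frame_index,
    )
    return seg


# ---------------------------------------------------------------------------
# Templates: generated deterministically from the synthetic scene model.


def make_templates(scene=None, cow=None, downsample: int = 2) -> dict[str, np.ndarray]:
    """Build front / rear / front_and_rear curvedness templates.

    Templates come from a deterministic, noiseless synthetic cow rendered
    with the given scene geometry: the full-body curvedness crop is the
    ``front_and_rear`` template and its head-end / tail-end halves give
    ``front`` and ``rear``.  The crop is downsampled to keep matching cheap.
    """
    from . import synthetic

    if scene is None:
        scene = synthetic.SceneParams()
    if cow is None:
        cow = synthetic.CowShapeParams(noise_sd=0.0, dropout_rate=0.0, seed=0)
    else:
        cow = replace(cow, noise_sd=0.0, dropout_rate=0.0)
    bg = synthetic.generate_background(scene)
    fr = synthetic.generate_cow_frame(scene, cow, position_x=0.0)
    seg = segment_cow(fr, bg)
    if seg is None:
        raise ValidationError("template cow was not segmentable in this scene")
    cmap = curvedness(seg.height_map, seg.mask)
    rows = np.any(seg.mask, axis=1).nonzero()[0]
    cols = np.any(seg.mask, axis=0).nonzero()[0]
    crop = cmap.values[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    crop = crop[::downsample, ::downsample]
    half = crop.shape[1] // 2
    # the cow walks towards +x, so the head end is the high-column side
    return {
        "front_and_rear": crop,
        "front": crop[:, half:],
        "rear": crop[:, :half],
    }


@functools.lru_cache(maxsize=4)
def _default_templates_cached(shape: tuple[int, int], mount_height_m: float):
    from . import synthetic

    scene = synthetic.SceneParams(
        geometry=CameraGeometry(mount_height_m=mount_height_m), shape=shape
    )
    return make_templates(scene)


def default_templates(shape=(480, 640), mount_height_m=2.3) -> dict[str, np.ndarray]:
    """Cached default template set for a given raster and mount height."""
    return _default_templates_cached(tuple(shape), float(mount_height_m))
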