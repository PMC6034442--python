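"""Weight estimation by depth integration.

The segmented back surface is assumed to cap a solid extending down to
the floor; integrating per-pixel height over the pixel's physical area
gives a volume, and multiplying by the density of water (1000 kg/m^3 by
default) gives a mass estimate:

    M = sum_xy h(x, y) * dx(x, y) * dy(x, y) * D

Pixel areas come from the field-of-view metric coordinates evaluated at
each pixel's own depth (local Jacobian of the pixel-to-ground mapping),
so the estimate is invariant to the camera mount height and correct on
sloped surface seen off-axis.
Heights are measured from the per-pixel background depth, so floor slope
and walls cancel.  Per session, the largest per-frame mass (the most
complete view of the animal) is the final estimate, after discarding
frames inflated by a following animal overlapping the imaged one
("bunching", detected as an implausibly large mask area).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SessionUnusableError
from .preprocess import CowSegment, pixel_areas

__all__ = [
    "WATER_DENSITY",
    "WeightEstimate",
    "frame_mass",
    "session_weight",
    "repeatability_range",
]

WATER_DENSITY = 1000.0  # kg/m^3

#: Frames whose mask area exceeds this multiple of the session median
#: area are treated as bunching outliers.
BUNCHING_AREA_FACTOR = 1.6


@dataclass
class WeightEstimate:
    """Per-frame masses and the session-level maximum over retained frames."""

    frame_masses: list[float]
    retained: list[int]
    session_mass: float
    argmax_frame: int
    density: float = WATER_DENSITY


def frame_mass(segment: CowSegment, density: float = WATER_DENSITY) -> float:
    """Mass (kg) of the solid from the back surface to the floor in one frame."""
    mask = segment.mask
    if not mask.any():
        raise DegenerateInputError("frame_mass requires a non-empty mask")
    area = pixel_areas(segment.depth, mask, segment.geometry)
    h = segment.height_map
    contrib = h[mask] * area[mask]
    contrib = contrib[np.isfinite(contrib)]
    return float(contrib.sum() * 1e-9 * density)


def session_weight(
    masses,
    bunching_flags=None,
    areas=None,
    area_factor: float = BUNCHING_AREA_FACTOR,
    density: float = WATER_DENSITY,
) -> WeightEstimate:
    """Aggregate per-frame masses into the session weight.

    Frames flagged in ``bunching_flags`` (or whose mask ``areas`` exceed
    ``area_factor`` times the session median area) are excluded first;
    the maximum of the retained masses -- attained at the most complete
    view of the animal -- is the session estimate.
    """
    masses = [float(m) for m in masses]
    n = len(masses)
    flagged = np.zeros(n, dtype=bool)
    if bunching_flags is not None:
        flagged |= np.asarray(list(bunching_flags), dtype=bool)
    if areas is not None and n >= 2:
        areas = np.asarray(list(areas), dtype=np.float64)
        flagged |= areas > area_factor * np.median(areas)
    retained = [i for i in range(n) if not flagged[i]]
    if not retained:
        raise SessionUnusableError("no frames retained for the weight estimate")
    argmax = max(retained, key=lambda i: masses[i])
    return WeightEstimate(
        frame_masses=masses,
        retained=retained,
        session_mass=masses[argmax],
        argmax_frame=argmax,
        density=density,
    )


def repeatability_range(masses_by_cow: dict) -> pd.DataFrame:
    """Per-cow range of repeated session weights, plus summary attributes.

    ``masses_by_cow`` maps cow id -> list of session masses (kg) from
    repeated passages.  Returns a DataFrame with per-cow ``n``, ``mean``,
    ``range`` and ``range_pct_of_mean`` columns; the frame's ``attrs``
    carry ``average_range`` and ``average_range_pct_of_mean`` (the
    average range as a percentage of the grand mean weight).
    """
    if not any(len(v) >= 2 for v in masses_by_cow.values()):
        raise DegenerateInputError("repeatability needs >= 2 repeats for >= 1 cow")
    rows = []
    for cow_id, masses in masses_by_cow.items():
        masses = np.asarray(list(masses), dtype=np.float64)
        rows.append(
            {
                "cow_id": cow_id,
                "n": masses.size,
                "mean": masses.mean(),
                "range": masses.max() - masses.min(),
            }
        )
    df = pd.DataFrame(rows)
    grand_mean = float(df["mean"].mean())
    df["range_pct_of_mean"] = 100.0 * df["range"] / grand_mean
    df.attrs["grand_mean"] = grand_mean
    df.attrs["average_range"] = float(df["range"].mean())
    df.attrs["average_range_pct_of_mean"] = 100.0 * df.attrs["average_range"] / grand_mean
    return df
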