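"""Per-session orchestration: one manifest in, one CowRecord out.

Pre-processing (segmentation, curvedness, region classification,
alignment, metric scaling) runs once per frame; the three trait
estimators -- angularity/BCS, spine-arch mobility and volumetric weight
-- then share the processed frames.  Frames and sessions that fail a
stage are excluded with a reason code rather than silently dropped, so
every record is either a value with QC "ok" or a reason with no value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bcs as bcs_mod
from . import mobility as mob
from . import weight as weight_mod
from .depthio import CameraGeometry, DepthFrame, SessionManifest, load_session_frames
from .errors import CowmonError, DegenerateInputError, SessionUnusableError
from .preprocess import (
    CowSegment,
    PreprocessParams,
    curvedness,
    default_templates,
    estimate_orientation,
    match_region,
    rotate_to_major_axis,
    segment_cow,
)

__all__ = ["PipelineConfig", "CowRecord", "process_session", "write_records"]

log = logging.getLogger("cowmon")

#: QC reason codes
QC_OK = "ok"
QC_NO_OBJECT = "no_object"
QC_NO_TEMPLATE_MATCH = "no_template_match"
QC_NOT_MOVING = "not_moving"
QC_NO_SPINE = "no_spine"
QC_NO_CALIBRATION = "no_calibration"
QC_BUNCHING = "bunching"
QC_NO_FRAMES = "no_frames"

RECORD_COLUMNS = [
    "cow_id",
    "session",
    "n_frames",
    "angularity",
    "bcs",
    "mobility_statistic",
    "lame",
    "weight_kg",
    "qc_bcs",
    "qc_mobility",
    "qc_weight",
    "frames_bcs",
    "frames_mobility",
    "frames_weight",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one validated block.

    All capture-rig constants appear here with their defaults: the 1.5 m
    detection threshold, 500 px minimum area, 1.35 m range threshold,
    top-5% curvedness cut, 70 px rolling ball, -0.3 lameness threshold
    and the density of water.
    """

    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    ball: bcs_mod.BallParams = field(default_factory=bcs_mod.BallParams)
    density: float = weight_mod.WATER_DENSITY
    lameness_threshold: float = mob.LAMENESS_THRESHOLD
    min_step_mm: float = 10.0
    spine_band_frac: float = 0.3
    bunching_area_factor: float = weight_mod.BUNCHING_AREA_FACTOR
    #: Calibration (slope, intercept) mapping angularity to BCS; None
    #: reports angularity only.
    calibration: bcs_mod.BcsCalibration | None = None
    #: Cap on the number of frames scored for angularity (the opening is
    #: by far the most expensive step; a spread of full views suffices).
    bcs_max_frames: int = 8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "geometry" in raw:
            kwargs["geometry"] = CameraGeometry(**raw["geometry"])
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessParams(**raw["preprocess"])
        if "ball" in raw:
            kwargs["ball"] = bcs_mod.BallParams(**raw["ball"])
        if "calibration" in raw and raw["calibration"] is not None:
            kwargs["calibration"] = bcs_mod.BcsCalibration(**raw["calibration"])
        for key in (
            "density", "lameness_threshold", "min_step_mm", "spine_band_frac",
            "bunching_area_factor", "bcs_max_frames", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            "geometry": asdict(self.geometry),
            "preprocess": asdict(self.preprocess),
            "ball": asdict(self.ball),
            "calibration": None if self.calibration is None else asdict(self.calibration),
            "density": self.density,
            "lameness_threshold": self.lameness_threshold,
            "min_step_mm": self.min_step_mm,
            "spine_band_frac": self.spine_band_frac,
            "bunching_area_factor": self.bunching_area_factor,
            "bcs_max_frames": self.bcs_max_frames,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class CowRecord:
    """Per-session outputs for one cow passage.

    Each trait carries either a value with QC "ok" or a reason code and
    no value.
    """

    cow_id: str
    session: int = 0
    n_frames: int = 0
    angularity: float | None = None
    bcs: float | None = None
    mobility_statistic: float | None = None
    lame: bool | None = None
    weight_kg: float | None = None
    qc_bcs: str = QC_NO_FRAMES
    qc_mobility: str = QC_NO_FRAMES
    qc_weight: str = QC_NO_FRAMES
    frames_bcs: int = 0
    frames_mobility: int = 0
    frames_weight: int = 0
    frame_log: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in RECORD_COLUMNS}


@dataclass
class _ProcessedFrame:
    index: int
    segment: CowSegment
    cmap: object
    region_label: str
    region_score: float
    mass_kg: float
    area_px: int


def _preprocess_frame(frame, background, config, templates):
    """Run the shared per-frame pipeline; returns (_ProcessedFrame | None, reason)."""
    seg = segment_cow(frame, background, config.preprocess, geometry=config.geometry)
    if seg is None:
        return None, QC_NO_OBJECT
    pitch = float(np.nanmedian(seg.depth[seg.mask])) * 2 * np.tan(
        np.radians(config.geometry.theta_horz_deg) / 2
    ) / seg.mask.shape[1]
    cmap = curvedness(
        seg.height_map, seg.mask,
        smooth_sigma=config.preprocess.curvedness_smooth_sigma,
        spacing=pitch,
    )
    region = match_region(cmap, templates, config.preprocess.ncc_threshold)
    if region.label == "none":
        return None, QC_NO_TEMPLATE_MATCH
    try:
        angle = estimate_orientation(cmap, config.preprocess.top_curvedness_pct)
    except DegenerateInputError:
        angle = 0.0
    if abs(angle) > 0.5:
        seg = rotate_to_major_axis(seg, angle)
        cmap = curvedness(
            seg.height_map, seg.mask,
            smooth_sigma=config.preprocess.curvedness_smooth_sigma,
            spacing=pitch,
        )
    mass = weight_mod.frame_mass(seg, density=config.density)
    return (
        _ProcessedFrame(
            index=frame.frame_index,
            segment=seg,
            cmap=cmap,
            region_label=region.label,
            region_score=region.score,
            mass_kg=mass,
            area_px=seg.area_px,
        ),
        QC_OK,
    )


def _bcs_trait(processed, config, record):
    """Mean angularity over a spread of the fullest views, then calibration."""
    frames = [p for p in processed if p.region_label == "front_and_rear"]
    if not frames:
        frames = list(processed)
    # prefer the most complete views (largest masks), keep frame order
    frames = sorted(frames, key=lambda p: -p.area_px)[: config.bcs_max_frames]
    frames = sorted(frames, key=lambda p: p.index)
    values = []
    for p in frames:
        try:
            values.append(
                bcs_mod.score_surface(p.segment.height_map, p.segment.mask, config.ball).value
            )
        except DegenerateInputError:
            continue
    if not values:
        record.qc_bcs = QC_NO_SPINE if processed else QC_NO_FRAMES
        return
    record.angularity = float(np.mean(values))
    record.frames_bcs = len(values)
    record.qc_bcs = QC_OK
    if config.calibration is not None:
        record.bcs = bcs_mod.predict_bcs(record.angularity, config.calibration)
    else:
        record.bcs = None


def _mobility_trait(processed, config, record):
    segs = [p.segment for p in processed]
    if len(segs) < 2 or not mob.is_moving(segs, config.min_step_mm):
        record.qc_mobility = QC_NOT_MOVING
        return
    arch_values = []
    for p in processed:
        roi = mob.extract_spine_roi(
            p.cmap, p.segment,
            top_pct=config.preprocess.top_curvedness_pct,
            band_frac=config.spine_band_frac,
        )
        if not roi.any():
            continue
        x, h = mob.spine_points(roi, p.segment)
        try:
            curve = mob.fit_spine(x, h, x_center=p.segment.centroid_x_mm)
        except DegenerateInputError:
            continue
        L = p.segment.major_axis_length_mm()
        H = float(np.mean(h))
        try:
            arch_values.append(mob.normalised_arch(curve, L, H))
        except DegenerateInputError:
            continue
    if not arch_values:
        record.qc_mobility = QC_NO_SPINE
        return
    record.mobility_statistic = mob.session_statistic(arch_values)
    record.lame = mob.classify_lameness(record.mobility_statistic, config.lameness_threshold)
    record.frames_mobility = len(arch_values)
    record.qc_mobility = QC_OK


def _weight_trait(processed, config, record):
    if not processed:
        record.qc_weight = QC_NO_FRAMES
        return
    try:
        est = weight_mod.session_weight(
            [p.mass_kg for p in processed],
            areas=[p.area_px for p in processed],
            area_factor=config.bunching_area_factor,
            density=config.density,
        )
    except SessionUnusableError:
        record.qc_weight = QC_BUNCHING
        return
    record.weight_kg = est.session_mass
    record.frames_weight = len(est.retained)
    record.qc_weight = QC_OK


def process_session(
    manifest_or_frames,
    background: DepthFrame,
    config: PipelineConfig | None = None,
    templates: dict | None = None,
    cow_id: str | None = None,
    session: int = 0,
) -> CowRecord:
    """Run the full pipeline over one session and aggregate a CowRecord.

    ``manifest_or_frames`` is either a :class:`SessionManifest` (frames
    are read from disk) or an iterable of :class:`DepthFrame`.  The
    per-frame pre-processing runs once and is shared by all three trait
    estimators; every discarded frame appears in ``record.frame_log``
    with its reason code.
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(manifest_or_frames, SessionManifest):
        frames = load_session_frames(manifest_or_frames)
        cow_id = cow_id or manifest_or_frames.cow_id
    else:
        frames = list(manifest_or_frames)
        cow_id = cow_id or "unknown"
    if templates is None:
        templates = default_templates(
            shape=background.shape, mount_height_m=config.geometry.mount_height_m
        )
    record = CowRecord(cow_id=cow_id, session=session, n_frames=len(frames))
    processed = []
    for frame in frames:
        try:
            pf, reason = _preprocess_frame(frame, background, config, templates)
        except CowmonError as exc:
            log.warning("frame %d failed: %s", frame.frame_index, exc)
            record.frame_log.append((frame.frame_index, f"error:{exc}"))
            continue
        if pf is None:
            record.frame_log.append((frame.frame_index, reason))
            continue
        record.frame_log.append((frame.frame_index, QC_OK))
        processed.append(pf)
    if not processed:
        record.qc_bcs = record.qc_mobility = record.qc_weight = QC_NO_OBJECT
        return record
    _bcs_trait(processed, config, record)
    if record.qc_bcs == QC_OK and record.bcs is None and config.calibration is None:
        record.qc_bcs = QC_OK  # angularity reported without calibrated BCS
    _mobility_trait(processed, config, record)
    _weight_trait(processed, config, record)
    return record


def write_records(records, path) -> None:
    """Write records as CSV with a fixed, documented column order."""
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a records CSV back into a DataFrame."""
    return pd.read_csv(path)
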