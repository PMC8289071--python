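"""Outer skin contour, waist circumference, and pipeline orchestration.

The circumference is the length of the outer margin of the skin on the
selected axial slice — a sub-pixel iso-contour of the filled body mask,
not its convex hull, so genuine skin-surface irregularities contribute
to the measured perimeter.  The contour is traced with marching squares
at level 0.5, each vertex coordinate is scaled by its axis spacing, and
segment lengths are summed; the result is reported in cm to 0.1 cm.

A scan whose body mask reaches the in-plane image border cannot be
measured: the contour would be clipped open.  Such scans are flagged
*non-evaluable* rather than failed, mirroring how an insufficient
field of view is triaged in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from . import landmarks as lm
from . import segmentation as seg
from .errors import CtwaistError, DataError, NonEvaluable, TechnicalFailure
from .landmarks import WaistRange
from .volume_io import CTVolume

logger = logging.getLogger(__name__)

STATUS_SUCCESS = "success"
STATUS_TECHNICAL_FAILURE = "technical_failure"
STATUS_NON_EVALUABLE = "non_evaluable"


@dataclass(frozen=True)
class Contour:
    """Closed polygon in physical mm coordinates, vertices as (y, x) rows."""

    vertices: np.ndarray  # (n, 2) float, mm
    closed: bool

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise DataError("a contour needs at least 3 vertices")

    def perimeter_mm(self) -> float:
        v = self.vertices
        segs = np.diff(v, axis=0, append=v[:1])
        return float(np.hypot(segs[:, 0], segs[:, 1]).sum())


@dataclass
class MeasurementReport:
    """Outcome of one waist measurement.

    ``status`` is one of ``success`` / ``technical_failure`` /
    ``non_evaluable``; ``wc_cm`` is present iff success.
    """

    status: str
    wc_cm: float | None = None
    z_mid: int | None = None
    waist_range: WaistRange | None = None
    reason: str | None = None
    source: str = "<memory>"

    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": 1,
            "source": self.source,
            "status": self.status,
            "wc_cm": self.wc_cm,
            "z_mid": self.z_mid,
        }
        if self.waist_range is not None:
            d["z_lowest_rib"] = self.waist_range.z_lowest_rib
            d["z_highest_iliac"] = self.waist_range.z_highest_iliac
        if self.reason is not None:
            d["reason"] = self.reason
        return d


def extract_outer_contour(
    body_slice: np.ndarray, spacing: tuple[float, float]
) -> Contour:
    """Trace the outer skin line of a binary axial slice in mm coordinates.

    Uses marching squares at iso-level 0.5; when the mask yields several
    closed contours the one enclosing the largest area is the skin line.
    The raw marching-squares polygon of a binary mask is a 45-degree
    staircase whose length overestimates a smooth boundary by ~5-6%, so
    contours long enough to carry it (>= 16 vertices) are regularized
    with a 5-point circular moving average of the vertices, which
    recovers sub-pixel boundary placement (residual length error < 0.5%
    for disc/ellipse masks at clinical resolutions).  Short contours are
    left exact, so degenerate cases keep their lattice geometry.

    Parameters
    ----------
    body_slice:
        2D binary mask (y, x).
    spacing:
        (dy, dx) in mm.

    Raises
    ------
    DataError
        If the mask is empty or produces no closed contour (clipped mask).
    """
    mask = np.asarray(body_slice, dtype=float)
    if not mask.any():
        raise DataError("empty slice mask: no contour")
    contours = measure.find_contours(mask, level=0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise DataError("no closed contour (mask clipped at image border?)")
    best = max(closed, key=_shoelace_area)
    dy, dx = spacing
    vertices = best[:-1] * np.array([dy, dx])  # drop duplicated end vertex
    if len(vertices) >= _SMOOTH_MIN_VERTICES:
        vertices = _smooth_closed(vertices, _SMOOTH_HALF_WINDOW)
    return Contour(vertices=vertices, closed=True)


def perimeter_cm(c: Contour, ndigits: int | None = 1) -> float:
    """Circumference of a closed contour in cm (default: reported to 0.1 cm).

    Pass ``ndigits=None`` for the unrounded value.
    """
    if not c.closed:
        raise DataError("perimeter is defined only for closed contours")
    p = c.perimeter_mm() / 10.0
    return p if ndigits is None else round(p, ndigits)


def check_fov(body_slice: np.ndarray) -> bool:
    """True iff the slice is evaluable: no mask pixel on the image border."""
    m = np.asarray(body_slice, dtype=bool)
    return not (m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


@dataclass
class PipelineConfig:
    """Tunable knobs of the measurement pipeline (HU thresholds, landmark
    band, gap length)."""

    body_threshold_hu: float = seg.DEFAULT_BODY_THRESHOLD_HU
    bone_threshold_hu: float = seg.DEFAULT_BONE_THRESHOLD_HU
    min_bone_component_mm3: float = seg.DEFAULT_MIN_BONE_COMPONENT_MM3
    central_fraction: float = lm.DEFAULT_CENTRAL_FRACTION
    min_gap_slices: int = lm.DEFAULT_MIN_GAP_SLICES


def measure_wc(vol: CTVolume, config: PipelineConfig | None = None) -> MeasurementReport:
    """Run the full pipeline on one canonical CT volume.

    Stages: body segmentation -> bone segmentation -> AP bone projection
    -> waist-range landmarking -> FOV check on the mid-waist slice ->
    outer-contour extraction -> perimeter in cm.  Failure modes never
    propagate as exceptions; they are folded into the report status.
    """
    cfg = config or PipelineConfig()
    wr: WaistRange | None = None
    try:
        body = seg.segment_body(vol, cfg.body_threshold_hu)
        logger.info("body mask: %d voxels", int(body.voxels.sum()))
        bone = seg.segment_bone(vol, cfg.bone_threshold_hu, cfg.min_bone_component_mm3)
        logger.info("bone mask: %d voxels", int(bone.voxels.sum()))
        proj = lm.project_bone_ap(bone)
        wr = lm.find_waist_range(
            proj, body, cfg.central_fraction, cfg.min_gap_slices
        )
        logger.info(
            "waist range: rib %d, iliac %d, mid %d",
            wr.z_lowest_rib, wr.z_highest_iliac, wr.z_mid,
        )
        mid_slice = body.voxels[wr.z_mid]
        if not check_fov(mid_slice):
            raise NonEvaluable(
                "skin mask discontinuity at mid-waist: body exceeds the FOV"
            )
        contour = extract_outer_contour(mid_slice, vol.spacing[1:])
        wc = perimeter_cm(contour)
        return MeasurementReport(
            status=STATUS_SUCCESS,
            wc_cm=wc,
            z_mid=wr.z_mid,
            waist_range=wr,
            source=vol.source,
        )
    except NonEvaluable as exc:
        return MeasurementReport(
            status=STATUS_NON_EVALUABLE,
            reason=exc.reason,
            z_mid=wr.z_mid if wr else None,
            waist_range=wr,
            source=vol.source,
        )
    except TechnicalFailure as exc:
        return MeasurementReport(
            status=STATUS_TECHNICAL_FAILURE, reason=exc.reason, source=vol.source
        )
    except CtwaistError as exc:
        return MeasurementReport(
            status=STATUS_TECHNICAL_FAILURE, reason=str(exc), source=vol.source
        )


_SMOOTH_HALF_WINDOW = 2  # 5-point moving average
_SMOOTH_MIN_VERTICES = 16


def _smooth_closed(vertices: np.ndarray, half_window: int) -> np.ndarray:
    acc = np.zeros_like(vertices)
    for k in range(-half_window, half_window + 1):
        acc += np.roll(vertices, k, axis=0)
    return acc / (2 * half_window + 1)


def _shoelace_area(contour: np.ndarray) -> float:
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(float(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1))))
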