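"""Body and bone masks from HU thresholding.

The waist pipeline needs exactly two masks: the filled *body* (skin)
mask, whose outer contour on an axial slice is the waist line, and the
*bone* mask, whose antero-posterior projection drives landmark
detection.  Both are produced by classical Hounsfield-unit thresholding
on noncontrast CT:

* body: HU above ``body_threshold_hu`` (default −400, the air/tissue
  boundary, robust to partial volume at 3 mm slices), restricted to the
  largest 3D connected component (suppresses the CT table and clothing),
  then 2D hole-filled per axial slice so lung and bowel gas become
  interior;
* bone: HU at or above ``bone_threshold_hu`` (default +200, cortical and
  dense trabecular bone on noncontrast CT), with connected components
  smaller than ``min_bone_component_mm3`` removed as noise.

Hole filling is deliberately per-slice: a 3D fill would incorrectly
close the open inferior end of a torso that extends past the scan range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DataError
from .volume_io import CTVolume

DEFAULT_BODY_THRESHOLD_HU = -400.0
DEFAULT_BONE_THRESHOLD_HU = 200.0
DEFAULT_MIN_BONE_COMPONENT_MM3 = 500.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity in 3D


@dataclass
class MaskVolume:
    """Binary mask on the same canonical (z, y, x) grid as its source volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    kind: str  # "body" | "bone"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise DataError("mask must be 3D")
        if self.kind not in ("body", "bone"):
            raise DataError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> None:
        """Export as a uint8 NIfTI on the same grid."""
        from .volume_io import write_volume

        vol = CTVolume.__new__(CTVolume)
        vol.voxels = self.voxels.astype(np.float32)
        vol.spacing = self.spacing
        vol.source = f"<{self.kind} mask>"
        vol.canonical = True
        write_volume(vol, path)


def segment_body(
    vol: CTVolume, body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU
) -> MaskVolume:
    """Segment the filled body (skin) mask.

    Raises
    ------
    DataError
        If no voxel exceeds the threshold ("no body found").
    """
    raw = vol.voxels > body_threshold_hu
    if not raw.any():
        raise DataError(f"no body found: no voxel above {body_threshold_hu} HU")
    labels, n = ndimage.label(raw, structure=_STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        body = labels == (1 + int(np.argmax(sizes)))
    else:
        body = raw
    filled = np.empty_like(body)
    for z in range(body.shape[0]):
        filled[z] = ndimage.binary_fill_holes(body[z])
    return MaskVolume(filled, vol.spacing, kind="body")


def segment_bone(
    vol: CTVolume,
    bone_threshold_hu: float = DEFAULT_BONE_THRESHOLD_HU,
    min_bone_component_mm3: float = DEFAULT_MIN_BONE_COMPONENT_MM3,
) -> MaskVolume:
    """Segment the bone mask (HU >= threshold, small components dropped).

    An empty bone mask is legal; landmark detection downstream reports a
    technical failure rather than this function erroring.
    """
    raw = vol.voxels >= bone_threshold_hu
    if raw.any() and min_bone_component_mm3 > 0:
        voxel_mm3 = float(np.prod(vol.spacing))
        min_voxels = int(np.ceil(min_bone_component_mm3 / voxel_mm3))
        if min_voxels > 1:
            labels, n = ndimage.label(raw, structure=_STRUCT_26)
            if n:
                sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
                keep = np.flatnonzero(sizes >= min_voxels) + 1
                raw = np.isin(labels, keep)
    return MaskVolume(raw, vol.spacing, kind="bone")
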