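"""Mid-waist slice selection from the bone projection.

The waist level is defined anatomically: the axial slice midway along z
between the *lowest rib margin* and the *highest iliac crest margin*.
Both landmarks are found on the antero-posterior (coronal) maximum-
intensity projection of the bone mask, where the rib cage and the pelvic
wings appear as lateral bone while the vertebral column and sacrum stay
near the body midline.

Concretely, for each axial level z we ask whether any projected bone
pixel lies *laterally* — outside a central exclusion band (default 30%
of the body width, centred on the body midline).  Ribs and iliac wings
set this flag; the spine does not.  The waist is the longest run of
consecutive z levels with no lateral bone that is bracketed by lateral
bone above (ribs) and below (iliac wings).  The slice midway through
that gap, rounding toward inferior, is the measurement level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TechnicalFailure
from .segmentation import MaskVolume

DEFAULT_CENTRAL_FRACTION = 0.30
DEFAULT_MIN_GAP_SLICES = 2
# Slices whose body area falls below this fraction of the median are
# treated as scan ends and excluded from the landmark search.
_MIN_AREA_FRACTION = 0.10


@dataclass(frozen=True)
class CoronalProjection:
    """Antero-posterior max projection of a bone mask, indexed (z, x)."""

    pixels: np.ndarray  # 2D bool, (n_z, n_x)
    spacing: tuple[float, float]  # (dz, dx) mm


@dataclass(frozen=True)
class WaistRange:
    """z indices bounding the waist and the selected mid-waist slice.

    ``z_highest_iliac <= z_mid <= z_lowest_rib`` always holds, with
    ``z_highest_iliac < z_lowest_rib`` strictly (z increases superiorly).
    """

    z_lowest_rib: int
    z_highest_iliac: int
    z_mid: int

    def __post_init__(self) -> None:
        if not (self.z_highest_iliac < self.z_lowest_rib):
            raise ValueError("iliac crest must lie inferior to the lowest rib")
        if not (self.z_highest_iliac <= self.z_mid <= self.z_lowest_rib):
            raise ValueError("z_mid must lie within the waist range")


def project_bone_ap(bone: MaskVolume) -> CoronalProjection:
    """Collapse the bone mask along y (max projection) into a (z, x) image."""
    dz, _, dx = bone.spacing
    return CoronalProjection(bone.voxels.any(axis=1), (dz, dx))


def find_waist_range(
    proj: CoronalProjection,
    body: MaskVolume,
    central_fraction: float = DEFAULT_CENTRAL_FRACTION,
    min_gap_slices: int = DEFAULT_MIN_GAP_SLICES,
) -> WaistRange:
    """Locate the rib/iliac gap on the projection and its midpoint slice.

    Parameters
    ----------
    proj:
        AP bone projection (z, x).
    body:
        Body mask on the same grid; supplies the midline and half-width
        used to build the central exclusion band, and the valid z range.
    central_fraction:
        Width of the exclusion band as a fraction of the full body width.
    min_gap_slices:
        Minimum run length (in slices) for a gap to qualify.

    Raises
    ------
    TechnicalFailure
        If there is no qualifying gap: lateral bone continuous in z, bone
        only above or only below, or no bone at all.
    """
    areas = body.voxels.sum(axis=(1, 2))
    present = areas > 0
    if not present.any():
        raise TechnicalFailure("empty body mask")
    median_area = float(np.median(areas[present]))
    valid = areas > _MIN_AREA_FRACTION * median_area
    zs = np.flatnonzero(valid)

    # Body midline and half-width from per-slice x extents, averaged.
    centers, halfwidths = [], []
    for z in zs:
        cols = np.flatnonzero(body.voxels[z].any(axis=0))
        centers.append(0.5 * (cols[0] + cols[-1]))
        halfwidths.append(0.5 * (cols[-1] - cols[0]))
    x_c = float(np.mean(centers))
    w = float(np.mean(halfwidths))

    n_x = proj.pixels.shape[1]
    x_idx = np.arange(n_x)
    lateral_cols = np.abs(x_idx - x_c) > central_fraction * w

    lateral_bone = np.zeros(body.shape[0], dtype=bool)
    lateral_bone[zs] = proj.pixels[np.ix_(zs, np.flatnonzero(lateral_cols))].any(axis=1)

    if not lateral_bone[zs].any():
        raise TechnicalFailure("no lateral bone found on projection")

    gaps = _qualifying_gaps(lateral_bone, zs, min_gap_slices)
    if not gaps:
        raise TechnicalFailure("no waist gap between rib and iliac bone")

    # Longest gap; ties go to the more superior one (abutting the ribs).
    start, end = max(gaps, key=lambda g: (g[1] - g[0], g[0]))
    z_highest_iliac = start - 1
    z_lowest_rib = end + 1
    z_mid = (z_lowest_rib + z_highest_iliac) // 2  # floor => inferior tie-break
    return WaistRange(z_lowest_rib, z_highest_iliac, z_mid)


def _qualifying_gaps(
    lateral_bone: np.ndarray, valid_zs: np.ndarray, min_gap: int
) -> list[tuple[int, int]]:
    """Maximal runs [start, end] of valid z without lateral bone, bracketed
    by lateral bone below and above within the valid range."""
    lo, hi = int(valid_zs[0]), int(valid_zs[-1])
    gaps: list[tuple[int, int]] = []
    z = lo
    while z <= hi:
        if lateral_bone[z]:
            z += 1
            continue
        start = z
        while z <= hi and not lateral_bone[z]:
            z += 1
        end = z - 1
        below = lateral_bone[lo:start].any()
        above = lateral_bone[end + 1 : hi + 1].any()
        if below and above and (end - start + 1) >= min_gap:
            gaps.append((start, end))
    return gaps
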