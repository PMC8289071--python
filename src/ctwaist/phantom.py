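"""Synthetic CT phantoms and paired-measurement cohorts.

Two kinds of synthetic data back the test battery and the worked
examples:

**Torso phantoms** — 3D HU volumes with an elliptical soft-tissue torso,
rib arcs painted laterally over a superior z range, iliac wings (plus a
central sacrum block) over an inferior z range, an optional spine
column, and optional Gaussian HU noise.  Because the geometry is
painted, the ground truth is known exactly: the waist gap bounds are the
painted rib/iliac z limits and the true circumference is the Ramanujan
perimeter of the mid-waist ellipse.  Rib arcs are confined to the
lateral parts of the torso so the projection-gap landmarking sees the
geometry it assumes; a ``hard_mode`` flag adds faint posterior rib tails
crossing the midline to stress the central exclusion band.

**Paired cohorts** — per-subject rows (sex, tape-measured WC, CT WC,
BMI) with the offset/noise structure typical of supine-CT versus
standing-tape comparisons: CT WC equals manual WC plus a sex-specific
systematic offset plus Gaussian noise, and BMI is an affine function of
manual WC calibrated so the conventional 85 cm (women) / 90 cm (men)
cutoffs correspond to BMI 25 kg/m².  Defaults reproduce a 757-subject
health-screening cohort: manual WC ~ N(80.4, 8.5) cm in women and
N(88.9, 7.6) cm in men; CT offsets 5.1 ± 4.3 cm and 6.8 ± 3.7 cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .landmarks import WaistRange
from .volume_io import CTVolume

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_BONE = 700.0


def ellipse_perimeter_mm(a_mm: float, b_mm: float) -> float:
    """Ramanujan's approximation to the ellipse perimeter (error < 1e-6
    relative for the aspect ratios used here)."""
    a, b = float(a_mm), float(b_mm)
    return np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))


@dataclass
class PhantomSpec:
    """Geometry and noise description of a torso phantom.

    z ranges are inclusive ``(z_min, z_max)`` index pairs with z
    increasing superiorly; ribs occupy the superior range and iliac
    wings the inferior one, leaving a bone-free waist gap between
    ``iliac_z[1]`` and ``rib_z[0]``.
    """

    n_slices: int = 64
    in_plane_shape: tuple[int, int] = (256, 256)  # (ny, nx)
    spacing: tuple[float, float, float] = (3.0, 1.5, 1.5)  # (dz, dy, dx) mm
    semi_axes_mm: tuple[float, float] = (150.0, 100.0)  # (a=half-width x, b=half-depth y)
    semi_axes_profile: np.ndarray | None = None  # optional per-slice (a, b) mm
    rib_z: tuple[int, int] = (40, 58)
    iliac_z: tuple[int, int] = (6, 24)
    spine: bool = True
    hu_air: float = HU_AIR
    hu_soft: float = HU_SOFT
    hu_bone: float = HU_BONE
    noise_sd_hu: float = 0.0
    fov_crop_mm: float | None = None
    table_bar: bool = False
    hard_mode: bool = False
    min_gap_slices: int = 2
    seed: int = 0

    def profile(self) -> np.ndarray:
        if self.semi_axes_profile is not None:
            prof = np.asarray(self.semi_axes_profile, dtype=float)
            if prof.shape != (self.n_slices, 2):
                raise DataError(
                    f"semi_axes_profile must have shape ({self.n_slices}, 2)"
                )
            return prof
        return np.tile(np.asarray(self.semi_axes_mm, dtype=float), (self.n_slices, 1))

    def validate(self) -> None:
        if self.rib_z[0] - self.iliac_z[1] - 1 < self.min_gap_slices:
            raise DataError(
                "phantom spec leaves no waist gap: rib_z[0] must exceed "
                f"iliac_z[1] by more than min_gap_slices={self.min_gap_slices}"
            )
        if not (0 <= self.iliac_z[0] <= self.iliac_z[1] < self.rib_z[0]
                <= self.rib_z[1] < self.n_slices):
            raise DataError("rib/iliac z ranges out of order or out of bounds")
        ny, nx = self.in_plane_shape
        a, b = self.profile().max(axis=0)
        if self.fov_crop_mm is None:
            if 2 * a >= nx * self.spacing[2] or 2 * b >= ny * self.spacing[1]:
                raise DataError("torso does not fit inside the FOV")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    waist_range: WaistRange
    wc_cm: float
    semi_axes_mm: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "z_lowest_rib": self.waist_range.z_lowest_rib,
            "z_highest_iliac": self.waist_range.z_highest_iliac,
            "z_mid": self.waist_range.z_mid,
            "wc_cm": self.wc_cm,
            "semi_axes_mm": list(self.semi_axes_mm),
        }


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Paint a torso phantom and return it with its ground truth.

    The true waist range is ``(z_lowest_rib=rib_z[0], z_highest_iliac=
    iliac_z[1])`` with the midpoint floored toward inferior; the true
    circumference is the Ramanujan perimeter of the mid-waist ellipse.
    """
    spec.validate()
    prof = spec.profile()
    nz = spec.n_slices
    ny, nx = spec.in_plane_shape
    dz, dy, dx = spec.spacing

    vol = np.full((nz, ny, nx), spec.hu_air, dtype=np.float32)
    yc_mm, xc_mm = ny * dy / 2.0, nx * dx / 2.0
    y_mm = (np.arange(ny) + 0.5) * dy - yc_mm
    x_mm = (np.arange(nx) + 0.5) * dx - xc_mm
    Y, X = np.meshgrid(y_mm, x_mm, indexing="ij")

    for z in range(nz):
        a, b = prof[z]
        torso = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        vol[z][torso] = spec.hu_soft

    rng = np.random.default_rng(spec.seed)

    def paint_ring(z: int, lateral_only: bool, frac: float = 0.85,
                   thickness_mm: float = 6.0) -> None:
        a, b = prof[z]
        r_out = (X / (frac * a)) ** 2 + (Y / (frac * b)) ** 2
        a_in = frac * a - thickness_mm
        b_in = frac * b - thickness_mm
        ring = (r_out <= 1.0) & ((X / a_in) ** 2 + (Y / b_in) ** 2 > 1.0)
        if lateral_only:
            ring &= np.abs(X) > 0.5 * a
        vol[z][ring] = spec.hu_bone

    for z in range(spec.rib_z[0], spec.rib_z[1] + 1):
        paint_ring(z, lateral_only=True)
        if spec.hard_mode:
            # faint posterior tails crossing the midline
            a, b = prof[z]
            tail = (np.abs(X) <= 0.2 * a) & (Y < -0.7 * b) & (
                (X / a) ** 2 + (Y / b) ** 2 <= 1.0
            )
            vol[z][tail] = spec.hu_bone
    for z in range(spec.iliac_z[0], spec.iliac_z[1] + 1):
        paint_ring(z, lateral_only=True, frac=0.8, thickness_mm=10.0)
        # sacrum: central posterior block, inside the exclusion band
        a, b = prof[z]
        sac = (np.abs(X) <= 0.15 * a) & (Y < -0.4 * b) & (Y > -0.8 * b)
        vol[z][sac] = spec.hu_bone
    if spec.spine:
        a0, b0 = prof[0]
        spine_col = (np.abs(X) <= 18.0) & (np.abs(Y + 0.5 * b0) <= 18.0)
        for z in range(nz):
            vol[z][spine_col] = spec.hu_bone

    if spec.table_bar:
        # flat bar under the body, separated by air so the largest-component
        # rule removes it from the body mask
        bar_rows = slice(1, 4)
        vol[:, bar_rows, :] = 100.0

    if spec.noise_sd_hu > 0:
        vol += rng.normal(0.0, spec.noise_sd_hu, size=vol.shape).astype(np.float32)

    if spec.fov_crop_mm is not None:
        keep = int(round(spec.fov_crop_mm / dx))
        if keep < nx:
            lo = (nx - keep) // 2
            vol = np.ascontiguousarray(vol[:, :, lo : lo + keep])

    z_lr, z_hi = spec.rib_z[0], spec.iliac_z[1]
    z_mid = (z_lr + z_hi) // 2
    wr = WaistRange(z_lowest_rib=z_lr, z_highest_iliac=z_hi, z_mid=z_mid)
    a_mid, b_mid = prof[z_mid]
    truth = PhantomTruth(
        waist_range=wr,
        wc_cm=ellipse_perimeter_mm(a_mid, b_mid) / 10.0,
        semi_axes_mm=(float(a_mid), float(b_mid)),
    )
    return CTVolume(vol, spec.spacing, source=f"<phantom seed={spec.seed}>"), truth


@dataclass
class CohortParams:
    """Distributional parameters of the paired-measurement simulator.

    Units: WC in cm, BMI in kg/m², offsets/SDs in cm.
    """

    prop_female: float = 326 / 757
    manual_mean: dict = field(default_factory=lambda: {"F": 80.4, "M": 88.9})
    manual_sd: dict = field(default_factory=lambda: {"F": 8.5, "M": 7.6})
    ct_offset: dict = field(default_factory=lambda: {"F": 5.1, "M": 6.8})
    ct_sd: dict = field(default_factory=lambda: {"F": 4.3, "M": 3.7})
    manual_cutoff: dict = field(default_factory=lambda: {"F": 85.0, "M": 90.0})
    bmi_slope: dict = field(default_factory=lambda: {"F": 0.35, "M": 0.34})
    bmi_at_cutoff: float = 25.0
    bmi_sd: float = 1.2
    # longitudinal second visit (optional)
    delta_manual_mean: float = -1.4
    delta_manual_sd: float = 4.0
    delta_ct_bias: float = -0.3
    delta_ct_sd: float = 4.5

    def validate(self) -> None:
        if not (0.0 < self.prop_female < 1.0):
            raise DataError("prop_female must be strictly between 0 and 1")
        for d in (self.manual_sd, self.ct_sd):
            if any(v < 0 for v in d.values()):
                raise DataError("standard deviations must be non-negative")
        if self.bmi_sd < 0 or self.delta_manual_sd < 0 or self.delta_ct_sd < 0:
            raise DataError("standard deviations must be non-negative")


WC_PLAUSIBLE = (50.0, 140.0)
BMI_PLAUSIBLE = (14.0, 45.0)


def generate_cohort(
    n: int,
    params: CohortParams | None = None,
    seed: int = 0,
    longitudinal: bool = False,
) -> pd.DataFrame:
    """Simulate a paired WC cohort as a tidy DataFrame.

    Columns: ``id, sex, visit, wc_manual_cm, wc_ct_cm, bmi_kg_m2``.
    With ``longitudinal=True`` every subject gets a second row
    (``visit=0``, the earlier visit) whose manual WC differs by
    N(delta_manual_mean, delta_manual_sd) and whose CT WC change tracks
    the manual change up to a small bias.

    Values are clipped to plausible human ranges (WC 50–140 cm,
    BMI 14–45 kg/m²).
    """
    if n < 2:
        raise DataError("cohort needs n >= 2")
    p = params or CohortParams()
    p.validate()
    rng = np.random.default_rng(seed)

    sex = np.where(rng.random(n) < p.prop_female, "F", "M")
    wc_manual = np.empty(n)
    wc_ct = np.empty(n)
    bmi = np.empty(n)
    for s in ("F", "M"):
        idx = sex == s
        m = idx.sum()
        wc_manual[idx] = rng.normal(p.manual_mean[s], p.manual_sd[s], m)
        wc_ct[idx] = wc_manual[idx] + p.ct_offset[s] + rng.normal(0, p.ct_sd[s], m)
        bmi[idx] = (
            p.bmi_at_cutoff
            + p.bmi_slope[s] * (wc_manual[idx] - p.manual_cutoff[s])
            + rng.normal(0, p.bmi_sd, m)
        )
    wc_manual = np.clip(wc_manual, *WC_PLAUSIBLE)
    wc_ct = np.clip(wc_ct, *WC_PLAUSIBLE)
    bmi = np.clip(bmi, *BMI_PLAUSIBLE)

    frames = [
        pd.DataFrame(
            {
                "id": np.arange(n),
                "sex": sex,
                "visit": 1,
                "wc_manual_cm": wc_manual,
                "wc_ct_cm": wc_ct,
                "bmi_kg_m2": bmi,
            }
        )
    ]
    if longitudinal:
        d_manual = rng.normal(p.delta_manual_mean, p.delta_manual_sd, n)
        d_ct = d_manual + rng.normal(p.delta_ct_bias, p.delta_ct_sd, n)
        prev = frames[0].copy()
        prev["visit"] = 0
        prev["wc_manual_cm"] = np.clip(wc_manual - d_manual, *WC_PLAUSIBLE)
        prev["wc_ct_cm"] = np.clip(wc_ct - d_ct, *WC_PLAUSIBLE)
        frames.append(prev)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["id", "visit"]).reset_index(drop=True)
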