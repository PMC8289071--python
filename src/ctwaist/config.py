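"""Run configuration: documented defaults, YAML loading, strict keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import landmarks as lm
from . import segmentation as seg
from .errors import DataError
from .waist import PipelineConfig


@dataclass
class RunConfig:
    """All tunables of a run, materialized with documented defaults.

    ``cutoffs`` holds the classification cutoffs (cm for WC, kg/m² for
    BMI) used by the validate command.
    """

    body_threshold_hu: float = seg.DEFAULT_BODY_THRESHOLD_HU
    bone_threshold_hu: float = seg.DEFAULT_BONE_THRESHOLD_HU
    min_bone_component_mm3: float = seg.DEFAULT_MIN_BONE_COMPONENT_MM3
    central_fraction: float = lm.DEFAULT_CENTRAL_FRACTION
    min_gap_slices: int = lm.DEFAULT_MIN_GAP_SLICES
    cutoffs: dict = field(
        default_factory=lambda: {
            "wc_ct_women_cm": 91.7,
            "wc_ct_men_cm": 96.7,
            "wc_manual_women_cm": 85.0,
            "wc_manual_men_cm": 90.0,
            "bmi_kg_m2": 25.0,
        }
    )
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Defaults < YAML file < explicit overrides; unknown keys rejected."""
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise DataError(f"config file {path} must contain a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "cutoffs" in data:
            merged = cls().cutoffs
            merged.update(data["cutoffs"])
            cfg.cutoffs = merged
        return cfg

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            body_threshold_hu=self.body_threshold_hu,
            bone_threshold_hu=self.bone_threshold_hu,
            min_bone_component_mm3=self.min_bone_component_mm3,
            central_fraction=self.central_fraction,
            min_gap_slices=self.min_gap_slices,
        )

    def to_dict(self) -> dict:
        return asdict(self)
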