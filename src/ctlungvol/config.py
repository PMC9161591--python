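"""Run configuration shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class RunConfig:
    """All tunables of one pipeline run, serialisable to/from YAML.

    The config hash stamped into every output lets a reader confirm two
    artifacts came from the same settings.
    """

    hu_low: float = -1000.0
    hu_high: float = 0.0
    body_threshold_hu: float = -500.0
    min_component_ml: float = 1.0
    airway_max_fraction: float = 0.05
    slice_thickness_mm: float | None = None
    equation_set: str | None = None  # path to YAML; None = bundled placeholder
    gap_variant: str = "original"  # or "modified"
    modified_gap_direct_threshold: bool = False
    cutoff_mode: str = "median"  # or "fixed"
    lv_cutoff_pct: float | None = None
    crp_cutoff_mg_dl: float | None = None
    survival_covariates: list[str] = field(
        default_factory=lambda: ["std_lv_total_pct", "crp"]
    )
    time_unit: str = "years"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hu_low", "hu_high", "body_threshold_hu"):
            v = getattr(self, name)
            if not HU_MIN <= v <= HU_MAX:
                raise ValueError(
                    f"{name}={v} outside physical HU range [{HU_MIN}, {HU_MAX}]"
                )
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be below hu_high")
        if self.gap_variant not in ("original", "modified"):
            raise ValueError("gap_variant must be 'original' or 'modified'")
        if self.cutoff_mode not in ("median", "fixed"):
            raise ValueError("cutoff_mode must be 'median' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}
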