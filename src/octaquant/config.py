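"""Pipeline configuration: a validated, YAML-round-trippable parameter set."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .flowdeficit import DEFAULT_SIZE_THRESHOLDS_UM2
from .perfusion import CONVENTIONS
from .vessels import DEFAULT_HESSIAN_SIGMAS, DEFAULT_MIN_CALIBER_UM, DEFAULT_N_ORIENTATIONS


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Every field is validated against the preconditions of the stage that
    consumes it; ``load``/``save`` round-trip through YAML and ``hash``
    fingerprints the configuration for output provenance.
    """

    scale_um_per_px: float = 5.859375  # 3 mm field over 512 px
    hessian_sigmas_px: tuple[float, ...] = DEFAULT_HESSIAN_SIGMAS
    gabor_orientations: int = DEFAULT_N_ORIENTATIONS
    threshold_method: str = "otsu"
    min_caliber_um: float = DEFAULT_MIN_CALIBER_UM
    region_outer_radius_mm: float | None = None  # None -> full field minus FAZ
    circularity_convention: str = "literal"
    cc_threshold_k: float = 1.0
    fv_thresholds_um2: tuple[float, ...] = DEFAULT_SIZE_THRESHOLDS_UM2
    logmar_per_line: float = 0.1
    ladder: str = "dr_progression"  # or "va_decline"
    seed: int = 0
    output_dir: str = "octaquant_out"
    n_simulated_images: int = 4
    cohort_n_patients: int = 192

    def __post_init__(self) -> None:
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if len(self.hessian_sigmas_px) == 0:
            raise ValueError("need at least one Hessian scale")
        if self.gabor_orientations < 1:
            raise ValueError("need at least one Gabor orientation")
        if self.threshold_method not in ("otsu", "local"):
            raise ValueError("threshold_method must be 'otsu' or 'local'")
        if not self.min_caliber_um > 0:
            raise ValueError("min_caliber_um must be positive")
        if self.region_outer_radius_mm is not None and not self.region_outer_radius_mm > 0:
            raise ValueError("region_outer_radius_mm must be positive or None")
        if self.circularity_convention not in CONVENTIONS:
            raise ValueError(f"circularity_convention must be one of {CONVENTIONS}")
        if any(t <= 0 for t in self.fv_thresholds_um2):
            raise ValueError("flow-void size thresholds must be positive")
        if self.ladder not in ("dr_progression", "va_decline"):
            raise ValueError("ladder must be 'dr_progression' or 'va_decline'")

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = asdict(self)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("hessian_sigmas_px", "fv_thresholds_um2"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        """Short stable fingerprint of the configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
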