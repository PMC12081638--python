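"""Run configuration and deterministic run manifests."""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["RunConfig", "write_manifest", "round_sig", "json_ready"]

VALID_STAGES = (
    "synth_plate",
    "synergy",
    "synth_image",
    "colonies",
    "synth_flow",
    "flow",
    "synth_counts",
    "dge",
    "enrich",
    "graph",
)


@dataclass
class RunConfig:
    """Shared parameters for a pipeline run.

    Holds the screen-wide constants: the FDR level (0.01), the per-experiment
    synergy category boundaries (2, 5), the observed-viability floor, the
    sub-G1 gate factor and the colony-detection parameter block.
    """

    seed: int = 0
    out_dir: str = "results"
    stages: list[str] = field(default_factory=lambda: ["synth_plate", "synergy"])
    fdr: float = 0.01
    synergy_thresholds: tuple[float, float] = (2.0, 5.0)
    observed_floor: float = 1e-4
    gate_factor: float = 0.8
    colony_params: dict = field(
        default_factory=lambda: {
            "rolling_ball_radius_px": 115,
            "gaussian_sigma_px": 2,
            "min_area_um2": 5000,
            "min_circularity": 0.5,
            "threshold": "otsu",
        }
    )
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must lie in (0, 1), got {self.fdr}")
        lower, upper = self.synergy_thresholds
        if not lower < upper:
            raise ValueError(f"synergy thresholds must be ordered, got {self.synergy_thresholds}")
        if self.observed_floor <= 0:
            raise ValueError("observed_floor must be > 0")
        if not 0 < self.gate_factor < 1:
            raise ValueError("gate_factor must lie in (0, 1)")
        unknown = [s for s in self.stages if s not in VALID_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid stages: {list(VALID_STAGES)}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from TOML or JSON (chosen by extension; both are equivalent)."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        if "synergy_thresholds" in data:
            data["synergy_thresholds"] = tuple(data["synergy_thresholds"])
        return cls(**data).validate()


def round_sig(value: float, digits: int = 12) -> float:
    """Round to a number of significant digits (stable float serialization)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, digits - 1 - int(math.floor(math.log10(abs(value)))))


def json_ready(obj, digits: int = 12):
    """Recursively convert to JSON-serializable values, rounding floats."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): json_ready(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_ready(v, digits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round_sig(float(obj), digits)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [json_ready(v, digits) for v in obj.tolist()]
    return obj


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_manifest(
    config: RunConfig,
    out_dir: str | Path,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
) -> Path:
    """Write a run manifest sufficient to re-execute the run exactly.

    Records the seed, all parameters, package and interpreter versions, and a
    SHA-256 digest of every input and output file.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "parameters": json_ready(asdict(config)),
        "versions": {
            "radscreen": __version__,
            "python": platform.python_version(),
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (outputs or {}).items()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
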