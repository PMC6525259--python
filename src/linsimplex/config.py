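"""Run configuration and reproducible seed fan-out."""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed: one global seed fans out via a hash of the
    stage name, so stages can be rerun independently yet reproducibly."""
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Every knob of the deconvolution pipeline, serializable to YAML/JSON.

    A saved config re-run on the same input reproduces outputs
    bit-identically.
    """

    # gene filtering
    filter_method: str = "permutation"  # permutation | threshold | none
    n_iterations: int = 1_000
    alpha: float = 0.01
    bonferroni: bool = False
    k1: int = 1
    threshold1: float = 0.75
    k2: int = 10
    threshold2: float = 0.25
    # cell-type number
    k_types: int | None = None  # None = auto from the scree
    cumulative_threshold: float = 0.95
    # corner identification
    corner_method: str = "sisal"  # sisal | mvsa | vca
    tau_grid: list[float] | None = None  # None = 2^-20..2^0
    use_smart_corners: bool = False
    max_combinations: int = 256
    n_restarts: int = 3
    g_top: int = 100
    # signatures
    signature_genes: str = "all"  # all | filtered
    # randomness
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(data)

    def resolved_tau_grid(self) -> np.ndarray:
        if self.tau_grid is None:
            return np.exp2(np.arange(-20, 1, dtype=float))
        return np.asarray(self.tau_grid, dtype=float)

    def validate(self) -> None:
        if self.filter_method not in ("permutation", "threshold", "none"):
            raise ValueError(f"unknown filter_method {self.filter_method!r}")
        if self.corner_method not in ("sisal", "mvsa", "vca"):
            raise ValueError(f"unknown corner_method {self.corner_method!r}")
        if self.signature_genes not in ("all", "filtered"):
            raise ValueError(f"unknown signature_genes {self.signature_genes!r}")
        if self.k_types is not None and self.k_types < 2:
            raise ValueError("k_types must be >= 2 (no mixture otherwise)")
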