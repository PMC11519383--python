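"""Pipeline configuration: validated blocks, TOML/JSON loading, hashing."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .kinetics import FIT_VARIABLES
from .preprocess import ISOLATION_MODES, ConfigError

__all__ = ["PreprocessConfig", "AlignmentConfig", "KineticsConfig",
           "PipelineConfig"]

VERSION = "0.1.0"


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; known: {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class PreprocessConfig:
    mode: str = "a_plus_negb"
    p_low: float = 1.0
    p_high: float = 99.0
    smooth_sigma: float = 1.0
    zero_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ISOLATION_MODES:
            raise ConfigError(f"mode must be one of {ISOLATION_MODES}")
        if not 0 <= self.p_low < self.p_high <= 100:
            raise ConfigError("require 0 ≤ p_low < p_high ≤ 100")
        if self.smooth_sigma < 0 or not 0 <= self.zero_floor <= 1:
            raise ConfigError("smooth_sigma ≥ 0 and zero_floor ∈ [0,1]")


@dataclass(frozen=True)
class AlignmentConfig:
    r_min: float = 0.05
    r_max: float = 0.45
    n_bins: int = 180

    def __post_init__(self) -> None:
        if not 0 <= self.r_min < self.r_max <= 0.5:
            raise ConfigError("require 0 ≤ r_min < r_max ≤ 0.5")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be ≥ 2")


@dataclass(frozen=True)
class KineticsConfig:
    fit_variable: str = "area"

    def __post_init__(self) -> None:
        if self.fit_variable not in FIT_VARIABLES:
            raise ConfigError(f"fit_variable must be one of {FIT_VARIABLES}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration; unknown keys are rejected on load."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    seed: int = 0
    version: str = VERSION

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - {"preprocess", "alignment", "kinetics",
                               "seed", "version"}
        if unknown:
            raise ConfigError(f"unknown config sections/keys: {sorted(unknown)}")
        return cls(
            preprocess=_from_dict(PreprocessConfig, data.get("preprocess", {})),
            alignment=_from_dict(AlignmentConfig, data.get("alignment", {})),
            kinetics=_from_dict(KineticsConfig, data.get("kinetics", {})),
            seed=int(data.get("seed", 0)),
            version=str(data.get("version", VERSION)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_bytes()
        if path.suffix.lower() == ".json":
            data = json.loads(raw)
        else:
            try:
                data = tomllib.loads(raw.decode())
            except tomllib.TOMLDecodeError:
                data = json.loads(raw)  # JSON fallback
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
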