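"""Pipeline configuration: stain vectors, thresholds, K-means and rendering.

A flat TOML file can override any default; flag values from the CLI override
the file.  Invalid values are rejected at load time with the offending key
named, and a config round-trips losslessly through ``to_toml``/``from_toml``.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .clustering import INITIAL_CENTROIDS
from .stains import RUIFROK_DAB, RUIFROK_E, RUIFROK_H, StainBasis

Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the scoring pipeline with validated defaults."""

    h_vector: Vec3 = RUIFROK_H
    e_vector: Vec3 = RUIFROK_E
    dab_vector: Vec3 = RUIFROK_DAB
    tissue_od_threshold: float = 0.15
    kmeans_max_iter: int = 100
    kmeans_tol: float = 0.5
    kmeans_centroids: tuple[Vec3, Vec3, Vec3, Vec3] = INITIAL_CENTROIDS
    watermark_alpha: float = 0.35
    # what the K-means sees: the DAB single-stain rendering or the raw block
    cluster_input: str = "dab"
    background_intensity: int = 255

    def __post_init__(self):
        if not 0 < self.tissue_od_threshold:
            raise ValueError("tissue_od_threshold: must be > 0")
        if self.kmeans_max_iter < 1:
            raise ValueError("kmeans_max_iter: must be >= 1")
        if self.kmeans_tol <= 0:
            raise ValueError("kmeans_tol: must be > 0")
        if not 0.0 <= self.watermark_alpha <= 1.0:
            raise ValueError("watermark_alpha: must be in [0, 1]")
        if self.cluster_input not in ("dab", "raw"):
            raise ValueError("cluster_input: must be 'dab' or 'raw'")
        if not 1 <= self.background_intensity <= 255:
            raise ValueError("background_intensity: must be in [1, 255]")
        if len(self.kmeans_centroids) != 4:
            raise ValueError("kmeans_centroids: exactly four centroids required")
        for name in ("h_vector", "e_vector", "dab_vector"):
            v = getattr(self, name)
            if len(v) != 3:
                raise ValueError(f"{name}: must have three components")
        # validates invertibility; raises SingularBasisError on bad vectors
        self.stain_basis()

    def stain_basis(self) -> StainBasis:
        return StainBasis(h=tuple(self.h_vector), e=tuple(self.e_vector), dab=tuple(self.dab_vector))

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = {}
        for key, val in raw.items():
            if key.endswith("_vector"):
                val = tuple(float(x) for x in val)
            elif key == "kmeans_centroids":
                val = tuple(tuple(float(x) for x in c) for c in val)
            kwargs[key] = val
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config in {path}: {exc}") from exc

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            val = getattr(self, f.name)
            lines.append(f"{f.name} = {_toml_value(val)}")
        Path(path).write_text("\n".join(lines) + "\n")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with non-None keyword values replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self


def _toml_value(val) -> str:
    if isinstance(val, bool):
        return "true" if val else "false"
    if isinstance(val, (int, float)):
        return repr(val)
    if isinstance(val, str):
        return f'"{val}"'
    if isinstance(val, tuple):
        return "[" + ", ".join(_toml_value(v) for v in val) + "]"
    raise TypeError(f"cannot serialise {type(val)} to TOML")
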