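"""Run configuration: TOML input, CLI overrides, JSON run manifest.

A :class:`RunConfig` collects every tunable of a pipeline run — model
parameters, analysis periods, execution options, paths — with documented
defaults.  Configs are read from TOML (stdlib ``tomllib``); unknown keys are
rejected with a nearest-match hint.  The resolved effective config is written
as a JSON run manifest next to the outputs, so every run is reproducible from
its manifest alone.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .pet import PetParams
from .snow import SnowParams
from .soil import ModelParams, SoilParams

__all__ = ["RunConfig", "parse_and_validate", "write_manifest"]


@dataclass
class RunConfig:
    """Fully resolved configuration of a run; serialisable to/from plain dicts."""

    # paths
    forcing: str | None = None
    attributes: str | None = None
    output: str | None = None
    # snow
    snow_t50: float = 1.0
    snow_partition_width: float = 3.0
    snow_melt_factor: float = 4.0
    snow_melt_threshold: float = 0.0
    snow_partition: str = "linear"
    # soil / vegetation
    whc: float = 150.0                      # fallback when no WHC grid is given
    interception_fraction: float = 0.0
    aet_scalar_min: float = 0.0
    aet_scalar_max: float = 1.0
    # PET
    latent_heat: float = 2.45               # MJ/kg
    oudin_offset: float = 5.0               # degC
    # execution
    water_year: bool = False
    spin_up: int = 0
    chunk_rows: int | None = None
    chunk_cols: int | None = None
    store_float32: bool = True
    # analysis
    trend_start: int | None = None
    trend_end: int | None = None
    period1: tuple[int, int] = (1980, 1999)
    period2: tuple[int, int] = (2000, 2019)
    n_zones: int = 9
    # fixtures only
    seed: int = 0

    def model_params(self) -> ModelParams:
        return ModelParams(
            snow=SnowParams(self.snow_t50, self.snow_partition_width,
                            self.snow_melt_factor, self.snow_melt_threshold,
                            self.snow_partition),
            soil=SoilParams(self.whc, self.interception_fraction,
                            (self.aet_scalar_min, self.aet_scalar_max)),
            pet=PetParams(self.latent_heat, self.oudin_offset))

    def chunks(self):
        if self.chunk_rows and self.chunk_cols:
            return (self.chunk_rows, self.chunk_cols)
        return None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period1"] = list(d["period1"])
        d["period2"] = list(d["period2"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        clean = {}
        for key, value in d.items():
            if key not in known:
                hint = difflib.get_close_matches(key, known, n=1)
                suffix = f"; did you mean {hint[0]!r}?" if hint else ""
                raise KeyError(f"unknown config key {key!r}{suffix}")
            if key in ("period1", "period2"):
                value = tuple(int(v) for v in value)
            clean[key] = value
        cfg = cls(**clean)
        cfg._validate()
        return cfg

    def _validate(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if f.name in ("period1", "period2"):
                if len(v) != 2:
                    raise ValueError(f"{f.name} must be a (start, end) pair")
                continue
            if f.type in ("float", "float | None") and isinstance(v, bool):
                raise TypeError(f"config key {f.name!r}: expected a number, got bool")
        if self.spin_up < 0:
            raise ValueError("spin_up must be >= 0")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")


def _flatten_toml(doc: dict) -> dict:
    """Allow one level of TOML sections ([snow], [soil], ...) or flat keys."""
    flat = {}
    for key, value in doc.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    return flat


def parse_and_validate(config_file=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus CLI overrides.

    Overrides (already-typed values keyed by config field name) win over file
    values; file values win over defaults.  Unknown keys from either source
    raise with a nearest-match suggestion.
    """
    merged: dict = {}
    if config_file is not None:
        with open(config_file, "rb") as fh:
            merged.update(_flatten_toml(tomllib.load(fh)))
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(merged)


def write_manifest(cfg: RunConfig, out_dir, extra: dict | None = None) -> Path:
    """Write the resolved config (plus provenance extras) as a JSON manifest."""
    from importlib.metadata import PackageNotFoundError, version
    try:
        ver = version("waterbal")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "package_version": ver}
    if extra:
        manifest.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
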