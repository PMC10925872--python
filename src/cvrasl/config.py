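"""Run configuration: a single YAML file validated before any stage runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """All pipeline knobs with protocol-faithful defaults.

    ``simulate`` toggles phantom generation; otherwise ``bold_path``,
    ``trace_path``, ``asl_path`` (+ ``asl_params_path``) and
    ``labels_path`` must point to existing inputs.
    """

    outdir: str = "cvrasl_out"
    seed: int = 0

    # simulation
    simulate: bool = True
    n_subjects: int = 14
    shape: tuple[int, int, int] = (16, 16, 10)
    trace_dt: float = 0.1
    trace_noise_sd: float = 0.5
    bold_noise_sd: float = 20.0
    tr: float = 1.05

    # file inputs (used when simulate is false; single subject)
    bold_path: str | None = None
    trace_path: str | None = None
    asl_path: str | None = None
    asl_params_path: str | None = None
    labels_path: str | None = None

    # preprocessing
    tnsr_percentile: float = 98.0
    max_shift: float = 15.0
    corr_threshold: float = 0.3
    fwhm_mm: tuple[float, float, float] = (4.0, 4.0, 7.0)
    interp_factor: int = 4

    # CVR / lag
    lag_range: tuple[float, float] = (-5.0, 15.0)

    # ASL
    run_asl: bool = True

    # statistics
    n_bins: int = 20
    fdr_q: float = 0.05

    def validate(self) -> "RunConfig":
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.interp_factor < 1:
            raise ConfigError("interp_factor must be >= 1")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q must lie in (0, 1)")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.lag_range[0] >= self.lag_range[1]:
            raise ConfigError("lag_range must be increasing")
        if not self.simulate:
            needed = {"bold_path": self.bold_path,
                      "trace_path": self.trace_path,
                      "labels_path": self.labels_path}
            if self.run_asl:
                needed["asl_path"] = self.asl_path
                needed["asl_params_path"] = self.asl_params_path
            for name, value in needed.items():
                if value is None:
                    raise ConfigError(f"{name} required when simulate is false")
                if not Path(value).exists():
                    raise ConfigError(f"{name} does not exist: {value}")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load + validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("shape", "fwhm_mm", "lag_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw).validate()
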