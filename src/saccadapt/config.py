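"""Run configuration schema, validation and run manifests.

Human-edited configs are YAML; machine artifacts (manifests, fitted
parameters) are JSON.  Every stochastic path requires a seed, and every run
writes a manifest recording the grid, seed, parameters and package version,
so two runs with identical manifests produce bitwise-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .grid import FieldGrid, PAPER_GRID, TEST_GRID
from .gainfields import ModelParams
from .protocol import ExperimentDesign

__all__ = ["GridSpec", "DesignSpec", "RunConfig", "load_config", "run_manifest",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class GridSpec(BaseModel):
    """Grid selection: a named mode or explicit custom geometry."""

    mode: Literal["paper", "test", "custom"] = "test"
    half_extent: Optional[float] = None
    step: Optional[float] = None

    @model_validator(mode="after")
    def _check_custom(self) -> "GridSpec":
        if self.mode == "custom" and (self.half_extent is None or self.step is None):
            raise ValueError("custom grid requires half_extent and step")
        return self

    def build(self) -> FieldGrid:
        if self.mode == "paper":
            return PAPER_GRID
        if self.mode == "test":
            return TEST_GRID
        return FieldGrid(self.half_extent, self.step)


class DesignSpec(BaseModel):
    """Experiment layout; probes default to the standard 11-probe set."""

    adaptation_target: tuple[float, float] = (12.0, 0.0)
    step: tuple[float, float] = (-3.0, 0.0)
    n_adapt_trials: int = Field(200, ge=1)
    kappa: Optional[float] = Field(None, ge=0.0, le=1.0)
    probes: Optional[list[tuple[float, float]]] = None

    def build(self) -> ExperimentDesign:
        return ExperimentDesign(
            adaptation_target=np.asarray(self.adaptation_target),
            step=np.asarray(self.step),
            n_adapt_trials=self.n_adapt_trials,
            kappa=self.kappa,
            probe_set=(
                None
                if self.probes is None
                else tuple(np.asarray(p, dtype=float) for p in self.probes)
            ),
        )


class RunConfig(BaseModel):
    """Validated run configuration with all defaults resolved."""

    schema_version: int = SCHEMA_VERSION
    grid: GridSpec = GridSpec()
    design: DesignSpec = DesignSpec()
    params: Optional[dict[str, float]] = None
    seed: int = 0
    motor_noise_sd: float = Field(0.0, ge=0.0)
    noise_sd: Optional[dict[str, float]] = None
    n_repeats: int = Field(5, ge=1)
    violation_fraction: float = Field(0.0, ge=0.0, le=1.0)
    verbosity: int = 0

    @model_validator(mode="after")
    def _check_constraints(self) -> "RunConfig":
        if self.params is not None:
            mp = ModelParams.from_dict(self.params)  # raises on bad keys/kappa
            delta1 = float(np.hypot(*self.design.adaptation_target))
            limit = delta1 / 3.0
            for name in ("sigma_vF", "sigma_mF", "sigma_cdF"):
                val = getattr(mp.learning, name)
                if val > limit + 1e-12:
                    raise ValueError(
                        f"{name} = {val} violates the foveal constraint "
                        f"{name} <= |adaptation_target|/3 = {limit:.4g}"
                    )
        return self

    def model_params(self) -> ModelParams:
        if self.params is None:
            raise ValueError("config contains no model parameters")
        return ModelParams.from_dict(self.params)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; all offending fields are reported."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_manifest(config: RunConfig, environment: dict | None = None) -> dict:
    """JSON-serializable record tying a run's outputs to its inputs."""
    grid = config.grid.build()
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash(config),
        "config": config.model_dump(mode="json"),
        "grid": {"half_extent": grid.half_extent, "step": grid.step},
        "seed": config.seed,
        "package": "saccadapt",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if environment:
        manifest["environment"] = environment
    return manifest
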