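"""Experiment configuration: versioned YAML schema, validation, provenance.

Every run writes its fully resolved configuration next to its outputs,
together with a content hash of the input files it consumed, so output
directories are self-describing.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .gan_branch import GanLossWeights
from .protocol import RunConfig
from .vae_branch import VaeLossWeights

__all__ = ["ExperimentConfig", "load_config", "save_resolved_config", "hash_inputs"]

SCHEMA_VERSION = 1


class CohortConfig(BaseModel):
    kind: str = "phantom"  # "phantom" or "directory"
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_source: int = 20
    n_target: int = 20
    paired: bool = False
    seed: int = 11
    deformation_amplitude: float = 1.5
    data_dir: str | None = None
    value_remap: dict[int, int] | None = None

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("phantom", "directory"):
            raise ValueError("cohort.kind must be 'phantom' or 'directory'")
        return v


class BranchConfig(BaseModel):
    out_xy: int = 32
    margin: int | None = 2
    width: int = 8
    latent_channels: int = 4
    lr: float = 2e-3
    weights: dict[str, float] = Field(default_factory=dict)


class ProtocolConfig(BaseModel):
    k_folds: int = 2
    supervision_levels: list[float] = [0.0, 0.1, 0.2, 0.3]
    steps: int = 200
    batch_size: int = 4
    seed: int = 0
    count_override: int | None = None

    @field_validator("supervision_levels")
    @classmethod
    def _levels(cls, v):
        for p in v:
            if not 0 <= p <= 1:
                raise ValueError(f"supervision level out of [0,1]: {p}")
        return v


class ExperimentConfig(BaseModel):
    version: int = SCHEMA_VERSION
    output_dir: str = "results"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    gan: BranchConfig = Field(default_factory=BranchConfig)
    vae: BranchConfig = Field(default_factory=BranchConfig)
    unet: BranchConfig = Field(default_factory=BranchConfig)

    @field_validator("version")
    @classmethod
    def _version(cls, v):
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {v}")
        return v

    def run_config(self, method: str) -> RunConfig:
        branch = getattr(self, method)
        rc = RunConfig(
            out_xy=branch.out_xy, margin=branch.margin, k_folds=self.protocol.k_folds,
            steps=self.protocol.steps, batch_size=self.protocol.batch_size,
            lr=branch.lr, width=branch.width, latent_channels=branch.latent_channels,
            seed=self.protocol.seed, count_override=self.protocol.count_override,
        )
        if method == "gan" and branch.weights:
            rc.gan_weights = GanLossWeights(**branch.weights)
        if method == "vae" and branch.weights:
            rc.vae_weights = VaeLossWeights(**branch.weights)
        return rc


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def save_resolved_config(config: ExperimentConfig, out_dir: str | Path,
                         input_hash: str | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = config.model_dump()
    if input_hash is not None:
        payload["input_hash"] = input_hash
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def hash_inputs(paths: list[str | Path]) -> str:
    """Git-style content hash over a sorted list of input files."""
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        fp = Path(p)
        if fp.is_file():
            h.update(fp.read_bytes())
    return h.hexdigest()[:16]
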