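"""Run configuration: every tunable of the pipeline in one validated object.

Serializes to/from YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """All pipeline tunables with their defaults.

    Graph smoothing
    ---------------
    use_smoothing : run the adjacency-based smoothing step at all.
    use_histology : fold image information into spot distances when present.
    histology_scale_s : weight of the histology axis; 1.0 matches its
        variance to the wider spatial axis, 0 disables histology.
    mean_neighbor_weight : calibration target for the mean off-diagonal
        adjacency row sum (0.5 = neighbors get half the self weight).
    pixel_window : side, in pixels, of the square averaged around each spot.
    pixel_order : 'xy' (column, row) or 'rc' (row, column) pixel coordinates.

    Preprocessing / embedding / clustering parameters mirror the module
    documentation; ``hvg_count`` of None means min(5000, n_genes).
    """

    model_config = ConfigDict(extra="forbid")

    # graph smoothing
    use_smoothing: bool = True
    use_histology: bool = True
    histology_scale_s: float = Field(1.0, ge=0)
    mean_neighbor_weight: float = Field(0.5, gt=0)
    pixel_window: int = Field(50, ge=1)
    pixel_order: str = "xy"

    # preprocessing
    hvg_count: int | None = Field(None, ge=1)

    # embedding network
    layer_dims: list[int] | None = None
    latent_dim: int = Field(64, ge=2)
    corruption_rate: float = Field(0.2, ge=0, lt=1)
    pretrain_epochs: int = Field(100, ge=0)
    finetune_epochs: int = Field(200, ge=0)
    batch_size: int = Field(256, ge=1)
    autoencoder_lr: float = Field(1e-3, gt=0)

    # clustering layer
    noise_scale: float = Field(1e-5, ge=0)
    # with column-normalized targets the KL gradient scales ~K/N relative
    # to the row-normalized convention, so the rate sits higher than the
    # classic 0.01 to keep per-epoch updates meaningful
    clustering_lr: float = Field(0.1, gt=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    convergence_delta: float = Field(0.01, gt=0)
    max_epochs: int = Field(2000, ge=1)

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
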