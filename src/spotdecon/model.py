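"""Model / results surface for spot-level cell-type deconvolution.

``SpotDeconvolution`` is constructed from a spatial dataset and an
annotated single-cell reference, holds the run configuration, and its
``fit()`` executes the full procedure:

1. optional histology-aware graph smoothing of the spot expression,
2. highly-variable-gene selection and joint standardization,
3. unsupervised stacked-denoising-autoencoder initialization of the
   encoder on the combined spot + cell matrix,
4. supervised optimization of the clustering layer on the labeled cells,
5. soft assignment of each spot to the cell-type centroids.

``fit()`` returns a :class:`DeconvolutionResults` carrying the proportion
estimates, the calibrated length scale, the training trace, and a
``summary()`` table; ``evaluate()`` scores the estimates against known
truth.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import benchmark as _bench
from . import deconvolution as _dec
from . import embedding as _emb
from . import graph as _graph
from . import preprocess as _prep
from .config import RunConfig
from .datasets import ProportionMatrix, SCReference, SRTDataset

logger = logging.getLogger(__name__)

__all__ = ["SpotDeconvolution", "DeconvolutionResults"]


@dataclass
class DeconvolutionResults:
    """Fitted proportions plus diagnostics of every pipeline stage."""

    proportions: ProportionMatrix
    model: _emb.DeconModel
    training_log: _dec.TrainingLog
    genes: list[str]
    length_scale: float | None = None
    mean_neighbor_weight: float | None = None
    smoothing_used: bool = False
    histology_used: bool = False
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config: RunConfig | None = None

    @property
    def converged(self) -> bool:
        return self.training_log.converged

    @property
    def n_epochs(self) -> int:
        return self.training_log.n_epochs

    def to_dataframe(self) -> pd.DataFrame:
        return self.proportions.to_dataframe()

    def evaluate(self, truth: ProportionMatrix) -> _bench.EvalReport:
        """Score the fitted proportions against known composition."""
        return _bench.evaluate(self.proportions, truth)

    def summary(self) -> str:
        P = self.proportions.proportions
        lines = [
            "Spot-level cell-type deconvolution results",
            "=" * 46,
            f"spots:                  {self.proportions.n_spots}",
            f"cell types:             {len(self.proportions.cell_types)}",
            f"genes used:             {len(self.genes)}",
            f"smoothing:              {'on' if self.smoothing_used else 'off'}"
            + (" (with histology)" if self.histology_used else ""),
        ]
        if self.length_scale is not None:
            lines.append(f"calibrated length scale: {self.length_scale:.4f}")
            lines.append(f"mean neighbor weight:    {self.mean_neighbor_weight:.4f}")
        lines += [
            f"training epochs:        {self.n_epochs} "
            f"({'converged' if self.converged else 'stopped'}: "
            f"{self.training_log.stop_reason})",
            f"final KL loss:          {self.training_log.losses[-1]:.4f}",
            "",
            "mean proportion per cell type:",
        ]
        for j, t in enumerate(self.proportions.cell_types):
            lines.append(f"  {t:<24s} {P[:, j].mean():.4f}")
        return "\n".join(lines)


class SpotDeconvolution:
    """Semi-supervised deconvolution of spot expression against a labeled
    single-cell reference.

    Parameters
    ----------
    srt : SRTDataset
        Spot x gene counts, optionally with coordinates and histology.
    reference : SCReference
        Annotated cell x gene counts (K >= 2 types).
    config : RunConfig, optional
        All tunables; keyword overrides win over the config object.
    """

    def __init__(self, srt: SRTDataset, reference: SCReference,
                 config: RunConfig | None = None, **overrides):
        self.srt = srt
        self.reference = reference
        base = config.model_dump() if config is not None else {}
        base.update(overrides)
        self.config = RunConfig(**base)

    @classmethod
    def from_dataframes(
        cls,
        srt_counts: pd.DataFrame,
        srt_positions: pd.DataFrame | None,
        sc_counts: pd.DataFrame,
        sc_labels: pd.Series,
        **kwargs,
    ) -> "SpotDeconvolution":
        """Build from plain pandas inputs (spots x genes, cells x genes)."""
        xy = None
        if srt_positions is not None:
            pos = srt_positions.loc[srt_counts.index]
            xy = pos[["x", "y"]].to_numpy(dtype=float)
        srt = SRTDataset(
            counts=srt_counts.to_numpy(dtype=float),
            spot_ids=[str(i) for i in srt_counts.index],
            gene_ids=[str(g) for g in srt_counts.columns],
            xy=xy,
        )
        labels = sc_labels.loc[sc_counts.index]
        ref = SCReference(
            counts=sc_counts.to_numpy(dtype=float),
            cell_ids=[str(i) for i in sc_counts.index],
            gene_ids=[str(g) for g in sc_counts.columns],
            labels=[str(l) for l in labels],
        )
        return cls(srt, ref, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> DeconvolutionResults:
        """Run smoothing -> preprocessing -> embedding -> deconvolution."""
        cfg = self.config
        if seed is not None:
            cfg = RunConfig(**{**cfg.model_dump(), "seed": seed})
        timings: dict[str, float] = {}

        # 1. graph smoothing (optional)
        t0 = time.perf_counter()
        X = self.srt.counts
        length_scale = None
        mean_w = None
        smoothing = cfg.use_smoothing and self.srt.has_spatial
        histology = False
        if smoothing:
            use_hist = cfg.use_histology and self.srt.has_histology
            adj = _graph.build_adjacency(
                self.srt.xy,
                image=self.srt.image if use_hist else None,
                pixel_xy=self.srt.pixel_xy if use_hist else None,
                s=cfg.histology_scale_s,
                target_mean_weight=cfg.mean_neighbor_weight,
                window=cfg.pixel_window,
                pixel_order=cfg.pixel_order,
            )
            X = _graph.smooth_expression(adj, X)
            length_scale = adj.l
            mean_w = adj.mean_neighbor_weight
            histology = use_hist and cfg.histology_scale_s > 0
            logger.info(
                "smoothing: l=%.4g, mean neighbor weight=%.4g%s",
                adj.l, adj.mean_neighbor_weight,
                " (histology)" if histology else "",
            )
        else:
            logger.info("smoothing skipped")
        timings["smoothing"] = time.perf_counter() - t0

        # 2. preprocessing
        t0 = time.perf_counter()
        h = cfg.hvg_count or min(5000, self.srt.n_genes)
        hvg = _prep.select_hvg(X, self.srt.gene_ids, h)
        pair = _prep.intersect_and_standardize(
            X, self.srt.gene_ids, self.reference.counts,
            self.reference.gene_ids, hvg,
        )
        logger.info("preprocessing: %d shared HVGs retained", len(pair.genes))
        timings["preprocessing"] = time.perf_counter() - t0

        # 3. unsupervised encoder initialization
        t0 = time.perf_counter()
        Y = np.vstack([pair.srt_z, pair.sc_z])
        spec = _emb.build_architecture(
            Y.shape[0], Y.shape[1],
            latent_dim=cfg.latent_dim,
            layer_dims=cfg.layer_dims,
            corruption_rate=cfg.corruption_rate,
            pretrain_epochs=cfg.pretrain_epochs,
            finetune_epochs=cfg.finetune_epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.autoencoder_lr,
            seed=cfg.seed,
        )
        encoders, decoders = _emb.pretrain_layerwise(Y, spec)
        model = _emb.finetune_stacked(Y, encoders, decoders, spec)
        model.genes = list(pair.genes)
        logger.info("embedding: architecture %s", spec.layer_dims)
        timings["embedding"] = time.perf_counter() - t0

        # 4. supervised clustering-layer training (reference cells only)
        t0 = time.perf_counter()
        model, tlog = _dec.train_clustering_layer(
            model,
            pair.sc_z,
            self.reference.label_indices(),
            self.reference.cell_types,
            noise_scale=cfg.noise_scale,
            learning_rate=cfg.clustering_lr,
            momentum=cfg.momentum,
            convergence_delta=cfg.convergence_delta,
            max_epochs=cfg.max_epochs,
            seed=cfg.seed,
        )
        logger.info("clustering: %d epochs, %s", tlog.n_epochs, tlog.stop_reason)
        timings["clustering"] = time.perf_counter() - t0

        # 5. inference on the spots
        t0 = time.perf_counter()
        proportions = _dec.infer_proportions(model, pair.srt_z, self.srt.spot_ids)
        timings["inference"] = time.perf_counter() - t0

        return DeconvolutionResults(
            proportions=proportions,
            model=model,
            training_log=tlog,
            genes=list(pair.genes),
            length_scale=length_scale,
            mean_neighbor_weight=mean_w,
            smoothing_used=smoothing,
            histology_used=histology,
            stage_seconds=timings,
            config=cfg,
        )
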