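"""End-to-end orchestration: peaks -> features -> graphs -> trained model.

Glue used by the command-line interface, the TSS sweep and the test suite;
each stage delegates to its module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .featurize import FeatureMatrix, align_views, build_feature_matrix
from .fusion import GenetModel, train_genet
from .io_genomics import ExpressionTable, GeneAnnotation, GenomicInterval
from .simnet import SimilarityGraph, build_similarity_graph
from .train_eval import MetricsReport, SplitMasks, compute_metrics, split_samples

__all__ = ["PipelineResult", "featurize_views", "run_genet_pipeline"]


@dataclass
class PipelineResult:
    model: GenetModel
    fm_tf: FeatureMatrix
    fm_hm: FeatureMatrix
    graph_tf: SimilarityGraph
    graph_hm: SimilarityGraph
    masks: SplitMasks
    y: np.ndarray
    y_pred: np.ndarray
    metrics: dict[str, MetricsReport]
    history: dict[str, list[float]]

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        return self.fm_tf.sample_ids


def featurize_views(
    peaks: dict[str, dict[str, list[GenomicInterval]]],
    genes: list[GeneAnnotation],
    cell_lines: list[str],
    expr: ExpressionTable,
    config: RunConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, np.ndarray]:
    """Both views' aligned feature matrices plus the label vector."""
    views = sorted(peaks)  # ('h3k27ac', 'tf') or whatever pair was supplied
    if len(views) != 2:
        raise ValueError(f"expected exactly 2 views, got {views}")
    tf_view = "tf" if "tf" in views else views[0]
    hm_view = next(v for v in views if v != tf_view)
    fm_tf = build_feature_matrix(
        peaks[tf_view], genes, cell_lines, config.tss_range, config.bin_size, tf_view
    )
    fm_hm = build_feature_matrix(
        peaks[hm_view], genes, cell_lines, config.tss_range, config.bin_size, hm_view
    )
    return align_views(fm_tf, fm_hm, expr)


def run_genet_pipeline(
    peaks: dict[str, dict[str, list[GenomicInterval]]],
    genes: list[GeneAnnotation],
    cell_lines: list[str],
    expr: ExpressionTable,
    config: RunConfig,
    masks: SplitMasks | None = None,
) -> PipelineResult:
    """Featurize, build per-view graphs, split, train, and score."""
    fm_tf, fm_hm, y = featurize_views(peaks, genes, cell_lines, expr, config)
    g_tf = build_similarity_graph(fm_tf, config.avg_degree, config.similarity_sharpening)
    g_hm = build_similarity_graph(fm_hm, config.avg_degree, config.similarity_sharpening)
    if masks is None:
        masks = split_samples(len(y), config.fractions, config.seed)
    model, y_pred, history = train_genet(
        fm_tf.values, fm_hm.values, g_tf.norm_adjacency, g_hm.norm_adjacency,
        y, masks.as_dict(), config,
    )
    metrics = {
        split: compute_metrics(y[m], y_pred[m])
        for split, m in masks.as_dict().items()
    }
    return PipelineResult(
        model, fm_tf, fm_hm, g_tf, g_hm, masks, y, y_pred, metrics, history
    )
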