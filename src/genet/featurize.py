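"""Per-view feature matrices: binned ChIP-seq signal in a TSS window.

For each (gene, cell line) sample and each view (TF binding, H3K27ac) the
window ``[tss - R, tss + R)`` is tiled into fixed-width bins and each bin
holds the mean per-base signal, where a base covered by several peaks gets
the sum of their signals and uncovered bases contribute zero.  ``R`` is the
"TSS range": the flank per side, so the window is ``2R`` wide.

The bin grid stays anchored at ``tss - R`` even when the window would start
before the chromosome origin; the missing bases simply contribute zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_genomics import ExpressionTable, GeneAnnotation, GenomicInterval

__all__ = [
    "FeatureMatrix",
    "build_tss_window",
    "bin_signal",
    "build_feature_matrix",
    "align_views",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x position-bins signal matrix for one view.

    ``sample_ids`` are (gene_id, cell_line) pairs in a deterministic order
    (genes outer, cell lines inner, both lexicographic); the same order is
    shared by both views after :func:`align_views`.
    """

    view: str
    sample_ids: list[tuple[str, str]]
    tss_range: int
    bin_size: int
    values: np.ndarray  # (n_samples, n_bins), float64, >= 0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_bins_for(self.tss_range, self.bin_size)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            expected,
        ):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {expected} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def n_bins_for(tss_range: int, bin_size: int) -> int:
    return math.ceil(2 * tss_range / bin_size)


def build_tss_window(gene: GeneAnnotation, tss_range: int) -> GenomicInterval:
    """The featurization window ``[tss - R, tss + R)``, clipped at 0.

    Clipping affects only the stored interval; binning anchors its grid at
    the unclipped ``tss - R`` (see :func:`bin_signal`).
    """
    if tss_range <= 0:
        raise ValueError(f"tss_range must be positive, got {tss_range}")
    start = max(0, gene.tss - tss_range)
    end = gene.tss + tss_range
    return GenomicInterval(gene.chrom, start, end, strand=gene.strand)


def bin_signal(
    peaks: list[GenomicInterval],
    window: GenomicInterval,
    bin_size: int,
    *,
    grid_start: int | None = None,
) -> np.ndarray:
    """Mean per-base summed peak signal in each bin of the window.

    ``grid_start`` is the (possibly negative, pre-clipping) coordinate the
    bin grid is anchored at; it defaults to ``window.start``.  Peaks are
    assumed pre-filtered to the window's chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if grid_start is None:
        grid_start = window.start
    width = window.end - grid_start
    n_bins = math.ceil(width / bin_size)
    base = np.zeros(n_bins * bin_size)
    for pk in peaks:
        lo = max(pk.start, max(grid_start, 0)) - grid_start
        hi = min(pk.end, grid_start + len(base)) - grid_start
        if hi > lo:
            base[lo:hi] += pk.signal
    return base.reshape(n_bins, bin_size).mean(axis=1)


def build_feature_matrix(
    peaks_by_cell_line: dict[str, list[GenomicInterval]],
    genes: list[GeneAnnotation],
    cell_lines: list[str],
    tss_range: int,
    bin_size: int,
    view: str,
) -> FeatureMatrix:
    """One row of binned window signal per (gene, cell line) pair.

    Rows follow gene-major lexicographic order regardless of input order.
    A gene whose chromosome is absent from a cell line's peak set gets a
    zero row (logged), not an error.
    """
    genes_sorted = sorted(genes, key=lambda g: g.gene_id)
    cells_sorted = sorted(cell_lines)
    for cl in cells_sorted:
        if cl not in peaks_by_cell_line:
            raise ValueError(f"no peak set (even empty) for cell line {cl!r}")

    # index peaks by (cell_line, chrom) once
    by_chrom: dict[tuple[str, str], list[GenomicInterval]] = {}
    for cl in cells_sorted:
        for pk in peaks_by_cell_line[cl]:
            by_chrom.setdefault((cl, pk.chrom), []).append(pk)

    nb = n_bins_for(tss_range, bin_size)
    sample_ids: list[tuple[str, str]] = []
    rows = np.zeros((len(genes_sorted) * len(cells_sorted), nb))
    r = 0
    for gene in genes_sorted:
        window = build_tss_window(gene, tss_range)
        grid_start = gene.tss - tss_range
        for cl in cells_sorted:
            peaks = by_chrom.get((cl, gene.chrom))
            if peaks is None:
                logger.debug(
                    "no peaks on %s for cell line %s; zero row for gene %s",
                    gene.chrom, cl, gene.gene_id,
                )
                peaks = []
            rows[r] = bin_signal(peaks, window, bin_size, grid_start=grid_start)
            sample_ids.append((gene.gene_id, cl))
            r += 1
    return FeatureMatrix(view, sample_ids, tss_range, bin_size, rows)


def align_views(
    fm_tf: FeatureMatrix,
    fm_hm: FeatureMatrix,
    expr: ExpressionTable,
) -> tuple[FeatureMatrix, FeatureMatrix, np.ndarray]:
    """Restrict both views and the labels to their common samples.

    Returns the two feature matrices and the label vector over the sorted
    intersection of (gene_id, cell_line) keys, in identical order.
    """
    common = sorted(set(fm_tf.sample_ids) & set(fm_hm.sample_ids) & expr.keys)
    if not common:
        raise ValueError("no samples shared by both views and the expression table")

    def subset(fm: FeatureMatrix) -> FeatureMatrix:
        index = {sid: i for i, sid in enumerate(fm.sample_ids)}
        idx = [index[sid] for sid in common]
        return FeatureMatrix(
            fm.view, list(common), fm.tss_range, fm.bin_size, fm.values[idx]
        )

    y = np.array([expr[sid] for sid in common])
    return subset(fm_tf), subset(fm_hm), y


def matrix_to_frame(fm: FeatureMatrix):
    """Serialize a FeatureMatrix as a DataFrame (TSV-friendly)."""
    import pandas as pd

    index = [f"{g}|{c}" for g, c in fm.sample_ids]
    cols = [f"bin{i}" for i in range(fm.n_bins)]
    return pd.DataFrame(fm.values, index=index, columns=cols)


def frame_to_matrix(df, view: str, tss_range: int, bin_size: int) -> FeatureMatrix:
    sample_ids = [tuple(s.split("|", 1)) for s in df.index]
    return FeatureMatrix(view, sample_ids, tss_range, bin_size, df.to_numpy(float))
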