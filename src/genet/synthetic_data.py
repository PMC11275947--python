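"""ENCODE-shaped synthetic fixtures with a planted, recoverable signal.

The generator emulates the shape of the real inputs — per-cell-line
narrowPeak files for two views (TF binding and H3K27ac), a BED6 gene
annotation, and a (gene, cell line) expression TSV — on a toy chromosome,
so the whole pipeline is exercisable without any download.

Planted structure
-----------------
* Genes are spaced so their TSS windows never overlap.
* Cell lines belong to latent clusters.  Peak *placement* (number,
  centers, widths, base amplitude) within each gene's window is drawn once
  per (cluster, gene, view); cell lines of the same cluster share it and
  differ only by an amplitude jitter plus a small private background peak.
  Same-cluster samples of a gene therefore have nearly proportional binned
  profiles (cosine similarity near 1), which is exactly the information the
  sample-similarity graph is meant to carry.
* Expression for each (gene, cell line) sample is

      y = alpha * s_tf + beta * s_hm + gamma * s_tf * s_hm + N(0, noise_sd)

  where ``s_tf`` and ``s_hm`` are the window-mean per-base signals the
  generator itself computes.  The interaction term makes purely linear
  models on the bin features suboptimal.  At ``noise_sd = 0`` ordinary
  least squares on (s_tf, s_hm, s_tf*s_hm) recovers (alpha, beta, gamma)
  exactly.

Defaults: 50 genes x 6 cell lines in 3 clusters (300 samples), 200 bp TSS
flank, unit effect weights, noise_sd 0.1 — small against the planted-signal
spread so the signal is recoverable but not trivially noiseless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_genomics import (
    ExpressionTable,
    GeneAnnotation,
    GenomicInterval,
    write_expression_table,
    write_gene_annotations_bed6,
    write_narrowpeak,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_null_dataset",
    "write_dataset",
]

VIEWS = ("tf", "h3k27ac")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 50
    n_cell_lines: int = 6
    n_clusters: int = 3
    tss_range: int = 200          # bp flank per side; windows are 2R wide
    noise_sd: float = 0.1
    alpha: float = 1.0            # weight of TF window-mean signal
    beta: float = 1.0             # weight of H3K27ac window-mean signal
    gamma: float = 1.0            # weight of the TF x H3K27ac interaction
    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int | None = None  # auto-sized when None

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_lines, self.n_clusters) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tss_range <= 0:
            raise ValueError("tss_range must be positive")


@dataclass
class GroundTruth:
    sample_ids: list[tuple[str, str]]
    s_tf: np.ndarray               # window-mean TF signal per sample
    s_hm: np.ndarray               # window-mean H3K27ac signal per sample
    noiseless: np.ndarray          # alpha*s_tf + beta*s_hm + gamma*s_tf*s_hm
    alpha: float
    beta: float
    gamma: float
    clusters: dict[str, int]       # cell line -> latent cluster


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneAnnotation]
    peaks: dict[str, dict[str, list[GenomicInterval]]]  # view -> cell line -> peaks
    expression: ExpressionTable
    truth: GroundTruth
    cell_lines: list[str] = field(default_factory=list)


def _gene_layout(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Genes on the toy chromosome with non-overlapping TSS windows."""
    spacing = 4 * cfg.tss_range + 1000
    needed = cfg.n_genes * spacing + 2 * cfg.tss_range
    if cfg.chrom_length is not None and cfg.chrom_length < needed:
        raise ValueError(
            f"chrom_length={cfg.chrom_length} cannot hold {cfg.n_genes} "
            f"non-overlapping TSS windows; need >= {needed}"
        )
    genes = []
    for i in range(cfg.n_genes):
        tss = cfg.tss_range + 500 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"G{i:03d}", cfg.chrom, strand, tss))
    return genes


def _window_mean(peaks: list[GenomicInterval], lo: int, hi: int) -> float:
    """Per-base accumulation oracle for the window-mean summed signal."""
    base = np.zeros(hi - lo)
    for pk in peaks:
        a, b = max(pk.start, lo), min(pk.end, hi)
        if b > a:
            base[a - lo : b - lo] += pk.signal
    return float(base.mean())


def _generate_features(cfg: SyntheticConfig, rng: np.random.Generator):
    genes = _gene_layout(cfg, rng)
    cell_lines = [f"CL{j:02d}" for j in range(cfg.n_cell_lines)]
    clusters = {cl: j % cfg.n_clusters for j, cl in enumerate(cell_lines)}
    R = cfg.tss_range

    # cluster-level peak architecture, drawn once per (view, cluster, gene)
    arch: dict[tuple[str, int, str], list[tuple[int, int, float]]] = {}
    for view in VIEWS:
        for k in range(cfg.n_clusters):
            for g in genes:
                n_peaks = int(rng.integers(2, 6))
                # shared activity scale: occupancy co-varies across a
                # window's peaks, as bound regions do within a promoter.
                # Bimodal across clusters — regulatory elements are mostly
                # on/off between cell types, graded when on; the cap
                # mirrors saturating fold-enrichment estimates
                if rng.random() < 0.4:
                    activity = float(rng.uniform(0.02, 0.15))
                else:
                    activity = min(float(rng.lognormal(0.3, 0.5)), 3.5)
                entries = []
                for _ in range(n_peaks):
                    center = g.tss + int(rng.integers(-int(0.8 * R), int(0.8 * R) + 1))
                    # narrow, footprint-like peaks: unrelated samples then
                    # overlap little, so their cosine similarity stays low
                    half = int(rng.integers(max(8, R // 20), max(9, R // 4) + 1))
                    # long-tailed fold-enrichment, as in real ChIP-seq peaks
                    amp = activity * float(rng.lognormal(0.5, 0.4))
                    entries.append((center - half, center + half, amp))
                arch[(view, k, g.gene_id)] = entries

    peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        v: {cl: [] for cl in cell_lines} for v in VIEWS
    }
    s: dict[str, np.ndarray] = {}
    sample_ids = [(g.gene_id, cl) for g in sorted(genes, key=lambda g: g.gene_id)
                  for cl in sorted(cell_lines)]
    for view in VIEWS:
        means = np.zeros(len(sample_ids))
        for cl in cell_lines:
            k = clusters[cl]
            jitter = float(rng.uniform(0.7, 1.3))  # cell-line amplitude factor
            for g in genes:
                gene_peaks = []
                for start, end, amp in arch[(view, k, g.gene_id)]:
                    signal = amp * jitter * float(rng.uniform(0.9, 1.1))
                    gene_peaks.append(
                        GenomicInterval(cfg.chrom, max(0, start), end,
                                        signal=round(signal, 6))
                    )
                # small private background peak (off-architecture noise)
                if rng.random() < 0.5:
                    c = g.tss + int(rng.integers(-R, R + 1))
                    w = int(rng.integers(10, 40))
                    gene_peaks.append(
                        GenomicInterval(cfg.chrom, max(0, c - w), c + w,
                                        signal=round(float(rng.uniform(0.02, 0.1)), 6))
                    )
                peaks[view][cl].extend(gene_peaks)
        for idx, (gid, cl) in enumerate(sample_ids):
            g = next(gg for gg in genes if gg.gene_id == gid)
            means[idx] = _window_mean(
                [p for p in peaks[view][cl]
                 if p.start < g.tss + R and p.end > g.tss - R],
                g.tss - R, g.tss + R,
            )
        s[view] = means
    return genes, cell_lines, clusters, peaks, sample_ids, s


def generate_dataset(
    cfg: SyntheticConfig, out_dir: str | os.PathLike | None = None
) -> SyntheticDataset:
    """Peaks, annotations and expression with the planted dependence."""
    rng = np.random.default_rng(cfg.seed)
    genes, cell_lines, clusters, peaks, sample_ids, s = _generate_features(cfg, rng)
    noiseless = (
        cfg.alpha * s["tf"] + cfg.beta * s["h3k27ac"]
        + cfg.gamma * s["tf"] * s["h3k27ac"]
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=len(sample_ids)) if cfg.noise_sd > 0 \
        else np.zeros(len(sample_ids))
    y = noiseless + noise
    table = ExpressionTable(
        {sid: float(v) for sid, v in zip(sample_ids, y)}
    )
    truth = GroundTruth(sample_ids, s["tf"], s["h3k27ac"], noiseless,
                        cfg.alpha, cfg.beta, cfg.gamma, clusters)
    ds = SyntheticDataset(cfg, genes, peaks, table, truth, cell_lines)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def generate_null_dataset(
    cfg: SyntheticConfig, out_dir: str | os.PathLike | None = None
) -> SyntheticDataset:
    """Same feature-generation path, expression independent of features."""
    rng = np.random.default_rng(cfg.seed)
    genes, cell_lines, clusters, peaks, sample_ids, s = _generate_features(cfg, rng)
    y = rng.normal(0.0, 1.0, size=len(sample_ids))
    table = ExpressionTable({sid: float(v) for sid, v in zip(sample_ids, y)})
    truth = GroundTruth(sample_ids, s["tf"], s["h3k27ac"],
                        np.zeros(len(sample_ids)), 0.0, 0.0, 0.0, clusters)
    ds = SyntheticDataset(cfg, genes, peaks, table, truth, cell_lines)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Serialize to the standard on-disk layout; round-trips via io_genomics."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    genes_path = out / "genes.bed"
    write_gene_annotations_bed6(ds.genes, genes_path)
    paths["genes"] = genes_path
    expr_path = out / "expression.tsv"
    write_expression_table(ds.expression, expr_path)
    paths["expression"] = expr_path
    for view in VIEWS:
        for cl, pks in ds.peaks[view].items():
            p = out / "peaks" / f"{view}_{cl}.narrowPeak"
            write_narrowpeak(sorted(pks, key=lambda x: (x.start, x.end)), p)
            paths[f"{view}/{cl}"] = p
    return paths
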