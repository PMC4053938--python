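"""TSS-anchored and scaled gene-body profile matrices and metaprofiles.

A ProfileMatrix holds one row per gene of binned mean per-bp signal around a
shared anchor.  Rows of minus-strand genes are built directly in transcript
orientation (5'->3'), so the shared axis always reads upstream -> downstream.
Signal values are mean per-bp within each bin, which keeps bins of unequal
width (scaled gene-body mode) comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, SignalTrack

log = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """genes x position-bins matrix of mean per-bp signal around an anchor.

    ``axis`` holds bin centers in bp relative to the anchor for TSS mode.  In
    scaled gene-body mode the axis is a composite coordinate: upstream flank
    bins in negative bp, the body mapped to [0, 1000] (per-mille of gene
    length), and the downstream flank offset past 1000.
    """

    gene_ids: list[str]
    axis: np.ndarray
    values: np.ndarray
    anchor: str  # "tss" | "scaled-body"
    flank: int
    bin_width: int
    clipped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.axis)):
            raise ValueError("values shape inconsistent with gene_ids/axis")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_bins(self) -> int:
        return len(self.axis)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Iterable[str]) -> "ProfileMatrix":
        wanted = set(gene_ids)
        keep = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        if not keep:
            raise ValueError("subset has no genes in common with the matrix")
        return ProfileMatrix(
            [self.gene_ids[i] for i in keep],
            self.axis,
            self.values[keep],
            self.anchor,
            self.flank,
            self.bin_width,
            self.clipped & wanted,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.axis)
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, anchor: str = "tss", flank: int = 0, bin_width: int = 0
    ) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        axis = np.array([float(c) for c in df.columns])
        return cls(list(df.index), axis, df.values, anchor, flank, bin_width)


@dataclass
class MetaProfile:
    """Column average of a ProfileMatrix over a gene subset."""

    axis: np.ndarray
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.axis) != len(self.values):
            raise ValueError("axis and values must have the same length")
        if self.n_genes <= 0:
            raise ValueError("a metaprofile needs at least one contributing gene")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"position": self.axis, "mean_signal": self.values}).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def _tss_bin_bounds(gene: GeneModel, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genome-coordinate [lo, hi) bounds for transcript-relative bin edges.

    Transcript-relative offset of base p is (p - tss) on +, (tss - p) on -.
    """
    tss = gene.tss
    if gene.strand == "+":
        return tss + edges[:-1], tss + edges[1:]
    # offset in [lo, hi) <=> p in (tss - hi, tss - lo] = [tss - hi + 1, tss - lo + 1)
    return tss - edges[1:] + 1, tss - edges[:-1] + 1


def build_tss_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int,
    bin_width: int,
) -> ProfileMatrix:
    """Mean per-bp signal in fixed-width bins over tss +/- flank for each gene."""
    if not genes:
        raise ValueError("empty gene list")
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    edges = np.arange(-flank, flank + bin_width, bin_width, dtype=np.int64)
    axis = (edges[:-1] + edges[1:]) / 2.0
    values = np.zeros((len(genes), n_bins))
    clipped: set[str] = set()
    sizes = track.chrom_sizes or {}
    for i, gene in enumerate(genes):
        lo, hi = _tss_bin_bounds(gene, edges)
        size = sizes.get(gene.chrom)
        clo = np.clip(lo, 0, None)
        chi = np.clip(hi, 0, None) if size is None else np.clip(hi, 0, size)
        if size is not None:
            clo = np.minimum(clo, size)
        if np.any(clo != lo) or np.any(chi != hi):
            clipped.add(gene.gene_id)
        widths = chi - clo
        sums = track.window_sums(gene.chrom, clo, chi)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(widths > 0, sums / np.maximum(widths, 1), 0.0)
        values[i] = row
    return ProfileMatrix(
        [g.gene_id for g in genes], axis, values, "tss", flank, bin_width, clipped
    )


def build_scaled_body_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int,
    n_body_bins: int,
    bin_width: int = 50,
) -> ProfileMatrix:
    """Fixed-bp flank bins plus a gene body rescaled to n_body_bins fractions.

    Every gene is rescaled regardless of length; genes shorter than
    n_body_bins bp get fractional-overlap body bins and are flagged.
    """
    if not genes:
        raise ValueError("empty gene list")
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_flank = flank // bin_width
    flank_edges = np.arange(0, flank + bin_width, bin_width, dtype=np.float64)
    axis = np.concatenate(
        [
            -flank + (flank_edges[:-1] + flank_edges[1:]) / 2.0,  # upstream
            (np.arange(n_body_bins) + 0.5) / n_body_bins * 1000.0,  # body, per-mille
            1000.0 + (flank_edges[:-1] + flank_edges[1:]) / 2.0,  # downstream
        ]
    )
    values = np.zeros((len(genes), 2 * n_flank + n_body_bins))
    clipped: set[str] = set()
    sizes = track.chrom_sizes or {}
    for i, gene in enumerate(genes):
        L = gene.length
        if L < n_body_bins:
            clipped.add(gene.gene_id)
        start, end = gene.interval.start, gene.interval.end
        body_edges = start + np.arange(n_body_bins + 1) * (L / n_body_bins)
        if gene.strand == "+":
            up_lo = start - flank + flank_edges[:-1]
            up_hi = start - flank + flank_edges[1:]
            body_lo, body_hi = body_edges[:-1], body_edges[1:]
            dn_lo = end + flank_edges[:-1]
            dn_hi = end + flank_edges[1:]
        else:
            # transcript 5'->3' runs right-to-left in genome coordinates
            up_lo = end + flank - flank_edges[1:]
            up_hi = end + flank - flank_edges[:-1]
            body_lo = body_edges[::-1][1:]
            body_hi = body_edges[::-1][:-1]
            dn_lo = start - flank_edges[1:]
            dn_hi = start - flank_edges[:-1]
        los = np.concatenate([up_lo, body_lo, dn_lo])
        his = np.concatenate([up_hi, body_hi, dn_hi])
        size = sizes.get(gene.chrom)
        clo = np.clip(los, 0, None if size is None else size)
        chi = np.clip(his, 0, None if size is None else size)
        if np.any(clo != los) or np.any(chi != his):
            clipped.add(gene.gene_id)
        widths = chi - clo
        sums = track.window_sums(gene.chrom, clo, chi)
        values[i] = np.where(widths > 0, sums / np.maximum(widths, 1e-12), 0.0)
    return ProfileMatrix(
        [g.gene_id for g in genes],
        axis,
        values,
        "scaled-body",
        flank,
        bin_width,
        clipped,
    )


def mean_profile(
    matrix: ProfileMatrix, subset: Iterable[str] | None = None
) -> MetaProfile:
    """Per-bin arithmetic mean over the selected rows (all rows by default)."""
    if subset is None:
        vals = matrix.values
        n = matrix.n_genes
    else:
        wanted = set(subset)
        keep = [i for i, g in enumerate(matrix.gene_ids) if g in wanted]
        if not keep:
            raise ValueError("subset has empty intersection with matrix rows")
        vals = matrix.values[keep]
        n = len(keep)
    return MetaProfile(matrix.axis, vals.mean(axis=0), n)


def genebody_density(track: SignalTrack, gene: GeneModel) -> float:
    """Total signal over the gene interval divided by gene length (signal/bp)."""
    if gene.length <= 0:
        raise ValueError("gene length must be > 0")
    return track.integral(gene.chrom, gene.interval.start, gene.interval.end) / gene.length


def order_rows(
    matrix: ProfileMatrix,
    key: Callable[[str], float] | dict[str, float],
    descending: bool = True,
) -> ProfileMatrix:
    """Stable sort of matrix rows by a per-gene key; ties break by gene_id.

    Genes missing from a dict key get 0 (logged).
    """
    if isinstance(key, dict):
        missing = [g for g in matrix.gene_ids if g not in key]
        if missing:
            log.warning("order_rows: %d gene(s) missing from key, using 0", len(missing))
        keyfun = lambda g: key.get(g, 0.0)  # noqa: E731
    else:
        keyfun = key
    scored = [(keyfun(g), g, i) for i, g in enumerate(matrix.gene_ids)]
    if descending:
        order = sorted(range(len(scored)), key=lambda i: (-scored[i][0], scored[i][1]))
    else:
        order = sorted(range(len(scored)), key=lambda i: (scored[i][0], scored[i][1]))
    return ProfileMatrix(
        [matrix.gene_ids[i] for i in order],
        matrix.axis,
        matrix.values[order],
        matrix.anchor,
        matrix.flank,
        matrix.bin_width,
        set(matrix.clipped),
    )


@dataclass
class ProfileComparison:
    """Per-bin metaprofile difference between two conditions with permutation p-values."""

    axis: np.ndarray
    diff: np.ndarray  # meanA - meanB
    pvalues: np.ndarray
    n_genes: int
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.axis, "diff": self.diff, "pvalue": self.pvalues}
        )


def compare_profiles(
    matrix_a: ProfileMatrix,
    matrix_b: ProfileMatrix,
    subset: Iterable[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ProfileComparison:
    """Per-bin difference of metaprofiles with a paired label-swap permutation test.

    Both matrices must share the axis and row universe (per-gene pairing).  The
    null swaps, independently per gene, which condition its row belongs to;
    two-sided p-values use (b + 1) / (n_perm + 1) smoothing.
    """
    if matrix_a.axis.shape != matrix_b.axis.shape or np.any(
        matrix_a.axis != matrix_b.axis
    ):
        raise ValueError("profile matrices have different axes")
    if matrix_a.gene_ids != matrix_b.gene_ids:
        raise ValueError("profile matrices have different row universes")
    if subset is not None:
        matrix_a = matrix_a.subset(subset)
        matrix_b = matrix_b.subset(subset)
    delta = matrix_a.values - matrix_b.values  # genes x bins
    n = delta.shape[0]
    obs = delta.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm = (signs @ delta) / n  # n_perm x bins
    exceed = (np.abs(perm) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
    pvals = (exceed + 1) / (n_perm + 1)
    return ProfileComparison(matrix_a.axis, obs, pvals, n, n_perm)
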