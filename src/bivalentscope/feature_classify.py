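"""Gene, promoter and enhancer classification schemes used for stratification.

Covers expression tiers (no / low / medium-high by RPKM), tissue-specific and
housekeeping gene selection across samples, CpG-content promoter classes
(LCP / ICP / HCP by windowed CpG observed/expected ratio and GC fraction),
chromatin promoter classes (K4, K27, K4/K27 bivalent, none by peak overlap),
and active/poised enhancer splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genomic_core import ExpressionTable, GeneModel, PeakSet, promoter_window

log = logging.getLogger(__name__)

CPG_CLASSES = ("LCP", "ICP", "HCP")
CHROMATIN_CLASSES = ("K4", "K27", "K4/K27", "none")
EXPRESSION_TIERS = ("none", "low", "mid_high")


@dataclass(frozen=True)
class PromoterClassification:
    gene_id: str
    cpg_class: str
    chromatin_class: str
    expression_tier: str

    def __post_init__(self) -> None:
        if self.cpg_class not in CPG_CLASSES:
            raise ValueError(f"bad cpg_class {self.cpg_class!r}")
        if self.chromatin_class not in CHROMATIN_CLASSES:
            raise ValueError(f"bad chromatin_class {self.chromatin_class!r}")
        if self.expression_tier not in EXPRESSION_TIERS:
            raise ValueError(f"bad expression_tier {self.expression_tier!r}")


def expression_tiers(
    table: ExpressionTable,
    sample: str,
    low_cut: float = 0.1,
    high_cut: float = 5.0,
) -> dict[str, str]:
    """Classify genes as none / low / mid_high expression by RPKM in one sample.

    Tier is ``none`` for RPKM < low_cut, ``low`` for low_cut <= RPKM < high_cut
    (left-closed), ``mid_high`` otherwise.  Defaults: 0.1 and 5 RPKM.
    """
    if not (0 <= low_cut < high_cut):
        raise ValueError("require 0 <= low_cut < high_cut")
    values = table.sample_values(sample)
    out = {}
    for gene, rpkm in values.items():
        if rpkm < low_cut:
            out[gene] = "none"
        elif rpkm < high_cut:
            out[gene] = "low"
        else:
            out[gene] = "mid_high"
    return out


def tissue_specific_genes(
    table: ExpressionTable,
    target: str,
    others: list[str],
    on_cut: float = 10.0,
    off_cut: float = 1.0,
) -> set[str]:
    """Genes expressed (RPKM >= on_cut) in the target sample and silent
    (RPKM < off_cut) in every other sample."""
    if target in others:
        raise ValueError("target sample must not be among the others")
    tv = table.sample_values(target)
    ov = [table.sample_values(s) for s in others]
    out = set()
    for gene in table.genes:
        if tv[gene] >= on_cut and all(v[gene] < off_cut for v in ov):
            out.add(gene)
    return out


def housekeeping_genes(
    table: ExpressionTable, samples: list[str], cut: float = 10.0
) -> set[str]:
    """Genes with RPKM strictly greater than ``cut`` in every listed sample."""
    if len(samples) < 2:
        raise ValueError("housekeeping selection needs >= 2 samples")
    vals = [table.sample_values(s) for s in samples]
    return {g for g in table.genes if all(v[g] > cut for v in vals)}


def cpg_observed_expected(seq: str) -> float:
    """CpG observed/expected ratio: (#CG dinucleotides * length) / (#C * #G)."""
    c = seq.count("C")
    g = seq.count("G")
    if c == 0 or g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (c * g)


def cpg_class(
    promoter_seq: str,
    window: int = 500,
    hcp_ratio: float = 0.75,
    hcp_gc: float = 0.55,
    lcp_ratio: float = 0.48,
) -> str:
    """LCP / ICP / HCP promoter class from windowed CpG content.

    Slides ``window``-bp windows (step 1) over the sequence; HCP if any window
    has CpG obs/exp ratio > hcp_ratio and GC fraction > hcp_gc; LCP if no
    window reaches lcp_ratio; ICP otherwise.  Sequences shorter than the
    window are scored as a single window.
    """
    seq = promoter_seq.upper()
    if len(seq) < 200:
        raise ValueError("promoter sequence must be >= 200 bp")
    n_count = seq.count("N")
    if n_count > len(seq) / 2:
        raise ValueError("promoter sequence is more than 50% N")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(seq), dtype=np.int64)
    if len(seq) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    w = min(window, len(seq))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    starts = np.arange(0, len(seq) - w + 1)
    c = cum_c[starts + w] - cum_c[starts]
    g = cum_g[starts + w] - cum_g[starts]
    # a CG dinucleotide counts in a window iff both bases are inside it
    cg = cum_cg[starts + w - 1] - cum_cg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((c > 0) & (g > 0), cg * w / np.maximum(c * g, 1), 0.0)
    gc = (c + g) / w
    if np.any((ratio > hcp_ratio) & (gc > hcp_gc)):
        return "HCP"
    if not np.any(ratio >= lcp_ratio):
        return "LCP"
    return "ICP"


def chromatin_class(
    gene: GeneModel,
    k4_peaks: PeakSet,
    k27_peaks: PeakSet,
    window: int = 1000,
    chrom_size: int | None = None,
) -> str:
    """K4 / K27 / K4/K27 / none by >= 1 bp peak overlap with tss +/- window."""
    if window <= 0:
        raise ValueError("window must be > 0")
    prom = promoter_window(gene, window, window, chrom_size)
    has_k4 = k4_peaks.overlaps_interval(prom)
    has_k27 = k27_peaks.overlaps_interval(prom)
    if has_k4 and has_k27:
        return "K4/K27"
    if has_k4:
        return "K4"
    if has_k27:
        return "K27"
    return "none"


def enhancer_class(
    enhancers: PeakSet,
    k27ac_peaks: PeakSet,
    k27me3_peaks: PeakSet,
) -> dict[int, str]:
    """Split enhancers into active (H3K27ac-overlapping) vs poised.

    Inputs are assumed pre-filtered to H3K4me1-positive distal elements; the
    k27me3 set is accepted for symmetry but any non-K27ac enhancer is poised.
    Returns {index in the sorted enhancer set: 'active' | 'poised'}.
    """
    if len(enhancers) == 0:
        raise ValueError("enhancer set is empty")
    out = {}
    for i, iv in enumerate(enhancers):
        out[i] = "active" if k27ac_peaks.overlaps_interval(iv) else "poised"
    return out


def classify_promoters(
    genes: list[GeneModel],
    sequences: dict[str, str],
    k4_peaks: PeakSet,
    k27_peaks: PeakSet,
    table: ExpressionTable,
    sample: str,
    chrom_size: int | None = None,
) -> list[PromoterClassification]:
    """Full per-gene classification combining all three schemes."""
    tiers = expression_tiers(table, sample)
    out = []
    for g in genes:
        out.append(
            PromoterClassification(
                gene_id=g.gene_id,
                cpg_class=cpg_class(sequences[g.gene_id]),
                chromatin_class=chromatin_class(
                    g, k4_peaks, k27_peaks, chrom_size=chrom_size
                ),
                expression_tier=tiers.get(g.gene_id, "none"),
            )
        )
    return out
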