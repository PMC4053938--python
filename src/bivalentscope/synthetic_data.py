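"""Synthetic genome, signal, peak, sequence, and expression generator.

Emulates the statistical structure the downstream analyses assume, with
ground truth for recovery tests:

* bivalent (K4/K27) promoters carry a bimodal Tet1 profile — a narrow
  component just upstream of the TSS plus a broad component centered a few
  hundred bp downstream — with 5hmC coincident with the downstream component
  and a broad H3K27me3 block;
* K4-only promoters carry a single narrow TSS-centered Tet1 component;
* 5hmC gene-body density rises with expression up to a mid-expression peak
  (log10 RPKM near 1) and falls again at high expression;
* promoter sequences hit target CpG classes (LCP / ICP / HCP);
* the expression table has tissue-specific and housekeeping structure across
  four samples (ESC, MEF, brain, liver).

All randomness flows through one numpy Generator seeded from SimConfig.seed,
and genes live on integer grids, so regeneration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .genomic_core import (
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    write_chrom_sizes,
    write_expression,
    write_gene_models,
    write_intervals,
    write_sequences,
    write_signal,
)

LOG10_LOW = -1.0  # log10 of the 0.1 RPKM tier cut
LOG10_HIGH = float(np.log10(5.0))


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixture."""

    seed: int = 1
    n_genes: int = 400
    chrom: str = "chrS"
    chrom_length: int = 12_000_000
    # promoter class mixture
    frac_bivalent: float = 0.30
    frac_k4_only: float = 0.50
    frac_silent: float = 0.20
    # bimodal truth for bivalent promoters (bp relative to TSS)
    mu1: float = -39.0
    sigma1: float = 80.0
    mu2: float = 455.0
    sigma2: float = 400.0
    weight_first: float = 0.4
    amplitude: float = 1.0
    # K4-only single component
    k4_sigma: float = 150.0
    k4_amplitude: float = 1.0
    # signal model
    noise_sd: float = 0.10  # fraction of component amplitude
    signal_step: int = 10  # bp resolution of emitted runs
    flank: int = 5000
    # 5hmC gene-body model: density peaks at log10 RPKM = 1, exons enriched
    hmc_body_max: float = 0.5
    hmc_body_logwidth: float = 0.8
    hmc_exon_boost: float = 1.5
    # Suz12 knockdown effect on the downstream 5hmC component
    kd_factor: float = 0.5
    # peak-calling stand-in
    peak_cutoff_frac: float = 0.25  # of the track's maximum amplitude
    peak_min_len: int = 50
    # expression model (log10 RPKM normals per tier, sd shared)
    expr_mu_none: float = -3.0
    expr_mu_low: float = 0.5
    expr_mu_mid: float = 1.5
    expr_sd: float = 0.6
    frac_housekeeping: float = 0.08  # of k4_only genes
    frac_liver_specific: float = 0.15  # of bivalent genes
    samples: tuple[str, ...] = ("ESC", "MEF", "brain", "liver")
    # CpG sequence model per class: (GC fraction, CpG retention)
    cpg_params: dict = field(
        default_factory=lambda: {
            "HCP": (0.60, 1.0),
            "ICP": (0.50, 0.60),
            "LCP": (0.40, 0.15),
        }
    )

    def __post_init__(self) -> None:
        total = self.frac_bivalent + self.frac_k4_only + self.frac_silent
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for name in ("sigma1", "sigma2", "k4_sigma", "amplitude", "expr_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Annotation:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    promoter_seqs: dict[str, str]
    gene_class: dict[str, str]  # bivalent | k4_only | silent
    cpg_target: dict[str, str]
    enhancers: PeakSet


@dataclass
class SimData:
    tracks: dict[str, SignalTrack]
    peaks: dict[str, PeakSet]
    expression: ExpressionTable
    truth: pd.DataFrame
    enhancer_truth: pd.DataFrame


# ------------------------------------------------------------------ sequences


def _draw_promoter_seq(rng: np.random.Generator, n: int, gc: float, keep_cpg: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    if keep_cpg < 1.0:
        cg = np.flatnonzero((bases[:-1] == ord("C")) & (bases[1:] == ord("G")))
        drop = cg[rng.random(len(cg)) > keep_cpg]
        bases[drop + 1] = ord("A")  # break the dinucleotide
    return bases.tobytes().decode()


# ------------------------------------------------------------------ annotation


def generate_annotation(config: SimConfig) -> Annotation:
    """Non-overlapping genes with mixed strands, exon structure, target CpG
    classes, and intergenic enhancer elements."""
    if config.n_genes < 10:
        raise ValueError("need n_genes >= 10")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    counts = [
        int(round(n * config.frac_bivalent)),
        int(round(n * config.frac_k4_only)),
    ]
    counts.append(n - sum(counts))
    classes = (
        ["bivalent"] * counts[0] + ["k4_only"] * counts[1] + ["silent"] * counts[2]
    )
    rng.shuffle(classes)

    genes: list[GeneModel] = []
    gene_class: dict[str, str] = {}
    cpg_target: dict[str, str] = {}
    seqs: dict[str, str] = {}
    enhancer_ivs: list[GenomicInterval] = []
    cursor = 10_000
    for i in range(n):
        gid = f"g{i:04d}"
        length = int(rng.integers(200, 1200)) * 10  # 2-12 kb, 10 bp grid
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor, cursor + length
        if end + config.flank > config.chrom_length:
            raise ValueError("genes do not fit in chrom_length")
        n_ex = int(rng.integers(2, 9))
        cuts = np.sort(
            rng.choice(np.arange(1, length // 10), size=2 * n_ex - 2, replace=False)
        ) * 10
        bounds = np.concatenate([[0], cuts, [length]])
        exons = tuple(
            GenomicInterval(config.chrom, start + int(bounds[2 * j]),
                            start + int(bounds[2 * j + 1]), strand)
            for j in range(n_ex)
        )
        gene = GeneModel(gid, GenomicInterval(config.chrom, start, end, strand), exons)
        genes.append(gene)
        cls = classes[i]
        gene_class[gid] = cls
        if cls == "bivalent":
            cpg = "HCP"
        elif cls == "k4_only":
            cpg = "HCP" if rng.random() < 0.8 else "ICP"
        else:
            cpg = "LCP" if rng.random() < 0.6 else "ICP"
        cpg_target[gid] = cpg
        gc, keep = config.cpg_params[cpg]
        seqs[gid] = _draw_promoter_seq(rng, 2000, gc, keep)
        # one distal enhancer upstream of every third gene slot, clear of all
        # gene signal regions (which extend at most 5 kb beyond the gene)
        if i % 3 == 0:
            enhancer_ivs.append(
                GenomicInterval(config.chrom, start - 8500, start - 8100)
            )
        cursor = end + int(rng.integers(1400, 1800)) * 10  # 14-18 kb gap
    return Annotation(
        genes=genes,
        chrom_sizes={config.chrom: config.chrom_length},
        promoter_seqs=seqs,
        gene_class=gene_class,
        cpg_target=cpg_target,
        enhancers=PeakSet(enhancer_ivs, source="enhancers"),
    )


# ------------------------------------------------------------------ signal


def _bimodal(d: np.ndarray, mu1, s1, mu2, s2, w, a) -> np.ndarray:
    return a * (
        w * np.exp(-((d - mu1) ** 2) / (2 * s1**2))
        + (1 - w) * np.exp(-((d - mu2) ** 2) / (2 * s2**2))
    )


def _offset_cells_to_genome(
    tss: int, strand: str, d_start: np.ndarray, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Genome [start, end) of cells covering transcript offsets [d, d + step)."""
    if strand == "+":
        return tss + d_start, tss + d_start + step
    return tss - d_start - step + 1, tss - d_start + 1


def _truncnorm_draw(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def threshold_peaks(
    track: SignalTrack, cutoff: float, min_len: int, source: str = ""
) -> PeakSet:
    """Peak-calling stand-in: maximal runs of contiguous signal above cutoff
    spanning at least min_len bp."""
    out = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end, value in track.iter_runs():
        above = value > cutoff
        if above and chrom == cur_chrom and start == cur_end:
            cur_end = end
            continue
        if cur_chrom is not None and cur_end - cur_start >= min_len:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
        cur_chrom, cur_start, cur_end = (chrom, start, end) if above else (None, 0, 0)
    if cur_chrom is not None and cur_end - cur_start >= min_len:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return PeakSet(out, source=source)


def generate_tracks(annotation: Annotation, config: SimConfig) -> SimData:
    """Signal tracks, peak sets, expression table and truth labels."""
    rng = np.random.default_rng(config.seed + 1)
    step = config.signal_step
    chrom = config.chrom
    genes = annotation.genes
    n = len(genes)
    gids = [g.gene_id for g in genes]
    cls = np.array([annotation.gene_class[g] for g in gids])

    # ---------------- expression -------------------------------------------
    tier_mu = {"none": config.expr_mu_none, "low": config.expr_mu_low,
               "mid_high": config.expr_mu_mid}
    tier_rng = {"none": (-8.0, LOG10_LOW - 1e-6),
                "low": (LOG10_LOW, LOG10_HIGH - 1e-6),
                "mid_high": (LOG10_HIGH, 3.5)}
    tier = np.empty(n, dtype=object)
    for i in range(n):
        c = cls[i]
        if c == "silent":
            tier[i] = "none"
        elif c == "bivalent":
            tier[i] = "none" if rng.random() < 0.5 else "low"
        else:
            tier[i] = "low" if rng.random() < 0.3 else "mid_high"
    housekeeping = np.zeros(n, dtype=bool)
    liver_specific = np.zeros(n, dtype=bool)
    k4_idx = np.flatnonzero(cls == "k4_only")
    biv_idx = np.flatnonzero(cls == "bivalent")
    hk = rng.choice(k4_idx, size=int(round(len(k4_idx) * config.frac_housekeeping)),
                    replace=False)
    housekeeping[np.sort(hk)] = True
    tier[housekeeping] = "mid_high"
    ls = rng.choice(biv_idx, size=int(round(len(biv_idx) * config.frac_liver_specific)),
                    replace=False)
    liver_specific[np.sort(ls)] = True
    tier[liver_specific] = "none"  # silent in ESC, expressed in liver

    expr = pd.DataFrame(index=pd.Index(gids, name="gene_id"),
                        columns=list(config.samples), dtype=float)
    for sample in config.samples:
        log10 = np.empty(n)
        for t in ("none", "low", "mid_high"):
            idx = np.flatnonzero((tier == t) & ~housekeeping & ~liver_specific)
            lo, hi = tier_rng[t]
            log10[idx] = _truncnorm_draw(rng, tier_mu[t], config.expr_sd, lo, hi,
                                         len(idx))
        hk_idx = np.flatnonzero(housekeeping)
        log10[hk_idx] = _truncnorm_draw(rng, 1.7, config.expr_sd, 1.05, 3.5,
                                        len(hk_idx))
        ls_idx = np.flatnonzero(liver_specific)
        if sample == "liver":
            log10[ls_idx] = _truncnorm_draw(rng, 1.7, config.expr_sd, 1.05, 3.5,
                                            len(ls_idx))
        else:
            log10[ls_idx] = _truncnorm_draw(rng, config.expr_mu_none, config.expr_sd,
                                            -8.0, -0.05, len(ls_idx))
        expr[sample] = np.power(10.0, log10)
    table = ExpressionTable(expr)

    # ---------------- signal tracks ----------------------------------------
    trk_runs: dict[str, list[tuple[str, int, int, float]]] = {
        "tet1": [], "5hmc": [], "5hmc_kd": [], "k27me3": []
    }
    ref_amp = {
        "tet1": max(config.amplitude, config.k4_amplitude),
        "5hmc": max(config.amplitude * (1 - config.weight_first), config.hmc_body_max),
        "5hmc_kd": max(config.amplitude * (1 - config.weight_first),
                       config.hmc_body_max),
        "k27me3": 1.0,
    }

    def emit(name: str, gene: GeneModel, d_start: np.ndarray, base: np.ndarray) -> None:
        """Add noise where the deterministic signal lives, clip, store runs."""
        mask = base > 1e-3 * ref_amp[name]
        vals = base.copy()
        if config.noise_sd > 0 and mask.any():
            vals[mask] += rng.normal(0.0, config.noise_sd * ref_amp[name],
                                     int(mask.sum()))
        np.clip(vals, 0.0, None, out=vals)
        keep = mask & (vals > 0)
        if not keep.any():
            return
        s, e = _offset_cells_to_genome(gene.tss, gene.strand, d_start[keep], step)
        trk_runs[name].extend(zip([chrom] * int(keep.sum()),
                                  s.tolist(), e.tolist(), vals[keep].tolist()))

    esc_rpkm = expr["ESC"].to_numpy()
    for i, gene in enumerate(genes):
        L = gene.length
        d_start = np.arange(-config.flank, max(config.flank, L), step)
        centers = d_start + step / 2.0
        in_body = (d_start >= 0) & (d_start < L)
        c = cls[i]
        # Tet1
        if c == "bivalent":
            tet1 = _bimodal(centers, config.mu1, config.sigma1, config.mu2,
                            config.sigma2, config.weight_first, config.amplitude)
        elif c == "k4_only":
            tet1 = config.k4_amplitude * np.exp(-(centers**2) / (2 * config.k4_sigma**2))
        else:
            tet1 = np.zeros_like(centers)
        emit("tet1", gene, d_start, tet1)
        # H3K27me3: broad block on bivalent promoters
        if c == "bivalent":
            k27 = np.where((centers >= -500) & (centers <= 2500), 1.0, 0.0)
            emit("k27me3", gene, d_start, k27)
        # 5hmC: downstream component on bivalent promoters + expression-tuned body
        body_density = config.hmc_body_max * np.exp(
            -((np.log10(esc_rpkm[i]) - 1.0) ** 2) / (2 * config.hmc_body_logwidth**2)
        )
        # exons carry more gene-body 5hmC than introns
        in_exon = np.zeros_like(in_body)
        for ex in gene.exons:
            if gene.strand == "+":
                lo, hi = ex.start - gene.interval.start, ex.end - gene.interval.start
            else:
                lo = gene.interval.end - ex.end
                hi = gene.interval.end - ex.start
            in_exon |= (d_start >= lo) & (d_start < hi)
        body = np.where(in_body, body_density, 0.0) * np.where(
            in_exon, config.hmc_exon_boost, 1.0
        )
        if c == "bivalent":
            down = config.amplitude * (1 - config.weight_first) * np.exp(
                -((centers - config.mu2) ** 2) / (2 * config.sigma2**2)
            )
            emit("5hmc", gene, d_start, body + down)
            emit("5hmc_kd", gene, d_start, body + config.kd_factor * down)
        else:
            emit("5hmc", gene, d_start, body)
            emit("5hmc_kd", gene, d_start, body)

    # enhancer-local signal: 5hmC on active enhancers (ESC), K27me3 on poised
    enh_class = {}
    for j, iv in enumerate(annotation.enhancers):
        enh_class[j] = "active" if j % 2 == 0 else "poised"
        cells = np.arange(iv.start, iv.end, step)
        vals = np.full(len(cells), 0.4)
        if config.noise_sd > 0:
            vals += rng.normal(0.0, config.noise_sd * 0.4, len(cells))
        vals = np.clip(vals, 0.0, None)
        name = "5hmc" if enh_class[j] == "active" else "k27me3"
        rows = list(zip([chrom] * len(cells), cells.tolist(),
                        (cells + step).tolist(), vals.tolist()))
        trk_runs[name].extend(rows)
        if name == "5hmc":
            trk_runs["5hmc_kd"].extend(rows)

    sizes = annotation.chrom_sizes
    tracks = {name: SignalTrack.from_intervals(runs, sizes)
              for name, runs in trk_runs.items()}

    # ---------------- peak sets --------------------------------------------
    peaks: dict[str, PeakSet] = {}
    for name in ("tet1", "5hmc", "k27me3"):
        cutoff = config.peak_cutoff_frac * ref_amp[name]
        peaks[name] = threshold_peaks(tracks[name], cutoff, config.peak_min_len,
                                      source=name)

    def offset_iv(gene: GeneModel, d1: int, d2: int) -> GenomicInterval:
        """Interval covering transcript offsets [d1, d2] inclusive."""
        if gene.strand == "+":
            return GenomicInterval(chrom, gene.tss + d1, gene.tss + d2 + 1)
        return GenomicInterval(chrom, gene.tss - d2, gene.tss - d1 + 1)

    k4me3, suz12, sin3a = [], [], []
    for i, gene in enumerate(genes):
        if cls[i] in ("bivalent", "k4_only"):
            k4me3.append(offset_iv(gene, -500, 500))
            sin3a.append(offset_iv(gene, -200, 200))
        if cls[i] == "bivalent":
            suz12.append(offset_iv(gene, 100, 800))
        if cls[i] == "silent":
            # most, not all, silent promoters keep Sin3a
            if rng.random() < 0.7:
                sin3a.append(offset_iv(gene, -200, 200))
            # a minority of silent genes carry PRC2 without Tet1
            if rng.random() < 0.15:
                suz12.append(offset_iv(gene, 100, 800))
    # Sin3a also binds many Tet1-free distal sites (midway into the gap)
    for i, gene in enumerate(genes):
        if i % 2 == 0:
            start = gene.interval.start - 7000
            sin3a.append(GenomicInterval(chrom, start, start + 300))
    peaks["k4me3"] = PeakSet(k4me3, source="k4me3")
    peaks["suz12"] = PeakSet(suz12, source="suz12")
    peaks["sin3a"] = PeakSet(sin3a, source="sin3a")
    peaks["k27ac"] = PeakSet(
        [iv for j, iv in enumerate(annotation.enhancers) if enh_class[j] == "active"],
        source="k27ac",
    )
    peaks["enhancers"] = annotation.enhancers

    truth = pd.DataFrame(
        {
            "gene_id": gids,
            "gene_class": cls,
            "cpg_class": [annotation.cpg_target[g] for g in gids],
            "expression_tier": tier,
            "housekeeping": housekeeping,
            "liver_specific": liver_specific,
            "mu1": np.where(cls == "bivalent", config.mu1, np.nan),
            "sigma1": np.where(cls == "bivalent", config.sigma1, np.nan),
            "mu2": np.where(cls == "bivalent", config.mu2, np.nan),
            "sigma2": np.where(cls == "bivalent", config.sigma2, np.nan),
            "weight_first": np.where(cls == "bivalent", config.weight_first, np.nan),
            "amplitude": np.where(cls == "bivalent", config.amplitude, np.nan),
        }
    ).set_index("gene_id")
    enh_truth = pd.DataFrame(
        {
            "start": [iv.start for iv in annotation.enhancers],
            "end": [iv.end for iv in annotation.enhancers],
            "state": [enh_class[j] for j in range(len(annotation.enhancers))],
        }
    )
    return SimData(tracks=tracks, peaks=peaks, expression=table, truth=truth,
                   enhancer_truth=enh_truth)


# ------------------------------------------------------------------ fixture


def emit_fixture(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the full file bundle plus a manifest with config echo and
    per-file checksums; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    data = generate_tracks(annotation, config)

    write_gene_models(annotation.genes, out / "genes.bed12")
    write_chrom_sizes(annotation.chrom_sizes, out / "chrom.sizes")
    write_sequences(annotation.promoter_seqs, out / "promoters.fa")
    write_expression(data.expression, out / "expression.tsv")
    data.truth.to_csv(out / "truth_genes.tsv", sep="\t", float_format="%.6g")
    data.enhancer_truth.to_csv(out / "truth_enhancers.tsv", sep="\t", index=False)
    for name, track in data.tracks.items():
        write_signal(track, out / f"track_{name}.bedgraph")
    for name, ps in data.peaks.items():
        fname = "enhancers.bed" if name == "enhancers" else f"peaks_{name}.bed"
        write_intervals(ps, out / fname)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    checksums = {}
    for fname in files:
        h = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        checksums[fname] = h
    cfg = asdict(config)
    cfg["samples"] = list(cfg["samples"])
    manifest = {"seed": config.seed, "config": cfg, "files": checksums}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
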