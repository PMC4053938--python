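"""Orchestration of the figure-level analyses over a file bundle.

Each analysis is a pure function of (inputs, parameters) writing deterministic
TSV/JSON outputs; a manifest records parameters, seeds and the
multiple-testing adjustment (Benjamini-Hochberg within each analysis's
p-value family).  Missing inputs for a requested analysis fail before any
computation starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cooccupancy import (
    benjamini_hochberg,
    element_density,
    enrichment_test,
    overlap_fraction,
    signal_correlation,
)
from .feature_classify import (
    chromatin_class,
    cpg_class,
    enhancer_class,
    expression_tiers,
    housekeeping_genes,
    tissue_specific_genes,
)
from .genomic_core import (
    GenomicInterval,
    PeakSet,
    promoter_window,
    read_chrom_sizes,
    read_expression,
    read_gene_models,
    read_intervals,
    read_sequences,
    read_signal,
)
from .profile_decomposition import cluster_profiles, cluster_stability, fit_two_gaussians
from .profile_engine import (
    build_scaled_body_matrix,
    build_tss_matrix,
    compare_profiles,
    genebody_density,
    mean_profile,
    order_rows,
)

log = logging.getLogger(__name__)

ALL_ANALYSES = (
    "fig1_heatmaps",
    "fig2_densities",
    "fig2_cormat",
    "fig3_k27_profiles",
    "fig4_overlap",
    "fig4_cluster",
    "fig4_fit",
    "fig6_differential",
)

#: input keys each analysis needs (keys into RunConfig.inputs)
REQUIRED_INPUTS = {
    "fig1_heatmaps": ["genes", "chrom_sizes", "expression", "track_5hmc"],
    "fig2_densities": [
        "genes", "chrom_sizes", "expression", "promoters_fa", "peaks_5hmc",
        "peaks_k4me3", "peaks_k27me3", "enhancers", "peaks_k27ac",
    ],
    "fig2_cormat": [
        "genes", "chrom_sizes", "track_5hmc", "track_k27me3", "track_tet1",
        "peaks_k4me3", "peaks_suz12", "peaks_sin3a",
    ],
    "fig3_k27_profiles": ["genes", "chrom_sizes", "track_5hmc", "track_k27me3"],
    "fig4_overlap": ["peaks_suz12", "peaks_sin3a", "peaks_tet1"],
    "fig4_cluster": ["genes", "chrom_sizes", "track_tet1"],
    "fig4_fit": [
        "genes", "chrom_sizes", "track_tet1", "peaks_k4me3", "peaks_k27me3",
    ],
    "fig6_differential": [
        "genes", "chrom_sizes", "track_5hmc", "track_5hmc_kd", "peaks_k4me3",
        "peaks_k27me3",
    ],
}


@dataclass
class RunConfig:
    inputs: dict[str, str]  # input key -> path
    out_dir: str
    analyses: list[str] = field(default_factory=lambda: list(ALL_ANALYSES))
    flank: int = 5000
    bin_width: int = 50
    narrow_flank: int = 2000
    narrow_bin_width: int = 25
    n_body_bins: int = 100
    k: int = 2
    n_perm: int = 999
    n_realizations: int = 100
    seed: int = 0
    expression_sample: str = "ESC"


def fixture_run_config(fixture_dir: str | Path, out_dir: str | Path,
                       **overrides) -> RunConfig:
    """RunConfig wired to the file names emit_fixture writes."""
    d = Path(fixture_dir)
    inputs = {
        "genes": str(d / "genes.bed12"),
        "chrom_sizes": str(d / "chrom.sizes"),
        "expression": str(d / "expression.tsv"),
        "promoters_fa": str(d / "promoters.fa"),
        "enhancers": str(d / "enhancers.bed"),
    }
    for mark in ("tet1", "5hmc", "5hmc_kd", "k27me3"):
        inputs[f"track_{mark}"] = str(d / f"track_{mark}.bedgraph")
    for mark in ("tet1", "5hmc", "k4me3", "k27me3", "suz12", "sin3a", "k27ac"):
        inputs[f"peaks_{mark}"] = str(d / f"peaks_{mark}.bed")
    return RunConfig(inputs=inputs, out_dir=str(out_dir), **overrides)


class _Loader:
    """Lazy, cached input loading so each file parses once per run."""

    def __init__(self, inputs: dict[str, str]):
        self.inputs = inputs
        self.cache: dict[str, object] = {}
        self.chrom_sizes = None
        if "chrom_sizes" in inputs:
            self.chrom_sizes = read_chrom_sizes(inputs["chrom_sizes"])

    def __call__(self, key: str):
        if key not in self.cache:
            path = self.inputs[key]
            if key == "genes":
                self.cache[key] = read_gene_models(path)
            elif key == "expression":
                self.cache[key] = read_expression(path)
            elif key == "promoters_fa":
                self.cache[key] = read_sequences(path)
            elif key.startswith("track_"):
                self.cache[key] = read_signal(path, self.chrom_sizes)
            else:
                self.cache[key] = read_intervals(path, source=key.removeprefix("peaks_"))
        return self.cache[key]


def _chromatin_classes(load: _Loader) -> dict[str, str]:
    genes = load("genes")
    k4, k27 = load("peaks_k4me3"), load("peaks_k27me3")
    sizes = load.chrom_sizes or {}
    return {
        g.gene_id: chromatin_class(g, k4, k27, chrom_size=sizes.get(g.chrom))
        for g in genes
    }


def _promoter_peakset(load: _Loader, half: int = 1000) -> PeakSet:
    sizes = load.chrom_sizes or {}
    ivs = [promoter_window(g, half, half, sizes.get(g.chrom)) for g in load("genes")]
    return PeakSet(ivs, source="promoters")


def run(config: RunConfig) -> dict:
    """Execute the requested analyses; returns a manifest dict (also written
    to out_dir/manifest.json)."""
    unknown = [a for a in config.analyses if a not in ALL_ANALYSES]
    if unknown:
        raise ValueError(f"unknown analyses: {unknown}")
    missing = []
    for a in config.analyses:
        for key in REQUIRED_INPUTS[a]:
            if key not in config.inputs:
                missing.append((a, key))
            elif not Path(config.inputs[key]).exists():
                missing.append((a, config.inputs[key]))
    if missing:
        raise FileNotFoundError(f"missing inputs for requested analyses: {missing}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(logging.INFO)
    root = logging.getLogger("bivalentscope")
    root.addHandler(fh)
    load = _Loader(config.inputs)
    outputs: dict[str, list[str]] = {}
    try:
        for a in config.analyses:
            log.info("running %s", a)
            outputs[a] = _DISPATCH[a](load, config, out)
    finally:
        root.removeHandler(fh)
        fh.close()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "flank": config.flank, "bin_width": config.bin_width,
            "narrow_flank": config.narrow_flank,
            "narrow_bin_width": config.narrow_bin_width,
            "n_body_bins": config.n_body_bins, "k": config.k,
            "n_perm": config.n_perm, "n_realizations": config.n_realizations,
            "expression_sample": config.expression_sample,
        },
        "multiple_testing": "Benjamini-Hochberg within each analysis family",
        "analyses": outputs,
    }
    with open(out / "manifest.json", "w") as fh2:
        json.dump(manifest, fh2, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------------------- analyses


def _fig1(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    genes = load("genes")
    track = load("track_5hmc")
    table = load("expression")
    sample = cfg.expression_sample
    rpkm = {g: table.rpkm(g, sample) for g in table.genes}
    matrix = build_scaled_body_matrix(track, genes, flank=2000,
                                     n_body_bins=cfg.n_body_bins,
                                     bin_width=cfg.bin_width)
    ordered = order_rows(matrix, rpkm, descending=True)
    ordered.to_tsv(out / "fig1_body_matrix.tsv")
    tiers = expression_tiers(table, sample)
    rows = []
    for tier in ("none", "low", "mid_high"):
        subset = [g for g in matrix.gene_ids if tiers.get(g) == tier]
        if subset:
            mp = mean_profile(matrix, subset)
            for pos, val in zip(mp.axis, mp.values):
                rows.append({"tier": tier, "position": pos, "mean_signal": val,
                             "n_genes": mp.n_genes})
    pd.DataFrame(rows).to_csv(out / "fig1_tier_profiles.tsv", sep="\t", index=False,
                              float_format="%.6g")
    # liver-specific vs housekeeping metaprofiles
    others = [s for s in table.samples if s != "liver"]
    liver = tissue_specific_genes(table, "liver", others)
    hk = housekeeping_genes(table, table.samples)
    rows = []
    for name, subset in (("liver_specific", liver), ("housekeeping", hk)):
        common = [g for g in matrix.gene_ids if g in subset]
        if common:
            mp = mean_profile(matrix, common)
            for pos, val in zip(mp.axis, mp.values):
                rows.append({"group": name, "position": pos, "mean_signal": val,
                             "n_genes": mp.n_genes})
    pd.DataFrame(rows).to_csv(out / "fig1_group_profiles.tsv", sep="\t", index=False,
                              float_format="%.6g")
    dens = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "rpkm": [rpkm.get(g.gene_id, 0.0) for g in genes],
            "genebody_density": [genebody_density(track, g) for g in genes],
        }
    )
    dens.to_csv(out / "fig1_genebody_density.tsv", sep="\t", index=False,
                float_format="%.6g")
    return ["fig1_body_matrix.tsv", "fig1_tier_profiles.tsv",
            "fig1_group_profiles.tsv", "fig1_genebody_density.tsv"]


def _fig2_densities(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    genes = load("genes")
    marks = load("peaks_5hmc")
    seqs = load("promoters_fa")
    sizes = load.chrom_sizes or {}
    proms = _promoter_peakset(load)
    exons = PeakSet([ex for g in genes for ex in g.exons], source="exons")
    introns = []
    for g in genes:
        prev = None
        for ex in g.exons:
            if prev is not None and ex.start > prev:
                introns.append(GenomicInterval(g.chrom, prev, ex.start, g.strand))
            prev = ex.end
    introns = PeakSet(introns, source="introns")
    chrom_cls = _chromatin_classes(load)
    cpg = {g.gene_id: cpg_class(seqs[g.gene_id]) for g in genes if g.gene_id in seqs}

    def prom_subset(ids: set[str], label: str) -> PeakSet:
        return PeakSet(
            [promoter_window(g, 1000, 1000, sizes.get(g.chrom))
             for g in genes if g.gene_id in ids],
            source=label,
        )

    enh = load("enhancers")
    states = enhancer_class(enh, load("peaks_k27ac"), load("peaks_k27me3"))
    active = PeakSet([iv for i, iv in enumerate(enh) if states[i] == "active"],
                     source="enhancers_active")
    poised = PeakSet([iv for i, iv in enumerate(enh) if states[i] == "poised"],
                     source="enhancers_poised")

    classes: dict[str, PeakSet] = {"promoters": proms, "exons": exons,
                                   "introns": introns}
    for label in ("LCP", "ICP", "HCP"):
        ids = {g for g, c in cpg.items() if c == label}
        if ids:
            classes[f"cpg_{label}"] = prom_subset(ids, f"cpg_{label}")
    for label in ("K4", "K27", "K4/K27"):
        ids = {g for g, c in chrom_cls.items() if c == label}
        if ids:
            key = "chromatin_" + label.replace("/", "")
            classes[key] = prom_subset(ids, key)
    if len(active):
        classes["enhancers_active"] = active
    if len(poised):
        classes["enhancers_poised"] = poised

    entries = [element_density(marks, ps, label) for label, ps in classes.items()]
    pd.DataFrame(
        {
            "class": [e.label for e in entries],
            "total_bp": [e.total_bp for e in entries],
            "covered_bp": [e.covered_bp for e in entries],
            "density": [e.density for e in entries],
        }
    ).to_csv(out / "fig2_densities.tsv", sep="\t", index=False, float_format="%.6g")

    pairs = [
        ("exons", "introns"),
        ("cpg_LCP", "cpg_HCP"),
        ("cpg_ICP", "cpg_HCP"),
        ("chromatin_K4K27", "chromatin_K4"),
        ("chromatin_K27", "chromatin_K4"),
        ("enhancers_active", "enhancers_poised"),
    ]
    rows = []
    for i, (a, b) in enumerate(pairs):
        if a not in classes or b not in classes:
            continue
        p, delta, method = enrichment_test(
            marks, classes[a], classes[b], n_perm=cfg.n_perm, seed=cfg.seed + i
        )
        rows.append({"class_a": a, "class_b": b, "delta_density": delta,
                     "pvalue": p, "method": method})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["qvalue_bh"] = benjamini_hochberg(tests["pvalue"].to_numpy())
    tests.to_csv(out / "fig2_enrichment_tests.tsv", sep="\t", index=False,
                 float_format="%.6g")
    return ["fig2_densities.tsv", "fig2_enrichment_tests.tsv"]


def _fig2_cormat(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    proms = _promoter_peakset(load)
    inputs = [
        ("5hmC", load("track_5hmc")),
        ("H3K27me3", load("track_k27me3")),
        ("Tet1", load("track_tet1")),
        ("H3K4me3", load("peaks_k4me3")),
        ("Suz12", load("peaks_suz12")),
        ("Sin3a", load("peaks_sin3a")),
    ]
    mat = signal_correlation(inputs, proms)
    mat.to_csv(out / "fig2_mark_correlation.tsv", sep="\t", float_format="%.6g")
    return ["fig2_mark_correlation.tsv"]


def _fig3(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    genes = load("genes")
    sizes = load.chrom_sizes or {}
    k27_track = load("track_k27me3")
    hmc_track = load("track_5hmc")
    k27_level = {
        g.gene_id: genebody_window_level(k27_track, g, sizes.get(g.chrom))
        for g in genes
    }
    hmc = build_tss_matrix(hmc_track, genes, cfg.flank, cfg.bin_width)
    k27 = build_tss_matrix(k27_track, genes, cfg.flank, cfg.bin_width)
    order_rows(hmc, k27_level).to_tsv(out / "fig3_5hmc_matrix.tsv")
    order_rows(k27, k27_level).to_tsv(out / "fig3_k27me3_matrix.tsv")
    positive = [g for g, v in k27_level.items() if v > 0]
    rows = []
    for name, mat in (("5hmC", hmc), ("H3K27me3", k27)):
        mp = mean_profile(mat, positive)
        for pos, val in zip(mp.axis, mp.values):
            rows.append({"mark": name, "position": pos, "mean_signal": val,
                         "n_genes": mp.n_genes})
    pd.DataFrame(rows).to_csv(out / "fig3_k27pos_profiles.tsv", sep="\t",
                              index=False, float_format="%.6g")
    return ["fig3_5hmc_matrix.tsv", "fig3_k27me3_matrix.tsv",
            "fig3_k27pos_profiles.tsv"]


def genebody_window_level(track, gene, chrom_size=None, half: int = 1000) -> float:
    """Mean per-bp signal over the tss +/- half window (row-ordering key)."""
    w = promoter_window(gene, half, half, chrom_size)
    return track.integral(w.chrom, w.start, w.end) / w.length


def _fig4_overlap(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    tet1 = load("peaks_tet1")
    rows = []
    for key in ("peaks_suz12", "peaks_sin3a"):
        rep = overlap_fraction(load(key), tet1)
        rows.append({"source": rep.source, "target": rep.target,
                     "n_source": rep.n_source, "n_hit": rep.n_hit,
                     "fraction": rep.fraction})
    pd.DataFrame(rows).to_csv(out / "fig4_overlap.tsv", sep="\t", index=False,
                              float_format="%.6g")
    return ["fig4_overlap.tsv"]


def _fig4_cluster(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    matrix = build_tss_matrix(load("track_tet1"), load("genes"), cfg.flank,
                              cfg.bin_width)
    result = cluster_profiles(matrix, cfg.k, seed=cfg.seed)
    pd.DataFrame(
        {"gene_id": sorted(result.assignment),
         "cluster": [result.assignment[g] for g in sorted(result.assignment)]}
    ).to_csv(out / "fig4_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(result.centroids.T, index=matrix.axis,
                 columns=[f"cluster_{c}" for c in range(cfg.k)]).to_csv(
        out / "fig4_centroids.tsv", sep="\t", index_label="position",
        float_format="%.6g")
    stab = cluster_stability(matrix, cfg.k, cfg.n_realizations, base_seed=cfg.seed)
    with open(out / "fig4_stability.json", "w") as fh:
        json.dump({"n_realizations": stab.n_realizations,
                   "mean_ari": stab.mean_ari}, fh, indent=2, sort_keys=True)
    return ["fig4_clusters.tsv", "fig4_centroids.tsv", "fig4_stability.json"]


def _fig4_fit(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    genes = load("genes")
    chrom_cls = _chromatin_classes(load)
    bivalent = [g.gene_id for g in genes
                if chrom_cls[g.gene_id] in ("K4/K27", "K27")]
    matrix = build_tss_matrix(load("track_tet1"), genes, cfg.flank, cfg.bin_width)
    mp = mean_profile(matrix, bivalent)
    fit = fit_two_gaussians(mp, bin_width=cfg.bin_width)
    payload = fit.to_dict()
    payload["n_genes"] = mp.n_genes
    with open(out / "fig4_bimodal_fit.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return ["fig4_bimodal_fit.json"]


def _fig6(load: _Loader, cfg: RunConfig, out: Path) -> list[str]:
    genes = load("genes")
    chrom_cls = _chromatin_classes(load)
    k27pos = [g.gene_id for g in genes if chrom_cls[g.gene_id] in ("K4/K27", "K27")]
    ctrl = build_tss_matrix(load("track_5hmc"), genes, cfg.narrow_flank,
                            cfg.narrow_bin_width)
    kd = build_tss_matrix(load("track_5hmc_kd"), genes, cfg.narrow_flank,
                          cfg.narrow_bin_width)
    cmp_ = compare_profiles(ctrl, kd, subset=k27pos, n_perm=cfg.n_perm,
                            seed=cfg.seed)
    df = cmp_.to_frame()
    df["qvalue_bh"] = benjamini_hochberg(df["pvalue"].to_numpy())
    df.to_csv(out / "fig6_differential.tsv", sep="\t", index=False,
              float_format="%.6g")
    return ["fig6_differential.tsv"]


_DISPATCH = {
    "fig1_heatmaps": _fig1,
    "fig2_densities": _fig2_densities,
    "fig2_cormat": _fig2_cormat,
    "fig3_k27_profiles": _fig3,
    "fig4_overlap": _fig4_overlap,
    "fig4_cluster": _fig4_cluster,
    "fig4_fit": _fig4_fit,
    "fig6_differential": _fig6,
}
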