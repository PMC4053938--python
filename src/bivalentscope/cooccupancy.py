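"""Element-class mark densities, co-binding fractions, and mark correlations.

Density is the covered-bp fraction of an element class: bp of the (merged)
elements overlapped by >= 1 mark interval, divided by total element bp.
Enrichment between two element classes is assessed by a label-reassignment
permutation test; when the number of distinct reassignments is small enough
the null is enumerated exhaustively, otherwise it is sampled with a seeded
generator and (b + 1) / (n + 1) smoothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genomic_core import PeakSet, SignalTrack

log = logging.getLogger(__name__)


@dataclass
class DensityEntry:
    label: str
    total_bp: int
    covered_bp: float
    density: float  # covered / total in [0, 1]


@dataclass
class DensityReport:
    entries: list[DensityEntry]
    pvalues: pd.DataFrame | None = None  # pairwise, raw
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [e.label for e in self.entries],
                "total_bp": [e.total_bp for e in self.entries],
                "covered_bp": [e.covered_bp for e in self.entries],
                "density": [e.density for e in self.entries],
            }
        )


@dataclass
class OverlapReport:
    source: str
    target: str
    n_source: int
    n_hit: int

    @property
    def fraction(self) -> float:
        return self.n_hit / self.n_source


def _per_element_coverage(
    marks: PeakSet, elements: PeakSet
) -> tuple[np.ndarray, np.ndarray]:
    """(covered bp, length) per merged element interval."""
    merged = elements.merged()
    cov = marks.coverage_track()
    lengths = np.array([iv.length for iv in merged.intervals], dtype=np.int64)
    covered = np.empty(len(merged.intervals))
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(merged.intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        s = np.array([merged.intervals[i].start for i in idxs], dtype=np.float64)
        e = np.array([merged.intervals[i].end for i in idxs], dtype=np.float64)
        covered[idxs] = cov.window_sums(chrom, s, e)
    return covered, lengths


def element_density(
    marks: PeakSet, elements: PeakSet, label: str | None = None
) -> DensityEntry:
    """Fraction of element bp covered by >= 1 mark interval."""
    if len(elements) == 0:
        raise ValueError("element set is empty")
    covered, lengths = _per_element_coverage(marks, elements)
    total = int(lengths.sum())
    return DensityEntry(
        label=label or elements.source,
        total_bp=total,
        covered_bp=float(covered.sum()),
        density=float(covered.sum() / total),
    )


def enrichment_test(
    marks: PeakSet,
    elements_a: PeakSet,
    elements_b: PeakSet,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, str]:
    """Two-sided permutation p-value for density(A) != density(B).

    The null reassigns element intervals between the two classes, preserving
    class sizes.  Returns (p, observed density difference, method) where
    method is 'exhaustive' or 'monte-carlo'.  Overlapping A/B universes are
    rejected: each element must belong to exactly one class.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ma, mb = elements_a.merged(), elements_b.merged()
    for iva in ma.intervals:
        if mb.overlaps_interval(iva):
            raise ValueError("element universes A and B overlap")
    cov_a, len_a = _per_element_coverage(marks, ma)
    cov_b, len_b = _per_element_coverage(marks, mb)
    cov = np.concatenate([cov_a, cov_b])
    lens = np.concatenate([len_a, len_b]).astype(np.float64)
    n_a, n = len(cov_a), len(cov)

    def delta(a_idx: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[a_idx] = True
        return float(
            cov[mask].sum() / lens[mask].sum() - cov[~mask].sum() / lens[~mask].sum()
        )

    obs = delta(np.arange(n_a))
    n_total = math.comb(n, n_a)
    if n_total <= n_perm:
        deltas = np.array([delta(np.array(c)) for c in combinations(range(n), n_a)])
        p = float((np.abs(deltas) >= abs(obs) - 1e-12).sum() / n_total)
        return p, obs, "exhaustive"
    rng = np.random.default_rng(seed)
    # vectorized sampling of class-A index sets: argsort of uniform noise
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(mask, picks, True, axis=1)
    da = (mask * cov).sum(axis=1) / (mask * lens).sum(axis=1)
    db = ((~mask) * cov).sum(axis=1) / ((~mask) * lens).sum(axis=1)
    exceed = int((np.abs(da - db) >= abs(obs) - 1e-12).sum())
    p = (exceed + 1) / (n_perm + 1)
    return float(p), obs, "monte-carlo"


def overlap_fraction(a: PeakSet, b: PeakSet) -> OverlapReport:
    """Fraction of A intervals sharing >= 1 bp with some B interval."""
    if len(a) == 0:
        raise ValueError("source peak set is empty")
    hits = sum(1 for iv in a if b.overlaps_interval(iv))
    return OverlapReport(
        source=a.source, target=b.source, n_source=len(a), n_hit=hits
    )


def signal_correlation(
    inputs: list[tuple[str, SignalTrack | PeakSet]],
    regions: PeakSet,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-region mark levels.

    Each mark contributes one value per region: mean per-bp signal for a
    SignalTrack, binary occupancy for a PeakSet.  Zero-variance vectors give
    NaN correlations with a logged warning.
    """
    if len(inputs) < 2:
        raise ValueError("need >= 2 inputs")
    if len(regions) == 0:
        raise ValueError("regions set is empty")
    labels = [lab for lab, _ in inputs]
    vectors = np.zeros((len(inputs), len(regions)))
    for k, (lab, src) in enumerate(inputs):
        if isinstance(src, SignalTrack):
            for i, iv in enumerate(regions):
                vectors[k, i] = src.integral(iv.chrom, iv.start, iv.end) / iv.length
        else:
            for i, iv in enumerate(regions):
                vectors[k, i] = 1.0 if src.overlaps_interval(iv) else 0.0
    stds = vectors.std(axis=1)
    flat = [labels[k] for k in range(len(inputs)) if stds[k] == 0]
    if flat:
        log.warning("zero-variance mark vector(s): %s; correlations are NaN", flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(vectors)
    return pd.DataFrame(mat, index=labels, columns=labels)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values for a family of raw p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
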