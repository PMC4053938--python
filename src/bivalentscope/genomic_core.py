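"""Domain types, coordinate arithmetic, and readers/writers for standard formats.

All coordinates are 0-based half-open (BED convention); the length of an
interval is ``end - start``.  The TSS of a minus-strand gene is ``end - 1``,
the last covered base, so that strand flips stay consistent under the
half-open convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (half-open: touching is not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with an exon structure; the substrate of promoter/gene-body analyses."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and disjoint"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: last transcribed base."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def exonic_bp(self) -> int:
        return sum(ex.length for ex in self.exons)


class SignalTrack:
    """Per-base non-negative coverage stored as sorted non-overlapping runs.

    Positions not covered by any run have value 0.  Querying an unknown
    chromosome returns zeros with a logged warning so that partial fixtures
    still run.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted run")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping runs are not allowed")
            self._runs[chrom] = (starts, ends, values)
            # cumulative integral up to the start of each run, for O(log n) range sums
            seg = values * (ends - starts)
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(seg)])
        self._warned: set[str] = set()

    # ---------------------------------------------------------------- builders
    @classmethod
    def from_intervals(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            s = np.array([r[0] for r in recs], dtype=np.int64)
            e = np.array([r[1] for r in recs], dtype=np.int64)
            v = np.array([r[2] for r in recs], dtype=np.float64)
            runs[chrom] = (s, e, v)
        return cls(runs, chrom_sizes)

    # ---------------------------------------------------------------- queries
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def _check(self, chrom: str) -> bool:
        if chrom not in self._runs:
            if chrom not in self._warned:
                log.warning("chromosome %r not in track; returning zeros", chrom)
                self._warned.add(chrom)
            return False
        return True

    def point(self, chrom: str, pos: int) -> float:
        """Signal value at a single base."""
        if not self._check(chrom):
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def _antiderivative(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """F(p) = integral of the track over [0, p); p may be fractional."""
        starts, ends, values = self._runs[chrom]
        cum = self._cum[chrom]
        pos = np.asarray(pos, dtype=np.float64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        valid = idx >= 0
        i = np.maximum(idx, 0)
        partial = np.clip(np.minimum(pos, ends[i]) - starts[i], 0.0, None) * values[i]
        return out + np.where(valid, partial, 0.0)

    def integral(self, chrom: str, a: float, b: float) -> float:
        """Total signal over [a, b); bounds may be fractional bp."""
        if a >= b:
            return 0.0
        if not self._check(chrom):
            return 0.0
        f = self._antiderivative(chrom, np.array([a, b]))
        return float(f[1] - f[0])

    def window_sums(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized total signal over many [start, end) windows."""
        starts = np.asarray(starts, dtype=np.float64)
        ends = np.asarray(ends, dtype=np.float64)
        if not self._check(chrom):
            return np.zeros(len(starts))
        return self._antiderivative(chrom, ends) - self._antiderivative(chrom, starts)

    @property
    def total_signal(self) -> float:
        return float(sum(cum[-1] for cum in self._cum.values()))

    def iter_runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._runs):
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


class PeakSet:
    """A sorted collection of intervals (e.g. MACS peak calls for one mark)."""

    def __init__(self, intervals: Iterable[GenomicInterval], source: str = "") -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self.source = source
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._by_chrom is None:
            by: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom = {
                c: (
                    np.array([p[0] for p in pairs], dtype=np.int64),
                    np.array([p[1] for p in pairs], dtype=np.int64),
                )
                for c, pairs in by.items()
            }
        return self._by_chrom

    def merged(self, source: str | None = None) -> "PeakSet":
        """Collapse overlapping or adjacent-overlapping intervals (union)."""
        out: list[GenomicInterval] = []
        cur: GenomicInterval | None = None
        for iv in self.intervals:
            if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
                if iv.end > cur.end:
                    cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            else:
                if cur is not None:
                    out.append(cur)
                cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        if cur is not None:
            out.append(cur)
        return PeakSet(out, source=source or self.source)

    @property
    def total_bp(self) -> int:
        """Union bp covered by the set."""
        return sum(iv.length for iv in self.merged().intervals)

    def overlaps_interval(self, query: GenomicInterval) -> bool:
        """True iff any interval in the set shares >= 1 bp with the query."""
        idx = self._index()
        if query.chrom not in idx:
            return False
        starts, ends = idx[query.chrom]
        i = int(np.searchsorted(starts, query.end, side="left"))
        return bool(np.any(ends[:i] > query.start))

    def coverage_track(self) -> SignalTrack:
        """Unit-value coverage of the merged set, for covered-bp arithmetic."""
        m = self.merged()
        return SignalTrack.from_intervals(
            (iv.chrom, iv.start, iv.end, 1.0) for iv in m.intervals
        )


class ExpressionTable:
    """gene_id -> per-sample RPKM, backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame) -> None:
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dupes[:5]}")
        if (df.values < 0).any():
            raise ValueError("RPKM values must be >= 0")
        self.df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def rpkm(self, gene_id: str, sample: str) -> float:
        return float(self.df.at[gene_id, sample])

    def sample_values(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"sample {sample!r} not in table")
        return self.df[sample]


# ------------------------------------------------------------------ file I/O


def read_intervals(path: str | Path, source: str | None = None) -> PeakSet:
    """Read a 3-6 column BED file into a sorted PeakSet."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = "."
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(GenomicInterval(chrom, start, end, strand, score))
    return PeakSet(intervals, source=source or path.stem)


def write_intervals(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 (name '.', score from the interval or 0)."""
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            score = 0.0 if iv.score is None else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score:g}\t{iv.strand}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models, reconstructing exons from the block columns."""
    path = Path(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            if offsets[0] != 0 or offsets[-1] + sizes[-1] != end - start:
                raise ParseError(
                    f"{path}:{lineno}: blocks inconsistent with chromStart/End"
                )
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end, strand), exons)
            )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.interval.start
            sizes = ",".join(str(ex.length) for ex in g.exons)
            offs = ",".join(str(ex.start - start) for ex in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{g.interval.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{g.interval.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_signal(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> SignalTrack:
    """Read a 4-column bedGraph.  Overlapping runs and negative values are errors."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative signal value")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: invalid run [{start}, {end})")
            records.append((f[0], start, end, value))
    return SignalTrack.from_intervals(records, chrom_sizes)


def write_signal(track: SignalTrack, path: str | Path, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            if skip_zero and value == 0.0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a TSV with a gene_id first column and one column per sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ParseError(
                    f"{path}: non-numeric RPKM at gene {row!r}, sample {col!r}"
                ) from None
        df = df.astype(float)
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        log.warning("%s: %d missing RPKM values set to 0", path, n)
        df = df.fillna(0.0)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read FASTA into {first-whitespace-token name: uppercase sequence}."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: empty FASTA record {rec.id!r}")
            out[rec.id] = seq
    return out


def write_sequences(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column 'chrom\\tlength' table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ------------------------------------------------------------- coordinate ops


def promoter_window(
    gene: GeneModel,
    upstream: int,
    downstream: int,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """Strand-aware half-open window around the TSS.

    On the + strand the window is ``[tss - upstream, tss + downstream)``; the
    minus-strand window is its exact base-level mirror,
    ``[tss - downstream + 1, tss + upstream + 1)``, so that a gene and its
    reflected counterpart produce reflected windows.  Clipped at chromosome
    bounds; a window entirely off-chromosome is an error.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    lo = max(start, 0)
    hi = end if chrom_size is None else min(end, chrom_size)
    if lo >= hi:
        raise ValueError(
            f"promoter window of {gene.gene_id} lies entirely off-chromosome"
        )
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)
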