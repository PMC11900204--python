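"""Genomic domain types and text-format I/O.

All in-memory coordinates are 0-based half-open, on every type. Formats
that use other conventions (GTF: 1-based closed; fixedStep WIG: 1-based)
are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced transcript: the unit that is classified and scored.

    ``exons`` are sorted by start, non-overlapping, and separated by at
    least one base; the intron chain (donor/acceptor pairs) is derived
    from consecutive exon boundaries.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exon on wrong chrom")
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted with gaps >= 1 "
                    f"(got {a.start}-{a.end} then {b.start}-{b.end})"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) pairs: (exon[k].end, exon[k+1].start)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, d, a, self.strand)
            for d, a in self.intron_chain
        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, attribute_dialect: str = "ensembl") -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exon records are grouped by ``transcript_id`` (order of first
    appearance); 1-based closed GTF coordinates become 0-based half-open.
    Overlapping or book-ended exon records within one transcript are
    merged with a warning. Declared transcripts with zero exon records
    are skipped with a warning.
    """
    if attribute_dialect != "ensembl":
        raise ValueError(f"unsupported attribute dialect {attribute_dialect!r}")
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    declared: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates {start1}-{end1}")
            if strand not in STRANDS:
                raise ValueError(f"malformed GTF line {lineno}: bad strand {strand!r}")
            if feature not in ("exon", "transcript"):
                continue
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"malformed GTF line {lineno}: missing transcript_id")
            gid = attr.get("gene_id") or tid
            if tid in meta:
                prev = meta[tid]
                if prev[1] != chrom or prev[2] != strand:
                    raise ValueError(
                        f"malformed GTF line {lineno}: transcript {tid} mixes "
                        "chromosomes or strands"
                    )
            else:
                meta[tid] = (gid, chrom, strand)
                declared.append(tid)
            if feature == "exon":
                exon_rows.setdefault(tid, []).append((start1 - 1, end1))
    models: list[TranscriptModel] = []
    for tid in declared:
        gid, chrom, strand = meta[tid]
        rows = exon_rows.get(tid)
        if not rows:
            warnings.warn(f"transcript {tid} has zero exon records; skipped")
            continue
        rows = sorted(rows)
        merged: list[list[int]] = [list(rows[0])]
        merged_any = False
        for s, e in rows[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged_any = True
            else:
                merged.append([s, e])
        if merged_any:
            warnings.warn(
                f"transcript {tid}: overlapping exon records merged "
                f"({len(rows)} -> {len(merged)})"
            )
        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)
        models.append(TranscriptModel(tid, gid, chrom, strand, exons))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "scnovel") -> None:
    """Write models as GTF (transcript + exon lines, fixed attribute order)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = m.span
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1].

    A position absent from the track is *null* (no data) and is
    distinguishable from an explicit score of 0.0.
    """

    def __init__(self, positions: Mapping[str, np.ndarray], scores: Mapping[str, np.ndarray]):
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(scores[chrom], dtype=float)
            if pos.shape != val.shape:
                raise ValueError(f"{chrom}: positions/scores length mismatch")
            order = np.argsort(pos, kind="stable")
            pos, val = pos[order], val[order]
            if pos.size and np.any(np.diff(pos) == 0):
                raise ValueError(f"{chrom}: duplicate positions in track")
            if val.size and (val.min() < 0 or val.max() > 1):
                raise ValueError(f"{chrom}: conservation scores must lie in [0, 1]")
            self._pos[chrom] = pos
            self._val[chrom] = val

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[int, float]]) -> "ConservationTrack":
        positions = {c: np.fromiter(d.keys(), dtype=np.int64, count=len(d)) for c, d in data.items()}
        scores = {c: np.fromiter(d.values(), dtype=float, count=len(d)) for c, d in data.items()}
        return cls(positions, scores)

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def n_positions(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self._pos.get(chrom, np.empty(0)).size)
        return int(sum(p.size for p in self._pos.values()))

    def get(self, chrom: str, position: int) -> float | None:
        """Score at one base, or None where the track has no data."""
        pos = self._pos.get(chrom)
        if pos is None or pos.size == 0:
            return None
        i = int(np.searchsorted(pos, position))
        if i < pos.size and pos[i] == position:
            return float(self._val[chrom][i])
        return None

    def scores_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores for [start, end); NaN marks null positions."""
        out = np.full(end - start, np.nan)
        pos = self._pos.get(chrom)
        if pos is None or pos.size == 0:
            return out
        lo = int(np.searchsorted(pos, start))
        hi = int(np.searchsorted(pos, end))
        out[pos[lo:hi] - start] = self._val[chrom][lo:hi]
        return out

    def items(self) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
        for chrom in self._pos:
            yield chrom, self._pos[chrom], self._val[chrom]


def _expand_bedgraph(starts: np.ndarray, ends: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lens = ends - starts
    total = int(lens.sum())
    offsets = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    return np.repeat(starts, lens) + offsets, np.repeat(scores, lens)


def read_conservation(path: str | Path, format: str = "bedgraph") -> ConservationTrack:
    """Load a bedGraph or fixedStep WIG conservation track.

    bedGraph intervals are 0-based half-open and expanded per base;
    overlapping intervals or scores outside [0, 1] raise. fixedStep
    positions are 1-based and converted.
    """
    if format == "bedgraph":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"malformed bedGraph line {lineno}")
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        if not rows:
            return ConservationTrack({}, {})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        if (df["score"] < 0).any() or (df["score"] > 1).any():
            raise ValueError("conservation scores outside [0, 1]")
        if (df["end"] <= df["start"]).any():
            raise ValueError("bedGraph interval with end <= start")
        positions, scores = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start", kind="stable")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping bedGraph intervals")
            positions[chrom], scores[chrom] = _expand_bedgraph(
                starts, ends, grp["score"].to_numpy()
            )
        return ConservationTrack(positions, scores)
    if format == "fixedstep_wig":
        data: dict[str, list[tuple[int, float]]] = {}
        chrom, start0, step, span = None, 0, 1, 1
        offset = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    start0 = int(kv["start"]) - 1  # WIG is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    offset = 0
                    continue
                if chrom is None:
                    raise ValueError(f"line {lineno}: value before fixedStep header")
                value = float(line)
                base = start0 + offset * step
                for s in range(span):
                    data.setdefault(chrom, []).append((base + s, value))
                offset += 1
        positions = {c: np.array([p for p, _ in v], dtype=np.int64) for c, v in data.items()}
        scores = {c: np.array([x for _, x in v]) for c, v in data.items()}
        return ConservationTrack(positions, scores)
    raise ValueError(f"unknown conservation format {format!r}")


def write_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging contiguous equal-score runs."""
    with open(path, "w") as fh:
        for chrom, pos, val in track.items():
            if pos.size == 0:
                continue
            breaks = np.flatnonzero((np.diff(pos) != 1) | (np.diff(val) != 0))
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [pos.size - 1]))
            for i, j in zip(starts, ends):
                fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{val[i]:g}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

NORMALIZATIONS = ("raw", "cpm", "log1p-cpm")


@dataclass
class ExpressionMatrix:
    """Transcripts x cells expression with optional cell-type labels."""

    values: pd.DataFrame  # index: feature ids, columns: cell ids
    cell_types: pd.Series | None = None
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.cell_types is not None:
            missing = [c for c in self.values.columns if c not in self.cell_types.index]
            if missing:
                raise ValueError(f"cells without a cell-type label: {missing[:10]}")
            self.cell_types = self.cell_types.reindex(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def require_cell_types(self) -> pd.Series:
        if self.cell_types is None:
            raise ValueError("operation requires cell-type labels")
        return self.cell_types

    def cpm(self) -> "ExpressionMatrix":
        """Counts-per-million normalization (per-cell column sums -> 1e6)."""
        if self.normalization == "cpm":
            return self
        if self.normalization != "raw":
            raise ValueError(f"cannot CPM-normalize {self.normalization} values")
        totals = self.values.sum(axis=0)
        zero = totals.index[totals == 0].tolist()
        if zero:
            raise ValueError(f"cells with zero total counts: {zero[:10]}")
        vals = self.values * (1e6 / totals)
        return ExpressionMatrix(vals, self.cell_types, "cpm")

    def log1p_cpm(self) -> "ExpressionMatrix":
        cpm = self.cpm() if self.normalization == "raw" else self
        return ExpressionMatrix(np.log1p(cpm.values), self.cell_types, "log1p-cpm")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cell_type"], dtype=str)
    return pd.Series(df["cell_type"].to_numpy(), index=df["cell_id"], name="cell_type")


def read_expression(
    matrix_path: str | Path,
    features_path: str | Path,
    cells_path: str | Path,
    labels_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a MatrixMarket triplet matrix (features x cells) plus id files."""
    mat = scipy_io.mmread(str(matrix_path))
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
    if dense.shape != (len(features), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} inconsistent with {len(features)} features "
            f"x {len(cells)} cells"
        )
    labels = read_labels(labels_path) if labels_path is not None else None
    values = pd.DataFrame(dense, index=features, columns=cells)
    return ExpressionMatrix(values, labels)


def read_dense_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Dense TSV alternative: header = cell ids, first column = feature ids."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    labels = read_labels(labels_path) if labels_path is not None else None
    return ExpressionMatrix(values.astype(float), labels)


def write_expression(matrix: ExpressionMatrix, outdir: str | Path, prefix: str = "matrix") -> dict[str, Path]:
    """Write MTX triplet + features/barcodes/labels TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
    }
    scipy_io.mmwrite(str(paths["matrix"]), sparse.coo_matrix(matrix.values.to_numpy()))
    pd.Series(matrix.features).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(matrix.cells).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    if matrix.cell_types is not None:
        paths["labels"] = outdir / "labels.tsv"
        matrix.cell_types.to_csv(paths["labels"], sep="\t", header=False)
    return paths
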