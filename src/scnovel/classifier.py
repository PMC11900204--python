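"""Class-code assignment of assembled transcripts against a reference.

Each assembled transcript (transfrag) receives a single-character class
code describing its relation to the reference annotation, in the spirit
of cuffcompare/gffcompare but restricted to the alphabet the novelty
pipeline consumes:

    '='  exact match (identical intron chain; single-exon: >= 80%
         reciprocal overlap with a single-exon reference)
    'c'  contained: exons within one reference's exons, intron chain a
         contiguous sub-chain of that reference's chain
    'j'  novel isoform sharing >= 1 exact splice junction
    'o'  other same-strand exonic overlap
    'i'  fully inside a single reference intron (any strand)
    'x'  exonic overlap on the opposite strand only
    'u'  intergenic (no reference overlap); also the catch-all when no
         rule above applies

Rules are evaluated in the order listed; the first match wins.
Unknown-strand ('.') queries are compared against both strands for the
same-strand rules and can never receive 'x'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_model import TranscriptModel

CLASS_CODES = ("=", "c", "j", "o", "i", "x", "u")

NOVELTY_BY_CODE = {
    "=": "annotated",
    "c": "annotated",
    "j": "novel_isoform",
    "i": "intronic",
    "u": "intergenic",
    "o": "other_overlap",
    "x": "other_overlap",
}

UNANNOTATED_CODES = frozenset("uij")
ANNOTATED_CODES = frozenset("=c")
OTHER_CODES = frozenset("ox")


@dataclass(frozen=True)
class ClassCode:
    code: str
    matched_reference: str | None = None
    shared_junctions: int = 0

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code in ("=", "c", "j") and self.matched_reference is None:
            raise ValueError(f"code {self.code!r} requires a matched reference")
        if self.code == "u" and (self.matched_reference is not None or self.shared_junctions):
            raise ValueError("code 'u' admits no matched reference or shared junctions")


@dataclass(frozen=True)
class ClassificationRecord:
    transcript_id: str
    class_code: ClassCode
    length: int
    exon_count: int

    @property
    def novelty(self) -> str:
        return NOVELTY_BY_CODE[self.class_code.code]


def _strands_match(query_strand: str, ref_strand: str) -> bool:
    return "." in (query_strand, ref_strand) or query_strand == ref_strand


class AnnotationIndex:
    """Interval/junction/chain indexes over a reference annotation."""

    def __init__(self, reference: Sequence[TranscriptModel] = ()):
        self.transcripts: dict[str, TranscriptModel] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._junctions: dict[tuple[str, str, int, int], set[str]] = {}
        self._chains: dict[tuple[str, str, tuple[tuple[int, int], ...]], set[str]] = {}
        for t in reference:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate reference transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        span = t.span
        self._span_trees.setdefault(t.chrom, IntervalTree()).addi(
            span.start, span.end, t.transcript_id
        )
        for donor, acceptor in t.intron_chain:
            self._junctions.setdefault((t.chrom, t.strand, donor, acceptor), set()).add(
                t.transcript_id
            )
        if t.exon_count > 1:
            self._chains.setdefault((t.chrom, t.strand, t.intron_chain), set()).add(
                t.transcript_id
            )

    # -- lookups ------------------------------------------------------------

    def span_overlaps(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.transcripts[i] for i in hits]

    def chain_matches(self, chrom: str, strand: str, chain: tuple[tuple[int, int], ...]) -> set[str]:
        out: set[str] = set()
        strands = ("+", "-") if strand == "." else (strand, ".")
        for s in strands:
            out |= self._chains.get((chrom, s, chain), set())
        return out

    def has_junction(self, chrom: str, strand: str, donor: int, acceptor: int) -> set[str]:
        out: set[str] = set()
        strands = ("+", "-") if strand == "." else (strand, ".")
        for s in strands:
            out |= self._junctions.get((chrom, s, donor, acceptor), set())
        return out

    @property
    def n_junctions(self) -> int:
        return len(self._junctions)

    @property
    def n_chains(self) -> int:
        return len(self._chains)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


def build_annotation_index(reference: Sequence[TranscriptModel]) -> AnnotationIndex:
    return AnnotationIndex(reference)


# ---------------------------------------------------------------------------
# rule machinery
# ---------------------------------------------------------------------------


def _exonic_overlap(query: TranscriptModel, ref: TranscriptModel) -> int:
    """Total overlapped bases between the two exon sets."""
    total = 0
    for qe in query.exons:
        for re_ in ref.exons:
            total += max(0, min(qe.end, re_.end) - max(qe.start, re_.start))
    return total


def _shared_junctions(query: TranscriptModel, ref: TranscriptModel) -> int:
    return len(set(query.intron_chain) & set(ref.intron_chain))


def _is_subchain(sub: tuple, chain: tuple) -> bool:
    """True when ``sub`` occurs as a contiguous slice of ``chain``."""
    if not sub:
        return True
    n, m = len(sub), len(chain)
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def _exons_contained(query: TranscriptModel, ref: TranscriptModel) -> bool:
    return all(
        any(re_.start <= qe.start and qe.end <= re_.end for re_ in ref.exons)
        for qe in query.exons
    )


def _pick_best(
    query: TranscriptModel, candidates: Iterable[TranscriptModel]
) -> TranscriptModel:
    """Deterministic tie-break: most shared junctions, longest exonic
    overlap, then lexicographically smallest reference id."""
    return min(
        candidates,
        key=lambda r: (
            -_shared_junctions(query, r),
            -_exonic_overlap(query, r),
            r.transcript_id,
        ),
    )


def assign_class_code(query: TranscriptModel, index: AnnotationIndex) -> ClassCode:
    """Assign the first matching class code in precedence order (total)."""
    span = query.span
    overlapping = index.span_overlaps(query.chrom, span.start, span.end)
    same_strand = [r for r in overlapping if _strands_match(query.strand, r.strand)]

    # (1) '=' exact match
    if query.exon_count > 1:
        ids = index.chain_matches(query.chrom, query.strand, query.intron_chain)
        if ids:
            ref = _pick_best(query, [index.transcripts[i] for i in ids])
            return ClassCode("=", ref.transcript_id, len(query.intron_chain))
    else:
        qlen = query.length
        hits = []
        for r in same_strand:
            if r.exon_count != 1:
                continue
            ov = _exonic_overlap(query, r)
            if ov >= 0.8 * qlen and ov >= 0.8 * r.length:
                hits.append(r)
        if hits:
            ref = _pick_best(query, hits)
            return ClassCode("=", ref.transcript_id, 0)

    # (2) 'c' contained
    contained = [
        r
        for r in same_strand
        if _exons_contained(query, r) and _is_subchain(query.intron_chain, r.intron_chain)
    ]
    if contained:
        ref = _pick_best(query, contained)
        return ClassCode("c", ref.transcript_id, len(query.intron_chain))

    # (3) 'j' shared junction
    if query.exon_count > 1:
        sharing = [r for r in same_strand if _shared_junctions(query, r) > 0]
        if sharing:
            ref = _pick_best(query, sharing)
            return ClassCode("j", ref.transcript_id, _shared_junctions(query, ref))

    # (4) 'o' same-strand exonic overlap without shared junction
    exonic = [r for r in same_strand if _exonic_overlap(query, r) > 0]
    if exonic:
        ref = _pick_best(query, exonic)
        return ClassCode("o", ref.transcript_id, 0)

    # (5) 'i' inside a single reference intron (any strand)
    for r in overlapping:
        if any(iv.start <= span.start and span.end <= iv.end for iv in r.introns):
            return ClassCode("i", None, 0)

    # (6) 'x' opposite-strand exonic overlap (stranded queries only)
    if query.strand in ("+", "-"):
        if any(
            r.strand in ("+", "-")
            and r.strand != query.strand
            and _exonic_overlap(query, r) > 0
            for r in overlapping
        ):
            return ClassCode("x", None, 0)

    # (7) 'u' intergenic / catch-all
    return ClassCode("u", None, 0)


def classify_assembly(
    queries: Sequence[TranscriptModel], index: AnnotationIndex
) -> list[ClassificationRecord]:
    return [
        ClassificationRecord(
            q.transcript_id, assign_class_code(q, index), q.length, q.exon_count
        )
        for q in queries
    ]


def partition_assembly(
    records: Sequence[ClassificationRecord],
) -> dict[str, set[str]]:
    """Split classified transcripts into unannotated {u,i,j}, annotated
    {=,c} and other {o,x} id sets (disjoint, covering the input)."""
    out = {"unannotated": set(), "annotated": set(), "other": set()}
    for rec in records:
        code = rec.class_code.code
        if code in UNANNOTATED_CODES:
            out["unannotated"].add(rec.transcript_id)
        elif code in ANNOTATED_CODES:
            out["annotated"].add(rec.transcript_id)
        else:
            out["other"].add(rec.transcript_id)
    return out


def records_to_frame(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "class_code": [r.class_code.code for r in records],
            "matched_reference": [r.class_code.matched_reference or "." for r in records],
            "shared_junctions": [r.class_code.shared_junctions for r in records],
            "novelty": [r.novelty for r in records],
            "length": [r.length for r in records],
            "exon_count": [r.exon_count for r in records],
        }
    )


def write_classification(records: Sequence[ClassificationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_classification(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
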