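"""Independent brute-force oracles used to cross-check the library.

Everything here deliberately avoids the library's interval indexes,
rank formulas and vectorized paths: class codes are decided by per-base
position sets over explicit (query, reference) pairs, ORFs by
enumerating every start, AUCs by counting concordant pairs, and
conservation means by querying the track one base at a time.
"""

from __future__ import annotations

import numpy as np

from scnovel.genome_model import ConservationTrack, TranscriptModel


# --- classifier oracle -----------------------------------------------------


def _exon_base_sets(t: TranscriptModel) -> list[set[int]]:
    return [set(range(e.start, e.end)) for e in t.exons]


def _all_exon_bases(t: TranscriptModel) -> set[int]:
    out: set[int] = set()
    for s in _exon_base_sets(t):
        out |= s
    return out


def _junctions(t: TranscriptModel) -> set[tuple[int, int]]:
    return set(t.intron_chain)


def _strand_compatible(q: str, r: str) -> bool:
    return "." in (q, r) or q == r


def oracle_class_code(query: TranscriptModel, refs: list[TranscriptModel]) -> str:
    """Evaluate rules 1-7 directly over every (query, reference) pair."""
    on_chrom = [r for r in refs if r.chrom == query.chrom]
    same = [r for r in on_chrom if _strand_compatible(query.strand, r.strand)]
    q_bases = _all_exon_bases(query)

    # 1 '='
    if query.exon_count > 1:
        for r in same:
            if r.exon_count > 1 and query.intron_chain == r.intron_chain:
                return "="
    else:
        for r in same:
            if r.exon_count == 1:
                ov = len(q_bases & _all_exon_bases(r))
                if ov >= 0.8 * len(q_bases) and ov >= 0.8 * r.length:
                    return "="
    # 2 'c'
    for r in same:
        contained = all(
            any(qe <= re for re in _exon_base_sets(r)) for qe in _exon_base_sets(query)
        )
        qc, rc = query.intron_chain, r.intron_chain
        sub = (not qc) or any(
            rc[i : i + len(qc)] == qc for i in range(len(rc) - len(qc) + 1)
        )
        if contained and sub:
            return "c"
    # 3 'j'
    if query.exon_count > 1:
        for r in same:
            if _junctions(query) & _junctions(r):
                return "j"
    # 4 'o'
    for r in same:
        if q_bases & _all_exon_bases(r):
            return "o"
    # 5 'i'
    span = query.span
    for r in on_chrom:
        for intron in r.introns:
            if intron.start <= span.start and span.end <= intron.end:
                return "i"
    # 6 'x'
    if query.strand in "+-":
        for r in on_chrom:
            if r.strand in "+-" and r.strand != query.strand:
                if q_bases & _all_exon_bases(r):
                    return "x"
    # 7 'u'
    return "u"


# --- ORF oracle ------------------------------------------------------------


def oracle_longest_orf(seq: str) -> tuple[int, int]:
    """(length, start) of the longest ATG..stop ORF by full enumeration;
    (0, -1) when there is none. Ties go to the 5'-most start."""
    seq = seq.upper()
    best = (0, -1)
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for stop in range(start, len(seq) - 2, 3):
            codon = seq[stop : stop + 3]
            if codon in ("TAA", "TAG", "TGA"):
                length = stop + 3 - start
                if length > best[0]:
                    best = (length, start)
                break
    return best


# --- AUC oracle ------------------------------------------------------------


def oracle_pair_auc(values: np.ndarray, member_mask: np.ndarray) -> float:
    """Normalized Mann-Whitney by explicit pair counting (ties = 1/2)."""
    g = values[member_mask]
    h = values[~member_mask]
    wins = 0.0
    for gv in g:
        for hv in h:
            if gv > hv:
                wins += 1.0
            elif gv == hv:
                wins += 0.5
    return wins / (len(g) * len(h))


# --- conservation oracle ---------------------------------------------------


def oracle_transcript_mean(
    model: TranscriptModel, track: ConservationTrack
) -> tuple[float | None, int, int]:
    """(mean, covered, total) by querying every exonic base one by one."""
    values = []
    total = 0
    for e in model.exons:
        for pos in range(e.start, e.end):
            total += 1
            v = track.get(model.chrom, pos)
            if v is not None:
                values.append(v)
    mean = sum(values) / len(values) if values else None
    return mean, len(values), total
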