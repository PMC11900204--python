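"""Coding-potential scoring and the lncRNA consensus gate.

A transcript's protein-coding potential is summarized by three classic
sequence features — longest ORF geometry, the Fickett TESTCODE statistic
(position asymmetry + base composition via the published lookup tables),
and in-frame hexamer usage bias (log-ratio of coding vs noncoding 6-mer
frequencies) — combined by a logistic model into a [0, 1] score.

The downstream gate follows the unanimous-vote convention: a transcript
called *coding* by every predictor (with sufficient expression) is an
unannotated coding transcript; one called *noncoding* by every predictor,
longer than 200 nt and expressed, is an unannotated lncRNA. Mixed votes
are ambiguous. External predictor calls (e.g. from dedicated ML tools)
can be supplied as TSV and enter the same consensus.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .genome_model import ExpressionMatrix, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_NAMES = ("orf_coverage", "log10_orf_length", "fickett", "hexamer")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced sense-strand sequence of a transcript.

    Exon sequences are concatenated in genomic order and, for '-'
    transcripts, reverse-complemented; unknown strand returns the
    plus-strand splice (callers may inspect ``model.strand``).
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {model.chrom} absent from genome") from exc
    if model.span.end > len(chrom_seq):
        raise ValueError(
            f"{model.transcript_id}: exon beyond end of {model.chrom} "
            f"({model.span.end} > {len(chrom_seq)})"
        )
    plus = "".join(chrom_seq[e.start : e.end] for e in model.exons).upper()
    return reverse_complement(plus) if model.strand == "-" else plus


# ---------------------------------------------------------------------------
# ORF
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfResult:
    orf_length: int
    orf_coverage: float
    frame: int
    has_stop: bool
    start: int = -1  # 0-based position of the ATG; -1 when no ORF


def find_longest_orf(seq: str, allow_open_ended: bool = False) -> OrfResult:
    """Longest ATG..stop ORF over the three sense frames.

    Length counts ATG through the stop codon inclusive. By default ORFs
    without an in-frame stop are ignored; with ``allow_open_ended`` they
    run (in frame) to the end of the sequence. Ties go to the 5'-most
    start. Codons containing characters other than A/C/G/T never match.
    """
    seq = seq.upper()
    n = len(seq)
    best_len, best_start, best_stop = 0, -1, False
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in _STOPS]
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        si = 0
        for start in starts:
            while si < len(stops) and stops[si] < start:
                si += 1
            # first in-frame stop at or after this start
            j = si
            stop_at = None
            while j < len(stops):
                if stops[j] >= start:
                    stop_at = stops[j]
                    break
                j += 1
            if stop_at is not None:
                length, stopped = stop_at + 3 - start, True
            elif allow_open_ended:
                length, stopped = 3 * ((n - start) // 3), False
            else:
                continue
            if length > best_len or (length == best_len and 0 <= start < best_start):
                best_len, best_start, best_stop = length, start, stopped
    if best_len == 0:
        return OrfResult(0, 0.0, 0, False, -1)
    return OrfResult(best_len, best_len / n, best_start % 3, best_stop, best_start)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

# Published TESTCODE lookup tables: probability that a window with the
# given position-asymmetry / composition parameter is coding, and the
# per-base weights combining the eight parameters.
_POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.75, 0.59, 0.86, 0.51, 0.64, 0.51),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.73, 0.64, 0.64, 0.68),
    "T": (0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.51, 0.63, 0.82),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARAM = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARAM = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def fickett_position_parameter(seq: str, base: str) -> float:
    """max/(min+1) of the base's counts in the three codon phases."""
    counts = [seq[i::3].count(base) for i in range(3)]
    return max(counts) / (min(counts) + 1)


def fickett_content_parameter(seq: str, base: str) -> float:
    denom = sum(seq.count(b) for b in "ACGT")
    return seq.count(base) / denom if denom else 0.0


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Weighted sum of eight table-looked-up probabilities (one position and
    one content parameter per base). Case-insensitive; N bases are
    ignored in the counts; other symbols raise.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN symbols in sequence: {bad}")
    if len(seq) < 200:
        warnings.warn("Fickett statistic is calibrated for sequences >= 200 nt")
    score = 0.0
    for base in "ACGT":
        pos = fickett_position_parameter(seq, base)
        cont = fickett_content_parameter(seq, base)
        score += _POSITION_WEIGHT[base] * _lookup(pos, _POSITION_PARAM, _POSITION_PROB[base])
        score += _CONTENT_WEIGHT[base] * _lookup(cont, _CONTENT_PARAM, _CONTENT_PROB[base])
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hexamer_index(hexamer: str) -> int | None:
    idx = 0
    for ch in hexamer:
        b = _BASE_INDEX.get(ch)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def _count_hexamers(seq: str, step: int) -> np.ndarray:
    counts = np.zeros(4096)
    for i in range(0, len(seq) - 5, step):
        idx = _hexamer_index(seq[i : i + 6])
        if idx is not None:
            counts[idx] += 1
    return counts


def train_hexamer_table(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Log2 ratio of in-frame hexamer frequencies, coding vs noncoding.

    Coding sequences contribute in-frame (step 3) hexamers over their
    longest ORF; noncoding sequences contribute step-3 hexamers from
    position 0. Returns a length-4096 array indexed by 2-bit encoding.
    """
    coding = np.full(4096, pseudocount)
    noncoding = np.full(4096, pseudocount)
    for seq in coding_seqs:
        seq = seq.upper()
        orf = find_longest_orf(seq)
        region = seq[orf.start : orf.start + orf.orf_length] if orf.orf_length else seq
        coding += _count_hexamers(region, step=3)
    for seq in noncoding_seqs:
        noncoding += _count_hexamers(seq.upper(), step=3)
    return np.log2((coding / coding.sum()) / (noncoding / noncoding.sum()))


def hexamer_bias_score(seq: str, hexamer_table: np.ndarray) -> float:
    """Mean in-frame hexamer log-ratio over the longest ORF (0 if none)."""
    seq = seq.upper()
    orf = find_longest_orf(seq)
    if orf.orf_length == 0:
        return 0.0
    region = seq[orf.start : orf.start + orf.orf_length]
    vals = [
        hexamer_table[idx]
        for i in range(0, len(region) - 5, 3)
        if (idx := _hexamer_index(region[i : i + 6])) is not None
    ]
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Logistic combiner and predictors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingCall:
    predictor: str
    label: str  # "coding" | "noncoding"
    score: float

    def __post_init__(self) -> None:
        if self.label not in ("coding", "noncoding"):
            raise ValueError(f"bad label {self.label!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("coding score must lie in [0, 1]")


def feature_vector(orf: OrfResult, fickett: float, hexamer: float) -> np.ndarray:
    """Intercept + (orf_coverage, log10(orf_length+1), fickett, hexamer)."""
    return np.array([1.0, orf.orf_coverage, math.log10(orf.orf_length + 1), fickett, hexamer])


def combine_coding_features(
    orf: OrfResult,
    fickett: float,
    hexamer: float,
    weights: np.ndarray,
    cutoff: float = 0.5,
    predictor: str = "combined",
) -> CodingCall:
    """Logistic combination of the three feature groups into a CodingCall."""
    score = float(expit(float(np.dot(weights, feature_vector(orf, fickett, hexamer)))))
    label = "coding" if score >= cutoff else "noncoding"
    return CodingCall(predictor, label, score)


@dataclass
class CodingPredictor:
    """One pluggable predictor slot: a logistic model over the internal
    features (a zero weight removes a feature from the model)."""

    name: str
    weights: np.ndarray  # length 5: intercept + FEATURE_NAMES
    hexamer_table: np.ndarray
    cutoff: float = 0.5

    def features(self, seq: str) -> tuple[OrfResult, float, float]:
        orf = find_longest_orf(seq)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fick = fickett_score(seq)
        hexa = hexamer_bias_score(seq, self.hexamer_table)
        return orf, fick, hexa

    def __call__(self, seq: str) -> CodingCall:
        orf, fick, hexa = self.features(seq)
        return combine_coding_features(
            orf, fick, hexa, self.weights, self.cutoff, predictor=self.name
        )


_PREDICTOR_SUBSETS = {
    # feature subsets per built-in predictor slot (indices into
    # FEATURE_NAMES); three views of the same evidence, mimicking a
    # multi-tool consensus
    "orf_fickett_hexamer": (0, 1, 2, 3),
    "fickett_hexamer": (2, 3),
    "orf_geometry": (0, 1),
}


def train_predictors(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    subsets: Mapping[str, tuple[int, ...]] | None = None,
) -> list[CodingPredictor]:
    """Fit one logistic predictor per feature subset on labeled sequences."""
    from sklearn.linear_model import LogisticRegression

    subsets = dict(subsets or _PREDICTOR_SUBSETS)
    table = train_hexamer_table(coding_seqs, noncoding_seqs)
    feats = []
    labels = []
    for seq, y in [(s, 1) for s in coding_seqs] + [(s, 0) for s in noncoding_seqs]:
        orf = find_longest_orf(seq)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fick = fickett_score(seq)
        feats.append(feature_vector(orf, fick, hexamer_bias_score(seq, table))[1:])
        labels.append(y)
    X = np.array(feats)
    y = np.array(labels)
    predictors = []
    for name, cols in subsets.items():
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[:, list(cols)], y)
        w = np.zeros(5)
        w[0] = clf.intercept_[0]
        for c, coef in zip(cols, clf.coef_[0]):
            w[1 + c] = coef
        predictors.append(CodingPredictor(name, w, table))
    return predictors


@functools.lru_cache(maxsize=1)
def default_predictors(seed: int = 7, n_train: int = 300) -> tuple[CodingPredictor, ...]:
    """Three built-in predictor configurations, trained deterministically
    on a seeded synthetic coding/noncoding set at first use."""
    from .synthetic_fixtures import make_training_set

    coding, noncoding = make_training_set(n_train, seed=seed)
    return tuple(train_predictors(coding, noncoding))


# ---------------------------------------------------------------------------
# Consensus gate
# ---------------------------------------------------------------------------

VERDICTS = (
    "unannotated_lncRNA",
    "unannotated_coding",
    "ambiguous",
    "excluded_short",
    "excluded_low_expression",
)


@dataclass(frozen=True)
class ExpressionStats:
    max_cpm: float
    n_cells_detected: int


@dataclass(frozen=True)
class GateThresholds:
    """Gate parameters: lncRNA length is a strict '> min_length' (201 nt
    passes, 200 fails); expression requires CPM >= min_cpm in >=
    min_cells cells."""

    min_length: int = 200
    min_cpm: float = 1.0
    min_cells: int = 3


@dataclass(frozen=True)
class BiotypeVerdict:
    transcript_id: str
    verdict: str
    evidence: tuple[CodingCall, ...]

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def consensus_gate(
    transcript_id: str,
    calls: Sequence[CodingCall],
    length: int,
    expression: ExpressionStats,
    thresholds: GateThresholds = GateThresholds(),
) -> BiotypeVerdict:
    """Unanimous-vote gate on coding calls, length and expression."""
    if not calls:
        raise ValueError(f"{transcript_id}: empty coding-call list")
    labels = {c.label for c in calls}
    evidence = tuple(calls)
    expressed = (
        expression.max_cpm >= thresholds.min_cpm
        and expression.n_cells_detected >= thresholds.min_cells
    )
    if labels == {"coding"}:
        verdict = "unannotated_coding" if expressed else "excluded_low_expression"
    elif labels == {"noncoding"}:
        if length <= thresholds.min_length:
            verdict = "excluded_short"
        elif not expressed:
            verdict = "excluded_low_expression"
        else:
            verdict = "unannotated_lncRNA"
    else:
        verdict = "ambiguous"
    return BiotypeVerdict(transcript_id, verdict, evidence)


def expression_stats_from_matrix(
    matrix: ExpressionMatrix, min_cpm: float = 1.0
) -> dict[str, ExpressionStats]:
    """Per-transcript (max CPM, number of cells with CPM >= min_cpm)."""
    cpm = matrix.cpm().values
    max_cpm = cpm.max(axis=1)
    n_det = (cpm >= min_cpm).sum(axis=1)
    return {
        tid: ExpressionStats(float(max_cpm[tid]), int(n_det[tid]))
        for tid in cpm.index
    }


def gate_assembly(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    matrix: ExpressionMatrix | None = None,
    predictors: Sequence[CodingPredictor] | None = None,
    external_calls: pd.DataFrame | None = None,
    thresholds: GateThresholds = GateThresholds(),
) -> pd.DataFrame:
    """Run predictors + consensus gate over transcripts; returns the
    verdict table (transcript_id, verdict, length, max_cpm,
    n_cells_detected)."""
    if predictors is None:
        predictors = default_predictors()
    stats = (
        expression_stats_from_matrix(matrix, thresholds.min_cpm)
        if matrix is not None
        else {}
    )
    ext: dict[str, list[CodingCall]] = {}
    if external_calls is not None:
        for row in external_calls.itertuples(index=False):
            ext.setdefault(str(row.transcript_id), []).append(
                CodingCall(str(row.predictor), str(row.label), float(row.score))
            )
    rows = []
    for m in models:
        seq = extract_sequence(m, genome)
        calls = [p(seq) for p in predictors] + ext.get(m.transcript_id, [])
        st = stats.get(
            m.transcript_id,
            ExpressionStats(math.inf, 10**9) if matrix is None else ExpressionStats(0.0, 0),
        )
        verdict = consensus_gate(m.transcript_id, calls, m.length, st, thresholds)
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "verdict": verdict.verdict,
                "length": m.length,
                "max_cpm": st.max_cpm,
                "n_cells_detected": st.n_cells_detected,
                "n_coding_votes": sum(c.label == "coding" for c in calls),
                "n_calls": len(calls),
            }
        )
    return pd.DataFrame(rows)


def read_external_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "predictor", "label", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"predictor-call TSV needs columns {sorted(required)}")
    return df
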