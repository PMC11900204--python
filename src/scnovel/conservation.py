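"""Per-transcript conservation averaging and category ECDF summaries.

A transcript's conservation is the mean of the per-base track scores
(phastCons-style probabilities in [0, 1]) over its *exonic* bases.
Positions absent from the track are null — excluded from numerator and
denominator alike — and a transcript with no covered exonic base has a
null mean, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ConservationTrack, TranscriptModel


@dataclass(frozen=True)
class ConservationSummary:
    transcript_id: str
    mean_score: float | None
    covered_bases: int
    total_exonic_bases: int

    def __post_init__(self) -> None:
        if self.covered_bases > self.total_exonic_bases:
            raise ValueError("covered_bases cannot exceed total_exonic_bases")
        if (self.mean_score is None) != (self.covered_bases == 0):
            raise ValueError("mean_score must be null exactly when no base is covered")


def transcript_conservation(
    model: TranscriptModel, track: ConservationTrack
) -> ConservationSummary:
    """Mean track score over the transcript's exonic bases with data."""
    per_base = np.concatenate(
        [track.scores_over(model.chrom, e.start, e.end) for e in model.exons]
    )
    covered = int(np.sum(~np.isnan(per_base)))
    mean = float(np.nanmean(per_base)) if covered else None
    return ConservationSummary(model.transcript_id, mean, covered, per_base.size)


def summarize_assembly(
    models: Sequence[TranscriptModel], track: ConservationTrack
) -> list[ConservationSummary]:
    return [transcript_conservation(m, track) for m in models]


def conservation_ecdf(
    summaries_by_category: Mapping[str, Sequence[ConservationSummary]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Right-continuous ECDF of mean scores per category.

    Null means are omitted from the ECDF and counted separately in the
    returned dict; a category whose summaries are all null is dropped
    with a warning. The ECDF is evaluated at the observed scores only
    (stat_ecdf semantics).
    """
    frames = []
    null_counts: dict[str, int] = {}
    for category, summaries in summaries_by_category.items():
        scores = np.array(
            [s.mean_score for s in summaries if s.mean_score is not None]
        )
        null_counts[category] = sum(1 for s in summaries if s.mean_score is None)
        if scores.size == 0:
            warnings.warn(f"category {category!r}: all conservation means null; omitted")
            continue
        scores = np.sort(scores)
        ecdf = np.searchsorted(scores, scores, side="right") / scores.size
        frames.append(
            pd.DataFrame(
                {"category": category, "score": scores, "cumulative_fraction": ecdf}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["category", "score", "cumulative_fraction"])
    )
    return df, null_counts


def summaries_to_frame(summaries: Sequence[ConservationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in summaries],
            "mean_score": [
                s.mean_score if s.mean_score is not None else np.nan for s in summaries
            ],
            "covered_bases": [s.covered_bases for s in summaries],
            "total_exonic_bases": [s.total_exonic_bases for s in summaries],
        }
    )


def write_conservation(summaries: Sequence[ConservationSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)
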