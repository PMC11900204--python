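"""Cell-type specificity by Jensen-Shannon divergence, and marker calls.

For a transcript with per-type mean expression profile p (normalized to
sum 1 over T cell types), the specificity toward type t is

    s_t = 1 - sqrt(JSD(p, e_t))

where e_t is the one-hot profile of type t and JSD uses log base 2
(so 0 <= JSD <= 1 and s_t in [0, 1]). s_t = 1 exactly when the
transcript is expressed in type t only. This is the Cabili-style
specificity popularized by cummeRbund's csSpecificity.

Marker transcripts are those specific enough to one type (max_t s_t),
detected in enough of that type's cells, and sufficiently enriched over
the remaining types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import ExpressionMatrix


def _entropy2(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits with the 0*log0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2, log base 2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0
    return float(_entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2.0)


@dataclass(frozen=True)
class SpecificityResult:
    transcript_id: str
    cell_types: tuple[str, ...]
    profile: tuple[float, ...] | None  # normalized mean profile p, sum 1
    scores: tuple[float, ...] | None  # s_t per type

    @property
    def defined(self) -> bool:
        return self.profile is not None

    @property
    def max_type(self) -> str | None:
        if not self.defined:
            return None
        return self.cell_types[int(np.argmax(self.scores))]

    @property
    def max_specificity(self) -> float | None:
        if not self.defined:
            return None
        return float(np.max(self.scores))


def type_mean_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-type mean CPM, features x cell types (linear scale)."""
    labels = matrix.require_cell_types()
    if labels.nunique() < 2:
        raise ValueError("specificity requires >= 2 cell types")
    cpm = matrix.cpm().values
    return cpm.T.groupby(labels).mean().T


def _specificity_from_profiles(means: pd.DataFrame) -> pd.DataFrame:
    """s_t per type from a features x types mean-expression table.

    All-zero transcripts get NaN rows (undefined specificity)."""
    types = list(means.columns)
    M = means.to_numpy(dtype=float)
    totals = M.sum(axis=1)
    defined = totals > 0
    P = np.full_like(M, np.nan)
    P[defined] = M[defined] / totals[defined, None]
    T = len(types)
    S = np.full_like(M, np.nan)
    hp = _entropy2(np.nan_to_num(P, nan=0.0), axis=1)  # H(p); e_t has H = 0
    for t in range(T):
        e = np.zeros(T)
        e[t] = 1.0
        mmid = (np.nan_to_num(P, nan=0.0) + e) / 2.0
        jsd = _entropy2(mmid, axis=1) - hp / 2.0
        S[:, t] = 1.0 - np.sqrt(np.clip(jsd, 0.0, 1.0))
    S[~defined] = np.nan
    out = pd.DataFrame(S, index=means.index, columns=[f"s_{t}" for t in types])
    best_idx = np.argmax(np.nan_to_num(S, nan=-1.0), axis=1)
    out["max_type"] = [
        types[i] if ok else None for i, ok in zip(best_idx, defined)
    ]
    out["max_specificity"] = [
        S[r, i] if ok else np.nan for r, (i, ok) in enumerate(zip(best_idx, defined))
    ]
    return out


def js_specificity_all(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Specificity table for every transcript in the matrix."""
    return _specificity_from_profiles(type_mean_profiles(matrix))


def js_specificity(matrix: ExpressionMatrix, transcript_id: str) -> SpecificityResult:
    """Specificity profile for one transcript (all-zero -> null result)."""
    means = type_mean_profiles(matrix)
    if transcript_id not in means.index:
        raise KeyError(f"transcript {transcript_id} not in matrix")
    row = means.loc[transcript_id].to_numpy(dtype=float)
    types = tuple(str(c) for c in means.columns)
    total = row.sum()
    if total == 0:
        return SpecificityResult(transcript_id, types, None, None)
    p = row / total
    scores = []
    for t in range(len(types)):
        e = np.zeros(len(types))
        e[t] = 1.0
        scores.append(1.0 - np.sqrt(max(jensen_shannon_divergence(p, e), 0.0)))
    return SpecificityResult(transcript_id, types, tuple(p), tuple(scores))


@dataclass(frozen=True)
class MarkerThresholds:
    min_specificity: float = 0.6
    min_detection_rate: float = 0.25
    min_fold_change: float = 2.0


def call_markers(
    matrix: ExpressionMatrix,
    specificity: pd.DataFrame | None = None,
    thresholds: MarkerThresholds = MarkerThresholds(),
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Marker calls: specificity, in-type detection rate and fold change.

    A transcript is a marker of its best type when all three thresholds
    pass. ``restrict_to`` limits candidates (e.g. to unannotated
    lncRNAs). Returns one row per candidate with an ``is_marker`` flag.
    """
    labels = matrix.require_cell_types()
    if specificity is None:
        specificity = js_specificity_all(matrix)
    cpm = matrix.cpm().values
    detected = matrix.values > 0
    type_means = cpm.T.groupby(labels).mean().T
    det_rates = detected.T.groupby(labels).mean().T
    n_types = type_means.shape[1]
    rows = []
    eps = 1e-9
    for tid, row in specificity.iterrows():
        if restrict_to is not None and tid not in restrict_to:
            continue
        if pd.isna(row["max_specificity"]):
            continue
        best = row["max_type"]
        spec = float(row["max_specificity"])
        det = float(det_rates.loc[tid, best])
        mean_in = float(type_means.loc[tid, best])
        mean_rest = float(
            (type_means.loc[tid].sum() - mean_in) / (n_types - 1)
        )
        fold = mean_in / max(mean_rest, eps)
        rows.append(
            {
                "transcript_id": tid,
                "cell_type": best,
                "max_specificity": spec,
                "detection_rate_in_type": det,
                "fold_change_vs_rest": fold,
                "is_marker": (
                    spec >= thresholds.min_specificity
                    and det >= thresholds.min_detection_rate
                    and fold >= thresholds.min_fold_change
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "cell_type",
            "max_specificity",
            "detection_rate_in_type",
            "fold_change_vs_rest",
            "is_marker",
        ],
    )


def write_specificity(specificity: pd.DataFrame, path: str | Path) -> None:
    specificity.to_csv(path, sep="\t", index_label="transcript_id")


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)
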