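"""Per-cell gene-set activity (novelScore) and downstream correlations.

The novelScore of a gene set G in one cell is the area under the
TPR-vs-FPR curve obtained by sweeping a rank cutoff f down that cell's
expression ranking: TPR(f) is the fraction of G in the top f% of genes,
FPR(f) the fraction of non-G genes there, and

    AUC_G = integral_0^1 TPR(f) dFPR(f).

Over the full ranking this equals the normalized Mann-Whitney U
statistic of G vs non-G ranks (ties counted one half). A
``top_fraction`` mode integrates the recovery curve over only the top
ceil(f*N) ranks, min-max normalized — the convention of AUCell — and
reduces exactly to the full integral at f = 1.

Also here: AUC-threshold exploration (mean + k*sd, Gaussian-mixture
crossing, fixed percentile), bulk signature scores, Pearson coexpression
with Benjamini-Hochberg control, and signature-vs-IC50 drug-sensitivity
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import ExpressionMatrix


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class CellScoreResult:
    cell_id: str
    auc: float
    mode: str
    above_threshold: bool | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.auc <= 1 + 1e-12:
            raise ValueError("auc must lie in [0, 1]")
        self.auc = min(max(self.auc, 0.0), 1.0)


def _member_mask(matrix: ExpressionMatrix, gene_set: GeneSet) -> np.ndarray:
    features = matrix.values.index
    mask = features.isin(gene_set.members)
    missing = len(gene_set.members) - int(mask.sum())
    if missing:
        warnings.warn(
            f"gene set {gene_set.name!r}: {missing} member(s) absent from the "
            "matrix; dropped"
        )
    n_in = int(mask.sum())
    if n_in == 0 or n_in == len(features):
        raise ValueError(
            f"gene set {gene_set.name!r} covers none or all matrix features; "
            "AUC is undefined"
        )
    return np.asarray(mask)


def novel_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    mode: str = "full_integral",
    top_fraction: float = 0.05,
) -> list[CellScoreResult]:
    """Rank-AUC activity of ``gene_set`` in every cell.

    Features are ranked by expression (descending, average ranks for
    ties). ``full_integral`` gives the normalized Mann-Whitney U;
    ``top_fraction`` the min-max-normalized area under the recovery
    curve restricted to the top ceil(f*N) ranks.
    """
    if mode not in ("full_integral", "top_fraction"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    mask = _member_mask(matrix, gene_set)
    X = matrix.values.to_numpy(dtype=float)
    N = X.shape[0]
    n_g = int(mask.sum())
    n_c = N - n_g
    # ascending ranks: larger expression -> larger rank; ties averaged
    asc = stats.rankdata(X, axis=0, method="average")
    mode_label = mode if mode == "full_integral" else f"top_fraction({top_fraction:g})"
    results = []
    if mode == "full_integral":
        u = asc[mask].sum(axis=0) - n_g * (n_g + 1) / 2.0
        aucs = u / (n_g * n_c)
    else:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        k = int(np.ceil(top_fraction * N))
        desc = (N + 1 - asc)[mask]  # descending average ranks of members
        # recovery curve y(x) = sum_g clip(x - r_g + 1, 0, 1) over integer
        # cutoffs x = 1..k; the clip splits tied (half-integer) ranks
        # linearly, so the f=1 area telescopes to the Mann-Whitney
        # numerator exactly. Per-member closed form of sum_x clip(...):
        c = np.ceil(desc)
        full = np.clip(k - c + 1.0, 0.0, None)
        frac = c - desc
        partial = np.where((frac > 0) & (c - 1 >= 1) & (c - 1 <= k), frac, 0.0)
        area = (full + partial).sum(axis=0)
        xi = np.arange(1, k + 1, dtype=float)
        max_area = np.minimum(xi, n_g).sum()
        min_area = np.maximum(xi - n_c, 0.0).sum()
        aucs = (area - min_area) / (max_area - min_area)
    for cell, auc in zip(matrix.cells, aucs):
        results.append(CellScoreResult(str(cell), float(auc), mode_label))
    return results


def scores_to_frame(scores: Sequence[CellScoreResult], set_name: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in scores],
            "set": set_name,
            "auc": [s.auc for s in scores],
            "mode": [s.mode for s in scores],
            "above_threshold": [s.above_threshold for s in scores],
        }
    )


# ---------------------------------------------------------------------------
# Threshold exploration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    method: str
    above: np.ndarray  # boolean per cell, strict '>'

    @property
    def n_above(self) -> int:
        return int(self.above.sum())


def explore_thresholds(
    scores: Sequence[CellScoreResult] | np.ndarray,
    method: str = "mean_sd",
    k: float = 3.0,
    percentile: float = 99.0,
    seed: int = 0,
) -> ThresholdResult:
    """Candidate AUC threshold and per-cell assignment.

    Methods: ``mean_sd`` (global mean + k*sd), ``mixture`` (crossing of
    a two-component Gaussian mixture), ``percentile`` (fixed).
    Degenerate constant score vectors fall back to the percentile with a
    warning. Cells are flagged when score > threshold (strict).
    """
    if isinstance(scores, np.ndarray):
        values = scores.astype(float)
    else:
        values = np.array([s.auc for s in scores], dtype=float)
    if values.size < 10:
        raise ValueError("threshold exploration needs >= 10 cells")
    if np.ptp(values) == 0:
        warnings.warn("constant scores; falling back to percentile threshold")
        thr = float(np.percentile(values, percentile))
        return _finalize(scores, values, thr, "percentile_fallback")
    if method == "mean_sd":
        thr = float(values.mean() + k * values.std(ddof=1))
    elif method == "percentile":
        thr = float(np.percentile(values, percentile))
    elif method == "mixture":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        gm.fit(values[:, None])
        means = gm.means_.ravel()
        lo, hi = float(means.min()), float(means.max())
        if hi - lo < 1e-9:
            warnings.warn("mixture components coincide; falling back to percentile")
            thr = float(np.percentile(values, percentile))
            return _finalize(scores, values, thr, "percentile_fallback")
        grid = np.linspace(lo, hi, 2001)
        post = gm.predict_proba(grid[:, None])
        hi_comp = int(np.argmax(means))
        crossing = np.flatnonzero(post[:, hi_comp] >= 0.5)
        thr = float(grid[crossing[0]]) if crossing.size else (lo + hi) / 2.0
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return _finalize(scores, values, thr, method)


def _finalize(scores, values: np.ndarray, thr: float, method: str) -> ThresholdResult:
    above = values > thr
    if not isinstance(scores, np.ndarray):
        for s, flag in zip(scores, above):
            s.above_threshold = bool(flag)
    return ThresholdResult(thr, method, above)


# ---------------------------------------------------------------------------
# Signature scores
# ---------------------------------------------------------------------------


def signature_score(
    matrix: ExpressionMatrix,
    markers: GeneSet,
    method: str = "mean_z",
    min_overlap: float = 0.5,
) -> pd.Series:
    """Per-sample signature score from a marker set.

    ``mean_z``: mean across markers of per-feature z-scores over
    samples (default for bulk cell-line panels); ``auc`` delegates to
    the rank-AUC novelScore. Requires >= ``min_overlap`` of the marker
    set to be measured.
    """
    present = [m for m in markers.members if m in matrix.values.index]
    missing = sorted(markers.members - set(present))
    if len(present) < min_overlap * len(markers.members):
        raise ValueError(
            f"only {len(present)}/{len(markers.members)} markers measured; "
            f"missing: {missing}"
        )
    if method == "auc":
        res = novel_score(matrix, GeneSet(markers.name, frozenset(present)))
        return pd.Series(
            [r.auc for r in res], index=matrix.cells, name=f"{markers.name}_score"
        )
    if method != "mean_z":
        raise ValueError(f"unknown signature method {method!r}")
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    return pd.Series(z.mean(axis=0), index=matrix.cells, name=f"{markers.name}_score")


# ---------------------------------------------------------------------------
# Coexpression
# ---------------------------------------------------------------------------


def _pearson_vs_target(X: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of each row of X vs target."""
    n = target.size
    xc = X - X.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ tc) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p


def coexpression(
    matrix: ExpressionMatrix,
    target_feature: str,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Pearson coexpression of every feature with a target transcript.

    Two-sided p-values are Benjamini-Hochberg adjusted across the
    non-degenerate features; a feature is flagged coexpressed when its
    adjusted p (or raw p with ``use_adjusted=False``) is below alpha.
    Zero-variance features get null r and are excluded from the FDR
    family.
    """
    if target_feature not in matrix.values.index:
        raise KeyError(f"target {target_feature} not in matrix")
    target = matrix.values.loc[target_feature].to_numpy(dtype=float)
    if target.std() == 0:
        raise ValueError(f"target {target_feature} has zero variance")
    others = matrix.values.index[matrix.values.index != target_feature]
    X = matrix.values.loc[others].to_numpy(dtype=float)
    r, p = _pearson_vs_target(X, target)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    crit = q if use_adjusted else p
    out = pd.DataFrame(
        {
            "feature": others,
            "pearson_r": r,
            "p_value": p,
            "fdr_q": q,
            "coexpressed": np.where(valid, crit < alpha, False),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Drug-sensitivity correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureCorrelation:
    drug: str
    n_lines: int
    pearson_r: float
    p_value: float
    fdr_q: float


def correlate_with_ic50(
    scores: pd.Series,
    ic50: pd.DataFrame,
    min_lines: int = 3,
) -> list[SignatureCorrelation]:
    """Pearson correlation of a per-cell-line signature score with IC50.

    ``ic50`` columns: cell_line, drug, ic50. Each drug is correlated
    over the cell lines shared with ``scores``; drugs with fewer than
    ``min_lines`` shared lines are skipped with a warning. p-values are
    BH-adjusted across the tested drugs.
    """
    required = {"cell_line", "drug", "ic50"}
    if not required <= set(ic50.columns):
        raise ValueError(f"IC50 table needs columns {sorted(required)}")
    rows = []
    for drug, grp in ic50.groupby("drug", sort=True):
        shared = grp[grp["cell_line"].isin(scores.index)]
        if len(shared) < min_lines:
            warnings.warn(f"drug {drug}: only {len(shared)} shared lines; skipped")
            continue
        x = scores.loc[shared["cell_line"]].to_numpy(dtype=float)
        y = shared["ic50"].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append((str(drug), len(shared), float(r), float(p)))
    if not rows:
        return []
    qvals = multipletests([p for *_, p in rows], method="fdr_bh")[1]
    return [
        SignatureCorrelation(drug, n, r, p, float(q))
        for (drug, n, r, p), q in zip(rows, qvals)
    ]


def correlations_to_frame(correlations: Sequence[SignatureCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug": [c.drug for c in correlations],
            "n_lines": [c.n_lines for c in correlations],
            "pearson_r": [c.pearson_r for c in correlations],
            "p_value": [c.p_value for c in correlations],
            "fdr_q": [c.fdr_q for c in correlations],
        }
    )


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from GMT (first matching line) or two-column TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and len(first.split("\t")) > 2 and not first.startswith("#"):
        # GMT: name <tab> description <tab> members...
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if name is None or parts[0] == name:
                    return GeneSet(parts[0], frozenset(parts[2:]))
        raise KeyError(f"gene set {name!r} not in {path}")
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 1:
        return GeneSet(name or path.stem, frozenset(df[0].astype(str)))
    sets = df.groupby(1)[0] if df.shape[1] == 2 else None
    # two-column TSV: member <tab> set-name
    for set_name, members in df.groupby(df.columns[-1]):
        if name is None or str(set_name) == name:
            return GeneSet(str(set_name), frozenset(members[df.columns[0]].astype(str)))
    raise KeyError(f"gene set {name!r} not in {path}")


def read_ic50(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df
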