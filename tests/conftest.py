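from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scnovel.genome_model import ExpressionMatrix, GenomicInterval, TranscriptModel
from scnovel import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def gbm_fixture():
    """The desk-scale study emulation (seed 42), shared across tests."""
    manifest = sf.emulate_paper_shape("gbm_like")
    manifest.seed = 42
    return sf.generate(manifest)


@pytest.fixture(scope="session")
def small_fixture():
    manifest = sf.FixtureManifest(seed=1)
    return sf.generate(manifest)


def make_transcript(
    tid: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    gene: str | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        tid,
        gene or tid,
        chrom,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def make_matrix(
    values: np.ndarray,
    features: list[str] | None = None,
    cells: list[str] | None = None,
    labels: list[str] | None = None,
) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"T{i + 1}" for i in range(values.shape[0])]
    cells = cells or [f"c{i + 1}" for i in range(values.shape[1])]
    types = (
        pd.Series(labels, index=cells, name="cell_type") if labels is not None else None
    )
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=cells), types)


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str,
    lo: int,
    hi: int,
    max_exons: int = 4,
) -> TranscriptModel:
    """A random (possibly unspliced) transcript anywhere in [lo, hi)."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = str(rng.choice(["+", "-", "."], p=[0.45, 0.45, 0.1]))
    exons = []
    cursor = int(rng.integers(lo, max(lo + 1, hi - 2500)))
    for k in range(n_exons):
        elen = int(rng.integers(30, 400))
        exons.append((cursor, cursor + elen))
        cursor += elen + int(rng.integers(30, 600))
    return make_transcript(tid, chrom, strand, exons)
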