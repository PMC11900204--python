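"""Seeded generator of ground-truthed synthetic inputs for every stage.

The generator lays out a random genome with spaced multi-exon reference
genes (protein-coding sequence written into their exons), then plants
assembled transcripts with known class codes by construction:

    '='  exact copy of a reference transcript
    'c'  the middle exons of a reference (a contained fragment)
    'j'  a reference copy with one splice junction shifted, the rest kept
    'i'  a single exon strictly inside a reference intron
    'o'  a single exon straddling a reference exon boundary, same strand
    'x'  the same geometry on the opposite strand
    'u'  exons in dedicated intergenic slots

Expression is negative-binomial with per-cell-type mean shifts: marker
transcripts draw their type profile from a Dirichlet concentrated on one
type, background transcripts from a flat Dirichlet; independent Bernoulli
dropout is applied on top. Conservation emulates the
annotated-above-novel contrast (annotated exon bases ~ Beta(5, 2), novel
~ Beta(2, 5)). A drug panel plants one signature-correlated IC50 profile
(population r = -0.7) among null drugs.

Identical seeds give byte-identical output files; the manifest is
serialized alongside them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    ConservationTrack,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    write_bedgraph,
    write_expression,
    write_fasta,
    write_gtf,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FixtureManifest:
    """Full specification of one synthetic study; the generator is a
    pure function of this object."""

    seed: int = 0
    # genome / reference geometry
    n_chroms: int = 3
    exon_count_range: tuple[int, int] = (3, 5)
    exon_length_range: tuple[int, int] = (90, 300)
    intron_length_range: tuple[int, int] = (420, 800)
    intergenic_gap: int = 800
    # planted assembly: class code -> count
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"=": 20, "c": 20, "j": 20, "i": 20, "u": 20, "o": 5, "x": 5}
    )
    # expression
    cell_types: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")
    cells_per_type: int = 40
    rare_type: str | None = None
    rare_prevalence: float = 0.03
    markers_per_type: int = 5
    nb_dispersion: float = 3.0
    dropout: float = 0.1
    base_mean_log: tuple[float, float] = (0.7, 0.6)  # lognormal(mu, sigma)
    marker_mean_log: tuple[float, float] = (1.6, 0.4)
    marker_alpha: float = 40.0
    background_alpha: float = 3.0
    coexpression_block_size: int = 15
    coexpression_loading: float = 0.8
    # conservation
    annotated_beta: tuple[float, float] = (5.0, 2.0)
    novel_beta: tuple[float, float] = (2.0, 5.0)
    # drug panel
    n_cell_lines: int = 30
    n_drugs: int = 20
    planted_drug_r: float = -0.7

    def validate(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) < 1:
            raise ValueError("manifest plants no transcripts")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0 < self.rare_prevalence < 1:
            raise ValueError("rare prevalence must lie in (0, 1)")
        bad = set(self.class_counts) - set("=cjiuox")
        if bad:
            raise ValueError(f"unknown class codes {sorted(bad)}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        raw = json.loads(text)
        for key in (
            "exon_count_range",
            "exon_length_range",
            "intron_length_range",
            "base_mean_log",
            "marker_mean_log",
            "annotated_beta",
            "novel_beta",
        ):
            raw[key] = tuple(raw[key])
        raw["cell_types"] = tuple(raw["cell_types"])
        return cls(**raw)


def emulate_paper_shape(profile: str = "gbm_like") -> FixtureManifest:
    """Manifest mirroring the study's shape at desk scale: ~1,000
    assembled transcripts with ~52.7% planted as unannotated (u/i/j), six
    major cell types plus a rare stemness-like subtype at 3%."""
    if profile != "gbm_like":
        raise ValueError(f"unknown profile {profile!r}")
    return FixtureManifest(
        class_counts={"=": 413, "c": 40, "j": 175, "i": 176, "u": 176, "o": 10, "x": 10},
        cell_types=("neoplastic", "astrocyte", "oligodendrocyte", "opc", "neuron", "immune"),
        cells_per_type=97,
        rare_type="stemness_like",
        rare_prevalence=0.03,
        markers_per_type=30,
    )


def planted_unannotated_fraction(manifest: FixtureManifest) -> float:
    total = sum(manifest.class_counts.values())
    novel = sum(manifest.class_counts.get(c, 0) for c in "uij")
    return novel / total


# ---------------------------------------------------------------------------
# sequence simulators (used for coding-potential training too)
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# biased codon usage: GC-ending codons preferred, as in highly expressed
# mammalian coding sequence; gives the hexamer feature signal to learn
_CODON_W = np.array([3.0 if c[2] in "GC" else 1.0 for c in _CODONS])
_CODON_W /= _CODON_W.sum()


def make_coding_seq(rng: np.random.Generator, length: int) -> str:
    """mRNA-like sequence: short UTRs around an ORF with biased codon
    usage covering most of the length."""
    utr5 = random_sequence(rng, int(rng.integers(10, 40))).replace("ATG", "ACG")
    n_codons = max((length - len(utr5) - 6) // 3, 30)
    body = "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_W))
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    seq = utr5 + "ATG" + body + stop
    if len(seq) < length:
        seq += random_sequence(rng, length - len(seq))
    return seq[: max(length, len(utr5) + 3 * n_codons + 6)]


def make_noncoding_seq(rng: np.random.Generator, length: int) -> str:
    return random_sequence(rng, length)


def make_training_set(
    n_per_class: int, seed: int = 7, length_range: tuple[int, int] = (400, 1500)
) -> tuple[list[str], list[str]]:
    """Labeled coding/noncoding sequences for predictor training."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    coding = [make_coding_seq(rng, int(rng.integers(lo, hi))) for _ in range(n_per_class)]
    noncoding = [make_noncoding_seq(rng, int(rng.integers(lo, hi))) for _ in range(n_per_class)]
    return coding, noncoding


# ---------------------------------------------------------------------------
# reference + planted-assembly geometry
# ---------------------------------------------------------------------------


def _make_gene(
    rng: np.random.Generator, manifest: FixtureManifest, chrom: str, start: int, idx: int
) -> TranscriptModel:
    n_exons = int(rng.integers(manifest.exon_count_range[0], manifest.exon_count_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    cursor = start
    for k in range(n_exons):
        elen = int(rng.integers(*manifest.exon_length_range))
        exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
        cursor += elen
        if k < n_exons - 1:
            cursor += int(rng.integers(*manifest.intron_length_range))
    return TranscriptModel(f"REF{idx:05d}", f"G{idx:05d}", chrom, strand, tuple(exons))


def _plant(
    rng: np.random.Generator,
    code: str,
    anchor: TranscriptModel | None,
    novel_id: str,
    slot: tuple[str, int, int] | None = None,
) -> TranscriptModel:
    """Construct one novel transcript with the requested true class code."""
    if code == "=":
        assert anchor is not None
        return TranscriptModel(novel_id, novel_id, anchor.chrom, anchor.strand, anchor.exons)
    if code == "c":
        assert anchor is not None
        inner = anchor.exons[1:-1]
        trimmed = tuple(
            GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in inner
        )
        return TranscriptModel(novel_id, novel_id, anchor.chrom, anchor.strand, trimmed)
    if code == "j":
        assert anchor is not None and anchor.exon_count >= 3
        shift = int(rng.integers(4, 20))
        exons = list(anchor.exons)
        first = exons[0]
        exons[0] = GenomicInterval(first.chrom, first.start, first.end - shift, first.strand)
        return TranscriptModel(novel_id, novel_id, anchor.chrom, anchor.strand, tuple(exons))
    if code == "i":
        assert anchor is not None
        intron = anchor.introns[int(rng.integers(len(anchor.introns)))]
        margin = 8
        strand = "+" if rng.random() < 0.5 else "-"
        exon = GenomicInterval(anchor.chrom, intron.start + margin, intron.end - margin, strand)
        return TranscriptModel(novel_id, novel_id, anchor.chrom, strand, (exon,))
    if code in ("o", "x"):
        assert anchor is not None
        first = anchor.exons[0]
        ext = int(rng.integers(120, 200))
        ov = int(rng.integers(40, min(70, max(41, int(0.7 * first.length)))))
        if code == "o":
            strand = anchor.strand
        else:
            strand = "-" if anchor.strand == "+" else "+"
        exon = GenomicInterval(anchor.chrom, first.start - ext, first.start + ov, strand)
        return TranscriptModel(novel_id, novel_id, anchor.chrom, strand, (exon,))
    if code == "u":
        assert slot is not None
        chrom, start, end = slot
        strand = rng.choice(["+", "-", "."], p=[0.45, 0.45, 0.1])
        if end - start > 700 and rng.random() < 0.3:
            mid = (start + end) // 2
            exons = (
                GenomicInterval(chrom, start, mid - 120, strand),
                GenomicInterval(chrom, mid, end, strand),
            )
        else:
            exons = (GenomicInterval(chrom, start, end, strand),)
        return TranscriptModel(novel_id, novel_id, chrom, str(strand), exons)
    raise ValueError(f"cannot plant class code {code!r}")


@dataclass
class Fixture:
    """In-memory result of one generator run."""

    manifest: FixtureManifest
    genome: dict[str, str]
    reference: list[TranscriptModel]
    assembly: list[TranscriptModel]
    truth_classes: pd.DataFrame  # transcript_id, class_code, anchor
    matrix: ExpressionMatrix
    truth_markers: pd.DataFrame  # transcript_id, cell_type
    track: ConservationTrack
    line_scores: pd.Series
    ic50: pd.DataFrame
    truth_drugs: pd.DataFrame
    coexpression_block: list[str]


def generate(manifest: FixtureManifest) -> Fixture:
    """Generate a complete fixture from a manifest (pure in the seed)."""
    manifest.validate()
    rng = np.random.default_rng(manifest.seed)

    counts = {c: manifest.class_counts.get(c, 0) for c in "=cjiuox"}
    anchored_codes = [c for c in "=cjiox" for _ in range(counts[c])]
    n_genes = len(anchored_codes)
    n_u = counts["u"]

    # --- lay out genes and intergenic 'u' slots round-robin over chroms
    chrom_names = [f"chr{i + 1}" for i in range(manifest.n_chroms)]
    cursors = {c: manifest.intergenic_gap for c in chrom_names}
    genes: list[TranscriptModel] = []
    for idx in range(n_genes):
        chrom = chrom_names[idx % manifest.n_chroms]
        gene = _make_gene(rng, manifest, chrom, cursors[chrom], idx)
        genes.append(gene)
        cursors[chrom] = gene.span.end + manifest.intergenic_gap
    u_slots: list[tuple[str, int, int]] = []
    for k in range(n_u):
        chrom = chrom_names[k % manifest.n_chroms]
        start = cursors[chrom]
        length = int(rng.integers(250, 900))
        u_slots.append((chrom, start, start + length))
        cursors[chrom] = start + length + manifest.intergenic_gap

    # --- plant the assembly
    order = rng.permutation(n_genes)
    assembly: list[TranscriptModel] = []
    truth_rows = []
    novel_idx = 0
    for gi, code in zip(order, anchored_codes):
        novel_idx += 1
        t = _plant(rng, code, genes[gi], f"NOV{novel_idx:05d}")
        assembly.append(t)
        truth_rows.append((t.transcript_id, code, genes[gi].transcript_id))
    for slot in u_slots:
        novel_idx += 1
        t = _plant(rng, "u", None, f"NOV{novel_idx:05d}", slot=slot)
        assembly.append(t)
        truth_rows.append((t.transcript_id, "u", "."))
    truth_classes = pd.DataFrame(
        truth_rows, columns=["transcript_id", "class_code", "anchor"]
    ).sort_values("transcript_id", kind="stable", ignore_index=True)
    assembly.sort(key=lambda t: t.transcript_id)

    # --- genome: random background, coding sequence written into genes
    chrom_arrays = {
        c: rng.choice(_BASES, size=cursors[c] + manifest.intergenic_gap).copy()
        for c in chrom_names
    }
    for gene in genes:
        total = gene.length
        mrna = make_coding_seq(rng, total)[:total]
        plus = mrna if gene.strand == "+" else _revcomp(mrna)
        arr = chrom_arrays[gene.chrom]
        pos = 0
        for e in gene.exons:
            arr[e.start : e.end] = np.frombuffer(
                plus[pos : pos + e.length].encode(), dtype="S1"
            )
            pos += e.length
    genome = {c: a.tobytes().decode() for c, a in chrom_arrays.items()}

    # --- cell labels
    types = list(manifest.cell_types)
    n_common = len(types) * manifest.cells_per_type
    labels = [t for t in types for _ in range(manifest.cells_per_type)]
    if manifest.rare_type:
        n_rare = max(int(round(manifest.rare_prevalence * n_common / (1 - manifest.rare_prevalence))), 3)
        labels += [manifest.rare_type] * n_rare
        types = types + [manifest.rare_type]
    cells = [f"CELL{i + 1:04d}" for i in range(len(labels))]
    label_s = pd.Series(labels, index=cells, name="cell_type")

    # --- choose markers among planted u/i transcripts (lncRNA candidates)
    lnc_pool = truth_classes.loc[
        truth_classes["class_code"].isin(["u", "i"]), "transcript_id"
    ].tolist()
    need = manifest.markers_per_type * len(types)
    if need > len(lnc_pool):
        raise ValueError(
            f"manifest requests {need} markers but only {len(lnc_pool)} u/i plants"
        )
    marker_ids = list(rng.choice(lnc_pool, size=need, replace=False)) if need else []
    marker_type = {
        tid: types[i // manifest.markers_per_type] for i, tid in enumerate(marker_ids)
    }
    truth_markers = pd.DataFrame(
        sorted(marker_type.items()), columns=["transcript_id", "cell_type"]
    )

    # --- expression: NB with Dirichlet type profiles + dropout
    feature_ids = [t.transcript_id for t in assembly]
    T = len(types)
    type_index = {t: i for i, t in enumerate(types)}
    cell_type_idx = np.array([type_index[l] for l in labels])
    profiles = np.empty((len(feature_ids), T))
    base_mu = np.empty(len(feature_ids))
    block = sorted(
        rng.choice(
            [f for f in feature_ids if f not in marker_type],
            size=min(manifest.coexpression_block_size, len(feature_ids)),
            replace=False,
        )
    )
    block_set = set(block)
    mu_log, sd_log = manifest.base_mean_log
    mmu_log, msd_log = manifest.marker_mean_log
    for fi, tid in enumerate(feature_ids):
        if tid in marker_type:
            alpha = np.full(T, 0.4)
            alpha[type_index[marker_type[tid]]] = manifest.marker_alpha
            base_mu[fi] = rng.lognormal(mmu_log, msd_log)
        else:
            alpha = np.full(T, manifest.background_alpha)
            base_mu[fi] = rng.lognormal(mu_log, sd_log)
        profiles[fi] = rng.dirichlet(alpha)
    mean = base_mu[:, None] * T * profiles[:, cell_type_idx]
    if block:
        factor = rng.normal(size=len(cells))
        rows = [feature_ids.index(b) for b in block]
        mean[rows] *= np.exp(
            manifest.coexpression_loading * factor[None, :]
            - manifest.coexpression_loading**2 / 2
        )
    r = manifest.nb_dispersion
    counts_mat = rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-9)))
    if manifest.dropout > 0:
        counts_mat = counts_mat * (rng.random(counts_mat.shape) >= manifest.dropout)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts_mat.astype(float), index=feature_ids, columns=cells),
        label_s,
    )

    # --- conservation: annotated exon bases Beta(a1), novel Beta(a2)
    ann_pos: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    for gene in genes:
        for e in gene.exons:
            ann_pos[gene.chrom].append(np.arange(e.start, e.end))
    novel_codes = {"u", "i"}
    nov_pos: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    novel_ids = set(
        truth_classes.loc[truth_classes["class_code"].isin(novel_codes), "transcript_id"]
    )
    for t in assembly:
        if t.transcript_id in novel_ids:
            for e in t.exons:
                nov_pos[t.chrom].append(np.arange(e.start, e.end))
    positions, scores = {}, {}
    a1, b1 = manifest.annotated_beta
    a2, b2 = manifest.novel_beta
    for chrom in chrom_names:
        ann = (
            np.unique(np.concatenate(ann_pos[chrom]))
            if ann_pos[chrom]
            else np.empty(0, dtype=np.int64)
        )
        nov = (
            np.unique(np.concatenate(nov_pos[chrom]))
            if nov_pos[chrom]
            else np.empty(0, dtype=np.int64)
        )
        nov = nov[~np.isin(nov, ann)]
        positions[chrom] = np.concatenate([ann, nov])
        scores[chrom] = np.concatenate(
            [rng.beta(a1, b1, size=ann.size), rng.beta(a2, b2, size=nov.size)]
        )
    track = ConservationTrack(positions, scores)

    # --- drug panel: planted signature/IC50 correlation among nulls
    lines = [f"LINE{i + 1:03d}" for i in range(manifest.n_cell_lines)]
    z = rng.normal(size=manifest.n_cell_lines)
    line_scores = pd.Series(z, index=lines, name="signature_score")
    rho = manifest.planted_drug_r
    drug_rows = []
    planted_drug = "DRUG01"
    for d in range(manifest.n_drugs):
        name = f"DRUG{d + 1:02d}"
        if name == planted_drug:
            y = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=len(lines))
        else:
            y = rng.normal(size=len(lines))
        for line, v in zip(lines, y):
            drug_rows.append((line, name, float(v)))
    ic50 = pd.DataFrame(drug_rows, columns=["cell_line", "drug", "ic50"])
    truth_drugs = pd.DataFrame(
        {"drug": [planted_drug], "planted_r": [rho]}
    )

    return Fixture(
        manifest=manifest,
        genome=genome,
        reference=genes,
        assembly=assembly,
        truth_classes=truth_classes,
        matrix=matrix,
        truth_markers=truth_markers,
        track=track,
        line_scores=line_scores,
        ic50=ic50,
        truth_drugs=truth_drugs,
        coexpression_block=block,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Serialize a fixture to its on-disk file set; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.json",
        "genome": outdir / "genome.fa",
        "reference": outdir / "reference.gtf",
        "assembly": outdir / "assembly.gtf",
        "truth_classes": outdir / "truth_classes.tsv",
        "conservation": outdir / "cons.bedgraph",
        "truth_markers": outdir / "truth_markers.tsv",
        "line_scores": outdir / "line_scores.tsv",
        "ic50": outdir / "ic50.tsv",
        "truth_drugs": outdir / "truth_drugs.tsv",
    }
    paths["manifest"].write_text(fixture.manifest.to_json() + "\n")
    write_fasta(fixture.genome, paths["genome"])
    write_gtf(fixture.reference, paths["reference"])
    write_gtf(fixture.assembly, paths["assembly"])
    fixture.truth_classes.to_csv(paths["truth_classes"], sep="\t", index=False)
    write_bedgraph(fixture.track, paths["conservation"])
    fixture.truth_markers.to_csv(paths["truth_markers"], sep="\t", index=False)
    fixture.line_scores.to_csv(paths["line_scores"], sep="\t", header=False)
    fixture.ic50.to_csv(paths["ic50"], sep="\t", index=False)
    fixture.truth_drugs.to_csv(paths["truth_drugs"], sep="\t", index=False)
    paths.update(write_expression(fixture.matrix, outdir))
    return paths


def generate_to_dir(manifest: FixtureManifest, outdir: str | Path) -> dict[str, Path]:
    return write_fixture(generate(manifest), outdir)
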