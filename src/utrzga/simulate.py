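"""Self-contained synthetic test universe for the whole pipeline.

Generates (a) a toy genome with multi-exon protein-coding genes on both
strands whose 3'UTRs carry planted DAZL-motif occurrences on an otherwise
T-free background, and (b) a negative-binomial count matrix over the
seven-stage triplicate design with planted temporal archetypes, plus
truth tables for every downstream stage of the analysis.

Why a T-free background: all six DAZL motifs contain U, so a background
drawn from {A,C,G} can never match by accident — every match in a UTR is
attributable to a planted word (or to the junction of a planted word with
its flanking spacer; truth counts are therefore recorded by an exact
regex recount of the finished sequence, so they are exact by
construction, not probabilistic).

Temporal archetypes are step functions on log2 stage means:

- ``zga1``          — up by ``effect_size`` at the zygote (minor-wave
  activation), held through EGK.VI, back down at EGK.VIII: the profile
  described for DAZL itself.
- ``zga2``          — up at EGK.III (major-wave activation), maintained.
- ``post_zga``      — up at EGK.VIII, maintained.
- ``maternal_decay``— monotone decline from the oocyte (steps down at
  EGK.I and EGK.VIII): maternal transcript clearance.
- ``constitutive``  — flat.
- ``silent``        — near-zero mean at every stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .design import STAGES, consecutive_contrasts, contrast_name
from .motifs import BUILTIN_MOTIF_SPECS, compile_motif

ARCHETYPES = (
    "maternal_decay",
    "zga1",
    "zga2",
    "post_zga",
    "constitutive",
    "silent",
)

#: Step offsets per archetype, in units of effect_size (log2), one per stage.
_ARCHETYPE_STEPS: dict[str, tuple[float, ...]] = {
    "constitutive": (0, 0, 0, 0, 0, 0, 0),
    "zga1": (0, 1, 1, 1, 1, 0, 0),
    "zga2": (0, 0, 0, 1, 1, 1, 1),
    "post_zga": (0, 0, 0, 0, 0, 1, 1),
    "maternal_decay": (0, 0, -1, -1, -1, -1, -2),
    "silent": (0, 0, 0, 0, 0, 0, 0),
}

#: Archetype -> expected temporal-pattern label from the classifier.
ARCHETYPE_EXPECTED_LABEL = {
    "zga1": "zga1_activated",
    "zga2": "zga2_activated",
    "post_zga": "post_zga_activated",
    "maternal_decay": "maternal_decay",
    "constitutive": "constitutive",
    "silent": "low_expressed",
}


class SizingError(ValueError):
    """Requested chromosome length cannot hold the requested genes."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic universe.

    Defaults emulate the study conditions: 7 stages x 3 replicates
    (21 samples), a log2 effect step of 2.0 per activation/decay event,
    NB dispersion 0.1, and well-expressed genes (base mean counts of
    100-800 per sample).
    """

    seed: int = 0
    n_genes: int = 200
    chrom_length: int | None = None  # None: sized automatically
    utr_length_range: tuple[int, int] = (150, 400)
    #: motif spec -> inclusive (min, max) planted occurrences per gene
    motif_plan: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {s: (0, 3) for s in BUILTIN_MOTIF_SPECS}
    )
    stage_design: tuple[tuple[str, int], ...] = tuple((s, 3) for s in STAGES)
    #: majority-constitutive, as in real transcriptomes: TMM (and the
    #: edgeR-style workflow) assumes most genes are not DE at any contrast
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "maternal_decay": 0.10,
            "zga1": 0.10,
            "zga2": 0.10,
            "post_zga": 0.08,
            "constitutive": 0.55,
            "silent": 0.07,
        }
    )
    effect_size: float = 2.0  # log2 fold step per activation event
    dispersion: float = 0.1  # NB dispersion phi (var = mu + phi mu^2)
    #: target total counts per sample, drawn uniformly then fixed
    lib_size_range: tuple[float, float] = (80_000.0, 160_000.0)
    base_mean_range: tuple[float, float] = (100.0, 800.0)
    silent_mean: float = 0.05
    decoy_fraction: float = 0.25  # genes that also get a shorter XM_ variant
    intron_fraction: float = 0.3  # genes with an intron inside the CDS
    intron_length: int = 40
    cds_codons: int = 12  # internal codons between start and stop

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix proportions sum to {total}, not 1")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for stage, n in self.stage_design:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 1:
                raise ValueError("each stage needs >= 1 replicate")

    @property
    def stages(self) -> list[str]:
        return [s for s, _ in self.stage_design]


@dataclass
class TruthTable:
    """Ground truth for every simulated gene.

    ``genes``: archetype, UTR genomic coordinates/strand, base mean.
    ``motif_counts``: exact per-motif occurrence counts in each primary UTR.
    ``true_logfc``: per-contrast true log2 fold change implied by the
    archetype step functions.
    """

    genes: pd.DataFrame
    motif_counts: pd.DataFrame
    true_logfc: pd.DataFrame


def _stage_offsets(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-archetype log2 offsets restricted to the configured stages."""
    idx = [STAGES.index(s) for s in config.stages]
    return {
        a: config.effect_size * np.asarray(_ARCHETYPE_STEPS[a], float)[idx]
        for a in ARCHETYPES
    }


def assign_archetypes(config: SimulationConfig) -> TruthTable:
    """Draw per-gene archetypes and derive true per-contrast log2FC.

    This is the expression-side truth only (no genome); used directly for
    expression simulations and internally by :func:`generate_annotation`.
    """
    rng = np.random.default_rng([config.seed, 11])
    names = sorted(config.archetype_mix)
    probs = np.array([config.archetype_mix[a] for a in names])
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    archetypes = rng.choice(names, size=config.n_genes, p=probs)

    genes = pd.DataFrame({"archetype": archetypes}, index=pd.Index(gene_ids, name="gene_id"))
    genes["expected_label"] = genes["archetype"].map(ARCHETYPE_EXPECTED_LABEL)

    offsets = _stage_offsets(config)
    contrasts = consecutive_contrasts(config.stages)
    lfc = {}
    for a, b in contrasts:
        ia, ib = config.stages.index(a), config.stages.index(b)
        lfc[contrast_name(a, b)] = [
            0.0 if arc == "silent" else offsets[arc][ib] - offsets[arc][ia]
            for arc in archetypes
        ]
    true_logfc = pd.DataFrame(lfc, index=genes.index)
    motif_cols = list(config.motif_plan)
    motif_counts = pd.DataFrame(
        0, index=genes.index, columns=motif_cols, dtype=int
    )
    return TruthTable(genes=genes, motif_counts=motif_counts, true_logfc=true_logfc)


_TFREE = np.array(list("ACG"))


def _background(rng: np.random.Generator, n: int) -> str:
    """T-free background: cannot contain any U-requiring motif."""
    return "".join(rng.choice(_TFREE, size=n)) if n > 0 else ""


def _regex_recount(utr_sense_dna: str, words: Sequence[str]) -> int:
    """Exact overlapping occurrence count via regex lookahead (DNA alphabet)."""
    pat = "|".join(w.replace("U", "T") for w in words)
    return len(re.findall(rf"(?=(?:{pat}))", utr_sense_dna))


def _build_utr(rng: np.random.Generator, config: SimulationConfig) -> tuple[str, dict[str, int]]:
    """One UTR sense-strand DNA sequence with planted motifs, plus exact counts."""
    compiled = {spec: compile_motif(spec) for spec in config.motif_plan}
    plants: list[str] = []
    for spec, (lo, hi) in config.motif_plan.items():
        n = int(rng.integers(lo, hi + 1))
        words = sorted(compiled[spec].words)
        for _ in range(n):
            w = words[int(rng.integers(len(words)))]
            plants.append(w.replace("U", "T"))
    rng.shuffle(plants)

    # >=7 T-free spacer bases between plants so no 7-mer window spans two
    parts = [_background(rng, int(rng.integers(7, 15)))]
    for w in plants:
        parts.append(w)
        parts.append(_background(rng, int(rng.integers(7, 15))))
    utr = "".join(parts)
    target = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
    if len(utr) < target:
        utr += _background(rng, target - len(utr))
    counts = {
        spec: _regex_recount(utr, sorted(p.words)) for spec, p in compiled.items()
    }
    return utr, counts


def _sense_to_genomic(span: tuple[int, int], g0: int, length: int, strand: str) -> tuple[int, int]:
    """Map a 1-based sense-space interval onto genomic coordinates."""
    s, e = span
    if strand == "+":
        return (g0 + s - 1, g0 + e - 1)
    return (g0 + length - e, g0 + length - s)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def generate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, list[TranscriptModel]], TruthTable]:
    """Build the toy genome, transcript models and ground truth.

    Each gene gets one primary transcript (``NM_`` accession): an ATG, a
    T-free CDS body (T-free codons can never spell a stop), a TAA stop, and
    the planted-motif UTR. Some genes additionally carry an intron inside
    the CDS (two exons) and/or a decoy ``XM_`` variant with a truncated UTR
    to exercise the primary-variant rule. Genes alternate strands.
    """
    truth = assign_archetypes(config)
    rng = np.random.default_rng([config.seed, 23])
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 1  # next free 1-based genomic coordinate
    transcripts: dict[str, list[TranscriptModel]] = {}
    utr_meta = []
    motif_rows = []

    for i, gene_id in enumerate(truth.genes.index):
        spacer = "".join(rng.choice(np.array(list("ACGT")), size=int(rng.integers(60, 150))))
        pieces.append(spacer)
        cursor += len(spacer)

        utr_dna, counts = _build_utr(rng, config)
        motif_rows.append(counts)
        body = _background(rng, 3 * config.cds_codons)
        cds_seq = "ATG" + body + "TAA"

        has_intron = rng.random() < config.intron_fraction
        if has_intron:
            # split the CDS between two codons; canonical GT..AG intron
            cut = 3 * int(rng.integers(2, config.cds_codons))
            intron = "GT" + _background(rng, config.intron_length - 4) + "AG"
            pre = cds_seq[:cut] + intron + cds_seq[cut:] + utr_dna
            L = len(pre)
            exons_sense = [(1, cut), (cut + len(intron) + 1, L)]
            cds_sense = [(1, cut), (cut + len(intron) + 1, cut + len(intron) + len(cds_seq) - cut)]
        else:
            pre = cds_seq + utr_dna
            L = len(pre)
            exons_sense = [(1, L)]
            cds_sense = [(1, len(cds_seq))]
        utr_sense = (len(pre) - len(utr_dna) + 1, len(pre))

        strand = "+" if i % 2 == 0 else "-"
        g0 = cursor
        genomic = pre if strand == "+" else _revcomp(pre)
        pieces.append(genomic)
        cursor += L

        def g(span: tuple[int, int]) -> tuple[int, int]:
            return _sense_to_genomic(span, g0, L, strand)

        tid = f"NM_{i + 1:06d}.1"
        primary = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            start=g0,
            end=g0 + L - 1,
            exons=tuple(g(s) for s in exons_sense),
            cds=tuple(g(s) for s in cds_sense),
        )
        models = [primary]
        if rng.random() < config.decoy_fraction and len(utr_dna) >= 40:
            # decoy: identical CDS, UTR truncated to about half
            dec_end_sense = utr_sense[0] - 1 + len(utr_dna) // 2
            dx = [(s, min(e, dec_end_sense)) for s, e in exons_sense if s <= dec_end_sense]
            dspan = g((1, dec_end_sense))
            models.append(
                TranscriptModel(
                    transcript_id=f"XM_{i + 1:06d}.1",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=dspan[0],
                    end=dspan[1],
                    exons=tuple(g(s) for s in dx),
                    cds=tuple(g(s) for s in cds_sense),
                )
            )
        transcripts[gene_id] = models
        us, ue = g(utr_sense)
        utr_meta.append(
            {
                "chrom": chrom,
                "strand": strand,
                "transcript_id": tid,
                "utr_start": us,
                "utr_end": ue,
                "utr_length": len(utr_dna),
            }
        )

    tail = "".join(rng.choice(np.array(list("ACGT")), size=int(rng.integers(60, 150))))
    pieces.append(tail)
    cursor += len(tail)
    seq = "".join(pieces)
    if config.chrom_length is not None:
        if len(seq) > config.chrom_length:
            raise SizingError(
                f"{config.n_genes} genes need {len(seq)} bases but "
                f"chrom_length is {config.chrom_length}"
            )
        seq += _background(rng, config.chrom_length - len(seq))

    meta = pd.DataFrame(utr_meta, index=truth.genes.index)
    truth.genes = truth.genes.join(meta)
    truth.motif_counts = pd.DataFrame(
        motif_rows, index=truth.genes.index
    ).astype(int)
    truth.motif_counts.index.name = "gene_id"
    return {chrom: seq}, transcripts, truth


def simulate_counts(
    config: SimulationConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB-distributed counts over the configured stage design.

    Per gene g and sample j: ``count ~ NB(mean = mu_gs * f_j, phi)`` where
    ``mu_gs`` follows the gene's archetype step function and ``f_j`` is a
    fixed per-sample library-size factor derived from a target total drawn
    uniformly from ``lib_size_range``.
    """
    if config.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng([config.seed, 37])
    offsets = _stage_offsets(config)
    arch = truth.genes["archetype"].to_numpy()
    G = len(arch)

    base = rng.uniform(*config.base_mean_range, size=G)
    base = np.where(arch == "silent", config.silent_mean, base)
    stage_off = np.stack([offsets[a] for a in arch])  # G x n_stages
    mu_stage = base[:, None] * 2.0 ** stage_off  # G x n_stages

    sample_ids, stages, reps = [], [], []
    for stage, n in config.stage_design:
        for r in range(1, n + 1):
            sample_ids.append(f"{stage}_rep{r}")
            stages.append(stage)
            reps.append(r)
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "stage": stages, "replicate": reps}
    )

    stage_idx = np.array([config.stages.index(s) for s in stages])
    targets = rng.uniform(*config.lib_size_range, size=len(sample_ids))
    expected_totals = mu_stage.sum(axis=0)[stage_idx]
    factors = targets / expected_totals
    mean = mu_stage[:, stage_idx] * factors[None, :]

    phi = config.dispersion
    p = 1.0 / (1.0 + phi * mean)
    counts = rng.negative_binomial(1.0 / phi, p)
    mat = pd.DataFrame(
        counts.astype(np.int64), index=truth.genes.index, columns=sample_ids
    )
    mat.columns.name = None
    truth.genes = truth.genes.assign(base_mean=base)
    return mat, sheet


@dataclass
class Bundle:
    """A complete simulated universe ready to run the pipeline on."""

    config: SimulationConfig
    genome: dict[str, str]
    transcripts: dict[str, list[TranscriptModel]]
    truth: TruthTable
    counts: pd.DataFrame
    samples: pd.DataFrame


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate annotation + counts in one deterministic call."""
    genome, transcripts, truth = generate_annotation(config)
    counts, samples = simulate_counts(config, truth)
    return Bundle(config, genome, transcripts, truth, counts, samples)


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Counts + sheet + truth without building a genome (for DE studies)."""
    truth = assign_archetypes(config)
    counts, sheet = simulate_counts(config, truth)
    return counts, sheet, truth


def _write_fasta(genome: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _cds_phases(cds: Sequence[tuple[int, int]], strand: str) -> list[int]:
    spans = list(cds) if strand == "+" else list(reversed(cds))
    phases, done = [], 0
    for s, e in spans:
        phases.append((3 - done % 3) % 3)
        done += e - s + 1
    return phases if strand == "+" else list(reversed(phases))


def _write_gff3(transcripts: Mapping[str, Sequence[TranscriptModel]], genome: Mapping[str, str], path: Path) -> None:
    lines = ["##gff-version 3"]
    for name, seq in genome.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for gene_id in transcripts:
        models = transcripts[gene_id]
        gs = min(m.start for m in models)
        ge = max(m.end for m in models)
        chrom, strand = models[0].chrom, models[0].strand
        lines.append(
            f"{chrom}\tutrzga\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}"
        )
        for m in models:
            lines.append(
                f"{chrom}\tutrzga\tmRNA\t{m.start}\t{m.end}\t.\t{strand}\t.\t"
                f"ID={m.transcript_id};Parent={gene_id}"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                lines.append(
                    f"{chrom}\tutrzga\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id}.exon{k};Parent={m.transcript_id}"
                )
            for (s, e), ph in zip(m.cds, _cds_phases(m.cds, strand)):
                lines.append(
                    f"{chrom}\tutrzga\tCDS\t{s}\t{e}\t.\t{strand}\t{ph}\t"
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bundle(bundle: Bundle, directory) -> dict[str, Path]:
    """Write genome.fa, annotation.gff3, counts.tsv, samples.tsv and truth/."""
    out = Path(directory)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gff3": out / "annotation.gff3",
            "counts": out / "counts.tsv",
            "samples": out / "samples.tsv",
            "truth_genes": out / "truth" / "genes.tsv",
            "truth_motifs": out / "truth" / "motif_counts.tsv",
            "truth_logfc": out / "truth" / "true_logfc.tsv",
        }
        _write_fasta(bundle.genome, paths["genome"])
        _write_gff3(bundle.transcripts, bundle.genome, paths["gff3"])
        bundle.counts.to_csv(paths["counts"], sep="\t")
        bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
        bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t")
        bundle.truth.motif_counts.to_csv(paths["truth_motifs"], sep="\t")
        bundle.truth.true_logfc.to_csv(paths["truth_logfc"], sep="\t")
    except OSError as exc:
        raise OSError(f"failed writing bundle under {out}: {exc}") from exc
    return paths
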