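"""Genome/annotation I/O, transcript models and 3'UTR extraction.

The 3'UTR of a coding transcript is the region between the stop codon and
the transcript end: on the + strand the genomic interval
``(stop_end + 1 .. transcript_end)``, on the - strand
``(transcript_start .. stop_start - 1)`` reverse-complemented. Sequences
are always reported 5'->3' in the RNA alphabet (T folded to U). When a
gene has several transcript variants, one primary variant is selected
deterministically and only its UTR is scanned downstream.

All genomic coordinates are GFF3-style: 1-based, inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .motifs import as_rna

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

Span = tuple[int, int]


class AnnotationError(ValueError):
    """Malformed genome or annotation input."""


@dataclass
class TranscriptModel:
    """One annotated transcript: exons, CDS span(s), strand, gene link."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Span, ...] = ()
    cds: tuple[Span, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"{self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if self.end < self.start:
            raise AnnotationError(f"{self.transcript_id}: end < start")
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        self.cds = tuple(sorted(tuple(c) for c in self.cds))
        for s, e in (*self.exons, *self.cds):
            if e < s:
                raise AnnotationError(f"{self.transcript_id}: feature end < start")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"{self.transcript_id}: feature outside transcript span"
                )
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.exons and self.cds:
            for s, e in self.cds:
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS segment not contained in an exon"
                    )

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def cds_start(self) -> int:
        return self.cds[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds[-1][1]

    @property
    def stop_codon_span(self) -> Span:
        """Genomic span of the stop codon, derived from the CDS terminus.

        The CDS is assumed to include the stop codon (RefSeq convention).
        """
        if not self.is_coding:
            raise AnnotationError(f"{self.transcript_id}: non-coding transcript")
        if self.strand == "+":
            return (self.cds_end - 2, self.cds_end)
        return (self.cds_start, self.cds_start + 2)

    def utr_span(self) -> Span:
        """Contiguous genomic span of the 3'UTR (may be empty: end < start)."""
        if self.strand == "+":
            return (self.cds_end + 1, self.end)
        return (self.start, self.cds_start - 1)

    def utr_span_length(self) -> int:
        s, e = self.utr_span()
        return max(0, e - s + 1)


@dataclass
class UTRRecord:
    """A gene's primary-variant 3'UTR sequence with genomic provenance."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    span: Span  # contiguous genomic span; end < start denotes length 0
    sequence: str  # 5'->3', RNA alphabet
    spliced: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome_fasta(path) -> dict[str, str]:
    """Load a FASTA genome into a chrom -> uppercase-DNA mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise AnnotationError(f"duplicated chromosome name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise AnnotationError(
                f"chromosome {rec.id!r}: invalid characters {sorted(bad)}"
            )
        genome[rec.id] = seq
    if not genome:
        raise AnnotationError(f"no FASTA records found in {path}")
    return genome


def read_gff3(path) -> dict[str, list[TranscriptModel]]:
    """Parse a GFF3 file into transcript models grouped by gene.

    One model is built per mRNA feature; exon and CDS children are attached
    via Parent links. mRNAs without CDS are kept but flagged non-coding
    (``is_coding`` False) and later excluded from UTR extraction.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # sqlite/parse failures from gffutils
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc

    genes: dict[str, list[TranscriptModel]] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents:
            raise AnnotationError(f"mRNA {mrna.id} has no Parent gene")
        gene_id = parents[0]
        try:
            db[gene_id]
        except gffutils.FeatureNotFoundError:
            raise AnnotationError(
                f"mRNA {mrna.id}: dangling Parent {gene_id!r}"
            ) from None
        exons = tuple(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = tuple((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene_id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            start=mrna.start,
            end=mrna.end,
            exons=exons or ((mrna.start, mrna.end),),
            cds=cds,
        )
        if not model.is_coding:
            log.warning("transcript %s has no CDS; flagged non-coding", mrna.id)
        genes.setdefault(gene_id, []).append(model)
    if not genes:
        raise AnnotationError(f"no mRNA features found in {path}")
    for models in genes.values():
        models.sort(key=lambda m: m.transcript_id)
    return genes


def _accession_key(transcript_id: str) -> tuple[int, float]:
    tid = transcript_id
    if tid.startswith("NM_"):
        rank = 0
    elif tid.startswith("XM_"):
        rank = 1
    else:
        rank = 2
    digits = "".join(c for c in tid.split("_", 1)[-1] if c.isdigit())
    num = float(int(digits)) if digits else float("inf")
    return rank, num


def select_primary_transcript(models: Sequence[TranscriptModel]) -> TranscriptModel:
    """Deterministically pick the primary variant of a gene.

    Rule: curated accessions (``NM_``) beat predicted ones (``XM_``), then
    the lowest numeric accession component, then the longest 3'UTR, then the
    lexicographically smallest id.
    """
    coding = [m for m in models if m.is_coding]
    if not coding:
        raise AnnotationError("gene has no coding transcript")
    return min(
        coding,
        key=lambda m: (
            *_accession_key(m.transcript_id),
            -m.utr_span_length(),
            m.transcript_id,
        ),
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_three_prime_utr(
    model: TranscriptModel,
    genome: Mapping[str, str],
    mode: str = "span",
) -> UTRRecord:
    """Extract a transcript's 3'UTR sequence, 5'->3' in the RNA alphabet.

    ``span`` mode takes the contiguous genomic slice from the base after the
    stop codon to the transcript end (stop codon excluded). ``spliced`` mode
    additionally removes any intronic gap using the exon structure. A
    zero-length UTR is legal and yields an empty sequence.
    """
    if mode not in {"span", "spliced"}:
        raise ValueError(f"mode must be 'span' or 'spliced', got {mode!r}")
    if not model.is_coding:
        raise AnnotationError(f"{model.transcript_id}: non-coding transcript")
    if model.chrom not in genome:
        raise AnnotationError(
            f"{model.transcript_id}: chromosome {model.chrom!r} missing from genome"
        )
    chrom_seq = genome[model.chrom]
    s, e = model.utr_span()

    if mode == "span":
        pieces = [(s, e)] if e >= s else []
    else:
        pieces = []
        for es, ee in model.exons:
            lo, hi = max(es, s), min(ee, e)
            if hi >= lo:
                pieces.append((lo, hi))

    dna = "".join(chrom_seq[ps - 1 : pe] for ps, pe in pieces)
    if model.strand == "-":
        dna = _revcomp(dna)
    return UTRRecord(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=model.strand,
        span=(s, e),
        sequence=as_rna(dna),
        spliced=(mode == "spliced"),
    )


def extract_utrs(
    genome: Mapping[str, str],
    genes: Mapping[str, Sequence[TranscriptModel]],
    mode: str = "span",
) -> tuple[list[UTRRecord], pd.DataFrame]:
    """Primary-variant 3'UTRs for every gene, plus a skipped-genes report.

    Genes with no coding transcript are skipped and reported (mirrors real
    annotations where some genes' 3'UTR is not well annotated).
    """
    records: list[UTRRecord] = []
    skipped: list[dict] = []
    for gene_id in sorted(genes):
        try:
            primary = select_primary_transcript(genes[gene_id])
            records.append(extract_three_prime_utr(primary, genome, mode=mode))
        except AnnotationError as exc:
            skipped.append({"gene_id": gene_id, "reason": str(exc)})
            log.warning("gene %s skipped: %s", gene_id, exc)
    report = pd.DataFrame(skipped, columns=["gene_id", "reason"])
    return records, report


def write_utr_fasta(records: Iterable[UTRRecord], path) -> None:
    """Write UTR records as FASTA, header ``gene|transcript|chrom:s-e(strand)``."""
    with open(path, "w") as fh:
        for rec in records:
            s, e = rec.span
            fh.write(f">{rec.gene_id}|{rec.transcript_id}|{rec.chrom}:{s}-{e}({rec.strand})\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_utr_fasta(path) -> list[UTRRecord]:
    """Read back a UTR FASTA written by :func:`write_utr_fasta`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        gene_id, transcript_id, locus = header.split("|")
        coords, strand = locus[:-3], locus[-2]
        chrom, span = coords.rsplit(":", 1)
        s, e = (int(x) for x in span.split("-"))
        records.append(
            UTRRecord(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=chrom,
                strand=strand,
                span=(s, e),
                sequence=as_rna(str(rec.seq)),
            )
        )
    return records
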