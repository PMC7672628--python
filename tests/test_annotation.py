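"""Genome/GFF3 parsing, primary-variant selection and 3'UTR extraction."""

import pytest

from utrzga import (
    TranscriptModel,
    extract_three_prime_utr,
    extract_utrs,
    read_genome_fasta,
    read_gff3,
    read_utr_fasta,
    select_primary_transcript,
    write_utr_fasta,
)
from utrzga.annotation import AnnotationError


def test_read_genome_fasta_basics(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nacgt\n>chr2\nNNAC\n")
    genome = read_genome_fasta(p)
    assert genome == {"chr1": "ACGT", "chr2": "NNAC"}


def test_read_genome_fasta_rejects_duplicates_and_bad_letters(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nACGT\n>chr1\nACGT\n")
    with pytest.raises(AnnotationError, match="duplicated"):
        read_genome_fasta(p)
    p.write_text(">chr1\nACXT\n")
    with pytest.raises(AnnotationError, match="invalid"):
        read_genome_fasta(p)


TOY_GFF = """##gff-version 3
chr1\ttoy\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\ttoy\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1
chr1\ttoy\texon\t101\t140\t.\t+\t.\tID=t1.e1;Parent=t1
chr1\ttoy\texon\t151\t200\t.\t+\t.\tID=t1.e2;Parent=t1
chr1\ttoy\tCDS\t101\t140\t.\t+\t0\tID=t1.c;Parent=t1
chr1\ttoy\tCDS\t151\t170\t.\t+\t2\tID=t1.c;Parent=t1
chr1\ttoy\tgene\t301\t340\t.\t+\t.\tID=g2
chr1\ttoy\tmRNA\t301\t340\t.\t+\t.\tID=t2;Parent=g2
chr1\ttoy\texon\t301\t340\t.\t+\t.\tID=t2.e1;Parent=t2
"""


def test_read_gff3_builds_models_and_flags_noncoding(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF)
    genes = read_gff3(p)
    t1 = genes["g1"][0]
    assert t1.exons == ((101, 140), (151, 200))
    assert t1.cds == ((101, 140), (151, 170))
    assert t1.is_coding
    assert not genes["g2"][0].is_coding


def test_read_gff3_dangling_parent_errors(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\nchr1\ttoy\tmRNA\t1\t10\t.\t+\t.\tID=t1;Parent=nope\n"
    )
    with pytest.raises(AnnotationError, match="dangling|Parent"):
        read_gff3(p)


def _tx(tid, start, end, cds, strand="+", gene="g"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom="chr1", strand=strand,
        start=start, end=end, exons=((start, end),), cds=(cds,),
    )


class TestPrimarySelection:
    def test_curated_accession_then_lowest_number(self):
        models = [
            _tx("XM_000002.1", 1, 100, (1, 30)),
            _tx("NM_000010.1", 1, 100, (1, 30)),
            _tx("NM_000002.1", 1, 100, (1, 30)),
        ]
        assert select_primary_transcript(models).transcript_id == "NM_000002.1"

    def test_single_variant_is_itself(self):
        m = _tx("NM_1.1", 1, 50, (1, 30))
        assert select_primary_transcript([m]) is m

    def test_longer_utr_breaks_ties(self):
        # same prefix class, no numeric component -> UTR length decides
        a = _tx("TX_A", 1, 70, (1, 30))  # UTR length 40
        b = _tx("TX_B", 1, 110, (1, 30))  # UTR length 80
        assert select_primary_transcript([a, b]).transcript_id == "TX_B"

    def test_no_coding_transcript_errors(self):
        m = TranscriptModel("t", "g", "chr1", "+", 1, 50, exons=((1, 50),))
        with pytest.raises(AnnotationError, match="no coding"):
            select_primary_transcript([m])


class TestUTRExtraction:
    def _genome(self):
        import numpy as np

        rng = np.random.default_rng(0)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=300))}

    def test_plus_strand_span(self):
        genome = self._genome()
        m = _tx("NM_1", 101, 200, (101, 160), strand="+")
        rec = extract_three_prime_utr(m, genome)
        assert rec.span == (161, 200)
        assert len(rec.sequence) == 40
        expected = genome["chr1"][160:200].replace("T", "U")
        assert rec.sequence == expected

    def test_minus_strand_is_reverse_complement(self):
        genome = self._genome()
        m = _tx("NM_1", 101, 200, (141, 200), strand="-")
        rec = extract_three_prime_utr(m, genome)
        assert rec.span == (101, 140)
        comp = {"A": "U", "C": "G", "G": "C", "T": "A"}
        manual = "".join(comp[c] for c in reversed(genome["chr1"][100:140]))
        assert rec.sequence == manual

    def test_zero_length_utr(self):
        genome = self._genome()
        m = _tx("NM_1", 101, 160, (101, 160), strand="+")
        rec = extract_three_prime_utr(m, genome)
        assert rec.sequence == ""

    def test_spliced_mode_removes_intron(self):
        genome = self._genome()
        m = TranscriptModel(
            "NM_1", "g", "chr1", "+", 101, 200,
            exons=((101, 170), (181, 200)), cds=((101, 160),),
        )
        span = extract_three_prime_utr(m, genome, mode="span")
        spl = extract_three_prime_utr(m, genome, mode="spliced")
        assert len(span.sequence) == 40
        assert len(spl.sequence) == 30  # 10-base intron removed
        assert spl.sequence == span.sequence[:10] + span.sequence[20:]

    def test_spliced_equals_span_without_utr_intron(self):
        genome = self._genome()
        m = _tx("NM_1", 101, 200, (101, 160))
        assert (
            extract_three_prime_utr(m, genome, mode="spliced").sequence
            == extract_three_prime_utr(m, genome, mode="span").sequence
        )

    def test_missing_chromosome_errors(self):
        m = _tx("NM_1", 101, 200, (101, 160))
        with pytest.raises(AnnotationError, match="missing"):
            extract_three_prime_utr(m, {"chr9": "ACGT"})


def _flip_bundle(genome, transcripts):
    """Reverse-complement every chromosome and mirror all features."""
    from utrzga.simulate import _revcomp

    lengths = {c: len(s) for c, s in genome.items()}
    flipped_genome = {c: _revcomp(s) for c, s in genome.items()}

    def flip_span(span, L):
        s, e = span
        return (L - e + 1, L - s + 1)

    flipped = {}
    for gid, models in transcripts.items():
        out = []
        for m in models:
            L = lengths[m.chrom]
            out.append(
                TranscriptModel(
                    transcript_id=m.transcript_id,
                    gene_id=m.gene_id,
                    chrom=m.chrom,
                    strand="-" if m.strand == "+" else "+",
                    start=L - m.end + 1,
                    end=L - m.start + 1,
                    exons=tuple(flip_span(x, L) for x in m.exons),
                    cds=tuple(flip_span(x, L) for x in m.cds),
                )
            )
        flipped[gid] = out
    return flipped_genome, flipped


def test_strand_symmetry_on_synthetic_bundle(bundle):
    """Reverse-complementing the genome and flipping every annotation must
    reproduce the exact same 5'->3' UTR sequence for every gene."""
    utrs, _ = extract_utrs(bundle.genome, bundle.transcripts)
    fg, ft = _flip_bundle(bundle.genome, bundle.transcripts)
    flipped_utrs, _ = extract_utrs(fg, ft)
    a = {r.gene_id: r.sequence for r in utrs}
    b = {r.gene_id: r.sequence for r in flipped_utrs}
    assert a == b


def test_utr_fasta_round_trip(tmp_path, bundle):
    utrs, _ = extract_utrs(bundle.genome, bundle.transcripts)
    path = tmp_path / "utr.fa"
    write_utr_fasta(utrs, path)
    back = read_utr_fasta(path)
    assert [r.gene_id for r in back] == [r.gene_id for r in utrs]
    assert all(x.sequence == y.sequence for x, y in zip(back, utrs))
    assert all(x.span == y.span and x.strand == y.strand for x, y in zip(back, utrs))


def test_extract_utrs_reports_skipped_noncoding(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF)
    genes = read_gff3(p)
    genome = {"chr1": "A" * 400}
    records, skipped = extract_utrs(genome, genes)
    assert [r.gene_id for r in records] == ["g1"]
    assert list(skipped["gene_id"]) == ["g2"]
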