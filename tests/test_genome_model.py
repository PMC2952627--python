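"""Coordinate handling, format readers and 5' UTR intron discovery."""

import warnings

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from stepminer.genome_model import (
    INDEL,
    SNP,
    TranscriptModel,
    find_5utr_introns,
    read_annotation,
    read_frequencies,
    read_gwas,
    read_ld,
    read_variants,
    write_annotation,
)

from conftest import genome_for, random_seq, random_transcript


def _write_fasta(path, chrom, seq):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n{seq}\n")


def _toy_gff(path, fmt="gff3", strand="+"):
    """2-exon gene: exon1 [10,50), intron [50,120), exon2 [120,180),
    CDS from 140 (plus strand numbers; 1-based in the file)."""
    rows_gff3 = [
        "chr1\ttest\tgene\t11\t180\t.\t{s}\t.\tID=g1;gene_id=g1",
        "chr1\ttest\tmRNA\t11\t180\t.\t{s}\t.\tID=t1;Parent=g1;gene_id=g1;transcript_id=t1",
        "chr1\ttest\texon\t11\t50\t.\t{s}\t.\tParent=t1;gene_id=g1;transcript_id=t1",
        "chr1\ttest\texon\t121\t180\t.\t{s}\t.\tParent=t1;gene_id=g1;transcript_id=t1",
        "chr1\ttest\tCDS\t141\t180\t.\t{s}\t0\tParent=t1;gene_id=g1;transcript_id=t1",
    ]
    rows_gtf = [
        'chr1\ttest\texon\t11\t50\t.\t{s}\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\ttest\texon\t121\t180\t.\t{s}\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\ttest\tCDS\t141\t180\t.\t{s}\t0\tgene_id "g1"; transcript_id "t1";',
    ]
    rows = rows_gff3 if fmt == "gff3" else rows_gtf
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
        for r in rows:
            fh.write(r.format(s=strand) + "\n")


def test_two_exon_plus_strand_gene(tmp_path, rng):
    seq = random_seq(rng, 200)
    _write_fasta(tmp_path / "g.fa", "chr1", seq)
    _toy_gff(tmp_path / "a.gff3")
    transcripts, genome = read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")
    assert len(transcripts) == 1
    t = transcripts[0]
    assert t.exons == [(10, 50), (120, 180)]
    assert t.cds_start == 140
    introns = t.introns(genome)
    assert len(introns) == 1
    assert (introns[0].start, introns[0].end) == (50, 120)
    assert introns[0].sequence == seq[50:120].upper()
    assert introns[0].is_5utr  # intron ends before the translation start


def test_minus_strand_gives_same_transcript_orientation_sequences(tmp_path, rng):
    """The same gene encoded on the minus strand (genome mirrored) must
    yield identical transcript-orientation exon and intron sequences."""
    seq = random_seq(rng, 200)
    _write_fasta(tmp_path / "p.fa", "chr1", seq)
    _toy_gff(tmp_path / "p.gff3", strand="+")
    (t_plus,), g_plus = read_annotation(tmp_path / "p.gff3", tmp_path / "p.fa")

    _write_fasta(tmp_path / "m.fa", "chr1", reverse_complement(seq))
    # mirrored coordinates: genomic [s,e) -> [200-e, 200-s), 1-based in file
    with open(tmp_path / "m.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for s, e, ftype in [(10, 50, "exon"), (120, 180, "exon"), (140, 180, "CDS")]:
            ms, me = 200 - e, 200 - s
            fh.write(
                f"chr1\ttest\t{ftype}\t{ms + 1}\t{me}\t.\t-\t.\t"
                "Parent=t1;gene_id=g1;transcript_id=t1\n"
            )
    (t_minus,), g_minus = read_annotation(tmp_path / "m.gff3", tmp_path / "m.fa")
    for i in range(2):
        assert t_plus.exon_sequence(g_plus, i) == t_minus.exon_sequence(g_minus, i)
    assert [x.sequence for x in t_plus.introns(g_plus)] == [
        x.sequence for x in t_minus.introns(g_minus)
    ]
    assert [x.is_5utr for x in t_minus.introns(g_minus)] == [True]


def test_gtf_dialect_reads_same_model_as_gff3(tmp_path, rng):
    seq = random_seq(rng, 200)
    _write_fasta(tmp_path / "g.fa", "chr1", seq)
    _toy_gff(tmp_path / "a.gff3", fmt="gff3")
    _toy_gff(tmp_path / "a.gtf", fmt="gtf")
    (t_gff,), _ = read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")
    (t_gtf,), _ = read_annotation(tmp_path / "a.gtf", tmp_path / "g.fa")
    assert t_gff.exons == t_gtf.exons
    assert t_gff.cds_start == t_gtf.cds_start
    assert t_gff.strand == t_gtf.strand
    assert t_gff.gene_id == t_gtf.gene_id


def test_annotation_round_trip_preserves_coordinates(tmp_path, rng):
    transcripts = [random_transcript(rng) for _ in range(20)]
    genome = genome_for(transcripts, rng)
    _write_fasta(tmp_path / "g.fa", "chr1", genome["chr1"])
    write_annotation(transcripts, tmp_path / "rt.gff3")
    back, _ = read_annotation(tmp_path / "rt.gff3", tmp_path / "g.fa")
    by_id = {t.transcript_id: t for t in back}
    assert len(by_id) == len(transcripts)
    for t in transcripts:
        r = by_id[t.transcript_id]
        assert r.exons == t.exons
        assert r.cds_start == t.cds_start
        assert r.strand == t.strand


def test_exon_outside_chromosome_is_hard_error(tmp_path):
    _write_fasta(tmp_path / "g.fa", "chr1", "ACGT" * 10)
    _toy_gff(tmp_path / "a.gff3")
    with pytest.raises(ValueError, match="t1"):
        read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")


def test_exons_and_introns_tile_the_transcript_span(rng):
    for _ in range(200):
        t = random_transcript(rng)
        genome = genome_for([t], rng)
        covered = set()
        for s, e in t.genomic_exons:
            covered |= set(range(s, e))
        for i in t.introns(genome):
            assert not covered & set(range(i.start, i.end))
            covered |= set(range(i.start, i.end))
        s, e = t.span
        assert covered == set(range(s, e))


class TestFind5utrIntrons:
    def _transcript(self, exons, cds_start, strand="+"):
        return TranscriptModel(
            transcript_id="t", gene_id="g", chrom="chr1", strand=strand,
            exons=exons, cds_start=cds_start,
        )

    def test_noncoding_first_exon_intron_is_5utr(self, rng):
        # non-coding exon 1, intron 1, CDS begins in exon 2
        t = self._transcript([(0, 40), (100, 200)], cds_start=130)
        genome = genome_for([t], rng)
        found = find_5utr_introns(t, genome)
        assert [(i.index, i.start, i.end) for i in found] == [(1, 40, 100)]

    def test_cds_in_first_exon_gives_none(self, rng):
        t = self._transcript([(0, 40), (100, 200)], cds_start=20)
        assert find_5utr_introns(t, genome_for([t], rng)) == []

    def test_cds_in_third_exon_gives_first_two_introns(self, rng):
        t = self._transcript([(0, 40), (100, 150), (200, 300)], cds_start=250)
        found = find_5utr_introns(t, genome_for([t], rng))
        assert [i.index for i in found] == [1, 2]

    def test_noncoding_transcript_gives_empty_list(self, rng):
        t = self._transcript([(0, 40), (100, 200)], cds_start=None)
        assert find_5utr_introns(t, genome_for([t], rng)) == []

    def test_agrees_with_per_base_brute_force(self):
        """On 1,000 random transcripts, an intron is 5' UTR iff every
        one of its bases is strictly 5' of cds_start in transcript
        orientation."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            t = random_transcript(rng)
            genome = genome_for([t], rng)
            flagged = {i.index for i in find_5utr_introns(t, genome)}
            expected = set()
            for i in t.introns(genome):
                bases = range(i.start, i.end)
                if t.strand == "+":
                    ok = all(g < t.cds_start for g in bases)
                else:
                    ok = all(g > t.cds_start for g in bases)
                if ok:
                    expected.add(i.index)
            assert flagged == expected


class TestVariantReaders:
    def _vcf(self, path, rows):
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=chr1,length=1000>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in rows:
                fh.write(r + "\n")

    def test_classes_and_triallelic(self, tmp_path):
        self._vcf(
            tmp_path / "v.vcf",
            [
                "chr1\t10\trs1\tA\tT\t.\t.\t.",
                "chr1\t20\trs2\tAT\tA\t.\t.\t.",
                "chr1\t30\trs3\tA\tG,T\t.\t.\t.",
            ],
        )
        v1, v2, v3 = read_variants(tmp_path / "v.vcf")
        assert v1.vclass == SNP and not v1.tri_allelic
        assert v1.pos == 9  # converted to 0-based
        assert v2.vclass == INDEL
        assert v3.vclass == SNP and v3.tri_allelic and v3.alts == ["G", "T"]

    def test_frequency_table_validation(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("snp_id\tpopulation\tminor_allele\tmaf\tn\nrs1\tCEU\tA\t0.3\t120\n")
        df = read_frequencies(p)
        assert df.iloc[0]["maf"] == 0.3
        p.write_text("snp_id\tpopulation\tminor_allele\tmaf\tn\nrs1\tCEU\tA\t0.7\t120\n")
        with pytest.raises(ValueError, match="line 2"):
            read_frequencies(p)
        p.write_text("snp_id\tpopulation\tminor_allele\tmaf\tn\nrs1\tXXX\tA\t0.3\t120\n")
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            df = read_frequencies(p)
        assert any("unknown population" in str(x.message) for x in w)
        assert len(df) == 1  # row kept

    def test_ld_and_gwas_tables(self, tmp_path):
        ld = tmp_path / "ld.tsv"
        ld.write_text("snp_a\tsnp_b\tr2\tdprime\nrs1\trs2\t0.5\t1.0\n")
        assert read_ld(ld).iloc[0]["r2"] == 0.5
        ld.write_text("snp_a\tsnp_b\tr2\tdprime\nrs1\trs2\t1.5\t1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_ld(ld)
        gw = tmp_path / "g.tsv"
        gw.write_text("snp_id\tdisease\tpvalue\nrs1\tdiabetes\t0.001\n")
        assert read_gwas(gw).iloc[0]["pvalue"] == 0.001
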