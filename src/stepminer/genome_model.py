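"""Genomic data model, file readers/writers and 5' UTR intron discovery.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` on the
genomic forward strand.  GFF3/GTF and VCF input (1-based, inclusive) is
converted on read and back on write.  Exons of a transcript are kept in
transcript orientation (5'->3' along the mRNA), so for minus-strand
transcripts the exon list runs from high to low genomic coordinates.

A 5' UTR intron is an intron lying entirely upstream of the translation
start (``cds_start``) in transcript orientation -- the kind of intron that,
when retained, lengthens the mRNA leader without touching the protein.
Non-coding transcripts have no ``cds_start`` and therefore contribute no
5' UTR introns (they still serve as splicing-pattern evidence downstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

#: HapMap-style population labels recognised without a warning.
KNOWN_POPULATIONS = frozenset({"CEU", "CHB", "YRI", "JPT"})

SNP = "SNP"
INDEL = "INDEL"
OTHER = "other"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain with an optional CDS start.

    ``exons`` are genomic ``[start, end)`` intervals ordered 5'->3' in
    transcript orientation.  ``cds_start`` is the genomic 0-based position
    of the first base of the start codon, ``None`` for non-coding
    transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        genomic = self.genomic_exons
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            if s2 == e1:
                raise ValueError(f"{self.transcript_id}: zero-length intron")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not ordered 5'->3' in "
                "transcript orientation"
            )

    @property
    def genomic_exons(self) -> list[tuple[int, int]]:
        """Exons sorted by ascending genomic coordinate."""
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        g = self.genomic_exons
        return g[0][0], g[-1][1]

    def genomic_introns(self) -> list[tuple[int, int]]:
        """Intron ``[start, end)`` intervals, ordered 5'->3' like exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    def introns(self, genome) -> list["Intron"]:
        """All introns with transcript-orientation sequences and UTR flags."""
        out = []
        for i, (s, e) in enumerate(self.genomic_introns(), start=1):
            seq = fetch(genome, self.chrom, s, e)
            if self.strand == "-":
                seq = reverse_complement(seq)
            out.append(
                Intron(
                    transcript_id=self.transcript_id,
                    index=i,
                    chrom=self.chrom,
                    strand=self.strand,
                    start=s,
                    end=e,
                    sequence=seq,
                    is_5utr=self._is_5utr_span(s, e),
                )
            )
        return out

    def _is_5utr_span(self, start: int, end: int) -> bool:
        if self.cds_start is None:
            return False
        if self.strand == "+":
            return end <= self.cds_start
        return start > self.cds_start

    def exon_sequence(self, genome, index: int) -> str:
        """Transcript-orientation sequence of exon ``index`` (0-based)."""
        s, e = self.exons[index]
        seq = fetch(genome, self.chrom, s, e)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class Intron:
    transcript_id: str
    index: int  # 1-based ordinal along the transcript
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    is_5utr: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.transcript_id} intron {self.index}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Variant:
    """A SNP/INDEL with one or more alternate alleles (genomic strand)."""

    variant_id: str
    chrom: str
    pos: int  # 0-based position of the first reference base
    ref: str
    alts: list[str]
    vclass: str = field(default="")
    maf_by_population: dict[str, tuple[float, int]] = field(default_factory=dict)
    minor_allele: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vclass:
            self.vclass = classify_alleles(self.ref, self.alts)
        for pop, (maf, _n) in self.maf_by_population.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(
                    f"{self.variant_id}: population MAF {maf} outside [0, 0.5]"
                )

    @property
    def tri_allelic(self) -> bool:
        return len(self.alts) >= 2

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref)


def classify_alleles(ref: str, alts: list[str]) -> str:
    """SNP when every allele is a single base, INDEL when every ref/alt
    pair changes length, otherwise 'other' (MNPs, mixed records)."""
    if not alts:
        return OTHER
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return SNP
    if all(len(a) != len(ref) for a in alts):
        return INDEL
    return OTHER


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Forward-strand sequence, uppercase.  ``genome`` may be a pyfaidx
    ``Fasta`` or any mapping of chromosome name to string."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    return str(genome[chrom][start:end]).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _feature_transcript_id(feat, db) -> str | None:
    if "transcript_id" in feat.attributes:
        return feat.attributes["transcript_id"][0]
    if "Parent" in feat.attributes:
        return feat.attributes["Parent"][0]
    return None


def _feature_gene_id(feat, db, tid: str) -> str:
    if "gene_id" in feat.attributes:
        return feat.attributes["gene_id"][0]
    try:
        parent = db[tid]
    except gffutils.FeatureNotFoundError:
        return tid
    if "gene_id" in parent.attributes:
        return parent.attributes["gene_id"][0]
    if "Parent" in parent.attributes:
        return parent.attributes["Parent"][0]
    return tid


def read_annotation(gff_path, fasta_path_or_genome) -> tuple[list[TranscriptModel], object]:
    """Read GFF3 or GTF plus genome FASTA into transcript models.

    Both dialects are accepted; exon/CDS rows are grouped by
    ``transcript_id`` (GTF) or ``Parent`` (GFF3).  Returns
    ``(transcripts, genome)`` so callers can fetch sequences later.
    """
    genome = _open_genome(fasta_path_or_genome)
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = _feature_transcript_id(feat, db)
        if tid is None:
            logger.warning("feature without transcript attribution skipped: %s", feat)
            continue
        gid = _feature_gene_id(feat, db, tid)
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts = []
    for tid, (gid, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        if chrom in genome:
            clen = chrom_length(genome, chrom)
            for s, e in ex:
                if s < 0 or e > clen:
                    raise ValueError(
                        f"exon [{s},{e}) of transcript {tid} outside "
                        f"chromosome {chrom} bounds [0,{clen})"
                    )
        cds_start = None
        if tid in cds:
            if strand == "+":
                cds_start = min(s for s, _ in cds[tid])
            else:
                cds_start = max(e for _, e in cds[tid]) - 1
        ordered = ex if strand == "+" else ex[::-1]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ordered,
                cds_start=cds_start,
            )
        )
    return transcripts, genome


def _open_genome(fasta_path_or_genome):
    if isinstance(fasta_path_or_genome, (str,)) or hasattr(fasta_path_or_genome, "__fspath__"):
        import pyfaidx

        return pyfaidx.Fasta(str(fasta_path_or_genome), sequence_always_upper=True)
    return fasta_path_or_genome


def write_annotation(transcripts: list[TranscriptModel], path) -> None:
    """Write transcripts as GFF3 (gene / mRNA / exon / CDS rows).

    ``cds_start`` is encoded as a CDS row anchored in its exon so that a
    read/write round trip preserves every coordinate exactly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            genes.setdefault(t.gene_id, []).append(t)
        for gid, ts in genes.items():
            start = min(t.span[0] for t in ts)
            end = max(t.span[1] for t in ts)
            t0 = ts[0]
            fh.write(
                f"{t0.chrom}\tstepminer\tgene\t{start + 1}\t{end}\t.\t{t0.strand}\t.\t"
                f"ID={gid};gene_id={gid}\n"
            )
            for t in ts:
                s, e = t.span
                fh.write(
                    f"{t.chrom}\tstepminer\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gid};gene_id={gid};"
                    f"transcript_id={t.transcript_id}\n"
                )
                for es, ee in t.genomic_exons:
                    fh.write(
                        f"{t.chrom}\tstepminer\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id};gene_id={t.gene_id};"
                        f"transcript_id={t.transcript_id}\n"
                    )
                if t.cds_start is not None:
                    cs, ce = _cds_row_span(t)
                    fh.write(
                        f"{t.chrom}\tstepminer\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t0\t"
                        f"Parent={t.transcript_id};gene_id={t.gene_id};"
                        f"transcript_id={t.transcript_id}\n"
                    )


def _cds_row_span(t: TranscriptModel) -> tuple[int, int]:
    for s, e in t.genomic_exons:
        if s <= t.cds_start < e:
            if t.strand == "+":
                return t.cds_start, e
            return s, t.cds_start + 1
    raise ValueError(f"{t.transcript_id}: cds_start {t.cds_start} not inside any exon")


# ---------------------------------------------------------------------------
# 5' UTR introns
# ---------------------------------------------------------------------------

def find_5utr_introns(transcript: TranscriptModel, genome) -> list[Intron]:
    """Introns lying entirely upstream of the translation start.

    Non-coding transcripts (no ``cds_start``) yield an empty list.  An
    intron containing ``cds_start`` is not a 5' UTR intron.
    """
    if transcript.cds_start is None:
        return []
    return [i for i in transcript.introns(genome) if i.is_5utr]


# ---------------------------------------------------------------------------
# variant and table readers
# ---------------------------------------------------------------------------

def read_variants(vcf_path) -> list[Variant]:
    """Read a VCF (plain text or bgzipped) into :class:`Variant` records.

    Positions become 0-based; tri-allelic records stay one variant with
    multiple alts; class is assigned from allele lengths.
    """
    out = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            alts = [a for a in (rec.alts or ()) if a is not None]
            vid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
            out.append(
                Variant(
                    variant_id=vid,
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref.upper(),
                    alts=[a.upper() for a in alts],
                )
            )
    return out


def _read_table(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table {path}: missing columns {missing}")
    return df


def read_frequencies(path) -> pd.DataFrame:
    """HapMap-style allele frequency table: snp_id, population,
    minor_allele, maf, n."""
    df = _read_table(path, ["snp_id", "population", "minor_allele", "maf", "n"],
                     "frequency")
    for i, row in df.iterrows():
        try:
            maf = float(row["maf"])
            n = int(row["n"])
        except ValueError as exc:
            raise ValueError(f"frequency table line {i + 2}: {exc}") from exc
        if not 0.0 <= maf <= 0.5:
            raise ValueError(f"frequency table line {i + 2}: maf {maf} outside [0,0.5]")
        if n < 0:
            raise ValueError(f"frequency table line {i + 2}: negative sample count")
        if row["population"] not in KNOWN_POPULATIONS:
            warnings.warn(
                f"frequency table line {i + 2}: unknown population "
                f"{row['population']!r} (row kept)"
            )
    df["maf"] = df["maf"].astype(float)
    df["n"] = df["n"].astype(int)
    return df


def read_ld(path) -> pd.DataFrame:
    """Pairwise LD table: snp_a, snp_b, r2, dprime."""
    df = _read_table(path, ["snp_a", "snp_b", "r2", "dprime"], "LD")
    for i, row in df.iterrows():
        try:
            r2 = float(row["r2"])
            float(row["dprime"])
        except ValueError as exc:
            raise ValueError(f"LD table line {i + 2}: {exc}") from exc
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"LD table line {i + 2}: r2 {r2} outside [0,1]")
    df["r2"] = df["r2"].astype(float)
    df["dprime"] = df["dprime"].astype(float)
    return df


def read_gwas(path) -> pd.DataFrame:
    """GWAS association table: snp_id, disease, pvalue."""
    df = _read_table(path, ["snp_id", "disease", "pvalue"], "GWAS")
    for i, row in df.iterrows():
        try:
            float(row["pvalue"])
        except ValueError as exc:
            raise ValueError(f"GWAS table line {i + 2}: {exc}") from exc
    df["pvalue"] = df["pvalue"].astype(float)
    return df


def attach_frequencies(variants: list[Variant], freq: pd.DataFrame) -> None:
    """Populate each variant's per-population MAF map in place."""
    by_id: dict[str, list] = {}
    for _, row in freq.iterrows():
        by_id.setdefault(row["snp_id"], []).append(row)
    for v in variants:
        for row in by_id.get(v.variant_id, []):
            v.maf_by_population[row["population"]] = (float(row["maf"]), int(row["n"]))
            v.minor_allele[row["population"]] = row["minor_allele"]
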