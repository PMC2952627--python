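"""Seeded synthetic datasets with known ground truth.

The generator emits a complete, parseable input bundle -- genome FASTA,
GFF3 annotation, VCF, HapMap-style frequency table, LD and GWAS tables,
EST FASTA, an external-predictor adapter table, a synthetic PWM set and
an ESE hexamer list -- together with a manifest recording every planted
candidate and its expected motif region, allelic score difference,
splicing-pattern labels and EST evidence.  Identical config + seed give
byte-identical outputs.

Each synthetic gene has a non-coding first exon, a 5' UTR intron
carrying consensus motifs (GTAAGT donor, a single planted CTGAC
branch-point match, a 12-base pyrimidine tract, CAG acceptor), a second
exon holding the translation start, and one coding intron as a negative
control.  Background composition follows genome-average base usage
(A/T 0.2 each, C/G 0.3 each).  Alternative isoforms plant the three
splicing-pattern evidence classes; EST reads are drawn either with
exact planted counts (noiseless oracles) or with allele-dependent
retention probabilities (stochastic tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mining
from . import motif_annotation as ma
from . import scoring as sc
from .genome_model import TranscriptModel, write_annotation

BACKGROUND_P = {"A": 0.2, "C": 0.3, "G": 0.3, "T": 0.2}
_BASES = np.array(["A", "C", "G", "T"])
_P = np.array([BACKGROUND_P[b] for b in _BASES])

EXON1_LEN = 80
EXON2_LEN = 150
EXON3_LEN = 120
INTRON2_LEN = 90
CDS_OFFSET_IN_EXON2 = 30
GENE_PAD = 50
MIN_INTRON = 50

BRANCH_A_OFFSET = -26  # planted CTGAC occupies -29..-25, A at -26

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ConfigError(ValueError):
    """Infeasible simulation spec."""


@dataclass
class GwasSpec:
    partner_id: str
    r2: float
    disease: str
    pvalue: float


@dataclass
class EstSpec:
    """EST planting.  ``counts`` mode plants exact read numbers
    (major-allele retained, minor-allele retained, spliced); ``probs``
    mode draws ``n_reads`` reads with per-allele retention
    probabilities."""

    mode: str = "counts"  # counts | probs
    major_retained: int = 0
    minor_retained: int = 0
    spliced: int = 0
    n_reads: int = 0
    retention_major: float = 0.0
    retention_minor: float = 0.0
    mismatch_rate: float = 0.0


@dataclass
class VariantPlant:
    """A variant planted in one motif region of the 5' UTR intron.

    ``label`` is the signed motif position: +1..+6 (donor), -3..-1
    (acceptor), -15..-4 (PPT), or -3..+1 relative to the branch
    adenosine.  ``alt`` is a transcript-orientation base (SNP) or None
    for an automatic transition; ``vclass`` is SNP or DEL1 (single-base
    deletion of the labelled base)."""

    region: str
    label: int
    alt: str | None = None
    vclass: str = "SNP"
    maf: float | None = None
    population: str = "CEU"
    predicted_support: int = 2
    gwas: list[GwasSpec] = field(default_factory=list)
    est: EstSpec | None = None


@dataclass
class GeneSpec:
    name: str
    strand: str = "+"
    intron_length: int = 120
    isoforms: tuple[str, ...] = ()  # subset of retention/alt_splice/downstream
    motif_conformity: float = 1.0
    variant: VariantPlant | None = None


@dataclass
class SimulationConfig:
    seed: int
    genes: list[GeneSpec]
    population: str = "CEU"
    chrom: str = "chr1"


# ---------------------------------------------------------------------------
# synthetic PWM set
# ---------------------------------------------------------------------------

def _col(preferred: str, p_pref: float, p_other: float) -> dict[str, float]:
    return {b: (p_pref if b == preferred else p_other) for b in sc.BASES}


def synthetic_pwm_set() -> sc.PwmSet:
    """A complete non-consensus PWM set: obligate GT/AG dinucleotides,
    preference columns elsewhere, with GC-rich/GC-poor flavours
    differing mildly in the non-obligate entries.  Synthetic stand-in
    for published splice-site matrices; values are generator choices,
    not transcriptions."""
    pwms = []
    for gc_class, d in ((sc.GC_RICH, 0.0), (sc.GC_POOR, 0.05)):
        five = {
            1: sc.obligate_column("G"),
            2: sc.obligate_column("T"),
            3: _col("A", 0.25 + d, 0.85),
            4: _col("A", 0.30 + d, 0.80),
            5: _col("G", 0.20 + d, 0.85),
            6: _col("T", 0.40 + d, 0.75),
        }
        pwms.append(sc.Pwm(sc.KIND_FIVE, gc_class, five))
        three = {-1: sc.obligate_column("G"), -2: sc.obligate_column("A"),
                 -3: _col("C", 0.30 + d, 0.80)}
        for pos in range(-15, -3):
            three[pos] = {"A": 0.85, "C": 0.50 + d, "G": 0.95, "T": 0.55 + d}
        pwms.append(sc.Pwm(sc.KIND_THREE, gc_class, three))
    branch = {
        -3: {"A": 0.95, "C": 0.50, "G": 0.95, "T": 0.60},
        -2: _col("T", 0.05, 0.95),
        -1: sc.background_column(),
        0: _col("A", 0.05, 0.95),
        1: {"A": 0.95, "C": 0.55, "G": 0.95, "T": 0.50},
    }
    pwms.append(sc.Pwm(sc.KIND_BRANCH, sc.GC_ANY, branch))
    return sc.PwmSet(pwms)


DEFAULT_ESE_HEXAMERS = [
    "GAAGAA", "CAGAAG", "GAAGGA", "AAGAAG", "TGAAGA", "GGAAGA",
    "ACGAAG", "GAAGAT",
]


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_P))


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def _build_intron(rng: np.random.Generator, length: int, conforming: bool) -> str:
    """Transcript-orientation 5' UTR intron with planted motifs.  The
    branch window (-34..-21) is filled from {C,G} outside the planted
    CTGAC so exactly one YTNAY match exists."""
    if length < MIN_INTRON:
        raise ConfigError(f"intron length {length} < minimum {MIN_INTRON}")
    seq = list(_random_seq(rng, length))
    donor = "GTAAGT" if conforming else "CAAAGT"
    seq[0:6] = donor
    # branch window: no stray T/A so no stray YTNAY
    for off in range(-34, -20):
        seq[length + off] = "C" if rng.random() < 0.5 else "G"
    for i, b in enumerate("CTGAC"):
        seq[length - 29 + i] = b
    seq[length - 15: length - 3] = "TCTTTCCTTTCT"
    seq[length - 3:] = "CAG" if conforming else "CAA"
    return "".join(seq)


@dataclass
class _Locus:
    """Transcript-orientation building blocks of one synthetic gene."""

    spec: GeneSpec
    exon1: str
    intron1: str
    exon2: str
    intron2: str
    exon3: str

    @property
    def gene_seq(self) -> str:
        return self.exon1 + self.intron1 + self.exon2 + self.intron2 + self.exon3

    def local_intervals(self) -> dict[str, tuple[int, int]]:
        p = 0
        out = {}
        for name, s in (("exon1", self.exon1), ("intron1", self.intron1),
                        ("exon2", self.exon2), ("intron2", self.intron2),
                        ("exon3", self.exon3)):
            out[name] = (p, p + len(s))
            p += len(s)
        return out


def _variant_intron_index(plant: VariantPlant, intron_len: int) -> int:
    region, label = plant.region, plant.label
    if region == ma.FIVE_SS:
        if not 1 <= label <= 6:
            raise ConfigError(f"donor label {label} outside +1..+6")
        return label - 1
    if region == ma.THREE_SS:
        if not -3 <= label <= -1:
            raise ConfigError(f"acceptor label {label} outside -3..-1")
        return intron_len + label
    if region == ma.PPT:
        if not -15 <= label <= -4:
            raise ConfigError(f"PPT label {label} outside -15..-4")
        return intron_len + label
    if region == ma.BRANCH_POINT:
        if not -3 <= label <= 1:
            raise ConfigError(f"branch label {label} outside -3..+1")
        return intron_len + BRANCH_A_OFFSET + label
    raise ConfigError(f"unknown region {region!r}")


def _expected_snp_difference(pwm_set: sc.PwmSet, region: str, label: int,
                             gc: float, ref_t: str, alt_t: str) -> float:
    """Manifest expectation by direct table lookup (independent of the
    mining path)."""
    if region == ma.FIVE_SS:
        pwm = pwm_set.select(sc.KIND_FIVE, gc)
    elif region in (ma.THREE_SS, ma.PPT):
        pwm = pwm_set.select(sc.KIND_THREE, gc)
    else:
        pwm = pwm_set.select(sc.KIND_BRANCH, gc)
    return abs(pwm.table[label][alt_t] - pwm.table[label][ref_t])


def _expected_del_difference(pwm_set: sc.PwmSet, region: str, gc: float,
                             intron_ref: str, intron_alt: str) -> float:
    """Per-position sum over the motif frame re-read under each allele."""
    if region == ma.FIVE_SS:
        pwm = pwm_set.select(sc.KIND_FIVE, gc)
        return sum(
            abs(pwm.table[p][intron_alt[p - 1]] - pwm.table[p][intron_ref[p - 1]])
            for p in range(1, 7)
        )
    pwm = pwm_set.select(sc.KIND_THREE, gc)
    return sum(
        abs(pwm.table[p][intron_alt[len(intron_alt) + p]]
            - pwm.table[p][intron_ref[len(intron_ref) + p]])
        for p in range(-15, 0)
    )


# ---------------------------------------------------------------------------
# EST reads
# ---------------------------------------------------------------------------

def simulate_est_reads(
    exon1: str,
    intron_by_allele: dict[str, str],
    exon2: str,
    minor_allele: str,
    maf: float,
    retention_probs: dict[str, float],
    n: int,
    rng: np.random.Generator,
    mismatch_rate: float = 0.0,
    read_prefix: str = "est",
) -> tuple[list[tuple[str, str]], dict[str, int], int]:
    """Draw EST reads under the allele-dependent retention model.

    Each read picks an allele (minor with probability ``maf``), retains
    the intron with that allele's probability (emitting flanking exon +
    full intron + flanking exon), otherwise emits a junction-spanning
    spliced fragment.  Reads are strand-flipped at random and mismatch
    noise applied outside the variant site.  Returns (reads, retained
    counts per allele, spliced count)."""
    for a, p in retention_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"retention probability {p} for allele {a}")
    alleles = list(intron_by_allele)
    major = next(a for a in alleles if a != minor_allele) if len(alleles) > 1 else alleles[0]
    reads: list[tuple[str, str]] = []
    retained_counts = {a: 0 for a in alleles}
    spliced = 0
    for i in range(n):
        allele = minor_allele if rng.random() < maf else major
        if rng.random() < retention_probs[allele]:
            seq = exon1[-20:] + intron_by_allele[allele] + exon2[:20]
            retained_counts[allele] += 1
        else:
            seq = exon1[-30:] + exon2[:30]
            spliced += 1
        seq = _apply_noise(seq, rng, mismatch_rate)
        if rng.random() < 0.5:
            seq = _revcomp(seq)
        reads.append((f"{read_prefix}{i}", seq))
    return reads, retained_counts, spliced


def _apply_noise(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _exact_est_reads(
    exon1: str,
    intron_by_allele: dict[str, str],
    exon2: str,
    minor_allele: str,
    spec: EstSpec,
    read_prefix: str,
) -> list[tuple[str, str]]:
    """Deterministic EST planting with exact counts (noiseless oracle)."""
    alleles = list(intron_by_allele)
    major = next(a for a in alleles if a != minor_allele)
    reads = []
    i = 0
    for allele, count in ((major, spec.major_retained), (minor_allele, spec.minor_retained)):
        for _ in range(count):
            reads.append((f"{read_prefix}{i}",
                          exon1[-20:] + intron_by_allele[allele] + exon2[:20]))
            i += 1
    for _ in range(spec.spliced):
        reads.append((f"{read_prefix}{i}", exon1[-30:] + exon2[:30]))
        i += 1
    return reads


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _expected_labels(isoforms: tuple[str, ...]) -> set[str]:
    labels: set[str] = set()
    if "retention" in isoforms:
        labels.add(mining.INTRON_RETENTION)
    if "alt_splice" in isoforms:
        labels.add(mining.ALTERNATIVE_SPLICE_SITE)
    if isoforms and not labels:
        labels.add(mining.UPSTREAM_TRANSCRIPT_START)
    return labels


def simulate(config: SimulationConfig, outdir) -> dict:
    """Generate the full input bundle under ``outdir``.

    Returns a dict of file paths plus the manifest DataFrame (also
    written as ``manifest.tsv``)."""
    import os

    os.makedirs(str(outdir), exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pwm_set = synthetic_pwm_set()

    chrom = config.chrom
    chrom_parts: list[str] = []
    offset = 0
    transcripts: list[TranscriptModel] = []
    vcf_rows = []  # (pos0, id, ref, alt)
    freq_rows = []
    ld_rows = []
    gwas_rows = []
    pred_rows = []
    est_reads: list[tuple[str, str]] = []
    manifest_rows = []

    for spec in config.genes:
        locus = _Locus(
            spec=spec,
            exon1=_random_seq(rng, EXON1_LEN),
            intron1=_build_intron(
                rng, spec.intron_length,
                conforming=bool(rng.random() < spec.motif_conformity),
            ),
            exon2=_random_seq(rng, EXON2_LEN),
            intron2=_random_seq(rng, INTRON2_LEN),
            exon3=_random_seq(rng, EXON3_LEN),
        )
        gene_seq = locus.gene_seq
        g_len = len(gene_seq)
        iv = locus.local_intervals()
        strand = spec.strand

        def to_genomic(local: tuple[int, int]) -> tuple[int, int]:
            s, e = local
            if strand == "+":
                return offset + s, offset + e
            return offset + g_len - e, offset + g_len - s

        chrom_parts.append(gene_seq if strand == "+" else _revcomp(gene_seq))

        # host transcript: exon1 | intron1 | exon2 | intron2 | exon3, CDS in exon2
        ex_local = [iv["exon1"], iv["exon2"], iv["exon3"]]
        exons_genomic = [to_genomic(x) for x in ex_local]
        cds_local = iv["exon2"][0] + CDS_OFFSET_IN_EXON2
        cds_start = (
            offset + cds_local if strand == "+" else offset + g_len - 1 - cds_local
        )
        host_id = f"{spec.name}_t1"
        transcripts.append(
            TranscriptModel(
                transcript_id=host_id,
                gene_id=spec.name,
                chrom=chrom,
                strand=strand,
                exons=exons_genomic if strand == "+" else sorted(exons_genomic)[::-1],
                cds_start=cds_start,
            )
        )
        # evidence isoforms (non-coding; they carry no 5' UTR introns)
        iso_defs = {
            "retention": [(iv["exon1"][0], iv["exon2"][1]), iv["exon3"]],
            "alt_splice": [(iv["exon1"][0], iv["exon1"][1] - 10), iv["exon2"]],
            "downstream": [iv["exon2"], iv["exon3"]],
        }
        for k, iso in enumerate(spec.isoforms, start=2):
            ex = [to_genomic(x) for x in iso_defs[iso]]
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{spec.name}_t{k}",
                    gene_id=spec.name,
                    chrom=chrom,
                    strand=strand,
                    exons=ex if strand == "+" else sorted(ex)[::-1],
                    cds_start=None,
                )
            )

        if spec.variant is not None:
            manifest_rows.extend(
                _plant_variant(
                    spec, locus, iv, to_genomic, strand, offset, g_len, chrom,
                    pwm_set, rng, config.population,
                    vcf_rows, freq_rows, ld_rows, gwas_rows, pred_rows, est_reads,
                )
            )
        chrom_parts.append(_random_seq(rng, GENE_PAD))
        offset += g_len + GENE_PAD

    chrom_seq = "".join(chrom_parts)
    paths = _write_bundle(
        outdir, chrom, chrom_seq, transcripts, vcf_rows, freq_rows, ld_rows,
        gwas_rows, pred_rows, est_reads, pwm_set, manifest_rows,
    )
    return paths


def _plant_variant(
    spec, locus, iv, to_genomic, strand, offset, g_len, chrom, pwm_set, rng,
    default_pop, vcf_rows, freq_rows, ld_rows, gwas_rows, pred_rows, est_reads,
):
    plant = spec.variant
    intron = locus.intron1
    n = len(intron)
    idx = _variant_intron_index(plant, n)
    if not 0 <= idx < n:
        raise ConfigError(f"gene {spec.name}: variant position beyond intron")
    local = iv["intron1"][0] + idx  # transcript-orientation local coordinate
    vid = f"rs_{spec.name}"
    gc = ma.gc_fraction(intron)
    ref_t = intron[idx]

    if plant.vclass == "SNP":
        alt_t = plant.alt or _TRANSITION[ref_t]
        if alt_t == ref_t:
            raise ConfigError(f"gene {spec.name}: alt equals ref")
        if strand == "+":
            pos0, ref_g, alt_g = offset + local, ref_t, alt_t
        else:
            pos0 = offset + g_len - 1 - local
            ref_g, alt_g = _revcomp(ref_t), _revcomp(alt_t)
        expected_diff = _expected_snp_difference(
            pwm_set, plant.region, plant.label, gc, ref_t, alt_t
        )
        intron_alt = intron[:idx] + alt_t + intron[idx + 1:]
    elif plant.vclass == "DEL1":
        if plant.region == ma.BRANCH_POINT:
            raise ConfigError(f"gene {spec.name}: DEL1 not supported in branch region")
        if (strand == "+" and idx == 0) or (strand == "-" and idx >= n - 1):
            raise ConfigError(f"gene {spec.name}: DEL1 needs an intronic anchor base")
        # VCF left-anchored deletion of the labelled base; on the minus
        # strand the forward-strand anchor is the next transcript base
        if strand == "+":
            pos0 = offset + local - 1
            ref_g = intron[idx - 1: idx + 1]
            alt_g = intron[idx - 1]
        else:
            pos0 = offset + g_len - 2 - local
            ref_g = _revcomp(intron[idx: idx + 2])
            alt_g = ref_g[0]
        intron_alt = intron[:idx] + intron[idx + 1:]
        expected_diff = _expected_del_difference(
            pwm_set, plant.region, gc, intron, intron_alt
        )
        alt_t = intron[idx - 1]
    else:
        raise ConfigError(f"gene {spec.name}: unsupported vclass {plant.vclass}")

    vcf_rows.append((chrom, pos0, vid, ref_g, alt_g))

    minor_allele_g = alt_g
    has_freq = plant.maf is not None
    if has_freq:
        freq_rows.append((vid, plant.population or default_pop, minor_allele_g,
                          plant.maf, 120))

    expected_impact = 0.0
    for g in plant.gwas:
        ld_rows.append((vid, g.partner_id, g.r2, 1.0))
        gwas_rows.append((g.partner_id, g.disease, g.pvalue))
        expected_impact = max(expected_impact, g.r2 * -math.log10(g.pvalue))

    for j in range(plant.predicted_support):
        tool = f"ext_tool{j + 1}"
        pred_rows.append((vid, tool, "ref", 1, 80.0 + 5 * j, 0))
        pred_rows.append((vid, tool, "alt", 1, 55.0 - 5 * j, 0))

    est_spec = plant.est
    est_truth = {}
    if est_spec is not None and plant.vclass == "SNP":
        intron_by_allele = {ref_t: intron, alt_t: intron_alt}
        minor_t = alt_t
        if est_spec.mode == "counts":
            reads = _exact_est_reads(
                locus.exon1, intron_by_allele, locus.exon2, minor_t, est_spec,
                read_prefix=f"{spec.name}_est",
            )
            retained = {ref_t: est_spec.major_retained, alt_t: est_spec.minor_retained}
            spliced = est_spec.spliced
        else:
            reads, retained, spliced = simulate_est_reads(
                locus.exon1, intron_by_allele, locus.exon2, minor_t,
                plant.maf if plant.maf is not None else 0.5,
                {ref_t: est_spec.retention_major, alt_t: est_spec.retention_minor},
                est_spec.n_reads, rng, est_spec.mismatch_rate,
                read_prefix=f"{spec.name}_est",
            )
        est_reads.extend(reads)
        est_truth = {
            "est_major_retained": retained[ref_t],
            "est_minor_retained": retained[alt_t],
            "est_spliced": spliced,
        }

    labels = _expected_labels(spec.isoforms)
    expected_shortlist = ""
    if est_spec is not None and est_spec.mode == "counts" and has_freq:
        total = est_spec.major_retained + est_spec.minor_retained
        if total:
            est_maf = est_spec.minor_retained / total
            expected_shortlist = bool(
                est_spec.spliced > 0 and abs(est_maf - plant.maf) > 0
            )
        else:
            expected_shortlist = False
    i1s, i1e = to_genomic(iv["intron1"])
    return [{
        "variant_id": vid,
        "gene_id": spec.name,
        "transcript_id": f"{spec.name}_t1",
        "chrom": chrom,
        "strand": strand,
        "pos": pos0 + 1,
        "ref": ref_g,
        "alt": alt_g,
        "vclass": "SNP" if plant.vclass == "SNP" else "INDEL",
        "region": plant.region,
        "position_label": plant.label,
        "maf": plant.maf if has_freq else "",
        "population": plant.population if has_freq else "",
        "minor_allele": minor_allele_g if has_freq else "",
        "expected_labels": ",".join(sorted(labels)),
        "expected_score_difference": expected_diff,
        "expected_disease_impact": expected_impact,
        "predicted_support": plant.predicted_support,
        "intron_start": i1s,
        "intron_end": i1e,
        "expected_shortlist": expected_shortlist,
        **est_truth,
    }]


def _write_bundle(outdir, chrom, chrom_seq, transcripts, vcf_rows, freq_rows,
                  ld_rows, gwas_rows, pred_rows, est_reads, pwm_set,
                  manifest_rows):
    import os

    outdir = str(outdir)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff": os.path.join(outdir, "annotation.gff3"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "frequencies": os.path.join(outdir, "frequencies.tsv"),
        "ld": os.path.join(outdir, "ld.tsv"),
        "gwas": os.path.join(outdir, "gwas.tsv"),
        "ests": os.path.join(outdir, "ests.fa"),
        "predictions": os.path.join(outdir, "predictions.tsv"),
        "ese": os.path.join(outdir, "ese_hexamers.txt"),
        "pwm_dir": os.path.join(outdir, "pwms"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(chrom_seq), 70):
            fh.write(chrom_seq[i:i + 70] + "\n")
    write_annotation(transcripts, paths["gff"])
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(chrom_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c, pos0, vid, ref, alt in sorted(vcf_rows, key=lambda r: r[1]):
            fh.write(f"{c}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\t.\t.\n")
    with open(paths["frequencies"], "w") as fh:
        fh.write("snp_id\tpopulation\tminor_allele\tmaf\tn\n")
        for row in freq_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["ld"], "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\tdprime\n")
        for row in ld_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["gwas"], "w") as fh:
        fh.write("snp_id\tdisease\tpvalue\n")
        for row in gwas_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["ests"], "w") as fh:
        for rid, seq in est_reads:
            fh.write(f">{rid}\n{seq}\n")
    with open(paths["predictions"], "w") as fh:
        fh.write("candidate_id\ttool\tallele\tsite_found\tscore\tsite_position\n")
        for row in pred_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["ese"], "w") as fh:
        fh.write("# synthetic ESE hexamer list\n")
        for h in DEFAULT_ESE_HEXAMERS:
            fh.write(h + "\n")
    sc.write_pwm_set(pwm_set, paths["pwm_dir"])
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    paths["manifest_df"] = manifest
    return paths


def config_from_yaml(path, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from YAML (structure mirrors the
    dataclasses; ``seed`` overrides the file's seed when given)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    genes = []
    for g in raw.get("genes", []):
        variant = None
        if g.get("variant"):
            v = dict(g["variant"])
            v["gwas"] = [GwasSpec(**x) for x in v.get("gwas", [])]
            if v.get("est"):
                v["est"] = EstSpec(**v["est"])
            variant = VariantPlant(**v)
        genes.append(
            GeneSpec(
                name=g["name"],
                strand=g.get("strand", "+"),
                intron_length=g.get("intron_length", 120),
                isoforms=tuple(g.get("isoforms", ())),
                motif_conformity=g.get("motif_conformity", 1.0),
                variant=variant,
            )
        )
    return SimulationConfig(
        seed=seed if seed is not None else raw.get("seed", 0),
        genes=genes,
        population=raw.get("population", "CEU"),
        chrom=raw.get("chrom", "chr1"),
    )


# ---------------------------------------------------------------------------
# random configs for property tests
# ---------------------------------------------------------------------------

def random_config(seed: int, n_genes: int = 3, with_est: bool = False) -> SimulationConfig:
    """A random but feasible simulation config (noiseless)."""
    rng = np.random.default_rng(seed)
    region_labels = {
        ma.FIVE_SS: list(range(1, 7)),
        ma.THREE_SS: list(range(-3, 0)),
        ma.PPT: list(range(-15, -3)),
        ma.BRANCH_POINT: list(range(-3, 2)),
    }
    iso_pool = ["retention", "alt_splice", "downstream"]
    genes = []
    for g in range(n_genes):
        region = list(region_labels)[rng.integers(0, 4)]
        label = region_labels[region][rng.integers(0, len(region_labels[region]))]
        n_iso = int(rng.integers(0, 4))
        isoforms = tuple(
            iso_pool[i] for i in sorted(rng.choice(3, size=n_iso, replace=False))
        )
        maf = round(float(rng.uniform(0.05, 0.5)), 3) if rng.random() < 0.8 else None
        est = None
        if with_est and maf is not None:
            est = EstSpec(mode="counts",
                          major_retained=int(rng.integers(5, 40)),
                          minor_retained=int(rng.integers(0, 10)),
                          spliced=int(rng.integers(0, 10)))
        gwas = []
        if rng.random() < 0.5:
            gwas.append(GwasSpec(partner_id=f"rs_partner{g}",
                                 r2=round(float(rng.uniform(0.2, 1.0)), 2),
                                 disease="disease_x",
                                 pvalue=float(10 ** -rng.uniform(1, 8))))
        genes.append(
            GeneSpec(
                name=f"gene{g}",
                strand="+" if rng.random() < 0.5 else "-",
                intron_length=int(rng.integers(MIN_INTRON + 10, 220)),
                isoforms=isoforms,
                variant=VariantPlant(region=region, label=label, maf=maf,
                                     gwas=gwas, est=est),
            )
        )
    return SimulationConfig(seed=int(rng.integers(0, 2**31 - 1)), genes=genes)
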