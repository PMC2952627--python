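"""Candidate detection and splicing-pattern classification.

A candidate is a variant whose reference span overlaps a conserved
splicing motif (donor, acceptor, PPT or branch-point YTNAY match) of a
5' UTR intron of a coding transcript.  Each candidate carries an allelic
score difference (scoring module), a disease impact score and a set of
splicing-pattern labels inferred from the gene's other transcripts:

* ``intron_retention``   -- some transcript has an exon completely
  spanning the host intron;
* ``alternative_splice_site`` -- some other transcript has an intron
  that overlaps the host intron but does not share both boundaries;
* ``upstream_transcript_start`` -- other transcripts exist but none of
  their exons or introns overlap the host intron.

Labels are a set: the groups overlap and their counts may exceed the
number of candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import motif_annotation as ma
from . import scoring as sc
from .genome_model import INDEL, SNP, Intron, TranscriptModel, Variant, fetch

logger = logging.getLogger(__name__)

INTRON_RETENTION = "intron_retention"
ALTERNATIVE_SPLICE_SITE = "alternative_splice_site"
UPSTREAM_TRANSCRIPT_START = "upstream_transcript_start"

#: fixed tie-break order when a variant overlaps two regions equally
REGION_PRIORITY = (ma.FIVE_SS, ma.THREE_SS, ma.PPT, ma.BRANCH_POINT)

#: summary table column order
SUMMARY_REGIONS = (ma.FIVE_SS, ma.THREE_SS, ma.BRANCH_POINT, ma.PPT)

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class CandidateStep:
    """One (variant, transcript-intron, motif region) pairing."""

    variant_id: str
    gene_id: str
    transcript_id: str
    intron_index: int
    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    motif_kind: str
    position_label: int | None
    vclass: str
    tri_allelic: bool
    score_ref: float | None
    score_alt: float | None
    score_difference: float
    disease_impact: float = 0.0
    pattern_labels: set[str] = field(default_factory=set)
    has_population_frequency: bool = False
    intron_offset: int | None = None
    ref_t: str = ""
    alt_t: str = ""
    pair_scores: list[tuple[str, float]] = field(default_factory=list)
    variant: Variant | None = None
    intron: Intron | None = None
    transcript: TranscriptModel | None = None


def _transcript_orient(seq: str, strand: str) -> str:
    return reverse_complement(seq) if strand == "-" else seq


def _variant_intron_span(variant: Variant, intron: Intron) -> tuple[int, int]:
    """Variant reference span as transcript-orientation intron indices
    (may extend beyond [0, len) for boundary-straddling INDELs)."""
    pos, end = variant.ref_span
    if intron.strand == "+":
        lo = pos - intron.start
        hi = end - intron.start
    else:
        lo = intron.end - end
        hi = intron.end - pos
    return lo, hi


def _assign_region(lo: int, hi: int, motifs: ma.MotifSet, n: int):
    """Pick the single motif region for a variant span by largest
    reference-base overlap, ties broken by REGION_PRIORITY.  Returns
    (kind, region-or-best-branch-match) or (None, None)."""
    best_kind, best_region, best_ov = None, None, 0
    for kind in REGION_PRIORITY:
        if kind == ma.BRANCH_POINT:
            candidates = motifs.branch_points
        else:
            r = getattr(motifs, kind)
            candidates = [r] if r is not None else []
        for region in candidates:
            rlo, rhi = region.indices(n)
            ov = max(0, min(hi, rhi) - max(lo, rlo))
            if ov > best_ov:
                best_kind, best_region, best_ov = kind, region, ov
    return best_kind, best_region


def _score_snp(
    pwm_set: sc.PwmSet,
    kind: str,
    motifs: ma.MotifSet,
    intron: Intron,
    gc: float,
    index: int,
    ref_t: str,
    alts_t: list[str],
    variant_id: str,
):
    """Score a SNP at intron index ``index``; tri-allelic sites report
    the maximum pairwise difference, all pairs retained."""
    n = len(intron)
    pos_off, neg_off = ma.index_to_offsets(index, n)
    if kind == ma.FIVE_SS:
        pwm = pwm_set.select(sc.KIND_FIVE, gc)
        label = pos_off
        scores = [
            (alt, sc.allelic_score_difference(pwm, label, ref_t, alt, variant_id))
            for alt in alts_t
        ]
    elif kind in (ma.THREE_SS, ma.PPT):
        pwm = pwm_set.select(sc.KIND_THREE, gc)
        label = neg_off
        scores = [
            (alt, sc.allelic_score_difference(pwm, label, ref_t, alt, variant_id))
            for alt in alts_t
        ]
    else:  # branch point: score every overlapping YTNAY match, keep max
        pwm = pwm_set.select(sc.KIND_BRANCH, gc)
        scores = []
        for alt in alts_t:
            best = None
            for match in motifs.branch_points:
                if not match.contains_index(index, n):
                    continue
                a_idx = ma.signed_offset_to_index(match.branch_a_offset, n)
                lbl = index - a_idx
                s = sc.allelic_score_difference(pwm, lbl, ref_t, alt, variant_id)
                if best is None or s.difference > best.difference:
                    best = s
            if best is not None:
                scores.append((alt, best))
        if not scores:
            return None, []
        label = scores[0][1].position_label
    best_alt, best = max(scores, key=lambda p: p[1].difference)
    return best, [(alt, s.difference) for alt, s in scores]


def _apply_indel(seq: str, lo: int, hi: int, alt_t: str) -> str:
    """Intron sequence under the alternate allele; boundary-straddling
    alleles are clipped to the intronic part."""
    n = len(seq)
    clip_left = max(0, -lo)
    clip_right = max(0, hi - n)
    alt_clipped = alt_t[clip_left: len(alt_t) - clip_right or None]
    return seq[: max(lo, 0)] + alt_clipped + seq[min(hi, n):]


def _score_indel(
    pwm_set: sc.PwmSet,
    kind: str,
    motifs: ma.MotifSet,
    intron: Intron,
    gc: float,
    lo: int,
    hi: int,
    alts_t: list[str],
    variant_id: str,
):
    seq = intron.sequence.upper()
    n = len(seq)
    results = []
    for alt in alts_t:
        alt_seq = _apply_indel(seq, lo, hi, alt)
        if kind == ma.FIVE_SS:
            pwm = pwm_set.select(sc.KIND_FIVE, gc)
            s = sc.indel_score_difference(pwm, seq, alt_seq, "five", variant_id)
        elif kind in (ma.THREE_SS, ma.PPT):
            pwm = pwm_set.select(sc.KIND_THREE, gc)
            s = sc.indel_score_difference(pwm, seq, alt_seq, "three", variant_id)
        else:
            pwm = pwm_set.select(sc.KIND_BRANCH, gc)
            best = None
            for match in motifs.branch_points:
                mlo, mhi = match.indices(n)
                if max(lo, mlo) >= min(hi, mhi):
                    continue
                cand = sc.indel_score_difference(
                    pwm, seq, alt_seq, "three", variant_id,
                    position_offset=match.branch_a_offset,
                )
                if best is None or cand.difference > best.difference:
                    best = cand
            if best is None:
                continue
            s = best
        results.append((alt, s))
    if not results:
        return None, []
    best_alt, best = max(results, key=lambda p: p[1].difference)
    return best, [(alt, s.difference) for alt, s in results]


def find_candidates(
    transcripts: list[TranscriptModel],
    variants: list[Variant],
    pwm_set: sc.PwmSet,
    genome,
) -> list[CandidateStep]:
    """One CandidateStep per (variant, transcript 5' UTR intron, motif
    region) overlap, scored through the PWM set.

    Variants whose reference allele disagrees with the genome are
    excluded with a warning.  An INDEL straddling the exon/intron
    boundary counts as intronic when at least one reference base is.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    out: list[CandidateStep] = []
    for t in transcripts:
        if t.cds_start is None:
            continue
        for intron in t.introns(genome):
            if not intron.is_5utr:
                continue
            n = len(intron)
            motifs = ma.extract_motif_regions(intron)
            gc = ma.gc_fraction(intron.sequence)
            for v in by_chrom.get(t.chrom, []):
                vs, ve = v.ref_span
                if not (vs < intron.end and ve > intron.start):
                    continue
                observed = fetch(genome, v.chrom, vs, ve)
                if observed != v.ref.upper():
                    warnings.warn(
                        f"variant {v.variant_id}: reference allele {v.ref!r} "
                        f"disagrees with genome {observed!r}; excluded"
                    )
                    continue
                lo, hi = _variant_intron_span(v, intron)
                kind, region = _assign_region(lo, hi, motifs, n)
                if kind is None:
                    continue
                ref_t = _transcript_orient(v.ref.upper(), t.strand)
                alts_t = [_transcript_orient(a.upper(), t.strand) for a in v.alts]
                if v.vclass == SNP:
                    score, pairs = _score_snp(
                        pwm_set, kind, motifs, intron, gc, lo, ref_t, alts_t,
                        v.variant_id,
                    )
                else:
                    score, pairs = _score_indel(
                        pwm_set, kind, motifs, intron, gc, lo, hi, alts_t,
                        v.variant_id,
                    )
                if score is None:
                    continue
                out.append(
                    CandidateStep(
                        variant_id=v.variant_id,
                        gene_id=t.gene_id,
                        transcript_id=t.transcript_id,
                        intron_index=intron.index,
                        chrom=t.chrom,
                        strand=t.strand,
                        intron_start=intron.start,
                        intron_end=intron.end,
                        motif_kind=kind,
                        position_label=score.position_label,
                        vclass=v.vclass,
                        tri_allelic=v.tri_allelic,
                        score_ref=score.score_ref,
                        score_alt=score.score_alt,
                        score_difference=score.difference,
                        has_population_frequency=bool(v.maf_by_population),
                        intron_offset=lo,
                        ref_t=ref_t,
                        alt_t=max(
                            pairs, key=lambda p: p[1]
                        )[0] if pairs else (alts_t[0] if alts_t else ""),
                        pair_scores=pairs,
                        variant=v,
                        intron=intron,
                        transcript=t,
                    )
                )
    return out


def classify_pattern(
    intron: Intron,
    gene_transcripts: list[TranscriptModel],
    host_transcript_id: str,
) -> set[str]:
    """Splicing-pattern labels for the host intron from the other
    transcripts of the same gene.  Single-transcript genes yield the
    empty set (no evidence)."""
    labels: set[str] = set()
    others = [t for t in gene_transcripts if t.transcript_id != host_transcript_id]
    any_overlap = False
    for t in others:
        for es, ee in t.genomic_exons:
            if es < intron.end and ee > intron.start:
                any_overlap = True
                if es <= intron.start and ee >= intron.end:
                    labels.add(INTRON_RETENTION)
        for is_, ie in t.genomic_introns():
            if is_ < intron.end and ie > intron.start:
                any_overlap = True
                if (is_, ie) != (intron.start, intron.end):
                    labels.add(ALTERNATIVE_SPLICE_SITE)
    if others and not any_overlap:
        labels.add(UPSTREAM_TRANSCRIPT_START)
    return labels


def attach_patterns(
    candidates: list[CandidateStep], transcripts: list[TranscriptModel]
) -> None:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for c in candidates:
        c.pattern_labels = classify_pattern(
            c.intron, by_gene.get(c.gene_id, []), c.transcript_id
        )


def attach_disease_impact(
    candidates: list[CandidateStep],
    ld_table: pd.DataFrame | None,
    gwas_table: pd.DataFrame | None,
) -> None:
    cache: dict[str, float] = {}
    for c in candidates:
        if c.variant_id not in cache:
            cache[c.variant_id] = sc.disease_impact(c.variant_id, ld_table, gwas_table)
        c.disease_impact = cache[c.variant_id]


def is_transition(ref: str, alt: str) -> bool:
    return frozenset((ref.upper(), alt.upper())) in TRANSITIONS


@dataclass
class SummaryReport:
    counts: pd.DataFrame
    score_stats: pd.DataFrame


def summarize(candidates: list[CandidateStep]) -> SummaryReport:
    """Per-region counts (distinct variants) and score statistics.

    A variant appearing in different motif regions in different
    transcripts is counted once per region; the total column is the sum
    over regions, so it may exceed the number of distinct variants.
    Tri-allelic SNPs occupy their own row, outside the
    transition/transversion split.
    """
    regions = list(SUMMARY_REGIONS)
    rows = ["candidates", "snps", "transitions", "transversions", "tri_allelic",
            "indels", "other"]
    counts = pd.DataFrame(0, index=rows, columns=regions + ["total"])
    seen: set[tuple[str, str]] = set()
    for c in candidates:
        key = (c.variant_id, c.motif_kind)
        if key in seen:
            continue
        seen.add(key)
        col = c.motif_kind
        counts.loc["candidates", col] += 1
        if c.vclass == SNP:
            counts.loc["snps", col] += 1
            if c.tri_allelic:
                counts.loc["tri_allelic", col] += 1
            elif is_transition(c.ref_t, c.alt_t):
                counts.loc["transitions", col] += 1
            else:
                counts.loc["transversions", col] += 1
        elif c.vclass == INDEL:
            counts.loc["indels", col] += 1
        else:
            counts.loc["other", col] += 1
    counts["total"] = counts[regions].sum(axis=1)

    stat_rows = []
    for col in regions + ["total"]:
        if col == "total":
            sel = candidates
        else:
            sel = [c for c in candidates if c.motif_kind == col]
        diffs = np.array([c.score_difference for c in sel], dtype=float)
        dis = np.array([c.disease_impact for c in sel], dtype=float)
        for name, arr in (("allelic_score_difference", diffs), ("disease_impact", dis)):
            if arr.size:
                stat_rows.append(
                    {
                        "region": col,
                        "statistic": name,
                        "mean": float(arr.mean()),
                        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                        "max": float(arr.max()),
                        "min": float(arr.min()),
                        "n": int(arr.size),
                    }
                )
            else:
                stat_rows.append(
                    {"region": col, "statistic": name, "mean": 0.0, "sd": 0.0,
                     "max": 0.0, "min": 0.0, "n": 0}
                )
    return SummaryReport(counts=counts, score_stats=pd.DataFrame(stat_rows))


def check_summary_consistency(counts: pd.DataFrame) -> bool:
    """Internal arithmetic of a candidate summary table.

    Verifies, per region column and for the total column, that the
    variant-class rows tile the candidate row (SNPs + INDELs + other =
    candidates; transitions + transversions + tri-allelic = SNPs) and
    that the total column is the row-wise sum over regions.  Raises
    ``ValueError`` on the first violated relation.
    """
    regions = [c for c in counts.columns if c != "total"]
    for row in counts.index:
        expected = counts.loc[row, regions].sum()
        if counts.loc[row, "total"] != expected:
            raise ValueError(
                f"summary row {row!r}: total {counts.loc[row, 'total']} != "
                f"sum over regions {expected}"
            )
    for col in counts.columns:
        c = counts[col]
        if c["snps"] + c["indels"] + c["other"] != c["candidates"]:
            raise ValueError(f"summary column {col!r}: variant classes != candidates")
        if c["transitions"] + c["transversions"] + c["tri_allelic"] != c["snps"]:
            raise ValueError(f"summary column {col!r}: SNP subtotals != SNP count")
    return True


def candidates_to_frame(candidates: list[CandidateStep]) -> pd.DataFrame:
    """Flat candidate table (one row per variant x transcript-intron x
    region) for TSV/SQLite output."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "variant_id": c.variant_id,
                "gene_id": c.gene_id,
                "transcript_id": c.transcript_id,
                "intron_index": c.intron_index,
                "chrom": c.chrom,
                "strand": c.strand,
                "intron_start": c.intron_start,
                "intron_end": c.intron_end,
                "motif_kind": c.motif_kind,
                "position_label": c.position_label,
                "vclass": c.vclass,
                "tri_allelic": c.tri_allelic,
                "ref": c.variant.ref if c.variant else c.ref_t,
                "alt": ",".join(c.variant.alts) if c.variant else c.alt_t,
                "score_ref": c.score_ref,
                "score_alt": c.score_alt,
                "score_difference": c.score_difference,
                "disease_impact": c.disease_impact,
                "pattern_labels": ",".join(sorted(c.pattern_labels)),
                "has_population_frequency": c.has_population_frequency,
            }
        )
    columns = [
        "variant_id", "gene_id", "transcript_id", "intron_index", "chrom",
        "strand", "intron_start", "intron_end", "motif_kind", "position_label",
        "vclass", "tri_allelic", "ref", "alt", "score_ref", "score_alt",
        "score_difference", "disease_impact", "pattern_labels",
        "has_population_frequency",
    ]
    return pd.DataFrame(rows, columns=columns)
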