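"""EST evidence of intron retention or exon extension.

For a candidate the retained (unspliced) mRNA form is probed with one
query per allele -- the whole intron for full retention, or a 41-base
window centred on the variant (20 bases each side) for partial
retention/exon extension -- and the spliced form with a single 40-base
exon-exon junction query whose junction lies between bases 20 and 21.
ESTs are searched on both strands for full-length containment of a
query (a configurable mismatch budget, default 0, never spent at the
variant site because each allele carries its own query).  Allele counts
among retained matches give an EST minor-allele frequency which, when a
spliced form is also seen and the frequency is biased away from the
population (HapMap) MAF, shortlists the candidate as a putative splice
translational efficiency polymorphism.

Note the EST MAF is the frequency of the *population-defined* minor
allele among retained reads and may exceed 0.5 (complete minor-allele
retention gives 1.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import reverse_complement

FULL_RETENTION = "full_retention"
PARTIAL_RETENTION = "partial_retention"

JUNCTION_FLANK = 20  # bases of each exon in the junction query
PARTIAL_FLANK = 20  # bases flanking the variant in a partial query


@dataclass
class QuerySet:
    """Search queries for one candidate/intron case."""

    candidate_id: str
    mode: str
    retained_queries: dict[str, str]  # allele -> query sequence
    junction_query: str
    variant_index: int  # 0-based index of the variant base in each retained query
    truncated: bool = False


@dataclass
class MatchCounts:
    allele_counts: dict[str, int] = field(default_factory=dict)
    spliced_count: int = 0
    ambiguous_ests: list[str] = field(default_factory=list)
    dual_form_ests: list[str] = field(default_factory=list)

    @property
    def retained_total(self) -> int:
        return sum(self.allele_counts.values())


@dataclass
class EstEvidence:
    candidate_id: str
    allele_counts: dict[str, int]
    spliced_count: int
    est_maf: float | None
    n_est_samples: int
    hapmap_maf: float
    shortlist: bool


def build_queries(
    candidate_id: str,
    intron_seq: str,
    upstream_exon_seq: str,
    downstream_exon_seq: str,
    variant_offset: int,
    alleles: dict[str, str],
    mode: str = FULL_RETENTION,
) -> QuerySet:
    """Construct per-allele retained queries plus the junction query.

    ``alleles`` maps allele name to the allele sequence in transcript
    orientation; ``variant_offset`` is the 0-based intron index of the
    first reference base.  Flanking exons shorter than 20 bases truncate
    the junction query, which is flagged.
    """
    intron_seq = intron_seq.upper()
    up = upstream_exon_seq.upper()
    down = downstream_exon_seq.upper()
    junction = up[-JUNCTION_FLANK:] + down[:JUNCTION_FLANK]
    truncated = len(junction) < 2 * JUNCTION_FLANK

    ref_allele = alleles.get("ref")
    if ref_allele is None:
        raise ValueError("alleles must include the 'ref' allele")
    retained: dict[str, str] = {}
    if mode == FULL_RETENTION:
        for name, allele in alleles.items():
            retained[name] = (
                intron_seq[:variant_offset]
                + allele
                + intron_seq[variant_offset + len(ref_allele):]
            )
        variant_index = variant_offset
    elif mode == PARTIAL_RETENTION:
        # 41-base window, variant at 1-based position 21, built on the
        # exon-intron context so windows near a boundary stay full length
        context = up + intron_seq + down
        ctx_off = len(up) + variant_offset
        for name, allele in alleles.items():
            with_allele = (
                context[:ctx_off] + allele + context[ctx_off + len(ref_allele):]
            )
            lo = ctx_off - PARTIAL_FLANK
            hi = ctx_off + len(allele) + PARTIAL_FLANK
            if lo < 0 or hi > len(with_allele):
                truncated = True
            retained[name] = with_allele[max(lo, 0):hi]
        variant_index = min(ctx_off, PARTIAL_FLANK)
    else:
        raise ValueError(f"unknown query mode {mode!r}")
    return QuerySet(
        candidate_id=candidate_id,
        mode=mode,
        retained_queries=retained,
        junction_query=junction,
        variant_index=variant_index,
        truncated=truncated,
    )


def read_ests(fasta_path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")]


def _contains(text: str, pattern: str, max_mismatches: int) -> bool:
    """Full-length containment of ``pattern`` in ``text`` with at most
    ``max_mismatches`` Hamming mismatches (N mismatches everything)."""
    if not pattern or len(pattern) > len(text):
        return False
    if max_mismatches == 0:
        return pattern in text
    m = len(pattern)
    for i in range(len(text) - m + 1):
        mm = 0
        for a, b in zip(text[i:i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def match_ests(
    queries: QuerySet,
    ests,
    max_mismatches: int = 0,
) -> MatchCounts:
    """Count retained-form matches per allele and spliced-form matches.

    ``ests`` is an iterable of (id, sequence) pairs or a FASTA path.
    Both strands of every EST are searched.  An EST matching more than
    one allele's query (possible only with a mismatch budget) is
    excluded as ambiguous; an EST containing both retained and spliced
    forms is counted once per form and flagged.
    """
    if isinstance(ests, (str,)) or hasattr(ests, "__fspath__"):
        ests = read_ests(ests)
    counts = MatchCounts(allele_counts={a: 0 for a in queries.retained_queries})
    for est_id, seq in ests:
        strands = (seq, reverse_complement(seq))
        hit_alleles = [
            allele
            for allele, q in queries.retained_queries.items()
            if any(_contains(s, q, max_mismatches) for s in strands)
        ]
        spliced = any(
            _contains(s, queries.junction_query, max_mismatches) for s in strands
        )
        if len(hit_alleles) > 1:
            warnings.warn(f"EST {est_id} matches multiple alleles; excluded as ambiguous")
            counts.ambiguous_ests.append(est_id)
        elif hit_alleles:
            counts.allele_counts[hit_alleles[0]] += 1
        if spliced:
            counts.spliced_count += 1
            if hit_alleles:
                counts.dual_form_ests.append(est_id)
    return counts


def evaluate(
    candidate_id: str,
    counts: MatchCounts,
    minor_allele: str,
    hapmap_maf: float,
    bias_threshold: float = 0.0,
) -> EstEvidence:
    """Shortlist rule: a spliced form must be seen AND the EST frequency
    of the population minor allele must differ from the population MAF
    (by at least ``bias_threshold``; the default 0 means any nonzero
    bias).  Zero retained matches leave the EST MAF undefined and never
    shortlist."""
    total = counts.retained_total
    if total == 0:
        est_maf = None
        shortlist = False
    else:
        est_maf = counts.allele_counts.get(minor_allele, 0) / total
        bias = abs(est_maf - hapmap_maf)
        shortlist = counts.spliced_count > 0 and bias > 0 and bias >= bias_threshold
    return EstEvidence(
        candidate_id=candidate_id,
        allele_counts=dict(counts.allele_counts),
        spliced_count=counts.spliced_count,
        est_maf=est_maf,
        n_est_samples=total,
        hapmap_maf=hapmap_maf,
        shortlist=shortlist,
    )
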