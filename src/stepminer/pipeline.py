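"""End-to-end pipeline: mine -> score -> classify -> EST evidence ->
prediction aggregation -> shortlist, plus TSV/SQLite reporting.

The final shortlist mirrors the intersection filter of the discovery
screen: a candidate survives only with (a) transcript evidence of
retention or exon extension, (b) EST evidence of a spliced form plus an
allele-frequency bias, (c) a positive prediction difference in at least
two tools, and (d) population frequency data present.  Every filter
decision is logged so shortlist membership is auditable.
"""

from __future__ import annotations

import logging
import os
import sqlite3
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio.Seq import reverse_complement

from . import est_evidence as ee
from . import mining
from . import motif_annotation as ma
from . import prediction_aggregation as pa
from . import scoring as sc
from .genome_model import (
    SNP,
    attach_frequencies,
    read_annotation,
    read_frequencies,
    read_gwas,
    read_ld,
    read_variants,
)

logger = logging.getLogger(__name__)

RETENTION_OR_EXTENSION = {mining.INTRON_RETENTION, mining.ALTERNATIVE_SPLICE_SITE}


@dataclass
class PipelineConfig:
    annotation: str
    fasta: str
    vcf: str
    pwm_dir: str
    out_dir: str
    frequencies: str | None = None
    ld: str | None = None
    gwas: str | None = None
    ests: str | None = None
    ese_list: str | None = None
    predictions: str | None = None  # external-tool adapter TSV
    population: str = "CEU"
    bias_threshold: float = 0.0
    max_mismatches: int = 0
    predictor_floor: float = pa.DEFAULT_SCORE_FLOOR
    min_tools: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("annotation", "fasta", "vcf", "pwm_dir", "frequencies",
                     "ld", "gwas", "ests", "ese_list", "predictions"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(str(path)):
                raise FileNotFoundError(f"pipeline input {name!r}: {path} not found")


@dataclass
class PipelineResult:
    candidates: list[mining.CandidateStep]
    candidate_table: pd.DataFrame
    summary: mining.SummaryReport
    est_table: pd.DataFrame
    prediction_table: pd.DataFrame
    shortlist: pd.DataFrame
    transcripts: list = field(default_factory=list)


def _flanking_exon_seqs(candidate, genome) -> tuple[str, str]:
    t = candidate.transcript
    up = t.exon_sequence(genome, candidate.intron_index - 1)
    down = t.exon_sequence(genome, candidate.intron_index)
    return up, down


def _variant_exonic_elsewhere(candidate, transcripts) -> bool:
    """Is the variant inside an exon of another transcript of the gene
    (the exon-extension situation probed with partial-retention
    queries)?"""
    vs, ve = candidate.variant.ref_span
    for t in transcripts:
        if t.gene_id != candidate.gene_id or t.transcript_id == candidate.transcript_id:
            continue
        for es, eexp in t.genomic_exons:
            if es < ve and eexp > vs:
                return True
    return False


def run_est_stage(
    candidates, transcripts, genome, ests, cfg: PipelineConfig
) -> dict[int, ee.EstEvidence]:
    """EST evidence per candidate row (keyed by list index).

    Full-retention queries when the candidate's intron has retention
    evidence, partial-retention (41-mer) queries when the variant is
    exonic in another transcript, full-retention otherwise."""
    out: dict[int, ee.EstEvidence] = {}
    est_records = ee.read_ests(ests)
    for i, c in enumerate(candidates):
        if c.vclass != SNP or c.tri_allelic:
            continue  # population frequency comparison needs biallelic SNPs
        if mining.INTRON_RETENTION in c.pattern_labels:
            mode = ee.FULL_RETENTION
        elif _variant_exonic_elsewhere(c, transcripts):
            mode = ee.PARTIAL_RETENTION
        else:
            mode = ee.FULL_RETENTION
        up, down = _flanking_exon_seqs(c, genome)
        queries = ee.build_queries(
            candidate_id=f"{c.variant_id}|{c.transcript_id}|{c.intron_index}",
            intron_seq=c.intron.sequence,
            upstream_exon_seq=up,
            downstream_exon_seq=down,
            variant_offset=c.intron_offset,
            alleles={"ref": c.ref_t, "alt": c.alt_t},
            mode=mode,
        )
        counts = ee.match_ests(queries, est_records, cfg.max_mismatches)
        pop = cfg.population
        freq = c.variant.maf_by_population.get(pop)
        if freq is None:
            hap_maf = 0.0
            minor_name = "alt"
        else:
            hap_maf = freq[0]
            minor_g = c.variant.minor_allele.get(pop, c.variant.alts[0])
            minor_t = reverse_complement(minor_g) if c.strand == "-" else minor_g
            minor_name = "alt" if minor_t == c.alt_t else "ref"
        ev = ee.evaluate(queries.candidate_id, counts, minor_name, hap_maf,
                         cfg.bias_threshold)
        if freq is None:
            ev.shortlist = False  # bias undefined without a population MAF
        out[i] = ev
    return out


def run_prediction_stage(
    candidates, genome, pwm_set, adapter, cfg: PipelineConfig
) -> dict[int, pa.AggregateRecord]:
    """Internal PWM predictor plus adapter tools, aggregated per
    candidate row.  Only splice-site and PPT SNPs are submitted."""
    out: dict[int, pa.AggregateRecord] = {}
    for i, c in enumerate(candidates):
        if c.vclass != SNP or c.motif_kind == ma.BRANCH_POINT:
            continue
        side = pa.DONOR if c.motif_kind == ma.FIVE_SS else pa.ACCEPTOR
        up, down = _flanking_exon_seqs(c, genome)
        try:
            windows = pa.build_windows(
                candidate_id=c.variant_id,
                intron_seq=c.intron.sequence,
                upstream_exon_seq=up,
                downstream_exon_seq=down,
                variant_offset=c.intron_offset,
                alleles={"ref": c.ref_t, "alt": c.alt_t},
                side=side,
            )
        except ValueError as exc:
            logger.warning("prediction windows skipped for %s: %s", c.variant_id, exc)
            continue
        tools = [
            pa.internal_tool_difference(
                windows["ref"], windows["alt"], pwm_set, cfg.predictor_floor
            )
        ]
        tools.extend(adapter.get(c.variant_id, []))
        out[i] = pa.aggregate(c.variant_id, tools, cfg.min_tools)
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    transcripts, genome = read_annotation(cfg.annotation, cfg.fasta)
    variants = read_variants(cfg.vcf)
    if cfg.frequencies:
        attach_frequencies(variants, read_frequencies(cfg.frequencies))
    ld = read_ld(cfg.ld) if cfg.ld else None
    gwas = read_gwas(cfg.gwas) if cfg.gwas else None
    pwm_set = sc.load_pwm_set(cfg.pwm_dir)
    adapter = pa.read_adapter_tsv(cfg.predictions) if cfg.predictions else {}

    candidates = mining.find_candidates(transcripts, variants, pwm_set, genome)
    mining.attach_patterns(candidates, transcripts)
    mining.attach_disease_impact(candidates, ld, gwas)
    summary = mining.summarize(candidates)
    mining.check_summary_consistency(summary.counts)

    est_by_row = (
        run_est_stage(candidates, transcripts, genome, cfg.ests, cfg)
        if cfg.ests else {}
    )
    pred_by_row = run_prediction_stage(candidates, genome, pwm_set, adapter, cfg)

    table = mining.candidates_to_frame(candidates)
    est_rows, pred_rows, shortlist_rows = [], [], []
    for i, c in enumerate(candidates):
        ev = est_by_row.get(i)
        ag = pred_by_row.get(i)
        if ev is not None:
            est_rows.append(
                {
                    "variant_id": c.variant_id,
                    "transcript_id": c.transcript_id,
                    "intron_index": c.intron_index,
                    "hapmap_maf": ev.hapmap_maf,
                    "est_maf": "" if ev.est_maf is None else round(ev.est_maf, 6),
                    "n_retained": ev.n_est_samples,
                    "n_spliced": ev.spliced_count,
                    "ref_count": ev.allele_counts.get("ref", 0),
                    "alt_count": ev.allele_counts.get("alt", 0),
                    "est_shortlist": ev.shortlist,
                }
            )
        if ag is not None:
            pred_rows.append(
                {
                    "variant_id": c.variant_id,
                    "transcript_id": c.transcript_id,
                    "intron_index": c.intron_index,
                    "support_count": ag.support_count,
                    "multi_tool_supported": ag.multi_tool_supported,
                    "average_difference": round(ag.average_difference, 6),
                    "tools": ";".join(
                        f"{t.tool}:{round(t.difference, 4)}" for t in ag.tool_differences
                    ),
                }
            )
        reasons = []
        if not (c.pattern_labels & RETENTION_OR_EXTENSION):
            reasons.append("no transcript evidence of retention/extension")
        if ev is None or not ev.shortlist:
            reasons.append("no EST evidence with allele bias")
        if ag is None or not ag.multi_tool_supported:
            reasons.append("fewer than 2 supporting prediction tools")
        if not c.has_population_frequency:
            reasons.append("no population frequency data")
        if reasons:
            logger.info("candidate %s/%s excluded from shortlist: %s",
                        c.variant_id, c.transcript_id, "; ".join(reasons))
        else:
            logger.info("candidate %s/%s shortlisted", c.variant_id, c.transcript_id)
            shortlist_rows.append(
                {
                    "variant_id": c.variant_id,
                    "gene_id": c.gene_id,
                    "transcript_id": c.transcript_id,
                    "intron_index": c.intron_index,
                    "motif_kind": c.motif_kind,
                    "score_difference": c.score_difference,
                    "disease_impact": c.disease_impact,
                    "pattern_labels": ",".join(sorted(c.pattern_labels)),
                    "hapmap_maf": ev.hapmap_maf,
                    "est_maf": round(ev.est_maf, 6),
                    "n_retained": ev.n_est_samples,
                    "n_spliced": ev.spliced_count,
                    "support_count": ag.support_count,
                    "average_difference": round(ag.average_difference, 6),
                }
            )

    est_table = pd.DataFrame(
        est_rows,
        columns=["variant_id", "transcript_id", "intron_index", "hapmap_maf",
                 "est_maf", "n_retained", "n_spliced", "ref_count", "alt_count",
                 "est_shortlist"],
    )
    pred_table = pd.DataFrame(
        pred_rows,
        columns=["variant_id", "transcript_id", "intron_index", "support_count",
                 "multi_tool_supported", "average_difference", "tools"],
    )
    shortlist = pd.DataFrame(
        shortlist_rows,
        columns=["variant_id", "gene_id", "transcript_id", "intron_index",
                 "motif_kind", "score_difference", "disease_impact",
                 "pattern_labels", "hapmap_maf", "est_maf", "n_retained",
                 "n_spliced", "support_count", "average_difference"],
    )

    table.to_csv(os.path.join(cfg.out_dir, "candidates.tsv"), sep="\t", index=False)
    summary.counts.to_csv(os.path.join(cfg.out_dir, "summary_counts.tsv"), sep="\t")
    summary.score_stats.to_csv(
        os.path.join(cfg.out_dir, "summary_stats.tsv"), sep="\t", index=False
    )
    est_table.to_csv(os.path.join(cfg.out_dir, "est_evidence.tsv"), sep="\t", index=False)
    pred_table.to_csv(os.path.join(cfg.out_dir, "predictions.tsv"), sep="\t", index=False)
    shortlist.to_csv(os.path.join(cfg.out_dir, "shortlist.tsv"), sep="\t", index=False)

    return PipelineResult(
        candidates=candidates,
        candidate_table=table,
        summary=summary,
        est_table=est_table,
        prediction_table=pred_table,
        shortlist=shortlist,
        transcripts=transcripts,
    )


# ---------------------------------------------------------------------------
# SQLite export and queries
# ---------------------------------------------------------------------------

def export_sqlite(result: PipelineResult, db_path) -> None:
    """Relational export supporting gene / rs / region / motif /
    variant-type queries."""
    if os.path.exists(str(db_path)):
        os.remove(str(db_path))
    con = sqlite3.connect(str(db_path))
    try:
        t_rows = [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "start": t.span[0],
                "end": t.span[1],
                "n_exons": len(t.exons),
                "cds_start": t.cds_start,
            }
            for t in result.transcripts
        ]
        pd.DataFrame(t_rows).to_sql("transcripts", con, index=False)
        i_rows = [
            {
                "transcript_id": c.transcript_id,
                "intron_index": c.intron_index,
                "chrom": c.chrom,
                "start": c.intron_start,
                "end": c.intron_end,
            }
            for c in result.candidates
        ]
        pd.DataFrame(i_rows).drop_duplicates().to_sql("introns", con, index=False)
        v_rows = []
        seen = set()
        for c in result.candidates:
            if c.variant_id in seen or c.variant is None:
                continue
            seen.add(c.variant_id)
            v_rows.append(
                {
                    "variant_id": c.variant_id,
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": ",".join(c.variant.alts),
                    "vclass": c.variant.vclass,
                }
            )
        pd.DataFrame(v_rows).to_sql("variants", con, index=False)
        df = result.candidate_table.copy()
        vpos = {r["variant_id"]: r["pos"] for r in v_rows}
        df["pos"] = df["variant_id"].map(vpos)
        df.to_sql("candidates", con, index=False)
        cur = con.cursor()
        cur.execute("CREATE INDEX idx_cand_gene ON candidates(gene_id)")
        cur.execute("CREATE INDEX idx_cand_variant ON candidates(variant_id)")
        cur.execute("CREATE INDEX idx_cand_region ON candidates(chrom, pos)")
        cur.execute("CREATE INDEX idx_cand_motif ON candidates(motif_kind)")
        cur.execute("CREATE INDEX idx_cand_vclass ON candidates(vclass)")
        con.commit()
    finally:
        con.close()


def query_db(
    db_path,
    gene: str | None = None,
    rs: str | None = None,
    transcript: str | None = None,
    region: tuple[str, int, int] | None = None,
    motif: str | None = None,
    vtype: str | None = None,
) -> pd.DataFrame:
    """Filter the candidate table by gene, rs id, transcript,
    chromosomal region, motif region and/or variant type."""
    clauses, params = [], []
    if gene:
        clauses.append("gene_id = ?")
        params.append(gene)
    if rs:
        clauses.append("variant_id = ?")
        params.append(rs)
    if transcript:
        clauses.append("transcript_id = ?")
        params.append(transcript)
    if region:
        chrom, start, end = region
        clauses.append("chrom = ? AND pos >= ? AND pos < ?")
        params.extend([chrom, start, end])
    if motif:
        clauses.append("motif_kind = ?")
        params.append(motif)
    if vtype:
        clauses.append("vclass = ?")
        params.append(vtype)
    sql = "SELECT * FROM candidates"
    if clauses:
        sql += " WHERE " + " AND ".join(clauses)
    con = sqlite3.connect(str(db_path))
    try:
        return pd.read_sql_query(sql, con, params=params)
    finally:
        con.close()
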