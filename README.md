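# stepminer

Discovery and evaluation of candidate **splice translational efficiency
polymorphisms (STEPs)** — variants in the splicing motifs of 5' UTR
introns whose alleles differentially affect intron retention in the
mRNA leader, changing how much protein is made without changing the
protein itself.  The package is aimed at regulatory-genomics analysts
who have standard annotation files (GFF3/GTF + FASTA + VCF, plus
HapMap-style frequency, LD and GWAS tables and an EST collection) and
want a reproducible, offline candidate screen.

## What it computes

For every variant overlapping a splice motif of a 5' UTR intron —
donor +1..+6, acceptor −3..−1, polypyrimidine tract −15..−4, or a
YTNAY branch-point match within −34..−21 — the pipeline reports:

* **Allelic score difference** from non-consensus-probability position
  weight matrices: entries are P(base does *not* appear at position),
  so for a SNP at position *i*,
  Δ = |M[i, alt] − M[i, ref]| ∈ [0, 1] —
  exactly 1 for a destroyed obligate base (the GT–AG rule), 0.1 for a
  transition at a background position (A/T entries 0.8, C/G 0.7 from
  genome-average base-pair frequencies).  INDELs re-read the motif
  frame under each allele and sum per-position differences.
* **Disease impact** = max over LD partners and diseases of
  r² · (−log₁₀ p) from GWAS tables (a variant partners itself with
  r² = 1).
* **Splicing-pattern labels** from the gene's other transcripts:
  intron retention (an exon spans the whole intron), alternative
  splice site (an intron incompletely overlaps it), or upstream
  transcript start (no overlap at all).
* **EST evidence**: per-allele counts of retained-form matches (whole
  intron per allele, or 41-mers around the variant) and of the 40-base
  exon–exon junction form; shortlisting requires a spliced form plus a
  bias of the EST minor-allele frequency away from the population MAF.
* **Prediction support**: per-allele 60-nt windows (20 exonic + 40
  intronic) scored by an internal PWM predictor and any external tools
  supplied via an adapter table; a candidate needs a positive
  difference in ≥ 2 tools.

A bundled, seeded synthetic-data generator emulates all inputs with a
planted-truth manifest, so the whole pipeline is testable without any
downloads.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a one-gene study — a donor +5 SNP (population MAF 0.483) in a
5' UTR intron, a second transcript retaining the intron, 100 retained
ESTs of which 7 carry the minor allele, 4 spliced ESTs, and a GWAS
partner at r² = 0.5 with p = 10⁻⁴ — then run the pipeline on it:

```sh
stepminer simulate --config sim.yaml --out bundle
# wrote bundle to bundle (1 planted variants)
stepminer pipeline --config pipe.yaml
# 1 candidate rows, 1 shortlisted (outputs in out)
```

`out/shortlist.tsv` (columns abridged):

```
variant_id  motif_kind  score_difference  disease_impact  pattern_labels    hapmap_maf  est_maf  n_retained  n_spliced  support_count
rs_geneA    five_ss     0.65              2.0             intron_retention  0.483       0.07     100         4          3
```

Reading the numbers: the donor +5 substitution changes the
non-consensus probability from 0.20 to 0.85, an allelic score
difference of 0.65; the LD partner contributes 0.5 × 4 = 2.0 disease
impact; among 100 retained EST reads the minor allele appears at
frequency 0.07 against a population MAF of 0.483 — a strong retention
bias of the major allele — while 4 reads show the spliced junction;
three prediction tools (two external adapters plus the internal PWM
predictor) give positive allelic differences.  All four evidence
filters pass, so the variant is shortlisted.  `stepminer export`
then builds a queryable SQLite database
(`stepminer query --db steps.sqlite --rs rs_geneA`).

## Layout

```
src/stepminer/
  genome_model.py            formats, coordinates, 5' UTR introns
  motif_annotation.py        motif extraction, branch scan, composition
  scoring.py                 non-consensus PWMs, allelic/INDEL scores,
                             disease impact
  mining.py                  candidate detection, pattern labels, summary
  est_evidence.py            EST queries, matching, shortlist rule
  prediction_aggregation.py  60-nt windows, internal predictor, adapters
  synthetic_fixtures.py      seeded simulator with truth manifest
  pipeline.py, cli.py        orchestration, SQLite export, CLI
```
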