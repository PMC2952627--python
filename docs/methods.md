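# Methods

## The problem and the model

Some human genes carry an intron entirely inside the 5' untranslated
region, separating a non-coding first exon from the exon that holds the
translation start.  A variant in one of that intron's splicing motifs
can make intron removal allele-dependent: one allele splices cleanly,
the other leaves (part of) the intron in the mRNA leader.  The protein
sequence is untouched, but leader length and structure change, and with
them translational efficiency — a splice translational efficiency
polymorphism (STEP), a class of protein quantitative trait locus.
`stepminer` detects such candidates in annotation + variant data and
weighs four independent lines of evidence: motif disruption (PWM
scoring), transcript-isoform structure, EST form counts, and
splice-site prediction differences.

## Motif geometry

All offsets are intron-relative in transcript orientation (+1 = first
intronic base, −1 = last):

| region          | span        | content                                   |
|-----------------|-------------|-------------------------------------------|
| donor (5'ss)    | +1..+6      | obligate GT plus four preference bases     |
| acceptor (3'ss) | −3..−1      | YAG, obligate AG at −2..−1                 |
| PPT             | −15..−4     | 12-base polypyrimidine tract               |
| branch point    | within −34..−21 | every YTNAY 5-mer wholly inside the window |

Branch points are reported for *all* YTNAY matches in the window, not
just a best one; a variant in the window is a branch-point candidate
only when it overlaps a match, and its score is the maximum over
overlapping matches.  Introns shorter than a region's span omit that
region with a flag rather than failing.

## Non-consensus PWM scoring

Matrices store the probability that a base does **not** appear at a
position.  Consequences used throughout:

* an obligate position has entry 0 for the required base and 1 for the
  others, so destroying it scores an allelic difference of exactly 1;
* a consensus-irrelevant position carries the genome-background column
  (A/T 0.8, C/G 0.7, from genome-average AT pair frequency 0.4 and CG
  pair frequency 0.6), so a transition there scores 0.1;
* SNP difference = |entry(alt) − entry(ref)| at the variant position,
  bounded by 1, symmetric in the alleles; tri-allelic sites report the
  maximum pairwise difference with every pair retained.

Donor and acceptor/PPT matrices come in GC-rich and GC-poor flavours
selected by whole-intron GC fraction; exactly 50% is classed GC-rich
(a deterministic, logged tie-break).  Positional independence is
assumed — coupling and periodicity between nearby bases are not
modelled.

**INDELs.**  No single-position rule can exceed 1, yet multi-position
events plainly can disrupt more.  An INDEL is scored by re-reading the
motif frame under each allele — frames anchored at the intron 5' end
for donors and at the 3' end for acceptor/PPT/branch frames, so the
allele shift slides flanking sequence through the frame — and summing
per-position absolute differences.  The result is bounded by the motif
length.  This summation rule is this package's documented
interpretation; output metadata flags INDEL scores accordingly.

A variant overlapping two regions (possible for INDELs) is assigned the
region with the largest reference-base overlap, ties broken
donor > acceptor > PPT > branch point.

## Disease impact

For a candidate variant v, `impact(v) = max over (partner, disease) of
r²(v, partner) × −log10(p)`, where partners are GWAS-typed SNPs linked
to v in the LD table plus v itself (r² = 1).  D' is stored but plays no
role.  The score is descriptive — an LD-weighted significance, not a
causal estimate — and is monotone in both r² and significance.

## Splicing-pattern classification

Evidence comes from the *other transcripts of the same gene* (cross-
gene overlap would be meaningless).  For the host intron:

* **intron retention** — some transcript has an exon completely
  spanning the intron;
* **alternative splice site** — some other transcript has an intron
  that overlaps the host intron but differs in start or end;
* **upstream transcript start** — other transcripts exist but none of
  their exons or introns touch the host intron.

Labels form a set (the groups overlap); a single-transcript gene yields
the empty set — absence of evidence, not an error.  Non-coding
transcripts contribute no candidate introns themselves but do count as
evidence.

## EST evidence

Per candidate: one retained-form query per allele — the whole intron
(full retention) or a 41-base window with the variant at base 21
(partial retention / exon extension) — plus one 40-base exon–exon
junction query with the junction between bases 20 and 21.  The original
screen ran these through a web BLAST against dbEST and kept full-length
subject matches; here matching is local and deterministic: an EST
(either strand) counts for a form when it contains the full query with
at most `max_mismatches` mismatches (default 0).  Each allele carries
its own query, so the variant site never spends mismatch budget; an EST
matching multiple allele queries is excluded as ambiguous, and one
containing both forms counts once per form with a flag.  An adapter
table accepts externally produced alignments for users who prefer BLAST.

The EST minor-allele frequency is the frequency of the
*population-defined* minor allele among retained matches — it may
exceed 0.5 (complete minor-allele retention gives 1.0).  Shortlist
rule: a spliced form must be observed AND |EST MAF − population MAF|
must be nonzero and ≥ `bias_threshold`.  The original criterion
("a bias") is unquantified; the default threshold 0 makes any nonzero
bias sufficient, and both frequencies are always reported so the rule
is auditable.

## Prediction aggregation

Each splice-site/PPT SNP yields per-allele 60-nt windows (20 exonic +
40 intronic around the annotated junction).  External predictors are
version-unstable web tools and are represented by an adapter format;
an internal PWM predictor keeps the pipeline self-contained.  It calls
a site at the annotated offset when (a) no obligate base is destroyed
(GT-AG rule) and (b) the mean per-position consensus strength reaches a
floor (default 0.5, a configuration value with no external analogue).
The per-tool difference is |score_ref − score_alt| when both alleles
have a site, the surviving allele's score when only one does (a missing
site is asserted as 0), and 0 with a "site not predicted" flag when
neither does.  Scores stay on each tool's native scale; a candidate is
multi-tool supported when ≥ 2 tools give a positive difference, which
suppresses single-tool over-prediction.

## Final shortlist

A candidate survives the pipeline only with all four of: transcript
evidence of retention or extension; EST shortlist; multi-tool
prediction support; and population frequency data.  Every exclusion is
logged with the violated rule.

## Synthetic data

The generator emulates the study's inputs with known truth: genes with
a non-coding first exon, a 5' UTR intron carrying consensus motifs
(GTAAGT donor, exactly one planted CTGAC branch match — the scan window
is otherwise filled from {C,G} so no stray YTNAY can form — a 12-base
pyrimidine tract and CAG acceptor), a coding second exon, and one
coding intron as a negative control.  Background composition uses the
genome-average base frequencies above.  Isoforms plant the three
pattern classes; EST reads are generated either with exact counts
(noiseless oracles; e.g. the emulated locus with MAF 0.483, 100
retained reads carrying 7 minor alleles and 4 spliced reads reproduces
an EST MAF of 0.070 and shortlists) or by the stochastic model: allele
~ Bernoulli(MAF), retention ~ Bernoulli(allele rate), random strand,
optional per-base mismatch noise (default 0 so oracle tests are exact).

What the simulator does *not* emulate: realistic population genetics
(no LD structure beyond the explicit table, no coalescent), EST error
profiles, fragmented or misannotated transcripts, and non-canonical
(GC-AG / AT-AC) introns.  Passing tests therefore demonstrate
correctness of the machinery on well-formed inputs, not recovery rates
on real annotation databases.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; GFF/VCF conversion
  happens at the I/O boundary only.
* An intron containing the translation start is not a 5' UTR intron;
  an INDEL straddling the exon/intron boundary is intronic when at
  least one reference base is.
* Variants whose reference allele disagrees with the genome are
  excluded with a warning; malformed table rows fail with line numbers.
* Zero retained EST matches leave the EST MAF undefined and never
  shortlist.
* Summary tables count distinct variants per region; the total column
  is the sum over regions (a variant in two regions counts in both).

## Problem sizes used in the test suite

Oracle suites run 1,000 random instances each (motif extraction,
branch scan, pattern classification, EST counting); full-pipeline
planting/recovery runs 50 random 3-gene configs; the stochastic EST
bias check runs 100 seeded replicates of 200 reads (retention 0.9 vs
0.1, MAF 0.48) and requires ≥ 95 shortlists.  Loci are kept small
(introns 50–220 bp) — the algorithms are length-agnostic, so small loci
exercise the same code paths.

## Known limitations

The three external predictors are not reimplemented; without adapter
data the internal predictor is the only tool and no candidate can reach
2-tool support.  PWM files for published matrices must be supplied by
the user (the package ships only the trivially forced obligate and
background columns plus the clearly-labelled synthetic set the
simulator writes); the loader validates but does not invent values.
Genome-wide candidate counts from the original 2009-era database
snapshots are not reproducible from desk-scale inputs and are not
targets of this package.
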