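"""Non-consensus-probability PWM scoring and the disease impact score.

The matrices used here are *non-consensus* position weight matrices:
each entry is the probability that a base does **not** appear at a
position.  An obligate position (e.g. the G of the intronic GT) has
entry 0 for the required base and 1 for the other three, so a
substitution destroying it scores an allelic difference of exactly 1.
A position irrelevant to the consensus carries genome-background
entries (A/T not-appearing 0.8, C/G 0.7, from genome-average AT pair
frequency 0.4 and CG pair frequency 0.6), so a transition such as A>G
scores |0.8 - 0.7| = 0.1.

The allelic score difference of a SNP is the absolute difference of the
two alleles' entries at the variant's motif position.  For INDELs the
motif frame (anchored at the intron end that defines the motif) is
re-read under each allele and per-position absolute differences are
summed, which is how differences can exceed 1.

The disease impact score of a variant is max over LD partners and
diseases of r^2 x -log10(p); a variant is its own partner with r^2 = 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

KIND_FIVE = "five_ss"
KIND_THREE = "three_ss_ppt"
KIND_BRANCH = "branch_point"

GC_RICH = "gc_rich"
GC_POOR = "gc_poor"
GC_ANY = "any"

#: background non-consensus probabilities from genome-average base use
BACKGROUND_NON_CONSENSUS = {"A": 0.8, "T": 0.8, "C": 0.7, "G": 0.7}


@dataclass
class Pwm:
    """Non-consensus probability matrix over labelled positions.

    ``table`` maps integer position label (+1..+6 for donors, -15..-1
    for the acceptor/PPT block, -3..+1 around the branch adenosine at 0)
    to {base: probability of that base *not* appearing}.
    """

    kind: str
    gc_class: str
    table: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        for pos, row in self.table.items():
            missing = [b for b in BASES if b not in row]
            if missing:
                raise ValueError(f"PWM {self.kind}: position {pos} missing {missing}")
            for b, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"PWM {self.kind}: entry {p} at ({pos},{b}) outside [0,1]"
                    )

    @property
    def positions(self) -> list[int]:
        return sorted(self.table)

    def score(self, position: int, base: str) -> float:
        base = base.upper()
        if base not in BASES:
            raise ValueError(
                f"ambiguous or invalid base {base!r}; expand ambiguity codes first"
            )
        if position not in self.table:
            raise KeyError(f"position {position} not in {self.kind} PWM")
        return self.table[position][base]

    def consensus_strength(self, position: int, base: str) -> float:
        """1 - non-consensus probability: how consensus-like a base is."""
        return 1.0 - self.score(position, base)

    def obligate_positions(self) -> dict[int, str]:
        """Positions with entry 0 for exactly one base and 1 elsewhere."""
        out = {}
        for pos, row in self.table.items():
            zeros = [b for b in BASES if row[b] == 0.0]
            ones = [b for b in BASES if row[b] == 1.0]
            if len(zeros) == 1 and len(ones) == 3:
                out[pos] = zeros[0]
        return out


@dataclass
class AllelicScore:
    variant_id: str
    motif_kind: str
    position_label: int | None
    score_ref: float | None
    score_alt: float | None
    difference: float
    detail: list[tuple[int, float, float]] = field(default_factory=list)


class PwmSet:
    """The per-run matrix collection: donor and acceptor/PPT matrices in
    GC-rich and GC-poor flavours plus one branch-point matrix."""

    def __init__(self, pwms: list[Pwm]):
        self._by_key = {(p.kind, p.gc_class): p for p in pwms}

    def select(self, kind: str, gc_fraction: float) -> Pwm:
        """Deterministic matrix choice: gc_fraction >= 0.5 -> GC-rich
        (the exact-50% tie goes to GC-rich and is logged)."""
        if (kind, GC_ANY) in self._by_key:
            return self._by_key[(kind, GC_ANY)]
        gc_class = GC_RICH if gc_fraction >= 0.5 else GC_POOR
        if gc_fraction == 0.5:
            logger.info("gc_fraction exactly 0.5: tie broken to gc_rich")
        key = (kind, gc_class)
        if key not in self._by_key:
            raise KeyError(f"no {kind} PWM for class {gc_class}")
        return self._by_key[key]

    def __iter__(self):
        return iter(self._by_key.values())


def load_pwm(tsv_path, kind: str, gc_class: str = GC_ANY) -> Pwm:
    """Load a PWM from TSV with header ``pos A C G T``; position labels
    like ``+1``/``-15``; entries validated to [0,1]."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    required = ["pos", "A", "C", "G", "T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PWM file {tsv_path}: missing columns {missing}")
    table: dict[int, dict[str, float]] = {}
    for i, row in df.iterrows():
        try:
            pos = int(str(row["pos"]).replace("+", ""))
        except ValueError as exc:
            raise ValueError(f"PWM file {tsv_path} row {i + 2}: bad position") from exc
        entry = {}
        for b in BASES:
            try:
                p = float(row[b])
            except ValueError as exc:
                raise ValueError(
                    f"PWM file {tsv_path}: unreadable entry at ({row['pos']},{b})"
                ) from exc
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"PWM file {tsv_path}: entry {p} at ({row['pos']},{b}) outside [0,1]"
                )
            entry[b] = p
        table[pos] = entry
    return Pwm(kind=kind, gc_class=gc_class, table=table)


def write_pwm(pwm: Pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for pos in pwm.positions:
            label = f"+{pos}" if pos > 0 else str(pos)
            row = pwm.table[pos]
            fh.write(label + "\t" + "\t".join(f"{row[b]:g}" for b in BASES) + "\n")


#: file names expected by :func:`load_pwm_set` inside a PWM directory
PWM_DIR_LAYOUT = {
    "five_ss_gc_rich.tsv": (KIND_FIVE, GC_RICH),
    "five_ss_gc_poor.tsv": (KIND_FIVE, GC_POOR),
    "three_ss_ppt_gc_rich.tsv": (KIND_THREE, GC_RICH),
    "three_ss_ppt_gc_poor.tsv": (KIND_THREE, GC_POOR),
    "branch_point.tsv": (KIND_BRANCH, GC_ANY),
}


def load_pwm_set(pwm_dir) -> PwmSet:
    """Load a full matrix set from a directory of TSV files (donor and
    acceptor/PPT matrices in GC-rich/GC-poor flavours, one branch-point
    matrix).  Missing files raise at first use of that matrix kind."""
    import os

    pwms = []
    for fname, (kind, gc_class) in PWM_DIR_LAYOUT.items():
        path = os.path.join(str(pwm_dir), fname)
        if os.path.exists(path):
            pwms.append(load_pwm(path, kind, gc_class))
    if not pwms:
        raise FileNotFoundError(f"no PWM files found in {pwm_dir}")
    return PwmSet(pwms)


def write_pwm_set(pwm_set: PwmSet, pwm_dir) -> None:
    import os

    os.makedirs(str(pwm_dir), exist_ok=True)
    names = {v: k for k, v in PWM_DIR_LAYOUT.items()}
    for pwm in pwm_set:
        fname = names[(pwm.kind, pwm.gc_class)]
        write_pwm(pwm, os.path.join(str(pwm_dir), fname))


def obligate_column(base: str) -> dict[str, float]:
    """A column forced by the GT-AG rule: 0 for the obligate base, 1 for
    the rest."""
    return {b: 0.0 if b == base else 1.0 for b in BASES}


def background_column() -> dict[str, float]:
    return dict(BACKGROUND_NON_CONSENSUS)


def allelic_score_difference(
    pwm: Pwm,
    position: int,
    ref_base: str,
    alt_base: str,
    variant_id: str = "",
) -> AllelicScore:
    """|non-consensus(alt) - non-consensus(ref)| at one motif position."""
    s_ref = pwm.score(position, ref_base)
    s_alt = pwm.score(position, alt_base)
    return AllelicScore(
        variant_id=variant_id,
        motif_kind=pwm.kind,
        position_label=position,
        score_ref=s_ref,
        score_alt=s_alt,
        difference=abs(s_alt - s_ref),
    )


def indel_score_difference(
    pwm: Pwm,
    ref_seq: str,
    alt_seq: str,
    anchor: str,
    variant_id: str = "",
    position_offset: int = 0,
) -> AllelicScore:
    """Per-position sum of |Δ| over a motif frame re-read under each
    allele.

    ``ref_seq``/``alt_seq`` are the intron sequence under each allele
    (transcript orientation).  ``anchor`` is ``"five"`` (frame counted
    from the 5' end, donor motifs) or ``"three"`` (counted from the 3'
    end, acceptor/PPT and branch frames): an INDEL shifts downstream or
    upstream sequence through the frame, which is how multi-position
    differences arise.  ``position_offset`` shifts the frame (used to
    anchor a branch-point matrix at its adenosine's 3'-end offset).
    """
    detail = []
    total = 0.0
    for pos in pwm.positions:
        shifted = pos + position_offset
        if anchor == "five":
            i_ref = i_alt = shifted - 1
        elif anchor == "three":
            i_ref = len(ref_seq) + shifted
            i_alt = len(alt_seq) + shifted
        else:
            raise ValueError(f"anchor must be 'five' or 'three', got {anchor!r}")
        if not (0 <= i_ref < len(ref_seq) and 0 <= i_alt < len(alt_seq)):
            continue  # frame runs off a (too short) allele sequence
        s_ref = pwm.score(pos, ref_seq[i_ref])
        s_alt = pwm.score(pos, alt_seq[i_alt])
        detail.append((pos, s_ref, s_alt))
        total += abs(s_alt - s_ref)
    return AllelicScore(
        variant_id=variant_id,
        motif_kind=pwm.kind,
        position_label=None,
        score_ref=None,
        score_alt=None,
        difference=total,
        detail=detail,
    )


def disease_impact(
    variant_id: str,
    ld_table: pd.DataFrame | None,
    gwas_table: pd.DataFrame | None,
) -> float:
    """max over (LD partner, disease) of r^2 x -log10(p), 0 if untyped.

    The variant is in perfect LD with itself (r^2 = 1), so being typed
    directly in a GWAS contributes -log10(p) itself.  Rows with p
    outside (0, 1] are rejected with a warning.
    """
    if gwas_table is None or len(gwas_table) == 0:
        return 0.0
    partners: dict[str, float] = {variant_id: 1.0}
    if ld_table is not None:
        for _, row in ld_table.iterrows():
            r2 = float(row["r2"])
            if row["snp_a"] == variant_id:
                partners[row["snp_b"]] = max(partners.get(row["snp_b"], 0.0), r2)
            elif row["snp_b"] == variant_id:
                partners[row["snp_a"]] = max(partners.get(row["snp_a"], 0.0), r2)
    best = 0.0
    for _, row in gwas_table.iterrows():
        snp = row["snp_id"]
        if snp not in partners:
            continue
        p = float(row["pvalue"])
        if not 0.0 < p <= 1.0:
            warnings.warn(
                f"GWAS row for {snp} ({row['disease']}): p-value {p} outside (0,1]; "
                "row rejected"
            )
            continue
        best = max(best, partners[snp] * -math.log10(p))
    return best
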