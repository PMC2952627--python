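"""Per-allele splice-site prediction windows and multi-tool aggregation.

Each donor- or acceptor-side candidate yields a pair of 60-nt windows
(20 exonic + 40 intronic around the transcript splice site), one per
allele.  External predictors are represented by an adapter table (they
are web tools with unstable versions); an internal PWM consensus
predictor makes the pipeline runnable offline.  Tool scores stay on
their native scales -- comparisons are within-tool only.

The per-tool difference score follows the asymmetric rule used for
splice-prediction screens: |score_ref - score_alt| when both alleles
have a predicted site at the annotated position, the surviving allele's
score when only one does, and 0 (recorded as "site not predicted") when
neither does.  A candidate is multi-tool supported when at least two
tools give a difference greater than zero, which guards against
over-prediction by any single tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import pandas as pd

from . import motif_annotation as ma
from . import scoring as sc

EXONIC_FLANK = 20
INTRONIC_FLANK = 40
WINDOW_LENGTH = EXONIC_FLANK + INTRONIC_FLANK

DONOR = "donor"
ACCEPTOR = "acceptor"

#: internal predictor's consensus-score floor (mean per-position
#: consensus strength in [0,1] required to call a site)
DEFAULT_SCORE_FLOOR = 0.5

INTERNAL_TOOL = "internal_pwm"


@dataclass
class PredictionWindow:
    candidate_id: str
    allele: str
    side: str  # donor or acceptor
    sequence: str
    site_offset: int  # index of the first base 3' of the splice junction
    variant_index: int
    truncated: bool = False


@dataclass
class PredictorResult:
    site_found: bool
    score: float | None
    site_position: int | None


@dataclass
class ToolDifference:
    tool: str
    score_ref: float | None
    score_alt: float | None
    site_found_ref: bool
    site_found_alt: bool
    difference: float = field(init=False)
    site_not_predicted: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.site_found_ref and self.site_found_alt:
            self.difference = abs(self.score_ref - self.score_alt)
            self.site_not_predicted = False
        elif self.site_found_ref:
            self.difference = self.score_ref
            self.site_not_predicted = False
        elif self.site_found_alt:
            self.difference = self.score_alt
            self.site_not_predicted = False
        else:
            self.difference = 0.0
            self.site_not_predicted = True


@dataclass
class AggregateRecord:
    candidate_id: str
    tool_differences: list[ToolDifference]
    support_count: int
    multi_tool_supported: bool
    average_difference: float


def build_windows(
    candidate_id: str,
    intron_seq: str,
    upstream_exon_seq: str,
    downstream_exon_seq: str,
    variant_offset: int,
    alleles: dict[str, str],
    side: str,
) -> dict[str, PredictionWindow]:
    """Per-allele 60-nt windows around the annotated splice site.

    Donor side: last 20 exonic + first 40 intronic bases, junction at
    window index 20.  Acceptor side: last 40 intronic + first 20 exonic
    bases, junction at index 40.  The variant (SNP) must fall inside
    the window; insufficient flanks truncate the window with a flag.
    """
    intron_seq = intron_seq.upper()
    up = upstream_exon_seq.upper()
    down = downstream_exon_seq.upper()
    n = len(intron_seq)
    out = {}
    for name, allele in alleles.items():
        with_allele = (
            intron_seq[:variant_offset] + allele + intron_seq[variant_offset + 1:]
        )
        if side == DONOR:
            exonic = up[-EXONIC_FLANK:]
            intronic = with_allele[:INTRONIC_FLANK]
            seq = exonic + intronic
            site_offset = len(exonic)
            variant_index = site_offset + variant_offset
        elif side == ACCEPTOR:
            intronic = with_allele[-INTRONIC_FLANK:]
            exonic = down[:EXONIC_FLANK]
            seq = intronic + exonic
            site_offset = len(intronic)
            variant_index = site_offset + (variant_offset - n)  # negative offset
        else:
            raise ValueError(f"side must be donor or acceptor, got {side!r}")
        if not 0 <= variant_index < len(seq):
            raise ValueError(
                f"variant at intron offset {variant_offset} lies outside the "
                f"{side} window of candidate {candidate_id}"
            )
        out[name] = PredictionWindow(
            candidate_id=candidate_id,
            allele=name,
            side=side,
            sequence=seq,
            site_offset=site_offset,
            variant_index=variant_index,
            truncated=len(seq) < WINDOW_LENGTH,
        )
    return out


def _site_score(window_seq: str, pos: int, pwm: sc.Pwm, side: str) -> float | None:
    """Mean consensus strength of the motif frame for a site at ``pos``
    (= index of the first intronic base for donors, first exonic base
    for acceptors).  None when the frame runs off the window or when an
    obligate position (the GT/AG dinucleotide) is destroyed -- the
    GT-AG rule makes such sites unsplicable regardless of the rest of
    the motif."""
    if side == DONOR:
        frame = window_seq[pos: pos + 6]
        labels = list(range(1, 7))
    else:
        frame = window_seq[pos - 15: pos]
        labels = list(range(-15, 0))
        if pos < 15:
            return None
    if len(frame) != len(labels):
        return None
    obligate = pwm.obligate_positions()
    for lbl, b in zip(labels, frame):
        if lbl in obligate and b != obligate[lbl]:
            return None
    return mean(pwm.consensus_strength(lbl, b) for lbl, b in zip(labels, frame))


def internal_predict(
    window: PredictionWindow,
    pwm_set: sc.PwmSet,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> PredictorResult:
    """PWM consensus predictor: a site is reported at the annotated
    offset when its mean consensus strength reaches the floor."""
    kind = sc.KIND_FIVE if window.side == DONOR else sc.KIND_THREE
    gc = ma.gc_fraction(window.sequence)
    pwm = pwm_set.select(kind, gc)
    score = _site_score(window.sequence, window.site_offset, pwm, window.side)
    if score is None or score < score_floor:
        return PredictorResult(site_found=False, score=None, site_position=None)
    return PredictorResult(site_found=True, score=score, site_position=window.site_offset)


def scan_sites(
    window_seq: str,
    pwm: sc.Pwm,
    side: str,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[tuple[int, float]]:
    """All window positions whose consensus score reaches the floor
    (used to audit the predictor against a threshold scan)."""
    out = []
    for pos in range(len(window_seq) + 1):
        s = _site_score(window_seq, pos, pwm, side)
        if s is not None and s >= score_floor:
            out.append((pos, s))
    return out


def internal_tool_difference(
    ref_window: PredictionWindow,
    alt_window: PredictionWindow,
    pwm_set: sc.PwmSet,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> ToolDifference:
    r = internal_predict(ref_window, pwm_set, score_floor)
    a = internal_predict(alt_window, pwm_set, score_floor)
    return ToolDifference(
        tool=INTERNAL_TOOL,
        score_ref=r.score,
        score_alt=a.score,
        site_found_ref=r.site_found,
        site_found_alt=a.site_found,
    )


def read_adapter_tsv(path) -> dict[str, list[ToolDifference]]:
    """External predictor results: TSV with columns candidate_id, tool,
    allele (ref/alt), site_found (0/1), score, site_position."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["candidate_id", "tool", "allele", "site_found", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"adapter table {path}: missing columns {missing}")
    grouped: dict[tuple[str, str], dict[str, tuple[bool, float | None]]] = {}
    for _, row in df.iterrows():
        found = str(row["site_found"]).strip().lower() in ("1", "true", "yes")
        score = float(row["score"]) if found else None
        grouped.setdefault((row["candidate_id"], row["tool"]), {})[
            row["allele"].lower()
        ] = (found, score)
    out: dict[str, list[ToolDifference]] = {}
    for (cid, tool), sides in grouped.items():
        fr, sr = sides.get("ref", (False, None))
        fa, sa = sides.get("alt", (False, None))
        out.setdefault(cid, []).append(
            ToolDifference(
                tool=tool, score_ref=sr, score_alt=sa,
                site_found_ref=fr, site_found_alt=fa,
            )
        )
    return out


def aggregate(
    candidate_id: str,
    tool_differences: list[ToolDifference],
    min_tools: int = 2,
) -> AggregateRecord:
    """Count tools with a positive difference; multi-tool support needs
    at least ``min_tools``.  The average difference runs over all
    reporting tools, with no-site cases contributing 0."""
    if not tool_differences:
        raise ValueError("aggregate requires at least one tool result")
    support = sum(1 for t in tool_differences if t.difference > 0)
    return AggregateRecord(
        candidate_id=candidate_id,
        tool_differences=sorted(tool_differences, key=lambda t: t.tool),
        support_count=support,
        multi_tool_supported=support >= min_tools,
        average_difference=mean(t.difference for t in tool_differences),
    )
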