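"""Splice-motif extraction and intron composition annotation.

Motif geometry (offsets are intron-relative; +1 is the first intronic
base, -1 the last):

* donor splice site (``five_ss``): +1..+6, the GT plus four preference
  bases;
* acceptor splice site (``three_ss``): -3..-1, the YAG;
* polypyrimidine tract (``ppt``): -15..-4, the 12-base pyrimidine run
  bound by PTB/U2AF;
* branch point (``branch_point``): every YTNAY 5-mer lying wholly within
  -34..-21, the region where the branch adenosine is sought in human
  introns.

All extraction is on the intron's transcript-orientation sequence, so it
is strand-agnostic by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_model import Intron

FIVE_SS = "five_ss"
THREE_SS = "three_ss"
PPT = "ppt"
BRANCH_POINT = "branch_point"

#: inclusive signed-offset spans of the fixed regions
REGION_SPANS = {
    FIVE_SS: (1, 6),
    THREE_SS: (-3, -1),
    PPT: (-15, -4),
}
BRANCH_WINDOW = (-34, -21)  # all 5 branch bases must fall in here
BRANCH_RE = re.compile(r"[CT]T[ACGT]A[CT]")

_PY = frozenset("CT")


@dataclass
class MotifRegion:
    """A motif occurrence within one intron.

    ``offset_start``/``offset_end`` are inclusive signed intron offsets
    (positive = 5'-anchored, negative = 3'-anchored).  For branch points
    ``branch_a_offset`` marks the branch adenosine (the A of YTNAY).
    """

    kind: str
    offset_start: int
    offset_end: int
    sequence: str
    branch_a_offset: int | None = None

    def indices(self, intron_length: int) -> tuple[int, int]:
        """Python slice bounds of the region within the intron sequence."""
        return (
            signed_offset_to_index(self.offset_start, intron_length),
            signed_offset_to_index(self.offset_end, intron_length) + 1,
        )

    def contains_index(self, i: int, intron_length: int) -> bool:
        lo, hi = self.indices(intron_length)
        return lo <= i < hi


@dataclass
class MotifSet:
    """Extraction result: the regions present plus which were omitted
    because the intron was too short to define them."""

    five_ss: MotifRegion | None = None
    three_ss: MotifRegion | None = None
    ppt: MotifRegion | None = None
    branch_points: list[MotifRegion] = field(default_factory=list)
    omitted: set[str] = field(default_factory=set)

    @property
    def regions(self) -> list[MotifRegion]:
        out = [r for r in (self.five_ss, self.three_ss, self.ppt) if r is not None]
        out.extend(self.branch_points)
        return out


@dataclass
class IntronAnnotation:
    gc_fraction: float
    gc_class: str
    ppt_pyrimidine_fraction: float | None
    ese_count_flanking_exons: int
    g_triplet_count: int
    g_triplet_pair_count: int
    branch_point_matches: list[MotifRegion]


def signed_offset_to_index(offset: int, intron_length: int) -> int:
    """Map a signed intron offset (+1 first base, -1 last base) to a
    0-based sequence index."""
    if offset == 0:
        raise ValueError("offset 0 is undefined; offsets are +/-1-based")
    return offset - 1 if offset > 0 else intron_length + offset


def index_to_offsets(i: int, intron_length: int) -> tuple[int, int]:
    """Both signed offsets (positive, negative) of a 0-based index."""
    return i + 1, i - intron_length


def extract_motif_regions(intron: Intron) -> MotifSet:
    """Extract donor, acceptor, PPT and branch-point regions.

    Regions whose span exceeds the intron length are omitted and listed
    in ``MotifSet.omitted``.  Introns of length >= 21 carry all three
    fixed regions without overlap; >= 25 admits branch-point scanning.
    """
    seq = intron.sequence.upper()
    n = len(seq)
    out = MotifSet()
    for kind, (a, b) in REGION_SPANS.items():
        span = abs(b - a) + 1
        if n < span or (a < 0 and n < -a):
            out.omitted.add(kind)
            continue
        lo = signed_offset_to_index(a, n)
        hi = signed_offset_to_index(b, n) + 1
        region = MotifRegion(kind, a, b, seq[lo:hi])
        setattr(out, kind, region)
    bps = find_branch_points(intron)
    if bps:
        out.branch_points = bps
    elif n < -BRANCH_WINDOW[1] + 4:  # no 5-mer can fit in the window
        out.omitted.add(BRANCH_POINT)
    return out


def find_branch_points(intron: Intron) -> list[MotifRegion]:
    """All YTNAY matches whose 5 bases lie wholly within -34..-21 from
    the intron 3' end.  Overlapping matches are all returned; introns
    shorter than 34 scan the available suffix of the window."""
    seq = intron.sequence.upper()
    n = len(seq)
    lo_off, hi_off = BRANCH_WINDOW
    out = []
    # start offsets for a 5-mer wholly inside the window
    for start_off in range(max(lo_off, -n), hi_off - 4 + 1):
        i = signed_offset_to_index(start_off, n)
        window = seq[i:i + 5]
        if len(window) == 5 and BRANCH_RE.fullmatch(window):
            out.append(
                MotifRegion(
                    BRANCH_POINT,
                    start_off,
                    start_off + 4,
                    window,
                    branch_a_offset=start_off + 3,
                )
            )
    return out


def pyrimidine_fraction(seq: str) -> float:
    """Fraction of C/T bases in a sequence (PPT richness)."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for b in seq.upper() if b in _PY) / len(seq)


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for b in seq.upper() if b in "GC") / len(seq)


def count_overlapping(seq: str, pattern: str) -> int:
    """Occurrences of ``pattern`` in ``seq``, overlaps counted."""
    count = 0
    start = 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def g_triplets(seq: str) -> list[int]:
    """Start indices of (overlapping) GGG runs, a suggested intronic
    splicing enhancer."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 2) if seq[i:i + 3] == "GGG"]


def g_triplet_pairs(starts: list[int]) -> int:
    """Pairs of distinct (non-overlapping) G-triplets separated by fewer
    than 4 intervening bases: start distance in [3, 7)."""
    count = 0
    for a in range(len(starts)):
        for b in range(a + 1, len(starts)):
            d = starts[b] - starts[a]
            if 3 <= d < 7:
                count += 1
    return count


def count_ese(exon_seq: str, ese_hexamers: list[str]) -> int:
    """Total (overlapping) occurrences of any listed exonic splice
    enhancer hexamer in an exon sequence."""
    seq = exon_seq.upper()
    return sum(count_overlapping(seq, h) for h in ese_hexamers)


def load_ese_hexamers(path) -> list[str]:
    """Plain-text ESE list, one hexamer per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            word = line.split("#")[0].strip().upper()
            if not word:
                continue
            if len(word) != 6 or any(b not in "ACGT" for b in word):
                raise ValueError(f"invalid ESE hexamer {word!r} in {path}")
            out.append(word)
    return out


def annotate_composition(
    intron: Intron,
    flanking_exons: list[str],
    ese_hexamers: list[str],
) -> IntronAnnotation:
    """Composition statistics for one intron plus its flanking exons.

    GC class uses the 50% boundary that switches the donor/acceptor
    scoring matrices; exactly 50% is classed GC-rich (deterministic
    tie-break).  PPT pyrimidine fraction is computed over the 12-base
    -15..-4 region and is ``None`` when the intron is too short.
    """
    seq = intron.sequence.upper()
    motifs = extract_motif_regions(intron)
    gc = gc_fraction(seq)
    ppt_frac = (
        pyrimidine_fraction(motifs.ppt.sequence) if motifs.ppt is not None else None
    )
    starts = g_triplets(seq)
    return IntronAnnotation(
        gc_fraction=gc,
        gc_class="gc_rich" if gc >= 0.5 else "gc_poor",
        ppt_pyrimidine_fraction=ppt_frac,
        ese_count_flanking_exons=sum(count_ese(e, ese_hexamers) for e in flanking_exons),
        g_triplet_count=len(starts),
        g_triplet_pair_count=g_triplet_pairs(starts),
        branch_point_matches=motifs.branch_points,
    )
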