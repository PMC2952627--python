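"""Shared fixtures: tiny in-memory genomes and random transcript models."""

from __future__ import annotations

import numpy as np
import pytest

from stepminer.genome_model import Intron, TranscriptModel

BASES = "ACGT"


def make_intron(seq: str, strand: str = "+", start: int = 0) -> Intron:
    return Intron(
        transcript_id="t", index=1, chrom="chr1", strand=strand,
        start=start, end=start + len(seq), sequence=seq, is_5utr=True,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def random_transcript(
    rng: np.random.Generator,
    chrom: str = "chr1",
    n_exons: int | None = None,
    coding: bool = True,
) -> TranscriptModel:
    """A random valid transcript: 2-5 exons of length 10-60 separated by
    introns of length 5-80, random strand, cds_start uniform over exonic
    positions when coding."""
    n_exons = n_exons or int(rng.integers(2, 6))
    pos = int(rng.integers(0, 50))
    genomic = []
    for _ in range(n_exons):
        length = int(rng.integers(10, 61))
        genomic.append((pos, pos + length))
        pos += length + int(rng.integers(5, 81))
    strand = "+" if rng.random() < 0.5 else "-"
    cds_start = None
    if coding:
        es, eexp = genomic[int(rng.integers(0, n_exons))]
        cds_start = int(rng.integers(es, eexp))
    return TranscriptModel(
        transcript_id=f"t{rng.integers(1e9)}",
        gene_id="g",
        chrom=chrom,
        strand=strand,
        exons=genomic if strand == "+" else genomic[::-1],
        cds_start=cds_start,
    )


def genome_for(transcripts, rng: np.random.Generator) -> dict[str, str]:
    """Random genome dict covering every transcript span."""
    length = max(t.span[1] for t in transcripts) + 10
    chroms = {t.chrom for t in transcripts}
    return {c: random_seq(rng, length) for c in chroms}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
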