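"""Candidate detection, pattern classification and the summary report."""

import numpy as np
import pytest

from stepminer import mining
from stepminer import synthetic_fixtures as sf
from stepminer.genome_model import Intron, TranscriptModel, Variant

from conftest import random_seq


@pytest.fixture(scope="module")
def pwm_set():
    return sf.synthetic_pwm_set()


def _toy_gene(rng, intron_seq):
    """Plus-strand gene: exon1 [0,40), 5' UTR intron, exon2 with CDS at
    +10, then a coding intron and exon3."""
    n = len(intron_seq)
    e2_start = 40 + n
    exons = [(0, 40), (e2_start, e2_start + 50),
             (e2_start + 100, e2_start + 150)]
    t = TranscriptModel(
        transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
        exons=exons, cds_start=e2_start + 10,
    )
    genome_seq = list(random_seq(rng, exons[-1][1] + 10))
    genome_seq[40:40 + n] = intron_seq
    return t, {"chr1": "".join(genome_seq)}


class TestFindCandidates:
    def test_donor_ppt_and_coding_intron_filter(self, rng, pwm_set):
        intron = sf._build_intron(np.random.default_rng(1), 120, True)
        t, genome = _toy_gene(rng, intron)
        variants = [
            # donor +2 of the 5' UTR intron
            Variant("rs_don", "chr1", 41, intron[1], ["A" if intron[1] != "A" else "C"]),
            # PPT -10 (intron index 110)
            Variant("rs_ppt", "chr1", 40 + 110, intron[110],
                    ["A" if intron[110] != "A" else "C"]),
            # inside the coding intron: not a 5' UTR candidate
            Variant("rs_cds", "chr1", t.exons[1][1] + 5,
                    genome["chr1"][t.exons[1][1] + 5], ["A"]),
        ]
        if variants[2].ref == "A":
            variants[2].alts = ["C"]
        cands = mining.find_candidates([t], variants, pwm_set, genome)
        by_id = {c.variant_id: c for c in cands}
        assert set(by_id) == {"rs_don", "rs_ppt"}
        assert by_id["rs_don"].motif_kind == "five_ss"
        assert by_id["rs_don"].position_label == 2
        assert by_id["rs_don"].score_difference == 1.0  # obligate T destroyed
        assert by_id["rs_ppt"].motif_kind == "ppt"
        assert by_id["rs_ppt"].position_label == -10

    def test_reference_mismatch_excluded_with_warning(self, rng, pwm_set):
        intron = sf._build_intron(np.random.default_rng(2), 120, True)
        t, genome = _toy_gene(rng, intron)
        wrong_ref = "C" if intron[1] != "C" else "G"
        v = Variant("rs_bad", "chr1", 41, wrong_ref, ["A"])
        with pytest.warns(UserWarning, match="disagrees with genome"):
            assert mining.find_candidates([t], [v], pwm_set, genome) == []

    def test_triallelic_takes_max_pair_difference(self, rng, pwm_set):
        intron = sf._build_intron(np.random.default_rng(3), 120, True)
        t, genome = _toy_gene(rng, intron)
        ref = intron[0]  # obligate G at +1
        v = Variant("rs_tri", "chr1", 40, ref, [b for b in "ACT" if b != ref][:2])
        (c,) = mining.find_candidates([t], [v], pwm_set, genome)
        assert c.tri_allelic
        assert c.score_difference == 1.0
        assert len(c.pair_scores) == 2


class TestClassifyPattern:
    def _intron(self, start, end):
        return Intron("host", 1, "chr1", "+", start, end, "N" * (end - start))

    def _t(self, tid, exons, cds=None):
        return TranscriptModel(tid, "g", "chr1", "+", exons, cds)

    def test_spanning_exon_is_intron_retention(self):
        host = self._t("host", [(0, 40), (100, 200)], 130)
        span = self._t("o1", [(0, 150), (180, 200)])
        labels = mining.classify_pattern(self._intron(40, 100), [host, span], "host")
        assert labels == {mining.INTRON_RETENTION}

    def test_shifted_intron_is_alternative_splice_site(self):
        host = self._t("host", [(0, 40), (100, 200)], 130)
        alt = self._t("o1", [(0, 60), (100, 200)])  # intron [60,100): same 3' end
        labels = mining.classify_pattern(self._intron(40, 100), [host, alt], "host")
        assert labels == {mining.ALTERNATIVE_SPLICE_SITE}

    def test_downstream_transcript_is_upstream_start(self):
        host = self._t("host", [(0, 40), (100, 200)], 130)
        down = self._t("o1", [(120, 160), (180, 200)])
        labels = mining.classify_pattern(self._intron(40, 100), [host, down], "host")
        assert labels == {mining.UPSTREAM_TRANSCRIPT_START}

    def test_single_transcript_gene_has_no_evidence(self):
        host = self._t("host", [(0, 40), (100, 200)], 130)
        assert mining.classify_pattern(self._intron(40, 100), [host], "host") == set()

    def test_identical_intron_in_other_transcript_adds_nothing(self):
        host = self._t("host", [(0, 40), (100, 200)], 130)
        twin = self._t("o1", [(10, 40), (100, 150)])
        labels = mining.classify_pattern(self._intron(40, 100), [host, twin], "host")
        assert labels == set()

    def test_labels_monotone_under_added_transcripts(self, rng):
        """Adding a transcript never removes retention or alternative
        splice site evidence."""
        from conftest import random_transcript

        keep = {mining.INTRON_RETENTION, mining.ALTERNATIVE_SPLICE_SITE}
        for _ in range(200):
            ts = [random_transcript(rng) for _ in range(int(rng.integers(2, 5)))]
            for t in ts:
                t.gene_id = "g"
            host = ts[0]
            gi = host.genomic_introns()
            if not gi:
                continue
            s, e = gi[0]
            intron = Intron(host.transcript_id, 1, "chr1", host.strand, s, e,
                            "N" * (e - s))
            before = mining.classify_pattern(intron, ts[:-1], host.transcript_id)
            after = mining.classify_pattern(intron, ts, host.transcript_id)
            assert before & keep <= after & keep


class TestSummary:
    def _candidate(self, vid, kind, vclass="SNP", ref="A", alt="G", tri=False,
                   diff=0.5, impact=1.0):
        return mining.CandidateStep(
            variant_id=vid, gene_id="g", transcript_id="t", intron_index=1,
            chrom="chr1", strand="+", intron_start=0, intron_end=100,
            motif_kind=kind, position_label=1, vclass=vclass, tri_allelic=tri,
            score_ref=0.0, score_alt=diff, score_difference=diff,
            disease_impact=impact, ref_t=ref, alt_t=alt,
        )

    def test_counts_match_planting(self):
        cands = [
            self._candidate("v1", "five_ss", ref="A", alt="G"),  # transition
            self._candidate("v2", "five_ss", ref="A", alt="C"),  # transversion
            self._candidate("v3", "ppt", vclass="INDEL"),
            self._candidate("v4", "branch_point", tri=True),
            self._candidate("v5", "three_ss", vclass="other"),
            self._candidate("v1", "five_ss"),  # duplicate row, counted once
        ]
        rep = mining.summarize(cands)
        c = rep.counts
        assert c.loc["candidates", "five_ss"] == 2
        assert c.loc["transitions", "five_ss"] == 1
        assert c.loc["transversions", "five_ss"] == 1
        assert c.loc["indels", "ppt"] == 1
        assert c.loc["tri_allelic", "branch_point"] == 1
        assert c.loc["other", "three_ss"] == 1
        assert c.loc["candidates", "total"] == 5
        assert mining.check_summary_consistency(c)

    def test_transition_transversion_definition(self):
        assert mining.is_transition("A", "G")
        assert mining.is_transition("C", "T")
        assert not mining.is_transition("A", "C")
        assert not mining.is_transition("G", "T")

    def test_empty_candidate_set_gives_all_zero_table(self):
        rep = mining.summarize([])
        assert (rep.counts.to_numpy() == 0).all()
        assert mining.check_summary_consistency(rep.counts)

    def test_consistency_checker_rejects_corrupt_table(self):
        rep = mining.summarize([self._candidate("v1", "five_ss")])
        bad = rep.counts.copy()
        bad.loc["candidates", "total"] += 1
        with pytest.raises(ValueError, match="total"):
            mining.check_summary_consistency(bad)
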