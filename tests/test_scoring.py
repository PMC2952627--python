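"""Non-consensus PWM scoring: worked values, INDEL frames, disease impact."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepminer import scoring as sc

bases = st.sampled_from("ACGT")


@pytest.fixture
def donor_pwm() -> sc.Pwm:
    """Obligate GT start, background elsewhere."""
    table = {1: sc.obligate_column("G"), 2: sc.obligate_column("T")}
    for p in range(3, 7):
        table[p] = sc.background_column()
    return sc.Pwm(sc.KIND_FIVE, sc.GC_ANY, table)


def test_obligate_base_change_scores_one(donor_pwm):
    s = sc.allelic_score_difference(donor_pwm, 1, "G", "A")
    assert s.difference == 1.0


def test_background_transition_scores_one_tenth(donor_pwm):
    s = sc.allelic_score_difference(donor_pwm, 3, "A", "G")
    assert s.difference == pytest.approx(0.1)


def test_identical_alleles_score_zero(donor_pwm):
    assert sc.allelic_score_difference(donor_pwm, 4, "A", "A").difference == 0.0


class TestLoader:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    def test_obligate_position_detected(self, tmp_path):
        p = tmp_path / "pwm.tsv"
        self._write(p, [["+1", 1, 1, 0, 1], ["+2", 0.8, 0.7, 0.7, 0.8]])
        pwm = sc.load_pwm(p, sc.KIND_FIVE)
        assert pwm.obligate_positions() == {1: "G"}

    def test_out_of_range_entry_rejected(self, tmp_path):
        p = tmp_path / "pwm.tsv"
        self._write(p, [["+1", 1.2, 1, 0, 1]])
        with pytest.raises(ValueError, match=r"\+1"):
            sc.load_pwm(p, sc.KIND_FIVE)

    def test_missing_base_column_rejected(self, tmp_path):
        p = tmp_path / "pwm.tsv"
        p.write_text("pos\tA\tC\tG\n+1\t1\t1\t0\n")
        with pytest.raises(ValueError, match="missing columns"):
            sc.load_pwm(p, sc.KIND_FIVE)

    def test_background_file_from_genome_frequencies_accepted(self, tmp_path):
        p = tmp_path / "pwm.tsv"
        self._write(p, [["+1", 0.8, 0.7, 0.7, 0.8]])
        pwm = sc.load_pwm(p, sc.KIND_FIVE)
        assert pwm.score(1, "A") == 0.8 and pwm.score(1, "C") == 0.7

    def test_round_trip(self, tmp_path, donor_pwm):
        sc.write_pwm(donor_pwm, tmp_path / "d.tsv")
        back = sc.load_pwm(tmp_path / "d.tsv", sc.KIND_FIVE)
        assert back.table == donor_pwm.table


def test_select_pwm_gc_boundary():
    rich = sc.Pwm(sc.KIND_FIVE, sc.GC_RICH, {1: sc.background_column()})
    poor = sc.Pwm(sc.KIND_FIVE, sc.GC_POOR, {1: sc.obligate_column("G")})
    pwms = sc.PwmSet([rich, poor])
    assert pwms.select(sc.KIND_FIVE, 0.6) is rich
    assert pwms.select(sc.KIND_FIVE, 0.4) is poor
    assert pwms.select(sc.KIND_FIVE, 0.5) is rich  # documented tie-break
    with pytest.raises(KeyError):
        pwms.select(sc.KIND_THREE, 0.6)


class TestIndelScoring:
    def test_deletion_shifting_perfect_donor_matches_bruteforce(self, donor_pwm):
        ref = "GTAAGT" + "ACGTACGT"
        alt = ref[:1] + ref[2:]  # delete the obligate T at +2
        got = sc.indel_score_difference(donor_pwm, ref, alt, "five").difference
        expected = sum(
            abs(donor_pwm.table[p][alt[p - 1]] - donor_pwm.table[p][ref[p - 1]])
            for p in range(1, 7)
        )
        assert got == pytest.approx(expected)
        assert got > 1.0  # multi-position event exceeds the SNP bound

    def test_insertion_recreating_identical_motif_scores_zero(self, donor_pwm):
        ref = "GTAAGTACGT"
        alt = "GTAAGT" + "GTAAGTACGT"[6:]  # same first six bases
        assert sc.indel_score_difference(donor_pwm, ref, alt, "five").difference == 0.0

    def test_uniform_matrix_is_score_invariant(self):
        uniform = sc.Pwm(
            sc.KIND_FIVE, sc.GC_ANY, {p: {b: 0.5 for b in sc.BASES} for p in range(1, 7)}
        )
        ref = "GTAAGTACGTAC"
        alt = ref[:3] + ref[4:]
        assert sc.indel_score_difference(uniform, ref, alt, "five").difference == 0.0

    def test_three_prime_anchored_frame(self, rng):
        """Acceptor-side deletions shift upstream sequence through the
        3'-anchored frame; agrees with explicit end-anchored slicing."""
        pwm = sc.Pwm(
            sc.KIND_THREE, sc.GC_ANY,
            {p: sc.background_column() for p in range(-15, 0)} | {-1: sc.obligate_column("G")},
        )
        ref = "".join(rng.choice(list("ACGT"), size=40))
        alt = ref[:20] + ref[21:]
        got = sc.indel_score_difference(pwm, ref, alt, "three").difference
        expected = sum(
            abs(pwm.table[p][alt[len(alt) + p]] - pwm.table[p][ref[len(ref) + p]])
            for p in range(-15, 0)
        )
        assert got == pytest.approx(expected)


class TestDiseaseImpact:
    def _tables(self, ld_rows, gwas_rows):
        ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2", "dprime"])
        gw = pd.DataFrame(gwas_rows, columns=["snp_id", "disease", "pvalue"])
        return ld, gw

    def test_self_typed_variant(self):
        ld, gw = self._tables([], [("rs1", "d", 0.1)])
        assert sc.disease_impact("rs1", ld, gw) == pytest.approx(1.0)

    def test_max_over_partner_products(self):
        ld, gw = self._tables(
            [("rs1", "rsA", 0.5, 1.0), ("rs1", "rsB", 1.0, 1.0)],
            [("rsA", "d", 1e-4), ("rsB", "d", 1e-1)],
        )
        assert sc.disease_impact("rs1", ld, gw) == pytest.approx(2.0)

    def test_no_partner_scores_zero(self):
        ld, gw = self._tables([], [("rsZ", "d", 1e-8)])
        assert sc.disease_impact("rs1", ld, gw) == 0.0

    def test_invalid_pvalue_rejected_with_warning(self):
        ld, gw = self._tables([], [("rs1", "d", 0.0), ("rs1", "d2", 0.5)])
        with pytest.warns(UserWarning, match="rejected"):
            assert sc.disease_impact("rs1", ld, gw) == pytest.approx(-math.log10(0.5))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        r2=st.floats(0.0, 1.0),
        bump=st.floats(0.0, 0.5),
        p=st.floats(1e-10, 1.0, exclude_min=False),
        shrink=st.floats(0.1, 1.0),
    )
    def test_monotone_in_r2_and_significance(self, r2, bump, p, shrink):
        def impact(r2_, p_):
            ld, gw = self._tables([("rs1", "rsA", r2_, 1.0)], [("rsA", "d", p_)])
            return sc.disease_impact("rs1", ld, gw)

        base = impact(r2, p)
        assert impact(min(r2 + bump, 1.0), p) >= base - 1e-12
        assert impact(r2, max(p * shrink, 1e-300)) >= base - 1e-12


@settings(deadline=None, derandomize=True, max_examples=200)
@given(a=bases, b=bases, c=bases, pos=st.integers(1, 6))
def test_snp_difference_symmetry_bound_and_triangle(a, b, c, pos):
    table = {p: sc.background_column() for p in range(1, 7)}
    table[1] = sc.obligate_column("G")
    pwm = sc.Pwm(sc.KIND_FIVE, sc.GC_ANY, table)

    def d(x, y):
        return sc.allelic_score_difference(pwm, pos, x, y).difference

    assert d(a, b) == d(b, a)
    assert 0.0 <= d(a, b) <= 1.0
    assert d(a, b) <= d(a, c) + d(c, b) + 1e-12
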