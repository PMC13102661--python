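from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miredit import site_calling as sc
from miredit.precursor_align import PrecursorAlignment
from miredit.reference_io import SiteKey, SNPRecord

from _oracles import bh_stepup, binomial_tail_exact


def aln(seq, count, prec, start, body_len, mismatches=(), tail="", weight=1.0):
    return PrecursorAlignment(seq, count, prec, start, body_len, tuple(mismatches), tail, weight)


class TestPileups:
    def test_perfect_reads_feed_reference(self, toy_precursor):
        seq = toy_precursor.sequence
        read = seq[4:26]
        pileups = sc.build_pileups(
            [aln(read, 50, "toy-mir-1", 5, 22)], {"toy-mir-1": toy_precursor}
        )
        for pos in range(5, 27):
            pp = pileups["toy-mir-1"][pos]
            assert pp.weighted[seq[pos - 1]] == 50 and pp.coverage == 50

    def test_mismatch_counts_split(self, toy_precursor):
        seq = toy_precursor.sequence
        ref = seq[11]
        alt = next(b for b in "ACGT" if b != ref)
        clean = aln(seq[4:26], 90, "toy-mir-1", 5, 22)
        edited_read = seq[4:11] + alt + seq[12:26]
        edited = aln(edited_read, 10, "toy-mir-1", 5, 22, [(12, ref, alt)])
        pileups = sc.build_pileups([clean, edited], {"toy-mir-1": toy_precursor})
        pp = pileups["toy-mir-1"][12]
        assert pp.weighted[ref] == 90 and pp.weighted[alt] == 10

    def test_tail_base_lands_one_past_body(self, toy_precursor):
        a = aln(toy_precursor.sequence[4:26] + "A", 5, "toy-mir-1", 5, 22, tail="A")
        pileups = sc.build_pileups([a], {"toy-mir-1": toy_precursor})
        assert pileups["toy-mir-1"][27].raw["A"] == 5

    def test_overhang_beyond_precursor_not_callable(self, toy_precursor):
        read = toy_precursor.sequence[-20:] + "AA"
        a = aln(read, 5, "toy-mir-1", 61, 20, tail="AA")
        pileups = sc.build_pileups([a], {"toy-mir-1": toy_precursor})
        assert max(pileups["toy-mir-1"]) <= 80


class TestEditingLevel:
    @pytest.mark.parametrize(
        "counts, alt, expected",
        [({"A": 90, "G": 10}, "G", 0.10), ({"A": 0, "G": 10}, "G", 1.0),
         ({"A": 45, "G": 5}, "G", 0.10)],
    )
    def test_level_is_weighted_fraction(self, counts, alt, expected):
        pp = sc.PositionPileup("p", 1, "A")
        for nt, n in counts.items():
            pp.weighted[nt] = float(n)
        assert sc.editing_level(pp, alt) == pytest.approx(expected)


class TestBinomialPvalue:
    def test_closed_forms(self):
        assert sc.binomial_site_pvalue(0, 500) == 1.0
        assert sc.binomial_site_pvalue(10, 10) == pytest.approx(1e-30, rel=1e-9)
        assert sc.binomial_site_pvalue(1, 1000) == pytest.approx(
            1 - 0.999**1000, rel=1e-12
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(sc.SiteCallingError):
            sc.binomial_site_pvalue(5, 4)
        with pytest.raises(sc.SiteCallingError):
            sc.binomial_site_pvalue(1, 10, e=0.0)

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_matches_exact_rational_sum(self, a, b):
        """Survival-sum p equals a big-rational binomial tail for n <= 50."""
        n, k = max(a, b), min(a, b)
        if n == 0:
            return
        exact = float(binomial_tail_exact(k, n, Fraction(1, 1000)))
        assert sc.binomial_site_pvalue(k, n, 1e-3) == pytest.approx(
            exact, rel=1e-9, abs=1e-300
        )


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        assert sc.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert sc.bh_adjust([0.05]) == pytest.approx([0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(sc.SiteCallingError):
            sc.bh_adjust([0.2, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_bruteforce_and_monotone(self, pvals):
        got = sc.bh_adjust(pvals)
        assert got == pytest.approx(bh_stepup(pvals), abs=1e-12)
        order = np.argsort(pvals)
        assert all(
            got[order[i]] <= got[order[i + 1]] + 1e-12 for i in range(len(pvals) - 1)
        )


class TestCallSites:
    def _pileups_with_alt(self, toy_precursor, alt_count, ref_count, pos=12):
        seq = toy_precursor.sequence
        ref = seq[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        clean = aln(seq[4:26], ref_count, "toy-mir-1", 5, 22)
        edited_read = seq[4 : pos - 1] + alt + seq[pos:26]
        edited = aln(edited_read, alt_count, "toy-mir-1", 5, 22, [(pos, ref, alt)])
        return sc.build_pileups([clean, edited], {"toy-mir-1": toy_precursor}), alt

    def test_support_rule_blocks_nine_reads(self, toy_precursor):
        pileups, alt = self._pileups_with_alt(toy_precursor, 9, 991)
        calls = [c for c in sc.call_sites(pileups) if c.key.alt == alt and c.key.position == 12]
        assert calls and not calls[0].significant and calls[0].raw_support == 9

    def test_ten_of_hundred_significant(self, toy_precursor):
        pileups, alt = self._pileups_with_alt(toy_precursor, 10, 90)
        (call,) = [c for c in sc.call_sites(pileups) if c.key.alt == alt and c.key.position == 12]
        assert call.significant and call.level == pytest.approx(0.10)
        assert call.p < 1e-15

    def test_level_rule_blocks_four_percent(self, toy_precursor):
        pileups, alt = self._pileups_with_alt(toy_precursor, 10, 240)
        (call,) = [c for c in sc.call_sites(pileups) if c.key.alt == alt and c.key.position == 12]
        assert call.level == pytest.approx(0.04) and not call.significant


class TestClassify:
    def _call(self, key, level=0.3, mean_weight=1.0, arm="5p"):
        return sc.SiteCall(
            key=key, level=level, k=30, n=100, raw_support=30, raw_coverage=100,
            p=1e-20, p_adj=1e-19, significant=True, mean_weight=mean_weight,
            arm=arm, tail_fraction=0.0,
        )

    def test_central_a_to_g_in_seed_is_a_to_i(self, toy_precursor):
        pos = 5  # inside the 5p arm's seed (positions 3..9)
        ref = toy_precursor.sequence[pos - 1]
        key = SiteKey("toy-mir-1", pos, ref, "G" if ref != "G" else "A")
        got = sc.classify_site(self._call(key), toy_precursor)
        expected = "A-to-I" if (ref, key.alt) == ("A", "G") else "Other"
        assert got == expected

    def test_past_mature_end_keyed_by_added_base(self, toy_precursor):
        # one past the 5p arm's 3' end (position 24)
        ref = toy_precursor.sequence[23]
        for alt, expected in [("A", "3'-A"), ("T", "3'-U"), ("C", "3'-Other")]:
            if alt == ref:
                continue
            key = SiteKey("toy-mir-1", 24, ref, alt)
            assert sc.classify_site(self._call(key), toy_precursor) == expected

    def test_before_mature_start_is_5prime(self, toy_precursor):
        ref = toy_precursor.sequence[53]  # position 54, before the 3p arm at 55
        alt = next(b for b in "ACGT" if b != ref)
        key = SiteKey("toy-mir-1", 54, ref, alt)
        assert sc.classify_site(self._call(key, arm="3p"), toy_precursor) == "5'-editing"

    def test_low_mean_weight_is_pseudo(self, toy_precursor):
        key = SiteKey("toy-mir-1", 12, toy_precursor.sequence[11], "G"
                      if toy_precursor.sequence[11] != "G" else "A")
        got = sc.classify_site(self._call(key, mean_weight=0.2), toy_precursor)
        assert got == "Pseudo"

    def test_catalog_match_with_full_level_is_snp(self, toy_precursor):
        pos = 12
        ref = toy_precursor.sequence[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        key = SiteKey("toy-mir-1", pos, ref, alt)
        snp = SNPRecord(chrom="chrT", position=1000 + pos, ref=ref, alt=alt)
        call = self._call(key, level=0.4)
        # a 100% level elsewhere in the cohort triggers the SNP rule
        assert sc.classify_site(call, toy_precursor, [snp], {key: 1.0}) == "SNP"
        assert sc.classify_site(call, toy_precursor, [snp], {key: 0.9}) != "SNP"

    def test_classification_total_over_alternatives(self, toy_precursor):
        """Every candidate receives exactly one of the nine types."""
        for pos in (1, 5, 24, 40, 54, 60, 78):
            ref = toy_precursor.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                key = SiteKey("toy-mir-1", pos, ref, alt)
                got = sc.classify_site(self._call(key, arm=None), toy_precursor)
                assert got in sc.SITE_TYPES


class TestTptm:
    def test_scaling_and_linearity(self):
        assert sc.tptm(5, 10**6) == pytest.approx(50.0)
        assert sc.tptm(0, 100) == 0.0
        assert sc.tptm(14, 7_000_000) == pytest.approx(2 * sc.tptm(7, 7_000_000))

    def test_zero_total_rejected(self):
        with pytest.raises(sc.SiteCallingError):
            sc.tptm(5, 0)
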