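import numpy as np
import pytest

from navvar.enumeration import (AA_INDEX, CODON_TABLE, SequenceError,
                                census_frame, enumerate_missense,
                                expected_transition_frequencies,
                                observed_expected_ratio)

BASES = "ACGT"


def brute_force_targets(codon):
    """Independent 9-way enumeration of one codon's missense targets."""
    ref = CODON_TABLE[codon]
    targets = {}
    for i in range(3):
        for base in BASES:
            if base != codon[i]:
                alt = CODON_TABLE[codon[:i] + base + codon[i + 1:]]
                if alt not in ("*", ref):
                    targets[alt] = targets.get(alt, 0) + 1
    return targets


class TestEnumerateMissense:
    def test_lysine_codon_aaa(self):
        census = enumerate_missense("AAA")
        assert census.total_with_duplicates == 7  # TAA stop and AAG synonym excluded
        assert census.total_unique == 6
        assert sorted(census.per_codon[0].targets) == sorted("QETRIN")
        assert census.per_codon[0].targets["N"] == 2  # AAC and AAT both give Asn

    def test_methionine_codon_atg(self):
        census = enumerate_missense("ATG")
        assert census.total_with_duplicates == 9  # no stop or synonym reachable
        assert census.total_unique == 6
        assert sorted(census.per_codon[0].targets) == sorted("LVKTRI")

    def test_agrees_with_brute_force_on_every_sense_codon(self):
        for b1 in BASES:
            for b2 in BASES:
                for b3 in BASES:
                    codon = b1 + b2 + b3
                    if CODON_TABLE[codon] == "*":
                        continue
                    census = enumerate_missense(codon)
                    assert census.per_codon[0].targets == brute_force_targets(codon)

    def test_totals_sum_over_codons(self, toy_census):
        assert toy_census.total_with_duplicates == sum(
            c.with_duplicates for c in toy_census.per_codon)
        assert toy_census.total_unique <= toy_census.total_with_duplicates
        assert all(c.with_duplicates <= 9 for c in toy_census.per_codon)

    def test_transition_matrix_consistent_with_per_codon(self, toy_census):
        total = toy_census.transition_matrix.sum()
        assert total == toy_census.total_with_duplicates

    def test_synonymous_recoding_changes_census(self):
        # same dipeptide SK, different codons: the reachable set is
        # codon-dependent, so totals differ between silent recodings
        a = enumerate_missense("TCTAAA")
        b = enumerate_missense("AGTAAG")
        assert a.protein == b.protein == "SK"
        assert (a.total_with_duplicates, a.total_unique) != \
               (b.total_with_duplicates, b.total_unique)

    def test_internal_stop_warns_and_skips(self):
        with pytest.warns(UserWarning, match="stop"):
            census = enumerate_missense("AAATAAAAG")
        assert census.protein == "KK"

    def test_input_errors(self):
        with pytest.raises(SequenceError, match="position 2"):
            enumerate_missense("AXGAAA")
        with pytest.raises(SequenceError, match="divisible"):
            enumerate_missense("AAAA")

    def test_census_frame_rows_match_unique_total(self, toy_census):
        frame = census_frame(toy_census)
        assert len(frame) == toy_census.total_unique
        assert frame["n_nt_changes"].sum() == toy_census.total_with_duplicates


class TestExpectedFrequencies:
    def test_sums_to_one(self, toy_census):
        assert expected_transition_frequencies(toy_census).sum() == pytest.approx(1)

    def test_single_codon_weights(self):
        census = enumerate_missense("AAA")
        expected = expected_transition_frequencies(census)
        assert expected[AA_INDEX["K"], AA_INDEX["N"]] == pytest.approx(2 / 7)
        assert expected[AA_INDEX["K"], AA_INDEX["Q"]] == pytest.approx(1 / 7)
        # everything not reachable from Lys by one change is zero
        assert expected.sum() == pytest.approx(expected[AA_INDEX["K"], :].sum())

    def test_unreachable_transitions_zero(self, toy_census):
        expected = expected_transition_frequencies(toy_census)
        reachable = toy_census.transition_matrix > 0
        assert (expected[~reachable] == 0).all()


class TestObservedExpectedRatio:
    def test_proportional_sample_gives_unit_ratios(self, toy_census):
        observed = [(c.position, c.from_aa, to_aa)
                    for c in toy_census.per_codon
                    for to_aa, n in c.targets.items()
                    for _ in range(n)]
        ratio = observed_expected_ratio(observed, toy_census)
        defined = ~np.isnan(ratio)
        reachable = toy_census.transition_matrix > 0
        assert np.allclose(ratio[defined & reachable], 1.0)

    def test_empty_observed_gives_zero_ratios(self, toy_census):
        ratio = observed_expected_ratio([], toy_census)
        defined = ~np.isnan(ratio)
        assert (ratio[defined] == 0).all()

    def test_enrichment_arithmetic(self, toy_census):
        # hand arithmetic: k of n observations on one transition with
        # expected proportion e must give ratio (k/n)/e
        expected = expected_transition_frequencies(toy_census)
        codon = toy_census.per_codon[0]
        to_aa = sorted(codon.targets)[0]
        i, j = AA_INDEX[codon.from_aa], AA_INDEX[to_aa]
        other = toy_census.per_codon[1]
        other_to = sorted(other.targets)[0]
        observed = [(codon.position, codon.from_aa, to_aa)] * 5 + \
                   [(other.position, other.from_aa, other_to)] * 5
        ratio = observed_expected_ratio(observed, toy_census)
        assert ratio[i, j] == pytest.approx(0.5 / expected[i, j])

    def test_reference_mismatch_is_error(self, toy_census):
        wrong = "A" if toy_census.protein[0] != "A" else "C"
        with pytest.raises(SequenceError, match="mismatch"):
            observed_expected_ratio([(1, wrong, "G")], toy_census)

    def test_unreachable_observation_warns(self, toy_census):
        codon = toy_census.per_codon[0]
        unreachable = next(aa for aa in "ACDEFGHIKLMNPQRSTVWY"
                           if aa not in codon.targets and aa != codon.from_aa)
        with pytest.warns(UserWarning, match="not reachable"):
            observed_expected_ratio(
                [(codon.position, codon.from_aa, unreachable)], toy_census)
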