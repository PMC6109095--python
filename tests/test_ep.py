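import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from navvar.ep import (EPDataError, EPReport, Variant, build_problem_dataset,
                       build_shift_dataset, discretize_shift,
                       frame_to_reports, isoform2_to_isoform1,
                       load_reports_sqlite, load_reports_tsv, majority_vote,
                       reports_to_frame, resolve_variants,
                       save_reports_sqlite, save_reports_tsv,
                       select_preferred_report, split_train_test)

V = Variant(558, "H", "R")


def report(findings=None, study="s1", year=2005, cell="HEK", alpha="b",
           beta1="yes", variant=V, **kwargs):
    return EPReport(variant=variant, study_id=study, year=year,
                    cell_type=cell, alpha_subunit=alpha, beta1=beta1,
                    findings=findings or {}, **kwargs)


class TestMajorityVote:
    @pytest.mark.parametrize("findings, expected", [
        (["affected", "affected", "unaffected"], "affected"),
        (["affected", "unaffected"], "excluded_tie"),
        (["not_measured", "not_measured"], "unknown"),
        (["unaffected"], "unaffected"),
        (["affected", "not_measured", "unaffected", "unaffected"], "unaffected"),
    ])
    def test_examples(self, findings, expected):
        reports = [report({"activation": f}, study=f"s{i}")
                   for i, f in enumerate(findings)]
        assert majority_vote(reports, "activation") == expected

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.sampled_from(["affected", "unaffected", "not_measured"]),
                    min_size=1, max_size=6))
    def test_agrees_with_brute_force_counter(self, findings):
        reports = [report({"late": f}, study=f"s{i}")
                   for i, f in enumerate(findings)]
        n_aff = findings.count("affected")
        n_un = findings.count("unaffected")
        if n_aff > n_un:
            expected = "affected"
        elif n_un > n_aff:
            expected = "unaffected"
        elif n_aff:
            expected = "excluded_tie"
        else:
            expected = "unknown"
        assert majority_vote(reports, "late") == expected
        # permutation invariance
        assert majority_vote(reports[::-1], "late") == expected

    def test_mixed_variants_rejected(self):
        reports = [report(), report(variant=Variant(1, "M", "V"), study="s2")]
        with pytest.raises(EPDataError, match="mix"):
            majority_vote(reports, "activation")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(EPDataError):
            majority_vote([report()], "conductance")


class TestDiscretizeShift:
    @pytest.mark.parametrize("shift, expected", [
        (-3.0, "mid"), (3.0, "mid"), (3.01, "pos"), (-3.01, "neg"),
        (0.0, "mid"), (-50.0, "neg"), (12.5, "pos"),
    ])
    def test_boundaries(self, shift, expected):
        assert discretize_shift(shift) == expected

    @settings(deadline=None, max_examples=200)
    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    def test_partitions_the_reals(self, shift):
        assert discretize_shift(shift) in ("neg", "mid", "pos")

    def test_non_finite_rejected(self):
        with pytest.raises(EPDataError):
            discretize_shift(math.nan)


class TestPreferredReport:
    def test_beta1_beats_recency(self):
        older = report(study="old", year=2001, beta1="yes")
        newer = report(study="new", year=2010, beta1="no")
        assert select_preferred_report([newer, older]) is older

    def test_alpha_b_preferred_second(self):
        a = report(study="a", alpha="a")
        b = report(study="b", alpha="b")
        assert select_preferred_report([a, b]) is b

    def test_hek_preferred_third(self):
        oocyte = report(study="x", cell="oocyte")
        hek = report(study="y", cell="HEK")
        assert select_preferred_report([oocyte, hek]) is hek

    def test_most_recent_last(self):
        r04 = report(study="r04", year=2004)
        r12 = report(study="r12", year=2012)
        assert select_preferred_report([r04, r12]) is r12

    def test_filters_skip_when_they_would_empty_the_pool(self):
        # nobody co-expressed beta1: the beta1 filter must not drop everyone
        a = report(study="a", beta1="no", year=2002)
        b = report(study="b", beta1="unknown", year=2009)
        assert select_preferred_report([a, b]) is b

    def test_returns_element_of_input(self):
        reports = [report(study=f"s{i}", year=2000 + i, beta1=b, cell=c)
                   for i, (b, c) in enumerate(
                       itertools.product(["yes", "no"], ["HEK", "CHO"]))]
        assert select_preferred_report(reports) in reports

    def test_empty_list_rejected(self):
        with pytest.raises(EPDataError):
            select_preferred_report([])


class TestResolveAndDatasets:
    def test_single_affected_outcome_marks_variant_changed(self):
        records = resolve_variants([report({"inactivation": "affected"})])
        assert records[0].labels["inactivation"] == "affected"
        assert records[0].labels["changed_unchanged"] == "affected"

    def test_tie_excluded_and_counted(self):
        reports = [report({"activation": "affected"}, study="s1"),
                   report({"activation": "unaffected"}, study="s2"),
                   report({"activation": "affected"},
                          variant=Variant(9, "A", "T"), study="s3")]
        records = resolve_variants(reports)
        dataset, excluded = build_problem_dataset(records, "activation")
        assert len(dataset) == 1
        assert excluded == pytest.approx(0.5)

    def test_all_unknown_variant_absent(self):
        records = resolve_variants([report({})])
        dataset, excluded = build_problem_dataset(records, "activation")
        assert dataset.empty
        assert excluded == 0.0

    def test_shift_dataset_uses_preferred_report(self):
        preferred = report({"inactivation": "affected"}, study="s1",
                           beta1="yes", inact_shift_mV=-8.0)
        other = report({"inactivation": "affected"}, study="s2",
                       beta1="no", inact_shift_mV=5.0, year=2015)
        records = resolve_variants([preferred, other])
        assert records[0].preferred_study == "s1"
        shift = build_shift_dataset(records, "inactivation")
        assert list(shift["label"]) == ["neg"]


class TestTrainTestSplit:
    def _dataset(self, n=243, p=0.72):
        n_pos = round(n * p)
        return pd.DataFrame({
            "position": range(1, n + 1),
            "from_aa": ["A"] * n, "to_aa": ["T"] * n,
            "label": ["affected"] * n_pos + ["unaffected"] * (n - n_pos)})

    def test_two_thirds_split_sizes(self):
        train, test = split_train_test(self._dataset(), seed=1)
        assert abs(len(train) - 162) <= 1
        assert len(train) + len(test) == 243

    def test_stratification_preserves_imbalance(self):
        train, test = split_train_test(self._dataset(), seed=1)
        for part in (train, test):
            frac = (part["label"] == "affected").mean()
            assert frac == pytest.approx(0.72, abs=0.01)

    def test_same_seed_reproducible(self):
        a = split_train_test(self._dataset(), seed=5)
        b = split_train_test(self._dataset(), seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seeds_differ(self):
        a, _ = split_train_test(self._dataset(), seed=1)
        b, _ = split_train_test(self._dataset(), seed=2)
        assert not a.equals(b)

    def test_single_class_warns(self):
        data = self._dataset(12, 1.0)
        with pytest.warns(UserWarning):
            split_train_test(data, seed=0)


class TestStorage:
    def _reports(self):
        return [
            report({"activation": "affected", "inactivation": "unaffected"},
                   act_shift_mV=-7.25),
            report({"zero_current": "affected"}, study="s2", cell="oocyte",
                   alpha="a*", beta1="no", variant=Variant(12, "G", "R")),
        ]

    def test_tsv_roundtrip_lossless(self, tmp_path):
        reports = self._reports()
        path = tmp_path / "reports.tsv"
        save_reports_tsv(reports, path)
        assert load_reports_tsv(path) == reports

    def test_sqlite_roundtrip_lossless(self, tmp_path):
        reports = self._reports()
        path = tmp_path / "reports.db"
        save_reports_sqlite(reports, path)
        assert load_reports_sqlite(path) == reports

    def test_frame_roundtrip(self):
        reports = self._reports()
        assert frame_to_reports(reports_to_frame(reports)) == reports


class TestNumbering:
    @pytest.mark.parametrize("pos2, pos1", [(1, 1), (1076, 1076),
                                            (1077, 1078), (2015, 2016)])
    def test_isoform2_shift(self, pos2, pos1):
        assert isoform2_to_isoform1(pos2) == pos1


class TestReportValidation:
    def test_shift_requires_measured_outcome(self):
        with pytest.raises(EPDataError):
            report({}, act_shift_mV=3.0)

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(EPDataError):
            report(cell="HeLa")

    def test_bad_finding_rejected(self):
        with pytest.raises(EPDataError):
            report({"activation": "maybe"})
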