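"""Panel scoring, gender calls, donor consistency and allele lookup."""

import numpy as np
import pandas as pd
import pytest

from hlascore.scoring import (
    DEFAULT_GENDER_PANEL,
    DEFAULT_HLA_PANEL,
    GenderPanel,
    MarkerPanel,
    call_gender,
    check_donor_consistency,
    combine_with_gender,
    compatible_alleles,
    score_sample,
    score_samples,
    summarize_dataset,
)


def _score_report(example_matrix, example_annotation, **kwargs):
    scored = score_samples(example_matrix, DEFAULT_HLA_PANEL)
    report = check_donor_consistency(scored, example_annotation, DEFAULT_HLA_PANEL, **kwargs)
    return scored, report


class TestScoreSample:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ((28, 4182, 48), "010"),   # published PBMC sample GSM155503
            ((45, 8041, 187), "011"),  # published PBMC sample GSM155495
            ((128, 128, 128), "000"),  # strictly-greater comparison at the boundary
            ((129, 127, 1e6), "101"),
        ],
    )
    def test_digit_strings(self, intensities, expected):
        assert score_sample(intensities, DEFAULT_HLA_PANEL).digits == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="3 intensities"):
            score_sample((1.0, 2.0), DEFAULT_HLA_PANEL)

    def test_missing_probe_named(self, example_matrix):
        panel = MarkerPanel("x", (("203290_at", 128.0), ("nope_at", 128.0)))
        with pytest.raises(KeyError, match="nope_at"):
            score_samples(example_matrix, panel)

    def test_panel_validation(self):
        with pytest.raises(ValueError, match="unique"):
            MarkerPanel("x", (("a", 1.0), ("a", 2.0)))
        with pytest.raises(ValueError, match="positive"):
            MarkerPanel("x", (("a", 0.0),))

    def test_score_space_size(self):
        assert DEFAULT_HLA_PANEL.n_possible_scores() == 8
        assert len(set(DEFAULT_HLA_PANEL.possible_scores())) == 8


class TestGenderCall:
    y_high = {p: 500.0 for p, _ in DEFAULT_GENDER_PANEL.male_probes}
    y_low = {p: 10.0 for p, _ in DEFAULT_GENDER_PANEL.male_probes}

    def test_male(self):
        assert call_gender({**self.y_high, "224588_at": 10.0}).call == "M"

    def test_female(self):
        assert call_gender({**self.y_low, "224588_at": 900.0}).call == "F"

    def test_conflicting_evidence_is_ambiguous(self):
        assert call_gender({**self.y_high, "224588_at": 900.0}).call == "ambiguous"

    def test_partial_y_panel_is_ambiguous(self):
        probes = dict(self.y_high)
        probes["201909_at"] = 10.0
        assert call_gender({**probes, "224588_at": 10.0}).call == "ambiguous"

    def test_missing_probe_rejected(self):
        with pytest.raises(KeyError, match="224588_at"):
            call_gender(self.y_high)

    def test_custom_thresholds(self):
        panel = GenderPanel("g", (("y1", 10.0),), (("x1", 10.0),))
        assert call_gender({"y1": 11.0, "x1": 9.0}, panel).call == "M"


class TestDonorConsistency:
    def test_concordant_donor_all_ok(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        d55 = report[report["donor_id"] == "55"]
        assert list(d55["flag"]) == ["OK"] * 4
        assert all(r == [] for r in d55["reasons"])

    def test_slight_transgression_is_soft(self, example_matrix, example_annotation):
        # 187 against threshold 128 is within two-fold: not critical
        _, report = _score_report(example_matrix, example_annotation)
        row = report[report["sample_id"] == "GSM155495"].iloc[0]
        assert row["flag"] == "SOFT"
        assert "209728_at" in row["reasons"][0]

    def test_distant_intensities_are_hard(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        row = report[report["sample_id"] == "GSM155478"].iloc[0]
        assert row["flag"] == "HARD"
        # 5 against 128 is ~26-fold away; 113 alone would have been soft
        assert any("209728_at" in r for r in row["reasons"])

    def test_three_distinct_scores_in_one_donor(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        d35 = report[report["donor_id"] == "35"]
        assert d35["hla_score"].nunique() == 3

    def test_single_sample_donor_noted(self, example_matrix):
        ann = pd.DataFrame(
            {
                "sample_id": ["GSM155503"],
                "donor_id": ["55"],
            }
        )
        scored = score_samples(example_matrix, DEFAULT_HLA_PANEL)
        report = check_donor_consistency(scored, ann, DEFAULT_HLA_PANEL)
        assert report.iloc[0]["flag"] == "OK"
        assert report.iloc[0]["note"] == "no repeat"

    def test_unknown_sample_rejected(self, example_matrix):
        ann = pd.DataFrame({"sample_id": ["missing"], "donor_id": ["1"]})
        scored = score_samples(example_matrix, DEFAULT_HLA_PANEL)
        with pytest.raises(KeyError, match="missing"):
            check_donor_consistency(scored, ann, DEFAULT_HLA_PANEL)

    def test_permutation_safety(self, example_matrix, example_annotation, rng):
        _, base = _score_report(example_matrix, example_annotation)
        # shuffling whole donor blocks must not change any flag; shuffling
        # within a donor can only move the tie-break, so flags per sample
        # stay identical for donors with a clear majority
        donors = list(example_annotation["donor_id"].unique())
        rng.shuffle(donors)
        shuffled = pd.concat(
            [example_annotation[example_annotation["donor_id"] == d] for d in donors]
        ).reset_index(drop=True)
        _, perm = _score_report(example_matrix, shuffled)
        merged = base.merge(perm, on="sample_id", suffixes=("_a", "_b"))
        assert (merged["flag_a"] == merged["flag_b"]).all()


class TestCombineWithGender:
    def test_gender_mismatch_escalates(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        calls = example_annotation.set_index("sample_id")["redkx_call"]
        declared = example_annotation.set_index("sample_id")["declared_sex"]
        out = combine_with_gender(report, calls, declared)
        # donor 32 time point 2: male call among declared females
        row = out[out["sample_id"] == "GSM155472"].iloc[0]
        assert row["flag"] == "HARD"
        assert any("gender mismatch" in r for r in row["reasons"])
        assert any("within donor" in r for r in row["reasons"])
        # donor 35 time point 1: female call in a male donor
        row = out[out["sample_id"] == "GSM155475"].iloc[0]
        assert row["flag"] == "HARD"
        assert any("gender" in r for r in row["reasons"])

    def test_concordant_calls_leave_report_unchanged(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        declared = example_annotation.set_index("sample_id")["declared_sex"]
        out = combine_with_gender(report, declared, declared)
        assert list(out["flag"]) == list(report["flag"])

    def test_soft_plus_gender_mismatch_becomes_hard(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        calls = example_annotation.set_index("sample_id")["declared_sex"].copy()
        calls["GSM155495"] = "M"  # the SOFT sample, declared F
        out = combine_with_gender(report, calls, example_annotation.set_index("sample_id")["declared_sex"])
        assert out[out["sample_id"] == "GSM155495"].iloc[0]["flag"] == "HARD"

    def test_never_deescalates(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        declared = example_annotation.set_index("sample_id")["declared_sex"]
        out = combine_with_gender(report, declared, declared)
        order = {"OK": 0, "SOFT": 1, "HARD": 2}
        assert all(
            order[a] <= order[b] for a, b in zip(report["flag"], out["flag"])
        )


class TestSummarize:
    def test_published_flag_counts(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        calls = example_annotation.set_index("sample_id")["redkx_call"]
        declared = example_annotation.set_index("sample_id")["declared_sex"]
        out = combine_with_gender(report, calls, declared)
        per_donor_hard = (
            out[out["flag"] == "HARD"].groupby("donor_id").size().to_dict()
        )
        # donor 35 contributes two flagged samples, donor 32 one, donor 45 none
        assert per_donor_hard == {"35": 2, "32": 1}
        summary = summarize_dataset(out, example_annotation)
        row = summary.iloc[0]
        assert row["n_samples"] == 20
        assert row["n_donors_with_repeats"] == 5
        assert row["n_flagged"] == 3  # SOFT does not count by default
        assert row["n_score_diff"] == 4

    def test_soft_configurable(self, example_matrix, example_annotation):
        _, report = _score_report(example_matrix, example_annotation)
        strict = summarize_dataset(report, example_annotation, soft_counts_as_flagged=True)
        lenient = summarize_dataset(report, example_annotation)
        assert strict.iloc[0]["n_flagged"] == lenient.iloc[0]["n_flagged"] + 1

    def test_clean_report_zero_flagged(self, example_matrix):
        ann = pd.DataFrame(
            {
                "sample_id": ["GSM155503", "GSM155504"],
                "donor_id": ["55", "55"],
                "dataset_id": ["X", "X"],
            }
        )
        scored = score_samples(example_matrix, DEFAULT_HLA_PANEL)
        report = check_donor_consistency(scored, ann, DEFAULT_HLA_PANEL)
        assert summarize_dataset(report, ann).iloc[0]["n_flagged"] == 0


class TestCompatibleAlleles:
    def test_dqa1_0401_like_digits(self):
        assert compatible_alleles((1, 0)) == ["HLA-DQA1*0401", "HLA-DQA1*0501"]

    def test_dqa1_0103_exact_match(self):
        assert compatible_alleles((0, 1), match_floor=11) == ["HLA-DQA1*0103"]

    def test_both_high_unresolved_at_full_floor(self):
        assert compatible_alleles((1, 1), match_floor=11) == []

    def test_bad_digits_rejected(self):
        with pytest.raises(ValueError):
            compatible_alleles((2, 0))
        with pytest.raises(ValueError):
            compatible_alleles((1,))
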