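"""Patient profiles, occupation rankings and missingness models."""

import numpy as np
import pandas as pd
import pytest

from occmine.cohort import (
    build_profiles,
    distinct_count_summary,
    fit_association_models,
    top_occupations,
)
from occmine.resources import default_healthcare_filter
from occmine.synth import simulate_profiles
from occmine.types import (
    MentionKind,
    OccupationAnnotation,
    Relation,
    TextSpan,
)


def _ann(label, relation=Relation.PATIENT):
    return OccupationAnnotation(span=TextSpan(0, 5), surface="xxxxx",
                                mention_kind=MentionKind.TITLE,
                                label=label, relation=relation)


def _structured(rows):
    return pd.DataFrame(rows, columns=["patient_id", "status_code"])


FILT = default_healthcare_filter()


class TestBuildProfiles:
    def test_structured_only_counts_as_recorded(self):
        profiles = build_profiles({}, _structured([("p1", 3)]), FILT)
        row = profiles.iloc[0]
        assert row.has_occupation
        assert row.extracted_labels == ()

    def test_other_label_alone_does_not_count(self):
        profiles = build_profiles({"p1": [_ann("other")]},
                                  _structured([]), FILT)
        row = profiles.iloc[0]
        assert not row.has_occupation
        assert row.n_distinct == 0

    def test_healthcare_labels_never_in_profiles(self):
        profiles = build_profiles(
            {"p1": [_ann("nurse"), _ann("builder")],
             "p2": [_ann("psychiatrist")]},
            _structured([]), FILT)
        for labels in profiles["extracted_labels"]:
            assert not set(labels) & set(FILT)
        assert profiles.set_index("patient_id").loc["p1", "extracted_labels"] \
            == ("builder",)

    def test_non_patient_relations_excluded(self):
        profiles = build_profiles(
            {"p1": [_ann("teacher", Relation.FAMILY)]}, _structured([]), FILT)
        assert not profiles.iloc[0].has_occupation

    def test_count_conservation(self):
        """|has_occupation| = |structured only| + |text only| + |both|."""
        anns = {"p1": [_ann("builder")], "p2": [_ann("teacher")],
                "p3": [_ann("other")]}
        structured = _structured([("p2", 1), ("p4", 2)])
        profiles = build_profiles(anns, structured, FILT)
        s_only = {"p4"}
        t_only = {"p1"}
        both = {"p2"}
        recorded = set(profiles.loc[profiles.has_occupation, "patient_id"])
        assert recorded == s_only | t_only | both

    def test_duplicate_structured_rows_keep_first(self, caplog):
        with caplog.at_level("WARNING"):
            profiles = build_profiles({}, _structured([("p1", 2), ("p1", 9)]),
                                      FILT)
        assert profiles.iloc[0].structured_status == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_combined_at_least_structured_only(self, trained):
        profiles = trained.profiles
        assert profiles["has_occupation"].mean() >= \
            profiles["structured_status"].notna().mean()


class TestTopOccupations:
    def test_statuses_dominate_generated_corpora(self, trained):
        top = top_occupations(trained.profiles, 5)
        assert set(top["label"][:2]) == {"student", "unemployed"}

    def test_percentages_over_all_patients(self):
        profiles = build_profiles(
            {"p1": [_ann("builder")]},
            _structured([("p2", 1), ("p3", 1), ("p4", 1)]), FILT)
        top = top_occupations(profiles, 5)
        assert top.loc[0, "pct"] == pytest.approx(25.0)  # 1 of 4 patients

    def test_label_counted_once_per_patient(self):
        profiles = build_profiles(
            {"p1": [_ann("builder"), _ann("builder")]}, _structured([]), FILT)
        assert top_occupations(profiles, 1).loc[0, "n_patients"] == 1

    def test_k_larger_than_label_count(self):
        profiles = build_profiles({"p1": [_ann("builder")]},
                                  _structured([]), FILT)
        assert len(top_occupations(profiles, 50)) == 1

    def test_ties_break_alphabetically(self):
        profiles = build_profiles(
            {"p1": [_ann("zebra-keeper")], "p2": [_ann("apiarist")]},
            _structured([]), FILT)
        assert list(top_occupations(profiles, 2)["label"]) == \
            ["apiarist", "zebra-keeper"]


class TestDistinctCounts:
    def test_single_label_patients(self):
        profiles = build_profiles(
            {f"p{i}": [_ann("builder")] for i in range(5)},
            _structured([]), FILT)
        s = distinct_count_summary(profiles)
        assert s.median == 1 and s.iqr_width == 0

    def test_empty_profiles_give_nulls(self):
        s = distinct_count_summary(
            build_profiles({}, _structured([]), FILT))
        assert s.n == 0 and s.median is None and s.iqr_width is None

    def test_reports_q1_q3_and_width(self, trained):
        s = distinct_count_summary(trained.profiles)
        assert s.q1 <= s.median <= s.q3
        assert s.iqr_width == pytest.approx(s.q3 - s.q1)


@pytest.fixture(scope="module")
def fitted():
    df = simulate_profiles(n_patients=3000, seed=12)
    return df, fit_association_models(
        df, predictors=("events_quartile", "gender", "age_band", "bed_days"))


class TestAssociationModels:
    def test_reference_levels_have_unit_or(self, fitted):
        _, table = fitted
        # the reference level is the first row of each variable/model block
        ref = table.groupby(["variable", "model"], sort=False).nth(0)
        assert (ref["odds_ratio"] == 1.0).all()
        assert ref["ci_low"].isna().all()

    def test_crude_ci_covers_built_in_or(self, fitted):
        _, table = fitted
        row = table[(table.variable == "events_quartile")
                    & (table.level == "high") & (table.model == "crude")].iloc[0]
        assert row.ci_low <= 2.0 <= row.ci_high

    def test_cis_bracket_estimates(self, fitted):
        _, table = fitted
        est = table.dropna(subset=["ci_low"])
        assert (est.ci_low <= est.odds_ratio).all()
        assert (est.odds_ratio <= est.ci_high).all()

    def test_null_predictor_lrt_not_significant(self, fitted):
        _, table = fitted
        p = table[(table.variable == "gender")
                  & (table.model == "crude")]["lrt_p"].iloc[0]
        assert p > 0.001  # gender is null by construction

    def test_informative_predictor_lrt_significant(self, fitted):
        _, table = fitted
        p = table[(table.variable == "events_quartile")
                  & (table.model == "crude")]["lrt_p"].iloc[0]
        assert p < 0.01

    def test_single_level_predictor_rejected(self):
        df = simulate_profiles(n_patients=200, seed=1)
        df["constant"] = "same"
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_association_models(df, predictors=("constant",))

    def test_three_model_families_reported(self, fitted):
        _, table = fitted
        assert set(table["model"]) == {"crude", "service_adjusted",
                                       "fully_adjusted"}

    def test_separated_level_reported_null(self):
        df = simulate_profiles(n_patients=400, seed=3)
        df["sep"] = np.where(df["has_occupation"], "a", "b")  # perfect
        table = fit_association_models(df, predictors=("sep", "gender"))
        crude_sep = table[(table.variable == "sep") & (table.model == "crude")
                          & (table.level == "b")]
        assert crude_sep["odds_ratio"].isna().all()
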