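"""Body-mass summaries: age classes, exclusion cascade, obesity rule,
monthly averaging, and the derived weight-file columns."""

import numpy as np
import pandas as pd
import pytest

from strepslife import mass
from strepslife.demography import LitterEvent
from tests.conftest import make_animals, make_weights


class TestClassifyAge:
    @pytest.mark.parametrize("age, expected", [
        (0.5, "IJ"),            # below minimum dam age
        (0.80, "young_adult"),  # inclusive lower boundary
        (1.59, "young_adult"),
        (1.60, "adult"),        # inclusive boundary at twice the minimum
        (10.0, "adult"),
    ])
    def test_boundaries_with_printed_cutoff(self, age, expected):
        assert mass.classify_age(age, 0.80) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            mass.classify_age(-0.1, 0.80)


class TestFilterWeights:
    def test_exclusion_cascade(self):
        cfg = mass.MassSummaryConfig()
        weights = make_weights([
            {"DLC_ID": "A", "Weight_Date": "2005-06-01"},
            {"DLC_ID": "B", "Weight_Date": "2005-06-01",
             "DaysBeforeDeath": 30.0},                       # near death
            {"DLC_ID": "C", "Weight_Date": "2005-06-01",
             "Preg_Status": "P"},                            # pregnant
            {"DLC_ID": "D", "Weight_Date": "2000-07-01",
             "Birth_Type": "WB", "Birth_Institution": "Madagascar"},
            # wild-born at estimated age 0.5 < 1.5
        ])
        kept = mass.filter_weights(weights, cfg)
        assert list(kept["DLC_ID"]) == ["A"]

    def test_predeath_window_is_strict(self):
        cfg = mass.MassSummaryConfig()
        weights = make_weights([
            {"DLC_ID": "A", "Weight_Date": "2005-06-01",
             "DaysBeforeDeath": 60.0},   # exactly 60: retained
            {"DLC_ID": "B", "Weight_Date": "2005-06-01",
             "DaysBeforeDeath": 59.0},   # inside the window: dropped
        ])
        assert list(mass.filter_weights(weights, cfg)["DLC_ID"]) == ["A"]

    def test_month_subset(self):
        cfg = mass.MassSummaryConfig(
            seasonal_month_subset=frozenset({4, 5, 6}))
        weights = make_weights([
            {"DLC_ID": "A", "Weight_Date": "2005-05-01", "MonthOfWeight": 5},
            {"DLC_ID": "B", "Weight_Date": "2005-11-01", "MonthOfWeight": 11},
        ])
        assert list(mass.filter_weights(weights, cfg)["DLC_ID"]) == ["A"]


class TestIndividualMeans:
    def test_monthly_buckets_weight_equally(self):
        weights = make_weights([
            {"Weight_Date": "2004-06-05", "Weight_g": 100.0},
            {"Weight_Date": "2004-06-25", "Weight_g": 110.0},
            {"Weight_Date": "2004-07-10", "Weight_g": 130.0},
        ])
        inds = mass.individual_mass_means(weights, "adult")
        assert len(inds) == 1
        assert inds["mean_g"].iloc[0] == pytest.approx(117.5)  # (105+130)/2

    def test_same_calendar_month_different_year_distinct_buckets(self):
        weights = make_weights([
            {"Weight_Date": "2004-06-05", "Weight_g": 100.0},
            {"Weight_Date": "2005-06-05", "Weight_g": 200.0},
        ])
        inds = mass.individual_mass_means(weights, "adult")
        assert inds["mean_g"].iloc[0] == pytest.approx(150.0)

    def test_single_weight_identity(self):
        weights = make_weights([{"Weight_Date": "2004-06-05",
                                 "Weight_g": 321.0}])
        inds = mass.individual_mass_means(weights, "adult")
        assert inds["mean_g"].iloc[0] == 321.0


class TestObesityFilter:
    def test_hand_computed_two_sd_threshold(self):
        # means 100 x9 and 300: mean 120, sd 63.25, threshold 246.5
        inds = pd.DataFrame({
            "DLC_ID": [str(i) for i in range(10)],
            "Sex": ["F"] * 10,
            "mean_g": [100.0] * 9 + [300.0]})
        kept, obese = mass.obesity_filter(inds, mass.MassSummaryConfig())
        assert list(obese["DLC_ID"]) == ["9"]
        assert mass.species_mass_summary(kept)["mean_g"] == 100.0

    def test_all_equal_none_flagged(self):
        inds = pd.DataFrame({"DLC_ID": list("abc"), "Sex": ["F"] * 3,
                             "mean_g": [200.0] * 3})
        kept, obese = mass.obesity_filter(inds, mass.MassSummaryConfig())
        assert len(kept) == 3 and obese.empty

    def test_single_individual_not_filtered(self):
        inds = pd.DataFrame({"DLC_ID": ["a"], "Sex": ["F"],
                             "mean_g": [999.0]})
        kept, obese = mass.obesity_filter(inds, mass.MassSummaryConfig())
        assert len(kept) == 1 and obese.empty

    def test_filter_never_raises_species_mean(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(2, 40))
            inds = pd.DataFrame({
                "DLC_ID": [str(i) for i in range(n)], "Sex": ["F"] * n,
                "mean_g": rng.lognormal(5, 0.5, n)})
            kept, _ = mass.obesity_filter(inds, mass.MassSummaryConfig())
            assert (mass.species_mass_summary(kept)["mean_g"]
                    <= mass.species_mass_summary(inds)["mean_g"] + 1e-9)


class TestNeonateSummary:
    def test_day0_day1_average_and_stillbirth_exclusion(self):
        animals = make_animals([
            {"DLC_ID": "A", "AgeOfLiving_y": 2.0},
            {"DLC_ID": "B", "AgeAtDeath_y": 0.0},   # died day 0: excluded
        ])
        weights = make_weights([
            {"DLC_ID": "A", "DOB": "2000-01-01", "Weight_Date": "2000-01-01",
             "Weight_g": 10.0},
            {"DLC_ID": "A", "DOB": "2000-01-01", "Weight_Date": "2000-01-02",
             "Weight_g": 12.0},
            {"DLC_ID": "B", "DOB": "2000-01-01", "Weight_Date": "2000-01-01",
             "Weight_g": 8.0},
        ])
        s = mass.neonate_summary(weights, animals, "SYNT")
        assert s == {"n": 1, "mean_g": 11.0, "min_g": 11.0, "max_g": 11.0}

    def test_day_two_weight_not_a_neonate_weight(self):
        animals = make_animals([{"DLC_ID": "A", "AgeOfLiving_y": 2.0}])
        weights = make_weights([
            {"DLC_ID": "A", "DOB": "2000-01-01", "Weight_Date": "2000-01-03",
             "Weight_g": 14.0}])
        assert mass.neonate_summary(weights, animals, "SYNT")["n"] == 0


class TestDerivedColumns:
    def _inputs(self):
        animals = make_animals([
            {"DLC_ID": "DAM", "Sex": "F", "DOB": "1995-01-01",
             "AgeOfLiving_y": 10.0},
            {"DLC_ID": "SIR", "Sex": "M", "DOB": "1995-01-01",
             "AgeOfLiving_y": 10.0},
        ])
        litters = [LitterEvent(
            taxon="SYNT", dam_id="DAM",
            birth_date=pd.Timestamp("2001-05-01"),
            conception_date=pd.Timestamp("2001-01-01"), size=2,
            member_ids=frozenset({"K1", "K2"}), any_survived_1d=True)]
        weights = make_weights([
            {"DLC_ID": "DAM", "DOB": "1995-01-01",
             "Weight_Date": "2001-03-02", "Weight_g": 2000.0},
            {"DLC_ID": "DAM", "DOB": "1995-01-01",
             "Weight_Date": "2001-03-07", "Weight_g": 2010.0},
            {"DLC_ID": "SIR", "DOB": "1995-01-01",
             "Weight_Date": "2001-03-02", "Weight_g": 2000.0},
        ])[["Taxon", "DLC_ID", "Weight_g", "Weight_Date"]]
        return weights, animals, litters

    def test_pregnancy_block_and_deltas(self):
        weights, animals, litters = self._inputs()
        out = mass.weight_derived_columns(
            weights, animals, litters, {"SYNT": 1.5})
        dam = out[out["DLC_ID"] == "DAM"].reset_index(drop=True)
        # 60 days before a 120-day-expected birth: half the pregnancy left
        assert dam.at[0, "Preg_Status"] == "P"
        assert dam.at[0, "DaysBeforeInfBirth_IfPreg"] == 60.0
        assert dam.at[0, "Pct_PregRemain_IfPreg"] == pytest.approx(0.5)
        assert dam.at[0, "InfantLitSz_IfPreg"] == 2.0
        # change-since-previous columns
        assert np.isnan(dam.at[0, "Days_Since_PrevWt"])
        assert dam.at[1, "Days_Since_PrevWt"] == 5.0
        assert dam.at[1, "Change_Since_PrevWt_g"] == 10.0
        assert dam.at[1, "Avg_Daily_WtChange_g"] == pytest.approx(2.0)
        # age columns track the day count
        assert dam.at[0, "AgeAtWt_d"] == 2252.0
        assert dam.at[0, "AgeAtWt_wk"] == pytest.approx(2252 / 7)
        assert dam.at[0, "AgeAtWt_mo_NoDec"] == np.floor(2252 / 365 * 12)
        assert dam.at[0, "Age_Category"] == "adult"

    def test_males_never_pregnant(self):
        weights, animals, litters = self._inputs()
        out = mass.weight_derived_columns(
            weights, animals, litters, {"SYNT": 1.5})
        sire = out[out["DLC_ID"] == "SIR"].iloc[0]
        assert sire["Preg_Status"] == "NP"
        assert pd.isna(sire["Pct_PregRemain_IfPreg"])

    def test_unsorted_input_sorted_internally(self):
        weights, animals, litters = self._inputs()
        shuffled = weights.iloc[::-1].reset_index(drop=True)
        a = mass.weight_derived_columns(weights, animals, litters,
                                        {"SYNT": 1.5})
        b = mass.weight_derived_columns(shuffled, animals, litters,
                                        {"SYNT": 1.5})
        pd.testing.assert_frame_equal(a, b)
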