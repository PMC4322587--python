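"""Schema reading/writing, round trips and the outlier validation screen."""

import numpy as np
import pandas as pd
import pytest

from strepslife import colony_io
from strepslife.colony_io import SchemaError
from strepslife.registry import default_registry
from tests.conftest import make_animals, make_weights


@pytest.fixture(scope="module")
def synth_registry(small_params=None):
    from strepslife import synthetic_colony as sc
    from tests.conftest import make_animals  # noqa: F401
    p = sc.ColonyParams(taxon="SYNT")
    return sc.params_registry([p])


class TestAnimalListRoundTrip:
    def test_write_read_reproduces_fields(self, small_colony, small_registry,
                                          tmp_path):
        animals, _, _ = small_colony
        path = tmp_path / "animals.csv"
        colony_io.write_animal_list(animals, path)
        back = colony_io.read_animal_list(path, small_registry)
        assert not back.attrs["validation"]
        a = animals.sort_values("DLC_ID").reset_index(drop=True)
        b = back.sort_values("DLC_ID").reset_index(drop=True)
        for col in colony_io.ANIMAL_COLUMNS:
            if pd.api.types.is_float_dtype(b[col]):
                assert np.allclose(
                    a[col].astype(float).fillna(-1),
                    b[col].astype(float).fillna(-1), atol=1e-9), col
            else:
                ax = a[col].astype(object).where(a[col].notna(), None)
                bx = b[col].astype(object).where(b[col].notna(), None)
                assert list(ax) == list(bx), col

    def test_derived_columns_verified_on_read(self, small_colony,
                                              small_registry, tmp_path):
        animals, _, _ = small_colony
        bad = animals.copy()
        bad.loc[bad.index[0], "Concep_Month"] = 99
        path = tmp_path / "animals.csv"
        colony_io.write_animal_list(bad, path)
        back = colony_io.read_animal_list(path, small_registry)
        assert "derived_mismatch" in back.attrs["validation"].kinds()
        # recompute mode overwrites instead of reporting
        again = colony_io.read_animal_list(path, small_registry,
                                           recompute=True)
        assert again.loc[0, "Concep_Month"] != 99

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "broken.csv"
        cols = [c for c in colony_io.ANIMAL_COLUMNS if c != "DLC_ID"]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="DLC_ID"):
            colony_io.read_animal_list(path, default_registry())

    def test_one_row_conception_arithmetic(self, tmp_path):
        animals = make_animals([
            {"Taxon": "CMED", "DOB": "2000-05-01",
             "Expected_Gestation_d": 60, "AgeOfLiving_y": 3.0}])
        animals["Estimated_Concep"] = pd.Timestamp("2000-03-02")
        animals["Birth_Month"] = 5
        animals["Concep_Month"] = 3
        path = tmp_path / "one.csv"
        colony_io.write_animal_list(animals, path)
        back = colony_io.read_animal_list(path, default_registry())
        assert back.loc[0, "Estimated_Concep"] == pd.Timestamp("2000-03-02")
        assert not back.attrs["validation"].by_kind("derived_mismatch")

    def test_dot_and_na_missing_tokens_accepted(self, tmp_path,
                                                small_registry):
        animals = make_animals([{"AgeOfLiving_y": 3.0}])
        path = tmp_path / "na.csv"
        colony_io.write_animal_list(animals, path)
        text = path.read_text().replace(",,", ",.,", 1)
        path.write_text(text)
        back = colony_io.read_animal_list(path, small_registry)
        assert len(back) == 1

    def test_us_style_dates_accepted(self, tmp_path, small_registry):
        animals = make_animals([{"AgeOfLiving_y": 3.0}])
        path = tmp_path / "us.csv"
        colony_io.write_animal_list(animals, path)
        path.write_text(path.read_text().replace("2000-01-01", "1/1/2000"))
        back = colony_io.read_animal_list(path, small_registry)
        assert back.loc[0, "DOB"] == pd.Timestamp("2000-01-01")

    def test_unknown_taxon_and_duplicate_id_reported(self, tmp_path,
                                                     small_registry):
        animals = make_animals([
            {"DLC_ID": "X", "AgeOfLiving_y": 1.0},
            {"DLC_ID": "X", "AgeOfLiving_y": 2.0},
            {"Taxon": "ZZZZ", "DLC_ID": "Y", "AgeOfLiving_y": 1.0}])
        path = tmp_path / "dups.csv"
        colony_io.write_animal_list(animals, path)
        rep = colony_io.read_animal_list(path, small_registry) \
            .attrs["validation"]
        assert {"duplicate_id", "unknown_taxon"} <= rep.kinds()


class TestWeightFileReading:
    def test_roundtrip_sorted_and_consistent(self, small_colony,
                                             small_registry, tmp_path):
        _, weights, _ = small_colony
        path = tmp_path / "weights.csv"
        colony_io.write_weight_file(weights, path)
        back = colony_io.read_weight_file(path, small_registry)
        assert not back.attrs["validation"]
        assert len(back) == len(weights)
        key = back[["DLC_ID", "Weight_Date"]]
        assert key.equals(key.sort_values(["DLC_ID", "Weight_Date"])
                          .reset_index(drop=True))

    def test_age_derivation_example(self, tmp_path, small_registry):
        w = make_weights([
            {"DOB": "2000-01-01", "Weight_Date": "2000-01-11",
             "Weight_g": 50.0, "MonthOfWeight": 1}])
        w["AgeAtWt_wk"] = 10 / 7
        w["AgeAtWt_mo"] = 10 / 365 * 12
        w["AgeAtWt_mo_NoDec"] = 0.0
        path = tmp_path / "w.csv"
        colony_io.write_weight_file(w, path)
        back = colony_io.read_weight_file(path, small_registry)
        assert back.loc[0, "AgeAtWt_d"] == 10
        assert back.loc[0, "AgeAtWt_wk"] == pytest.approx(10 / 7)
        assert not back.attrs["validation"].by_kind("derived_mismatch")

    def test_negative_age_and_nonpositive_weight_flagged(self, tmp_path,
                                                         small_registry):
        w = make_weights([
            {"DOB": "2000-06-01", "Weight_Date": "2000-01-11",
             "Weight_g": 50.0, "MonthOfWeight": 1},
            {"DOB": "2000-01-01", "Weight_Date": "2000-01-11",
             "Weight_g": 0.0, "MonthOfWeight": 1}])
        path = tmp_path / "w.csv"
        colony_io.write_weight_file(w, path)
        rep = colony_io.read_weight_file(path, small_registry) \
            .attrs["validation"]
        assert {"negative_age", "nonpositive_weight"} <= rep.kinds()


class TestValidateColony:
    def test_clean_synthetic_colony_is_clean(self, small_colony):
        animals, weights, _ = small_colony
        report = colony_io.validate_colony(animals, weights)
        assert not report, report.summary()

    def test_death_before_birth_flagged(self):
        animals = make_animals([
            {"DOB": "2000-01-01", "DOD": "1999-01-01",
             "AgeAtDeath_y": -1.0}])
        weights = make_weights([{"Weight_Date": "2000-02-01"}])
        report = colony_io.validate_colony(animals, weights)
        assert "negative_age" in report.kinds()

    def test_order_of_magnitude_weight_flagged(self):
        animals = make_animals([{"DLC_ID": "A", "AgeOfLiving_y": 5.0}])
        rows = [{"DLC_ID": "A", "Weight_Date": "2004-01-01",
                 "Weight_g": 80.0}] * 20
        rows.append({"DLC_ID": "A", "Weight_Date": "2004-06-01",
                     "Weight_g": 8000.0})
        report = colony_io.validate_colony(animals, make_weights(rows))
        assert "weight_out_of_range" in report.kinds()

    def test_orphan_weight_and_age_rule(self):
        animals = make_animals([{"DLC_ID": "A", "AgeOfLiving_y": 5.0,
                                 "AgeAtDeath_y": 5.0}])
        weights = make_weights([{"DLC_ID": "GHOST",
                                 "Weight_Date": "2004-01-01"}])
        report = colony_io.validate_colony(animals, weights)
        assert {"orphan_weight", "age_rule"} <= report.kinds()

    def test_project_range(self):
        animals = make_animals([{"DOB": "1930-01-01",
                                 "AgeOfLiving_y": 70.0}])
        weights = make_weights([{"Weight_Date": "2000-01-01"}])
        report = colony_io.validate_colony(
            animals, weights, project_range=("1960-01-01", "2030-12-31"))
        assert "date_out_of_range" in report.kinds()
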