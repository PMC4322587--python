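"""Shared fixtures: small simulated colonies and hand-built record frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strepslife import synthetic_colony as sc
from strepslife.registry import Registry, TaxonInfo


@pytest.fixture(scope="session")
def small_params() -> sc.ColonyParams:
    return sc.ColonyParams(
        taxon="SYNT", n_founders=16, years_simulated=12,
        max_litters_per_year=10, weighing_interval_d=60)


@pytest.fixture(scope="session")
def small_colony(small_params):
    """A modest simulated colony shared by read-only tests."""
    animals, weights, truth = sc.simulate_colony(small_params, seed=42)
    return animals, weights, truth


@pytest.fixture(scope="session")
def small_registry(small_params) -> Registry:
    return sc.params_registry([small_params])


def make_animals(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal animal-list frame; unstated columns default sanely."""
    defaults = {
        "Taxon": "SYNT", "DLC_ID": None, "Hybrid": "N", "Sex": "F",
        "Name": None, "Current_Resident": "N", "StudBook": None,
        "DOB": pd.Timestamp("2000-01-01"), "Birth_Month": 1,
        "Estimated_DOB": None, "Birth_Type": "CB",
        "Birth_Institution": "Duke Prim", "Litter_Size": None,
        "Expected_Gestation_d": 120, "Estimated_Concep": None,
        "Concep_Month": None, "Dam_ID": None, "Dam_Name": None,
        "Dam_Taxon": None, "Dam_DOB": None, "Dam_AgeAtConcep_y": None,
        "Sire_ID": None, "Sire_Name": None, "Sire_Taxon": None,
        "Sire_DOB": None, "Sire_AgeAtConcep_y": None, "DOD": None,
        "AgeAtDeath_y": None, "AgeOfLiving_y": None,
        "AgeLastVerified_y": None, "AgeMax_LiveOrDead_y": None,
        "N_known_offspring": 0,
    }
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        if r["DLC_ID"] is None:
            r["DLC_ID"] = str(1000 + i)
        if r["Estimated_Concep"] is None and r["DOB"] is not None:
            r["Estimated_Concep"] = (
                pd.Timestamp(r["DOB"])
                - pd.Timedelta(days=r["Expected_Gestation_d"]))
        if r["AgeMax_LiveOrDead_y"] is None:
            r["AgeMax_LiveOrDead_y"] = next(
                (r[c] for c in ("AgeAtDeath_y", "AgeOfLiving_y",
                                "AgeLastVerified_y") if r[c] is not None),
                None)
        out.append(r)
    df = pd.DataFrame(out)
    for col in ["DOB", "Estimated_Concep", "Dam_DOB", "Sire_DOB", "DOD"]:
        df[col] = pd.to_datetime(df[col])
    return df


def make_weights(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal weight-file frame for unit tests."""
    defaults = {
        "Taxon": "SYNT", "Hybrid": "N", "DLC_ID": "1000", "Sex": "F",
        "Name": None, "DOB": pd.Timestamp("2000-01-01"),
        "Estimated_DOB": None, "Weight_g": 100.0, "Weight_Date": None,
        "MonthOfWeight": None, "AgeAtWt_d": None, "AgeAtWt_wk": None,
        "AgeAtWt_mo": None, "AgeAtWt_mo_NoDec": None, "AgeAtWt_y": None,
        "Days_Since_PrevWt": None, "Change_Since_PrevWt_g": None,
        "Avg_Daily_WtChange_g": None, "DOD": None, "DaysBeforeDeath": None,
        "Birth_Type": "CB", "Birth_Institution": "Duke Prim",
        "Litter_Size": None, "R_Min_Dam_AgeAtConcep_y": 1.5,
        "Age_Category": None, "Current_Resident": "N", "Preg_Status": "NP",
        "Expected_Gestation_d": 120, "ConcepDate_IfPreg": None,
        "InfantDOB_IfPreg": None, "DaysBeforeInfBirth_IfPreg": None,
        "Pct_PregRemain_IfPreg": None, "InfantLitSz_IfPreg": None,
    }
    out = []
    for row in rows:
        r = {**defaults, **row}
        if r["Weight_Date"] is not None and r["AgeAtWt_d"] is None:
            days = (pd.Timestamp(r["Weight_Date"])
                    - pd.Timestamp(r["DOB"])).days
            r["AgeAtWt_d"] = float(days)
            r["AgeAtWt_y"] = days / 365
        if r["Age_Category"] is None and r["AgeAtWt_y"] is not None:
            m = r["R_Min_Dam_AgeAtConcep_y"]
            r["Age_Category"] = ("IJ" if r["AgeAtWt_y"] < m else
                                 "young_adult" if r["AgeAtWt_y"] < 2 * m
                                 else "adult")
        out.append(r)
    df = pd.DataFrame(out)
    for col in ["DOB", "Weight_Date", "DOD", "ConcepDate_IfPreg",
                "InfantDOB_IfPreg"]:
        df[col] = pd.to_datetime(df[col])
    return df
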