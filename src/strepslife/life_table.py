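"""Assemble the 91-variable per-taxon life-history summary table.

Every variable is named ``Category_Measurement_Group_Variable_Units``:
``S`` sample sizes and counts, ``R`` reproduction, ``M`` body mass, ``L``
longevity and mortality, ``O`` other; the group term is All/M/F/ND or
Dam/Sire; units y (years), d (days) or g (grams).

Two serializations exist: a *reference* layout (91 rows, one column per
taxon, every cell character, missing printed as ``.``) for looking values
up, and an *analysis* layout (one row per taxon, 91 columns, numeric
columns numeric) for loading directly into statistical software.  The two
are exact transposes of one another after formatting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import demography, mass, seasonality, survival
from .colony_io import is_home_born
from .mass import MassSummaryConfig
from .registry import Registry, TaxonInfo

#: The 91 variables, in reference-table order.
VARIABLES = [
    "S_N_All_Historic", "S_N_M_Historic", "S_N_F_Historic", "S_N_ND_Historic",
    "S_N_All_CaptiveBorn", "S_N_M_CaptiveBorn", "S_N_F_CaptiveBorn",
    "S_N_All_WildBorn", "S_N_M_WildBorn", "S_N_F_WildBorn",
    "S_N_All_CurrentResident", "S_N_M_CurrentResident", "S_N_F_CurrentResident",
    "S_N_All_DLCBorn_Infant", "S_N_M_DLCBorn_Infant", "S_N_F_DLCBorn_Infant",
    "S_N_ND_DLCBorn_Infant",
    "R_Ratio_MtoF_DLCBirths",
    "S_N_All_DLCBorn_Litter",
    "R_Mean_LitterSize", "R_MostCommon_LitterSize",
    "R_Freq_MostCommon_LitterSize", "R_Min_LitterSize", "R_Max_LitterSize",
    "R_Expected_Gestation_d", "R_Range_Gestation_d", "R_Pattern_Breeding",
    "R_Peak_Breeding_Month", "R_Peak_Breeding_Season",
    "R_Peak_Birth_Month", "R_Peak_Birth_Season",
    "R_Min_Dam_AgeAtConcep_y", "R_Min_Sire_AgeAtConcep_y",
    "R_Max_Dam_AgeAtConcep_y", "R_Max_Sire_AgeAtConcep_y",
    "R_Active_DLCBreeding",
    "S_N_All_AdultsWeighed",
    "M_Mean_All_AdultWeight_g", "M_Min_All_AdultWeight_g",
    "M_Max_All_AdultWeight_g",
    "S_N_M_AdultsWeighed",
    "M_Mean_M_AdultWeight_g", "M_Min_M_AdultWeight_g", "M_Max_M_AdultWeight_g",
    "S_N_F_AdultsWeighed",
    "M_Mean_F_AdultWeight_g", "M_Min_F_AdultWeight_g", "M_Max_F_AdultWeight_g",
    "S_N_All_NeonatesWeighed",
    "M_Mean_All_NeonateWeight_g", "M_Min_All_NeonateWeight_g",
    "M_Max_All_NeonateWeight_g",
    "S_N_M_NeonatesWeighed",
    "M_Mean_M_NeonateWeight_g", "M_Min_M_NeonateWeight_g",
    "M_Max_M_NeonateWeight_g",
    "S_N_F_NeonatesWeighed",
    "M_Mean_F_NeonateWeight_g", "M_Min_F_NeonateWeight_g",
    "M_Max_F_NeonateWeight_g",
    "S_N_All_YngAdltsWeighed",
    "M_Mean_All_YngAdultWeight_g", "M_Min_All_YngAdultWeight_g",
    "M_Max_All_YngAdultWeight_g",
    "S_N_M_YngAdultsWeighed",
    "M_Mean_M_YngAdultWeight_g", "M_Min_M_YngAdultWeight_g",
    "M_Max_M_YngAdultWeight_g",
    "S_N_F_YngAdultsWeighed",
    "M_Mean_F_YngAdultWeight_g", "M_Min_F_YngAdultWeight_g",
    "M_Max_F_YngAdultWeight_g",
    "L_Max_All_Age_y", "L_Max_M_Age_y", "L_Max_F_Age_y",
    "L_Median_All_Longevity_gt30d_y", "L_Median_M_Longevity_gt30d_y",
    "L_Median_F_Longevity_gt30d_y",
    "S_N_All_Survival_gt30d", "S_N_M_Survival_gt30d", "S_N_F_Survival_gt30d",
    "L_Pct_All_InfMort_lt30d", "L_Pct_M_InfMort_lt30d",
    "L_Pct_F_InfMort_lt30d", "L_Pct_ND_InfMort_lt30d",
    "S_N_All_InfMort_lt30d", "S_N_M_InfMort_lt30d", "S_N_F_InfMort_lt30d",
    "S_N_ND_InfMort_lt30d",
    "O_NocturnalOrDiurnal", "O_N_All_Biosample_Individuals",
]

assert len(VARIABLES) == 91

# formatting class per variable: int / 1dp? ratios 3dp; years, %, g 2dp
_FMT3 = {"R_Ratio_MtoF_DLCBirths"}
_FMT2 = {v for v in VARIABLES
         if v.endswith("_y") or v.endswith("_g")
         or v.startswith("L_Pct") or v in (
             "R_Mean_LitterSize", "R_Freq_MostCommon_LitterSize")}
_FMT2 -= {"R_Expected_Gestation_d"}
_INT = {v for v in VARIABLES
        if v.startswith("S_N") or v in (
            "R_Min_LitterSize", "R_Max_LitterSize", "R_Expected_Gestation_d",
            "O_N_All_Biosample_Individuals")}


def format_cell(variable: str, value) -> str:
    """Render one value the way the reference table prints it."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "."
    if variable in _FMT3:
        return f"{value:.3f}"
    if variable in _FMT2:
        return f"{value:.2f}"
    if variable in _INT:
        return str(int(value))
    return str(value)


def _counts(sub: pd.DataFrame, mask=None) -> dict[str, int]:
    s = sub if mask is None else sub[mask]
    return {"All": len(s), "M": int((s["Sex"] == "M").sum()),
            "F": int((s["Sex"] == "F").sum()),
            "ND": int((s["Sex"] == "ND").sum())}


def _zero_missing(n: int) -> Optional[int]:
    # the reference table prints '.' for an empty count
    return n if n else None


def _peak_fields(months: list[int], pattern: str) -> tuple:
    if pattern == "NS" or not months:
        return "0", "0"
    hist = seasonality.month_histogram(months)
    peak = seasonality.peak_month(hist)
    season = seasonality.peak_season(hist)
    return str(peak), seasonality.format_season(season, pattern)


def build_taxon_row(animals: pd.DataFrame, weights: pd.DataFrame,
                    taxon: TaxonInfo, registry: Registry,
                    cfg: Optional[MassSummaryConfig] = None) -> dict:
    """All 91 variables for one taxon, as python values (None = missing)."""
    cfg = cfg or MassSummaryConfig()
    code = taxon.taxon_code
    sub = animals[animals["Taxon"] == code]
    row: dict = {v: None for v in VARIABLES}

    row["R_Expected_Gestation_d"] = taxon.expected_gestation_d
    row["R_Range_Gestation_d"] = (
        f"{taxon.gestation_range_d[0]}-{taxon.gestation_range_d[1]}")
    row["R_Pattern_Breeding"] = taxon.breeding_pattern
    row["R_Active_DLCBreeding"] = taxon.active_dlc_breeding
    row["O_NocturnalOrDiurnal"] = taxon.activity
    row["O_N_All_Biosample_Individuals"] = taxon.n_biosample_individuals
    if taxon.breeding_pattern == "NS":
        for v in ("R_Peak_Breeding_Month", "R_Peak_Breeding_Season",
                  "R_Peak_Birth_Month", "R_Peak_Birth_Season"):
            row[v] = "0"
    if sub.empty:
        return row

    # --- S: counts ---------------------------------------------------------
    c = _counts(sub)
    row["S_N_All_Historic"] = c["All"]
    row["S_N_M_Historic"] = _zero_missing(c["M"])
    row["S_N_F_Historic"] = _zero_missing(c["F"])
    row["S_N_ND_Historic"] = _zero_missing(c["ND"])
    c = _counts(sub, sub["Birth_Type"] == "CB")
    row["S_N_All_CaptiveBorn"] = _zero_missing(c["All"])
    row["S_N_M_CaptiveBorn"] = _zero_missing(c["M"])
    row["S_N_F_CaptiveBorn"] = _zero_missing(c["F"])
    c = _counts(sub, sub["Birth_Type"] == "WB")
    row["S_N_All_WildBorn"] = _zero_missing(c["All"])
    row["S_N_M_WildBorn"] = _zero_missing(c["M"])
    row["S_N_F_WildBorn"] = _zero_missing(c["F"])
    c = _counts(sub, sub["Current_Resident"] == "Y")
    row["S_N_All_CurrentResident"] = _zero_missing(c["All"])
    row["S_N_M_CurrentResident"] = _zero_missing(c["M"])
    row["S_N_F_CurrentResident"] = _zero_missing(c["F"])
    home = is_home_born(sub)
    c = _counts(sub, home)
    row["S_N_All_DLCBorn_Infant"] = _zero_missing(c["All"])
    row["S_N_M_DLCBorn_Infant"] = _zero_missing(c["M"])
    row["S_N_F_DLCBorn_Infant"] = _zero_missing(c["F"])
    row["S_N_ND_DLCBorn_Infant"] = _zero_missing(c["ND"])

    # --- R: reproduction ---------------------------------------------------
    row["R_Ratio_MtoF_DLCBirths"] = demography.birth_sex_ratio(animals, code)
    litters = demography.build_litters(animals, code, registry)
    if litters:
        row["S_N_All_DLCBorn_Litter"] = len(litters)
        st = demography.litter_stats(litters)
        row["R_Mean_LitterSize"] = st["mean"]
        row["R_MostCommon_LitterSize"] = st["most_common"]
        row["R_Freq_MostCommon_LitterSize"] = st["freq_most_common"]
        row["R_Min_LitterSize"] = st["min"]
        row["R_Max_LitterSize"] = st["max"]
        if taxon.breeding_pattern == "S":
            # conception months only from litters with a 1-day survivor
            # (conception dates of possible premature births are unreliable)
            concep_months = [l.conception_date.month for l in litters
                             if l.any_survived_1d]
            birth_months = [l.birth_date.month for l in litters]
            (row["R_Peak_Breeding_Month"],
             row["R_Peak_Breeding_Season"]) = _peak_fields(concep_months, "S")
            (row["R_Peak_Birth_Month"],
             row["R_Peak_Birth_Season"]) = _peak_fields(birth_months, "S")
    ext = demography.parental_age_extremes(animals, code)
    row["R_Min_Dam_AgeAtConcep_y"] = ext["min_dam"]
    row["R_Max_Dam_AgeAtConcep_y"] = ext["max_dam"]
    row["R_Min_Sire_AgeAtConcep_y"] = ext["min_sire"]
    row["R_Max_Sire_AgeAtConcep_y"] = ext["max_sire"]

    # --- M: body mass ------------------------------------------------------
    wsub = weights[weights["Taxon"] == code]
    neo = mass.neonate_summary(wsub, animals, code, cfg=cfg)
    row["S_N_All_NeonatesWeighed"] = _zero_missing(neo["n"])
    row["M_Mean_All_NeonateWeight_g"] = neo["mean_g"]
    row["M_Min_All_NeonateWeight_g"] = neo["min_g"]
    row["M_Max_All_NeonateWeight_g"] = neo["max_g"]
    for sex in ("M", "F"):
        neo = mass.neonate_summary(wsub, animals, code, sex_filter=sex,
                                   cfg=cfg)
        row[f"S_N_{sex}_NeonatesWeighed"] = _zero_missing(neo["n"])
        row[f"M_Mean_{sex}_NeonateWeight_g"] = neo["mean_g"]
        row[f"M_Min_{sex}_NeonateWeight_g"] = neo["min_g"]
        row[f"M_Max_{sex}_NeonateWeight_g"] = neo["max_g"]

    filtered = mass.filter_weights(wsub, cfg)
    for age_class, label in ((mass.AGE_ADULT, "Adult"),
                             (mass.AGE_YOUNG_ADULT, "YngAdult")):
        inds = mass.individual_mass_means(filtered, age_class)
        kept, _obese = mass.obesity_filter(inds, cfg)
        nvar = ("S_N_{}_AdultsWeighed" if label == "Adult"
                else "S_N_{}_YngAdultsWeighed")
        # the printed table abbreviates the all-individuals young-adult n
        n_all_var = ("S_N_All_AdultsWeighed" if label == "Adult"
                     else "S_N_All_YngAdltsWeighed")
        s = mass.species_mass_summary(kept)
        row[n_all_var] = _zero_missing(s["n"])
        row[f"M_Mean_All_{label}Weight_g"] = s["mean_g"]
        row[f"M_Min_All_{label}Weight_g"] = s["min_g"]
        row[f"M_Max_All_{label}Weight_g"] = s["max_g"]
        for sex in ("M", "F"):
            s = mass.species_mass_summary(kept, sex_filter=sex)
            row[nvar.format(sex)] = _zero_missing(s["n"])
            row[f"M_Mean_{sex}_{label}Weight_g"] = s["mean_g"]
            row[f"M_Min_{sex}_{label}Weight_g"] = s["min_g"]
            row[f"M_Max_{sex}_{label}Weight_g"] = s["max_g"]

    # --- L: longevity and infant mortality ---------------------------------
    for sex, grp in ((None, "All"), ("M", "M"), ("F", "F")):
        mx = survival.max_age(animals, code, sex)
        row[f"L_Max_{grp}_Age_y"] = None if mx is None else round(mx, 2)
        med = survival.median_longevity(animals, code, sex)
        row[f"L_Median_{grp}_Longevity_gt30d_y"] = (
            None if med is None else round(med, 2))
        row[f"S_N_{grp}_Survival_gt30d"] = _zero_missing(
            survival.survival_group_size(animals, code, sex))
    for sex, grp in ((None, "All"), ("M", "M"), ("F", "F"), ("ND", "ND")):
        pct, died, born = survival.infant_mortality(animals, code, sex)
        row[f"L_Pct_{grp}_InfMort_lt30d"] = (
            None if pct is None else round(pct, 2))
        row[f"S_N_{grp}_InfMort_lt30d"] = _zero_missing(died)
    return row


def build_life_history_table(animals: pd.DataFrame, weights: pd.DataFrame,
                             registry: Registry,
                             cfg: Optional[MassSummaryConfig] = None
                             ) -> pd.DataFrame:
    """Analysis-layout table: one row per taxon, the 91 variables as columns.

    Raises ``KeyError`` naming any taxon code present in the files but
    absent from the registry.
    """
    present = set(animals["Taxon"]) | set(weights["Taxon"])
    missing = sorted(present - set(registry.codes))
    if missing:
        raise KeyError(
            "taxa present in files but absent from registry: "
            + ", ".join(missing))
    rows = {}
    for taxon in registry:
        rows[taxon.taxon_code] = build_taxon_row(
            animals, weights, taxon, registry, cfg)
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    table = table[VARIABLES]
    table.index.name = "Taxon"
    return table


def to_reference(table: pd.DataFrame) -> pd.DataFrame:
    """Reference layout: 91 rows x one character column per taxon."""
    ref = pd.DataFrame(index=VARIABLES, columns=table.index, dtype=object)
    ref.index.name = "Variable"
    for taxon in table.index:
        for var in VARIABLES:
            ref.at[var, taxon] = format_cell(var, table.at[taxon, var])
    return ref


def serialize_reference(table: pd.DataFrame, path: str | Path) -> None:
    to_reference(table).to_csv(path)


def serialize_analysis(table: pd.DataFrame, path: str | Path) -> None:
    """Analysis layout CSV: numeric cells numeric, missing as '.'."""
    out = table.copy()
    for var in VARIABLES:
        out[var] = [
            "." if (v is None or (isinstance(v, float) and np.isnan(v)))
            else format_cell(var, v)
            for v in out[var]
        ]
    out.to_csv(path)


def read_analysis(path: str | Path) -> pd.DataFrame:
    """Read an analysis-layout CSV back; numeric columns become numeric."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=["."]).set_index("Taxon")
    for var in VARIABLES:
        if var in _FMT2 or var in _FMT3 or var in _INT:
            df[var] = pd.to_numeric(df[var], errors="coerce")
    return df
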