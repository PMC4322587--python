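"""Body-mass summaries with the exclusion cascade, and weight-file columns.

Species body-mass values are built defensively, because longitudinal colony
weights over-represent unusual states:

* weights within 60 days of death are dropped (terminal decline);
* weights of pregnant females are dropped;
* weights of wild-caught animals at estimated ages below the species'
  minimum dam age at conception are dropped (their age class would be a
  guess);
* within an individual, weights are averaged per calendar month and the
  individual's value is the mean of its monthly means, so weeks of
  frequent clinical weighing do not dominate;
* individuals whose mean lies more than two standard deviations above the
  group mean are flagged obese and removed before species means are taken
  (a single flagging pass, not iterated).

Age classes are anchored on the species' minimum dam age at conception m:
infant/juvenile below m, young adult in [m, 2m), adult at and above 2m.
An individual's weights can span classes; each weight contributes to the
class it was taken in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colony_io import DAYS_PER_YEAR, recompute_weight_ages
from .demography import LitterEvent

AGE_IJ = "IJ"
AGE_YOUNG_ADULT = "young_adult"
AGE_ADULT = "adult"


@dataclass
class MassSummaryConfig:
    """Tunable exclusion thresholds for body-mass summaries."""

    predeath_exclusion_d: int = 60      # drop weights this close to death
    obesity_sd_multiplier: float = 2.0  # flag means above mean + k*SD
    neonate_min_survival_d: int = 1     # neonate must survive this long
    adult_age_multiplier: float = 2.0   # adult at multiplier * min dam age
    seasonal_month_subset: Optional[frozenset[int]] = None

    def __post_init__(self) -> None:
        if (self.predeath_exclusion_d <= 0 or self.obesity_sd_multiplier <= 0
                or self.neonate_min_survival_d <= 0
                or self.adult_age_multiplier <= 0):
            raise ValueError("mass-summary thresholds must be positive")


def classify_age(age_y: float, min_dam_aac_y: float,
                 adult_multiplier: float = 2.0) -> str:
    """Age class from age and the species' minimum dam age at conception."""
    if age_y < 0:
        raise ValueError("negative age")
    if min_dam_aac_y <= 0:
        raise ValueError("min dam age at conception must be positive")
    if age_y < min_dam_aac_y:
        return AGE_IJ
    if age_y < adult_multiplier * min_dam_aac_y:
        return AGE_YOUNG_ADULT
    return AGE_ADULT


def filter_weights(weights: pd.DataFrame,
                   cfg: MassSummaryConfig) -> pd.DataFrame:
    """Apply the record-level exclusions ahead of any mass summary."""
    keep = weights["Weight_g"].notna()
    keep &= ~(weights["DaysBeforeDeath"].notna()
              & (weights["DaysBeforeDeath"] < cfg.predeath_exclusion_d))
    keep &= weights["Preg_Status"] != "P"
    wildish = weights["Birth_Type"].isin(["WB", "UNK"])
    keep &= ~(wildish & (weights["AgeAtWt_y"]
                         < weights["R_Min_Dam_AgeAtConcep_y"]))
    if cfg.seasonal_month_subset is not None:
        keep &= weights["MonthOfWeight"].isin(cfg.seasonal_month_subset)
    return weights[keep]


def individual_mass_means(weights: pd.DataFrame,
                          age_class: str) -> pd.DataFrame:
    """Per-individual mean mass within one age class.

    Weights are bucketed by calendar year-month, averaged per bucket, and
    the individual's value is the unweighted mean of its bucket means.
    Returns columns ``DLC_ID``, ``Sex``, ``mean_g`` (one row per
    individual).
    """
    sub = weights[weights["Age_Category"] == age_class]
    if sub.empty:
        return pd.DataFrame(columns=["DLC_ID", "Sex", "mean_g"])
    ym = sub["Weight_Date"].dt.strftime("%Y-%m")
    monthly = (sub.groupby(["DLC_ID", "Sex", ym], observed=True)["Weight_g"]
               .mean())
    overall = monthly.groupby(["DLC_ID", "Sex"], observed=True).mean()
    out = overall.reset_index()
    out.columns = ["DLC_ID", "Sex", "mean_g"]
    return out


def obesity_filter(individuals: pd.DataFrame, cfg: MassSummaryConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split individual means into (kept, obese) by the +2 SD rule.

    Sample standard deviation (n-1) over the group's individual means; a
    mean strictly above mean + multiplier*SD is obese.  With fewer than two
    individuals the SD is undefined and nothing is flagged.
    """
    if len(individuals) < 2:
        return individuals, individuals.iloc[0:0]
    mu = individuals["mean_g"].mean()
    sd = individuals["mean_g"].std(ddof=1)
    obese = individuals["mean_g"] > mu + cfg.obesity_sd_multiplier * sd
    return individuals[~obese], individuals[obese]


def species_mass_summary(kept: pd.DataFrame,
                         sex_filter: Optional[str] = None) -> dict:
    """n / mean / min / max over kept individual means (n = individuals)."""
    sub = kept if sex_filter is None else kept[kept["Sex"] == sex_filter]
    if sub.empty:
        return {"n": 0, "mean_g": None, "min_g": None, "max_g": None}
    v = sub["mean_g"]
    return {"n": int(len(v)), "mean_g": round(float(v.mean()), 2),
            "min_g": round(float(v.min()), 2),
            "max_g": round(float(v.max()), 2)}


def neonate_summary(weights: pd.DataFrame, animals: pd.DataFrame,
                    taxon: str, sex_filter: Optional[str] = None,
                    cfg: Optional[MassSummaryConfig] = None) -> dict:
    """Neonate mass: weights on day 0 and/or day 1 of life.

    An individual's value is its day-0 weight, its day-1 weight, or the
    average when both exist.  Individuals that did not survive at least one
    day (unviable stillbirths) are excluded.
    """
    cfg = cfg or MassSummaryConfig()
    min_surv_y = cfg.neonate_min_survival_d / DAYS_PER_YEAR
    a = animals.set_index("DLC_ID")
    sub = weights[(weights["Taxon"] == taxon)
                  & weights["AgeAtWt_d"].isin([0, 1])
                  & weights["Weight_g"].notna()]
    if sex_filter is not None:
        sub = sub[sub["Sex"] == sex_filter]
    aad = sub["DLC_ID"].map(a["AgeAtDeath_y"])
    sub = sub[aad.isna() | (aad >= min_surv_y)]
    if sub.empty:
        return {"n": 0, "mean_g": None, "min_g": None, "max_g": None}
    per_day = sub.groupby(["DLC_ID", "AgeAtWt_d"])["Weight_g"].mean()
    per_ind = per_day.groupby("DLC_ID").mean()
    return {"n": int(len(per_ind)),
            "mean_g": round(float(per_ind.mean()), 2),
            "min_g": round(float(per_ind.min()), 2),
            "max_g": round(float(per_ind.max()), 2)}


def weight_derived_columns(weights: pd.DataFrame, animals: pd.DataFrame,
                           litters: Sequence[LitterEvent],
                           min_dam_aac_y: dict[str, Optional[float]],
                           adult_multiplier: float = 2.0) -> pd.DataFrame:
    """Fill every derived weight-file column from core fields.

    Computes age columns, change-since-previous columns, days before death,
    the age category, and — for dams pregnant at weighing time (the weight
    date falls in [conception, birth) of one of her litters) — the
    pregnancy block.  Input order is irrelevant; output is sorted by
    (DLC_ID, Weight_Date).
    """
    w = weights.sort_values(["DLC_ID", "Weight_Date"],
                            kind="mergesort").reset_index(drop=True)
    a = animals.set_index("DLC_ID")

    # identity/status columns carried from the animal list
    for wcol, acol in [("Taxon", "Taxon"), ("Hybrid", "Hybrid"),
                       ("Sex", "Sex"), ("Name", "Name"), ("DOB", "DOB"),
                       ("Estimated_DOB", "Estimated_DOB"), ("DOD", "DOD"),
                       ("Birth_Type", "Birth_Type"),
                       ("Birth_Institution", "Birth_Institution"),
                       ("Litter_Size", "Litter_Size"),
                       ("Current_Resident", "Current_Resident"),
                       ("Expected_Gestation_d", "Expected_Gestation_d")]:
        w[wcol] = w["DLC_ID"].map(a[acol])

    derived = recompute_weight_ages(w)
    for col in derived.columns:
        w[col] = derived[col]

    grp = w.groupby("DLC_ID", sort=False)
    w["Days_Since_PrevWt"] = (
        w["Weight_Date"] - grp["Weight_Date"].shift(1)).dt.days
    w["Change_Since_PrevWt_g"] = w["Weight_g"] - grp["Weight_g"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w["Avg_Daily_WtChange_g"] = (
            w["Change_Since_PrevWt_g"] / w["Days_Since_PrevWt"])
    w.loc[w["Days_Since_PrevWt"] == 0, "Avg_Daily_WtChange_g"] = np.nan

    w["R_Min_Dam_AgeAtConcep_y"] = w["Taxon"].map(
        lambda t: min_dam_aac_y.get(t))
    m = w["R_Min_Dam_AgeAtConcep_y"]
    w["Age_Category"] = np.where(
        m.isna() | w["AgeAtWt_y"].isna(), None,
        np.where(w["AgeAtWt_y"] < m, AGE_IJ,
                 np.where(w["AgeAtWt_y"] < adult_multiplier * m,
                          AGE_YOUNG_ADULT, AGE_ADULT)))

    # pregnancy block
    w["Preg_Status"] = "NP"
    for col in ["ConcepDate_IfPreg", "InfantDOB_IfPreg"]:
        w[col] = pd.NaT
    for col in ["DaysBeforeInfBirth_IfPreg", "Pct_PregRemain_IfPreg",
                "InfantLitSz_IfPreg"]:
        w[col] = np.nan

    by_dam: dict[str, list[LitterEvent]] = {}
    for lit in litters:
        if lit.dam_id is not None:
            by_dam.setdefault(lit.dam_id, []).append(lit)
    females = w["Sex"] == "F"
    for dam_id, dam_litters in by_dam.items():
        rows = w.index[females & (w["DLC_ID"] == dam_id)]
        if not len(rows):
            continue
        dates = w.loc[rows, "Weight_Date"]
        for lit in dam_litters:
            preg = rows[(dates >= lit.conception_date)
                        & (dates < lit.birth_date)]
            if not len(preg):
                continue
            w.loc[preg, "Preg_Status"] = "P"
            w.loc[preg, "ConcepDate_IfPreg"] = lit.conception_date
            w.loc[preg, "InfantDOB_IfPreg"] = lit.birth_date
            days_left = (lit.birth_date - w.loc[preg, "Weight_Date"]).dt.days
            w.loc[preg, "DaysBeforeInfBirth_IfPreg"] = days_left.astype(float)
            w.loc[preg, "Pct_PregRemain_IfPreg"] = (
                days_left / w.loc[preg, "Expected_Gestation_d"])
            w.loc[preg, "InfantLitSz_IfPreg"] = float(lit.size)
    w.loc[w["Sex"] == "M", "Preg_Status"] = "NP"
    return w
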