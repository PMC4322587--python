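"""Read, validate and write the two colony record schemas.

The pipeline's inputs are two longitudinal CSV files maintained by colony
staff:

* the **animal list** — one row per individual with 32 single-copy
  variables (identity, pedigree, dates of birth/death, estimate codes,
  derived ages);
* the **weight file** — one row per weighing event with 33 variables
  (the measurement plus derived age, pregnancy and change-since-previous
  columns).

Records are held as :class:`pandas.DataFrame` objects with the fixed column
sets below.  Dates are ``datetime64[ns]`` columns in memory and ISO-8601 on
disk; missing values are empty fields on write and any of ``''``, ``'.'``,
``'NA'`` on read.  Derived columns are recomputed on read and compared
against the stored values; disagreements beyond tolerance are collected in
a validation report rather than silently overwritten (pass
``recompute=True`` to overwrite instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .registry import Registry

DAYS_PER_YEAR = 365  # divisor used throughout for age-in-years; no leap correction

ANIMAL_COLUMNS = [
    "Taxon", "DLC_ID", "Hybrid", "Sex", "Name", "Current_Resident",
    "StudBook", "DOB", "Birth_Month", "Estimated_DOB", "Birth_Type",
    "Birth_Institution", "Litter_Size", "Expected_Gestation_d",
    "Estimated_Concep", "Concep_Month", "Dam_ID", "Dam_Name", "Dam_Taxon",
    "Dam_DOB", "Dam_AgeAtConcep_y", "Sire_ID", "Sire_Name", "Sire_Taxon",
    "Sire_DOB", "Sire_AgeAtConcep_y", "DOD", "AgeAtDeath_y",
    "AgeOfLiving_y", "AgeLastVerified_y", "AgeMax_LiveOrDead_y",
    "N_known_offspring",
]

WEIGHT_COLUMNS = [
    "Taxon", "Hybrid", "DLC_ID", "Sex", "Name", "DOB", "Estimated_DOB",
    "Weight_g", "Weight_Date", "MonthOfWeight", "AgeAtWt_d", "AgeAtWt_wk",
    "AgeAtWt_mo", "AgeAtWt_mo_NoDec", "AgeAtWt_y", "Days_Since_PrevWt",
    "Change_Since_PrevWt_g", "Avg_Daily_WtChange_g", "DOD",
    "DaysBeforeDeath", "Birth_Type", "Birth_Institution", "Litter_Size",
    "R_Min_Dam_AgeAtConcep_y", "Age_Category", "Current_Resident",
    "Preg_Status", "Expected_Gestation_d", "ConcepDate_IfPreg",
    "InfantDOB_IfPreg", "DaysBeforeInfBirth_IfPreg", "Pct_PregRemain_IfPreg",
    "InfantLitSz_IfPreg",
]

ANIMAL_DATE_COLUMNS = ["DOB", "Estimated_Concep", "Dam_DOB", "Sire_DOB", "DOD"]
WEIGHT_DATE_COLUMNS = ["DOB", "Weight_Date", "DOD", "ConcepDate_IfPreg",
                       "InfantDOB_IfPreg"]

_NA_TOKENS = ["", ".", "NA"]

# institution names treated as "born at this colony"
HOME_INSTITUTIONS = {"duke prim", "duke primate center", "duke lemur center", "dlc"}


def is_home_born(animals: pd.DataFrame) -> pd.Series:
    """Boolean mask: individuals born at the colony itself (``DLC-born``)."""
    inst = animals["Birth_Institution"].fillna("").str.strip().str.lower()
    return (animals["Birth_Type"] == "CB") & inst.isin(HOME_INSTITUTIONS)


@dataclass
class ValidationIssue:
    kind: str
    message: str
    dlc_id: Optional[str] = None
    row: Optional[int] = None


@dataclass
class ValidationReport:
    """Accumulated record-level problems; producing one is never an error."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, kind: str, message: str, dlc_id: Optional[str] = None,
            row: Optional[int] = None) -> None:
        self.issues.append(ValidationIssue(kind, message, dlc_id, row))

    def kinds(self) -> set[str]:
        return {i.kind for i in self.issues}

    def by_kind(self, kind: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == kind]

    def __len__(self) -> int:
        return len(self.issues)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def summary(self) -> str:
        if not self.issues:
            return "no issues"
        lines = []
        for kind in sorted(self.kinds()):
            n = len(self.by_kind(kind))
            lines.append(f"{kind}: {n}")
        return "; ".join(lines)


class SchemaError(ValueError):
    """A file does not conform to the expected column schema."""


def _parse_dates(df: pd.DataFrame, columns: list[str], path: str,
                 report: ValidationReport) -> None:
    for col in columns:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
        # second chance: US-style M/D/YYYY
        retry = parsed.isna() & raw.notna()
        if retry.any():
            parsed[retry] = pd.to_datetime(
                raw[retry], format="%m/%d/%Y", errors="coerce"
            )
        bad = parsed.isna() & raw.notna()
        for idx in df.index[bad]:
            report.add("unparseable_date",
                       f"{path}: column {col} row {idx}: {raw[idx]!r}",
                       row=int(idx))
        df[col] = parsed


def _check_columns(df: pd.DataFrame, expected: list[str], path: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): "
                          + ", ".join(missing))


def _recompute_animal_derived(animals: pd.DataFrame) -> pd.DataFrame:
    """Derived animal-list columns from their defining core columns."""
    out = pd.DataFrame(index=animals.index)
    out["Birth_Month"] = animals["DOB"].dt.month
    gest = pd.to_timedelta(animals["Expected_Gestation_d"], unit="D")
    out["Estimated_Concep"] = animals["DOB"] - gest
    out["Concep_Month"] = out["Estimated_Concep"].dt.month
    out["Dam_AgeAtConcep_y"] = (
        (out["Estimated_Concep"] - animals["Dam_DOB"]).dt.days / DAYS_PER_YEAR
    )
    out["Sire_AgeAtConcep_y"] = (
        (out["Estimated_Concep"] - animals["Sire_DOB"]).dt.days / DAYS_PER_YEAR
    )
    out["AgeAtDeath_y"] = (animals["DOD"] - animals["DOB"]).dt.days / DAYS_PER_YEAR
    return out


def _compare_derived(stored: pd.DataFrame, computed: pd.DataFrame,
                     report: ValidationReport, tol: float = 1e-6) -> None:
    for col in computed.columns:
        s, c = stored[col], computed[col]
        if pd.api.types.is_numeric_dtype(c):
            both = s.notna() & c.notna()
            bad = both & ((s - c).abs() > tol)
        else:
            bad = s.notna() & c.notna() & (s != c)
        for idx in stored.index[bad]:
            report.add(
                "derived_mismatch",
                f"{col} row {idx}: stored {s[idx]!r} != computed {c[idx]!r}",
                dlc_id=str(stored.at[idx, "DLC_ID"])
                if "DLC_ID" in stored else None,
                row=int(idx),
            )


def read_animal_list(path: str | Path, registry: Registry,
                     recompute: bool = False,
                     report: Optional[ValidationReport] = None) -> pd.DataFrame:
    """Read and validate an animal-list CSV.

    Returns a DataFrame with the 32 schema columns.  Unknown taxon codes and
    duplicate IDs go into *report*; a missing mandatory column raises
    :class:`SchemaError`.
    """
    if report is None:
        report = ValidationReport()
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=_NA_TOKENS)
    _check_columns(df, ANIMAL_COLUMNS, str(path))
    df = df[ANIMAL_COLUMNS].copy()
    _parse_dates(df, ANIMAL_DATE_COLUMNS, str(path), report)
    for col in ["Birth_Month", "Concep_Month", "Expected_Gestation_d",
                "Litter_Size", "N_known_offspring"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ["Dam_AgeAtConcep_y", "Sire_AgeAtConcep_y", "AgeAtDeath_y",
                "AgeOfLiving_y", "AgeLastVerified_y", "AgeMax_LiveOrDead_y"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    unknown = ~df["Taxon"].isin(registry.codes)
    for idx in df.index[unknown]:
        report.add("unknown_taxon", f"row {idx}: taxon {df.at[idx, 'Taxon']!r}",
                   dlc_id=str(df.at[idx, "DLC_ID"]), row=int(idx))
    dups = df["DLC_ID"][df["DLC_ID"].duplicated()].unique()
    for d in dups:
        report.add("duplicate_id", f"duplicate DLC_ID {d!r}", dlc_id=str(d))

    computed = _recompute_animal_derived(df)
    if recompute:
        stored_aad = df["AgeAtDeath_y"].copy()
        for col in computed.columns:
            df[col] = computed[col]
        # keep stored value where core inputs were absent
        df["AgeAtDeath_y"] = df["AgeAtDeath_y"].fillna(stored_aad)
    else:
        _compare_derived(df, computed, report)
    df.attrs["validation"] = report
    return df


def read_weight_file(path: str | Path, registry: Registry,
                     recompute: bool = False,
                     report: Optional[ValidationReport] = None) -> pd.DataFrame:
    """Read and validate a weight-file CSV, sorted by (DLC_ID, Weight_Date)."""
    if report is None:
        report = ValidationReport()
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=_NA_TOKENS)
    _check_columns(df, WEIGHT_COLUMNS, str(path))
    df = df[WEIGHT_COLUMNS].copy()
    _parse_dates(df, WEIGHT_DATE_COLUMNS, str(path), report)
    num_cols = ["Weight_g", "MonthOfWeight", "AgeAtWt_d", "AgeAtWt_wk",
                "AgeAtWt_mo", "AgeAtWt_mo_NoDec", "AgeAtWt_y",
                "Days_Since_PrevWt", "Change_Since_PrevWt_g",
                "Avg_Daily_WtChange_g", "DaysBeforeDeath", "Litter_Size",
                "R_Min_Dam_AgeAtConcep_y", "Expected_Gestation_d",
                "DaysBeforeInfBirth_IfPreg", "Pct_PregRemain_IfPreg",
                "InfantLitSz_IfPreg"]
    for col in num_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    unknown = ~df["Taxon"].isin(registry.codes)
    for idx in df.index[unknown]:
        report.add("unknown_taxon", f"row {idx}: taxon {df.at[idx, 'Taxon']!r}",
                   dlc_id=str(df.at[idx, "DLC_ID"]), row=int(idx))

    neg = (df["Weight_Date"] - df["DOB"]).dt.days < 0
    for idx in df.index[neg]:
        report.add("negative_age", f"row {idx}: weight date precedes birth",
                   dlc_id=str(df.at[idx, "DLC_ID"]), row=int(idx))
    nonpos = df["Weight_g"].notna() & (df["Weight_g"] <= 0)
    for idx in df.index[nonpos]:
        report.add("nonpositive_weight",
                   f"row {idx}: weight {df.at[idx, 'Weight_g']} g",
                   dlc_id=str(df.at[idx, "DLC_ID"]), row=int(idx))

    computed = recompute_weight_ages(df)
    if recompute:
        for col in computed.columns:
            df[col] = computed[col]
    else:
        _compare_derived(df, computed, report)

    df = df.sort_values(["DLC_ID", "Weight_Date"], kind="mergesort")
    df = df.reset_index(drop=True)
    df.attrs["validation"] = report
    return df


def recompute_weight_ages(weights: pd.DataFrame) -> pd.DataFrame:
    """Age and days-before-death columns from Weight_Date, DOB and DOD."""
    out = pd.DataFrame(index=weights.index)
    days = (weights["Weight_Date"] - weights["DOB"]).dt.days
    out["MonthOfWeight"] = weights["Weight_Date"].dt.month
    out["AgeAtWt_d"] = days.astype(float)
    out["AgeAtWt_wk"] = days / 7
    out["AgeAtWt_mo"] = days / DAYS_PER_YEAR * 12
    out["AgeAtWt_mo_NoDec"] = np.floor(out["AgeAtWt_mo"])
    out["AgeAtWt_y"] = days / DAYS_PER_YEAR
    out["DaysBeforeDeath"] = (weights["DOD"] - weights["Weight_Date"]).dt.days
    return out


def _format_for_write(df: pd.DataFrame, date_cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in date_cols:
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            # integers stored as float (nullable) print without trailing .0
            as_int = out[col].dropna() % 1 == 0
            if len(as_int) and as_int.all():
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else str(int(v)))
    return out


def write_animal_list(animals: pd.DataFrame, path: str | Path) -> None:
    _format_for_write(animals[ANIMAL_COLUMNS], ANIMAL_DATE_COLUMNS).to_csv(
        path, index=False, na_rep="")


def write_weight_file(weights: pd.DataFrame, path: str | Path) -> None:
    _format_for_write(weights[WEIGHT_COLUMNS], WEIGHT_DATE_COLUMNS).to_csv(
        path, index=False, na_rep="")


def validate_animals(animals: pd.DataFrame,
                     report: Optional[ValidationReport] = None
                     ) -> ValidationReport:
    """Record-level invariants of the animal list.

    Checks the one-of-three age rule (each individual has exactly one of
    age-at-death, age-if-living, age-last-verified, and the maximum-age
    column equals it), death-after-birth ordering, and nonnegative ages.
    """
    if report is None:
        report = ValidationReport()
    three = animals[["AgeAtDeath_y", "AgeOfLiving_y", "AgeLastVerified_y"]]
    npop = three.notna().sum(axis=1)
    for idx in animals.index[npop != 1]:
        report.add("age_rule",
                   f"row {idx}: {npop[idx]} of the three age columns populated",
                   dlc_id=str(animals.at[idx, "DLC_ID"]), row=int(idx))
    the_one = three.astype(float).bfill(axis=1).iloc[:, 0]
    ok = npop == 1
    bad = ok & ((animals["AgeMax_LiveOrDead_y"] - the_one).abs() > 1e-6)
    for idx in animals.index[bad]:
        report.add("age_rule",
                   f"row {idx}: AgeMax_LiveOrDead_y disagrees with its source",
                   dlc_id=str(animals.at[idx, "DLC_ID"]), row=int(idx))
    neg = (animals["DOD"] - animals["DOB"]).dt.days < 0
    for idx in animals.index[neg]:
        report.add("negative_age", f"row {idx}: death precedes birth",
                   dlc_id=str(animals.at[idx, "DLC_ID"]), row=int(idx))
    for col in ["AgeAtDeath_y", "AgeOfLiving_y", "AgeLastVerified_y",
                "AgeMax_LiveOrDead_y"]:
        negc = animals[col].notna() & (animals[col] < 0)
        for idx in animals.index[negc]:
            report.add("negative_age", f"row {idx}: {col} < 0",
                       dlc_id=str(animals.at[idx, "DLC_ID"]), row=int(idx))
    wb = animals["Birth_Type"].isin(["WB", "UNK"])
    noest = wb & animals["Estimated_DOB"].isna()
    for idx in animals.index[noest]:
        report.add("missing_estimate_code",
                   f"row {idx}: wild/unknown origin without DOB estimate code",
                   dlc_id=str(animals.at[idx, "DLC_ID"]), row=int(idx))
    return report


def validate_colony(animals: pd.DataFrame, weights: pd.DataFrame,
                    project_range: tuple[str, str] = ("1960-01-01", "2030-12-31"),
                    weight_band_multiplier: float = 10.0) -> ValidationReport:
    """Cross-file plausibility screen for impossible outliers.

    Flags dates outside the project range, weights more than
    *weight_band_multiplier* times (or under 1/multiplier of) the taxon
    median, negative ages, weight records whose individual is absent from
    the animal list, and animals violating the one-of-three age rule.
    """
    report = validate_animals(animals)
    lo = pd.Timestamp(project_range[0])
    hi = pd.Timestamp(project_range[1])
    for df, cols, label in (
        (animals, ["DOB", "DOD"], "animal list"),
        (weights, ["Weight_Date"], "weight file"),
    ):
        for col in cols:
            out = df[col].notna() & ((df[col] < lo) | (df[col] > hi))
            for idx in df.index[out]:
                report.add("date_out_of_range",
                           f"{label} row {idx}: {col} = "
                           f"{df.at[idx, col].date()}",
                           dlc_id=str(df.at[idx, "DLC_ID"]), row=int(idx))

    # reference mass per taxon: median of weights taken at >= 1 y of age,
    # so that legitimately tiny infant weights do not distort the band and
    # are not themselves flagged on the low side
    age_y = (weights["Weight_Date"] - weights["DOB"]).dt.days / DAYS_PER_YEAR
    grown = weights[age_y >= 1]
    ref_by_taxon = grown.groupby("Taxon")["Weight_g"].median()
    ref = weights["Taxon"].map(ref_by_taxon)
    wild = weights["Weight_g"].notna() & ref.notna() & (
        (weights["Weight_g"] > ref * weight_band_multiplier)
        | ((age_y >= 1) & (weights["Weight_g"] < ref / weight_band_multiplier))
    )
    for idx in weights.index[wild]:
        report.add("weight_out_of_range",
                   f"row {idx}: {weights.at[idx, 'Weight_g']} g vs taxon "
                   f"reference {ref[idx]:.1f} g",
                   dlc_id=str(weights.at[idx, "DLC_ID"]), row=int(idx))

    negw = (weights["Weight_Date"] - weights["DOB"]).dt.days < 0
    for idx in weights.index[negw]:
        report.add("negative_age", f"weight row {idx}: weighed before birth",
                   dlc_id=str(weights.at[idx, "DLC_ID"]), row=int(idx))

    known = set(animals["DLC_ID"])
    orphan = ~weights["DLC_ID"].isin(known)
    for d in weights["DLC_ID"][orphan].unique():
        report.add("orphan_weight",
                   f"weight records for DLC_ID {d!r} not in animal list",
                   dlc_id=str(d))
    return report
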