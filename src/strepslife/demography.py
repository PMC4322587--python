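"""Conception estimation, estimated birth dates, parental ages, litters.

Reproductive statistics are computed on *litter events*: a litter's birth
(or its back-calculated conception) is one event regardless of how many
infants it contained.  Conception dates are estimates — the species'
expected gestation length subtracted from the infant's exact birth date —
so infants that did not survive at least one day (candidate premature
births and stillbirths) are excluded from every calculation that involves a
conception date, where a shortened true gestation would bias the estimate
early.

Wild-caught animals carry estimated dates of birth assigned on arrival: for
seasonal breeders the first day of the middle month of the breeding season
in the country of origin in the estimated birth year; for non-seasonal
breeders the month and day of acquisition with the estimated year.  Animals
documented only as "adult" are assigned an age equal to the species'
minimum dam age at conception, making every age computed for them a
minimum: such animals may enter maxima but never minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import pandas as pd

from .colony_io import DAYS_PER_YEAR, is_home_born
from .registry import Registry

logger = logging.getLogger(__name__)

#: Age (years) an infant must reach for its conception date to be trusted.
MIN_SURVIVAL_FOR_CONCEPTION_Y = 1 / DAYS_PER_YEAR


def estimate_conception(dob: date, gestation_d: int) -> date:
    """Expected conception date: birth date minus gestation days."""
    if gestation_d < 0:
        raise ValueError("gestation must be nonnegative")
    return dob - timedelta(days=int(gestation_d))


def assign_estimated_dob(acquisition_date: date,
                         est_birth_year: Optional[int],
                         pattern: str,
                         origin_midmonth: Optional[int] = None,
                         adult_only: bool = False,
                         min_dam_aac_y: Optional[float] = None
                         ) -> tuple[date, str]:
    """Estimated date of birth and estimate code for a wild-caught animal.

    Returns ``(dob, code)`` where code ``'Y'`` marks a year-level estimate
    and ``'U'`` an unknown age assigned from adult status alone.
    """
    if adult_only:
        if min_dam_aac_y is None:
            raise ValueError("adult-only estimate needs min_dam_aac_y")
        return (acquisition_date - timedelta(days=round(min_dam_aac_y * DAYS_PER_YEAR)),
                "U")
    if est_birth_year is None:
        raise ValueError("need an estimated birth year or adult_only=True")
    if pattern == "S":
        if origin_midmonth is None:
            raise ValueError("seasonal breeder needs origin_midmonth")
        return date(est_birth_year, origin_midmonth, 1), "Y"
    day = min(acquisition_date.day, 28) if acquisition_date.month == 2 \
        else acquisition_date.day
    return date(est_birth_year, acquisition_date.month, day), "Y"


@dataclass
class LitterEvent:
    """One litter: the infants born to one dam on one date."""

    taxon: str
    dam_id: Optional[str]
    birth_date: pd.Timestamp
    conception_date: pd.Timestamp
    size: int
    member_ids: frozenset[str]
    any_survived_1d: bool


def build_litters(animals: pd.DataFrame, taxon: str,
                  registry: Registry) -> list[LitterEvent]:
    """Group colony-born individuals of a taxon into litter events.

    The litter key is (dam id, exact birth date); records with no dam
    recorded become singleton events.  A stored litter-size field that
    disagrees with the member count is logged; the member count wins.
    """
    gest = registry[taxon].expected_gestation_d
    sub = animals[(animals["Taxon"] == taxon) & is_home_born(animals)]
    litters: list[LitterEvent] = []

    def survived(rows: pd.DataFrame) -> bool:
        aad = rows["AgeAtDeath_y"]
        return bool((aad.isna() | (aad >= MIN_SURVIVAL_FOR_CONCEPTION_Y)).any())

    def make(dam_id, dob, rows: pd.DataFrame) -> LitterEvent:
        stored = rows["Litter_Size"].dropna().unique()
        if len(stored) and not (stored == len(rows)).all():
            logger.warning(
                "taxon %s dam %s dob %s: stored litter size %s != %d members",
                taxon, dam_id, dob, stored, len(rows))
        return LitterEvent(
            taxon=taxon, dam_id=dam_id, birth_date=dob,
            conception_date=dob - pd.Timedelta(days=gest),
            size=len(rows), member_ids=frozenset(rows["DLC_ID"]),
            any_survived_1d=survived(rows))

    with_dam = sub[sub["Dam_ID"].notna()]
    for (dam_id, dob), rows in with_dam.groupby(["Dam_ID", "DOB"], sort=True):
        litters.append(make(dam_id, dob, rows))
    for _, row in sub[sub["Dam_ID"].isna()].iterrows():
        litters.append(make(None, row["DOB"], sub.loc[[row.name]]))
    return litters


def litter_stats(litters: list[LitterEvent]) -> dict:
    """Mean, most common (ties comma-joined ascending), frequency of the
    most common size, min and max litter size."""
    if not litters:
        raise ValueError("no litters")
    sizes = pd.Series([l.size for l in litters])
    vc = sizes.value_counts()
    top = vc.max()
    modes = sorted(vc.index[vc == top])
    return {
        "mean": round(float(sizes.mean()), 2),
        "most_common": ",".join(str(m) for m in modes),
        "freq_most_common": round(top / len(sizes), 2),
        "min": int(sizes.min()),
        "max": int(sizes.max()),
    }


def birth_sex_ratio(animals: pd.DataFrame, taxon: str) -> Optional[float]:
    """Males per female among colony births (3 dp); ``None`` with no females."""
    sub = animals[(animals["Taxon"] == taxon) & is_home_born(animals)]
    m = int((sub["Sex"] == "M").sum())
    f = int((sub["Sex"] == "F").sum())
    if f == 0:
        return None
    return round(m / f, 3)


def _multi_or_unknown_sire(sire_id: pd.Series) -> pd.Series:
    sid = sire_id.fillna("").str.upper()
    return sid.str.startswith("MULT") | sid.isin(["", "UNK", "WILD"])


def parental_age_extremes(animals: pd.DataFrame, taxon: str) -> dict:
    """Min/max dam and sire ages at conception (years) for one taxon.

    Minima use only parents with exact (non-estimated) birth dates known in
    the colony records; maxima admit estimated birth dates as well (an
    estimated age cannot exceed the true age).  Offspring that did not
    survive one day are excluded, as are sire statistics for offspring with
    multiple or unknown possible sires.
    """
    sub = animals[animals["Taxon"] == taxon]
    survived = (sub["AgeAtDeath_y"].isna()
                | (sub["AgeAtDeath_y"] >= MIN_SURVIVAL_FOR_CONCEPTION_Y))
    sub = sub[survived]

    # parents whose own colony record shows an exact date of birth
    exact_dob_ids = set(
        animals.loc[animals["Estimated_DOB"].isna()
                    & (animals["Birth_Type"] == "CB"), "DLC_ID"])

    out: dict[str, Optional[float]] = {}
    for parent, id_col, dob_col in (
        ("dam", "Dam_ID", "Dam_DOB"),
        ("sire", "Sire_ID", "Sire_DOB"),
    ):
        rows = sub[sub[dob_col].notna() & sub["Estimated_Concep"].notna()]
        if parent == "sire":
            rows = rows[~_multi_or_unknown_sire(rows[id_col])]
        ages = (rows["Estimated_Concep"] - rows[dob_col]).dt.days / DAYS_PER_YEAR
        exact = rows[id_col].isin(exact_dob_ids)
        out[f"min_{parent}"] = (
            round(float(ages[exact].min()), 2) if exact.any() else None)
        out[f"max_{parent}"] = (
            round(float(ages.max()), 2) if len(ages) else None)
    return out


def count_offspring(animals: pd.DataFrame) -> pd.Series:
    """Known offspring per individual, indexed by DLC_ID.

    Counts records naming the individual as dam, or as unique sire; when
    multiple sires are possible the offspring is counted for none of them.
    """
    dam_counts = animals["Dam_ID"].dropna().value_counts()
    sires = animals.loc[~_multi_or_unknown_sire(animals["Sire_ID"]), "Sire_ID"]
    sire_counts = sires.value_counts()
    total = dam_counts.add(sire_counts, fill_value=0)
    out = pd.Series(0, index=animals["DLC_ID"], dtype=int)
    known = total.index.intersection(out.index)
    out.loc[known] = total.loc[known].astype(int)
    return out
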