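"""Simulate a captive breeding colony with known ground-truth parameters.

The simulator emits the two record schemas (animal list and weight file)
for a colony whose demographic and physiological parameters are chosen up
front, so that every derivation rule in the pipeline can be checked against
a known answer.  It emulates the statistical structure the derivations
assume:

* seasonal or non-seasonal conception-month distributions, with births
  offset from conception by the species' gestation length;
* litter-size distributions and managed pairing within a dam breeding
  window;
* early infant mortality (deaths before 30 days, stillbirths included,
  some of undetermined sex) and exponential adult mortality;
* right-censoring: animals alive at the end of the simulated window, and
  animals transferred out whose status is only "last verified alive";
* wild-caught founders with estimated dates of birth, assigned through the
  same estimation rule the pipeline uses;
* asymptotic growth to an adult plateau with seasonal mass oscillation,
  pregnancy mass gain, terminal pre-death decline, a configurable obese
  fraction, and multiplicative measurement noise.

Individual-level reproductive timing in a real managed colony is decided
by husbandry staff; the simulator reproduces only the species-level
structure (random pairing within the breeding window), which is all the
derived table measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import demography, mass
from .colony_io import DAYS_PER_YEAR
from .registry import Registry, TaxonInfo

_SEASONAL_PMF = (0.15, 0.05, 0, 0, 0, 0, 0, 0, 0, 0.10, 0.40, 0.30)
_UNIFORM_PMF = tuple(np.full(12, 1 / 12))


@dataclass
class ColonyParams:
    """Ground-truth configuration for one simulated taxon.

    Rates are per year, masses in grams, ages in years, the conception
    month distribution is a 12-vector over January-December.
    """

    taxon: str = "SYNT"
    n_founders: int = 30
    years_simulated: int = 25
    start_year: int = 1985
    gestation_d: int = 120
    breeding_pattern: str = "S"
    conception_month_pmf: tuple = _SEASONAL_PMF
    litter_size_pmf: tuple = (0.60, 0.30, 0.08, 0.02, 0.0)  # sizes 1..5
    infant_mort_prob: float = 0.25
    adult_hazard: float = 0.08            # exponential death rate, 1/y
    sex_ratio_at_birth: float = 0.5       # P(male)
    nd_sex_prob_given_infant_death: float = 0.5
    censor_living_fraction: float = 0.15  # transferred out, status uncertain
    wildborn_fraction: float = 0.5        # of founders
    min_dam_age_y: float = 1.5
    max_dam_age_y: float = 15.0
    growth_asymptote_g: float = 2500.0
    # ~90% of the plateau at the minimum breeding age, ~99% at twice that
    # age: animals keep growing slowly through the young-adult window
    growth_rate_per_y: float = 1.5
    neonate_mass_g: float = 70.0
    seasonal_mass_amplitude: float = 0.05
    obesity_fraction: float = 0.05
    obesity_multiplier: float = 2.0
    pregnancy_gain_frac: float = 0.15     # proportional gain at term
    terminal_decline_frac: float = 0.20   # proportional loss over final 60 d
    weighing_interval_d: int = 30
    measurement_cv: float = 0.02
    multi_sire_fraction: float = 0.02
    origin_breeding_midmonth: int = 5
    max_litters_per_year: int = 14  # husbandry cap on managed breedings

    def validate(self) -> None:
        probs = [self.infant_mort_prob, self.sex_ratio_at_birth,
                 self.nd_sex_prob_given_infant_death,
                 self.censor_living_fraction, self.wildborn_fraction,
                 self.obesity_fraction, self.multi_sire_fraction]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"{self.taxon}: probabilities must be in [0,1]")
        for name, pmf in (("conception_month_pmf", self.conception_month_pmf),
                          ("litter_size_pmf", self.litter_size_pmf)):
            arr = np.asarray(pmf, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"{self.taxon}: {name} must sum to 1")
        if self.gestation_d <= 0:
            raise ValueError(f"{self.taxon}: gestation_d must be positive")
        if self.obesity_multiplier <= 1:
            raise ValueError(f"{self.taxon}: obesity_multiplier must exceed 1")
        if self.breeding_pattern not in ("S", "NS"):
            raise ValueError(f"{self.taxon}: bad breeding_pattern")


@dataclass
class TaxonTruth:
    """True parameter values behind one simulated taxon."""

    taxon: str
    peak_conception_month: int
    median_longevity_y: float     # ln 2 / adult hazard
    infant_mortality: float
    adult_mean_mass_g: float
    obese_ids: list[str] = field(default_factory=list)
    censored_ids: list[str] = field(default_factory=list)
    n_founders: int = 0
    n_births: int = 0


@dataclass
class GroundTruth:
    taxa: dict[str, TaxonTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in self.taxa.items()}, fh,
                      indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: TaxonTruth(**v) for k, v in raw.items()})


def params_registry(params: Sequence[ColonyParams]) -> Registry:
    """A taxon registry matching a set of simulation parameters."""
    return Registry(
        TaxonInfo(
            taxon_code=p.taxon,
            latin_name=f"Synthetica {p.taxon.lower()}",
            common_name=f"Synthetic {p.taxon}",
            expected_gestation_d=p.gestation_d,
            gestation_range_d=(p.gestation_d, p.gestation_d + 8),
            breeding_pattern=p.breeding_pattern,
            activity="N" if p.growth_asymptote_g < 500 else "D",
            active_dlc_breeding="Y",
            n_biosample_individuals=None,
            origin_breeding_midmonth=(
                p.origin_breeding_midmonth
                if p.breeding_pattern == "S" else None),
        )
        for p in params
    )


class _Animal:
    __slots__ = ("id", "sex", "true_dob", "dob", "est_code", "birth_type",
                 "institution", "dam", "sire", "sire_mult", "litter_size",
                 "death", "transfer", "obese", "founder")

    def __init__(self, **kw):
        for k in self.__slots__:
            setattr(self, k, kw.get(k))


def _sample_month(rng, pmf) -> int:
    return int(rng.choice(12, p=np.asarray(pmf, dtype=float))) + 1


def _simulate_taxon(p: ColonyParams, rng: np.random.Generator,
                    id_counter: list[int]) -> tuple[list[_Animal], TaxonTruth]:
    start = pd.Timestamp(p.start_year, 1, 1)
    end = start + pd.Timedelta(days=p.years_simulated * DAYS_PER_YEAR)
    animals: list[_Animal] = []

    def new_id() -> str:
        id_counter[0] += 1
        return str(id_counter[0])

    def residual_life(age_now_y: float) -> float:
        return age_now_y + rng.exponential(1 / p.adult_hazard) \
            if p.adult_hazard > 0 else math.inf

    # --- founders: adults present at colony start -------------------------
    for i in range(p.n_founders):
        sex = "M" if i % 2 == 0 else "F"
        age0 = rng.uniform(p.min_dam_age_y + 0.2,
                           max(p.min_dam_age_y + 1.0, min(8.0, p.max_dam_age_y)))
        true_dob = start - pd.Timedelta(days=round(age0 * DAYS_PER_YEAR))
        wild = rng.random() < p.wildborn_fraction
        if wild:
            dob, code = demography.assign_estimated_dob(
                start.date(), true_dob.year, p.breeding_pattern,
                p.origin_breeding_midmonth)
            dob = pd.Timestamp(dob)
            birth_type, inst, dam = "WB", "Madagascar", "WILD"
        else:
            dob, code = true_dob, None
            birth_type, inst, dam = "CB", "Other Facility", None
        death_age = residual_life(age0)
        animals.append(_Animal(
            id=new_id(), sex=sex, true_dob=true_dob, dob=dob, est_code=code,
            birth_type=birth_type, institution=inst, dam=dam, sire=None,
            sire_mult=False, litter_size=None,
            death=true_dob + pd.Timedelta(days=round(death_age * DAYS_PER_YEAR))
            if math.isfinite(death_age) else None,
            transfer=None, obese=rng.random() < p.obesity_fraction,
            founder=True))

    # --- yearly managed breeding -----------------------------------------
    n_births = 0
    sizes = np.arange(1, len(p.litter_size_pmf) + 1)
    last_birth: dict[str, pd.Timestamp] = {}
    for year in range(p.years_simulated):
        yr = p.start_year + year
        males = [a for a in animals if a.sex == "M"]
        dams = [a for a in animals if a.sex == "F"]
        # breeding is managed: at most max_litters_per_year dams are paired,
        # chosen at random among the eligible, keeping the colony near a
        # target size instead of growing without bound
        dams = [dams[i] for i in rng.permutation(len(dams))]
        litters_this_year = 0
        for dam in dams:
            if litters_this_year >= p.max_litters_per_year:
                break
            month = _sample_month(rng, p.conception_month_pmf)
            # mid-month days only: keeps birth month = conception month +
            # gestation at whole-month offsets, independent of month length
            concep = pd.Timestamp(yr, month, int(rng.integers(3, 28)))
            birth = concep + pd.Timedelta(days=p.gestation_d)
            if birth >= end:
                continue
            dam_age = (concep - dam.true_dob).days / DAYS_PER_YEAR
            if not (p.min_dam_age_y <= dam_age <= p.max_dam_age_y):
                continue
            if dam.death is not None and dam.death <= birth:
                continue
            if dam.transfer is not None and dam.transfer <= birth:
                continue
            if dam.id in last_birth and concep <= last_birth[dam.id]:
                continue  # still pregnant from the previous litter

            def eligible_sire(s: _Animal) -> bool:
                if s.death is not None and s.death <= concep:
                    return False
                if s.transfer is not None and s.transfer <= concep:
                    return False
                return ((concep - s.true_dob).days / DAYS_PER_YEAR
                        >= p.min_dam_age_y)

            sires = [s for s in males if eligible_sire(s)]
            if not sires:
                continue
            sire = sires[int(rng.integers(len(sires)))]
            mult = rng.random() < p.multi_sire_fraction
            lit_size = int(rng.choice(sizes, p=np.asarray(p.litter_size_pmf)))
            last_birth[dam.id] = birth
            litters_this_year += 1
            for _ in range(lit_size):
                sex = "M" if rng.random() < p.sex_ratio_at_birth else "F"
                if rng.random() < p.infant_mort_prob:
                    # early death, before 30 days; some are stillbirths
                    day = 0 if rng.random() < 0.2 else int(rng.integers(1, 30))
                    death = birth + pd.Timedelta(days=day)
                    if rng.random() < p.nd_sex_prob_given_infant_death:
                        sex = "ND"
                else:
                    age = 30 / DAYS_PER_YEAR + (
                        rng.exponential(1 / p.adult_hazard)
                        if p.adult_hazard > 0 else math.inf)
                    death = (birth + pd.Timedelta(days=round(age * DAYS_PER_YEAR))
                             if math.isfinite(age) else None)
                animals.append(_Animal(
                    id=new_id(), sex=sex, true_dob=birth, dob=birth,
                    est_code=None, birth_type="CB", institution="Duke Prim",
                    dam=dam.id, sire="MULT2" if mult else sire.id,
                    sire_mult=mult, litter_size=lit_size, death=death,
                    transfer=None, obese=rng.random() < p.obesity_fraction,
                    founder=False))
                n_births += 1

    # --- transfers out (status becomes "last verified alive") -------------
    # The candidate transfer date is drawn independently of the (unknown to
    # the institutions involved) death date, and takes effect only if the
    # animal is still alive then: censoring must carry no information about
    # residual lifetime or the survivorship fit would be biased.
    for a in animals:
        if rng.random() >= p.censor_living_fraction:
            continue
        lo = a.true_dob + pd.Timedelta(days=DAYS_PER_YEAR)
        if a.founder:
            lo = max(lo, start + pd.Timedelta(days=30))
        window = (end - lo).days
        if window < 100:
            continue
        cand = lo + pd.Timedelta(days=int(rng.integers(0, window)))
        if a.death is None or cand < a.death:
            a.transfer = cand

    truth = TaxonTruth(
        taxon=p.taxon,
        peak_conception_month=int(np.argmax(p.conception_month_pmf)) + 1,
        median_longevity_y=(math.log(2) / p.adult_hazard
                            if p.adult_hazard > 0 else math.inf),
        infant_mortality=p.infant_mort_prob,
        adult_mean_mass_g=p.growth_asymptote_g,
        obese_ids=[a.id for a in animals if a.obese],
        censored_ids=[a.id for a in animals if a.transfer is not None],
        n_founders=p.n_founders, n_births=n_births)
    return animals, truth


def _emit_animal_frame(p: ColonyParams, animals: list[_Animal]) -> pd.DataFrame:
    start = pd.Timestamp(p.start_year, 1, 1)
    end = start + pd.Timedelta(days=p.years_simulated * DAYS_PER_YEAR)
    by_id = {a.id: a for a in animals}
    rows = []
    for a in animals:
        concep = a.dob - pd.Timedelta(days=p.gestation_d)
        dam = by_id.get(a.dam)
        sire = None if a.sire_mult else by_id.get(a.sire)
        dod = age_death = age_living = age_verified = None
        if a.transfer is not None:
            age_verified = (a.transfer - a.dob).days / DAYS_PER_YEAR
        elif a.death is not None and a.death <= end:
            dod = a.death
            age_death = (dod - a.dob).days / DAYS_PER_YEAR
        else:
            age_living = (end - a.dob).days / DAYS_PER_YEAR
        current = "Y" if (a.transfer is None and dod is None) else "N"
        rows.append({
            "Taxon": p.taxon, "DLC_ID": a.id, "Hybrid": "N", "Sex": a.sex,
            "Name": f"{p.taxon}-{a.id}", "Current_Resident": current,
            "StudBook": None, "DOB": a.dob, "Birth_Month": a.dob.month,
            "Estimated_DOB": a.est_code, "Birth_Type": a.birth_type,
            "Birth_Institution": a.institution,
            "Litter_Size": a.litter_size,
            "Expected_Gestation_d": p.gestation_d,
            "Estimated_Concep": concep, "Concep_Month": concep.month,
            "Dam_ID": a.dam,
            "Dam_Name": f"{p.taxon}-{dam.id}" if dam else None,
            "Dam_Taxon": p.taxon if dam else None,
            "Dam_DOB": dam.dob if dam else None,
            "Dam_AgeAtConcep_y": ((concep - dam.dob).days / DAYS_PER_YEAR
                                  if dam else None),
            "Sire_ID": a.sire,
            "Sire_Name": f"{p.taxon}-{sire.id}" if sire else None,
            "Sire_Taxon": p.taxon if sire else None,
            "Sire_DOB": sire.dob if sire else None,
            "Sire_AgeAtConcep_y": ((concep - sire.dob).days / DAYS_PER_YEAR
                                   if sire else None),
            "DOD": dod, "AgeAtDeath_y": age_death,
            "AgeOfLiving_y": age_living, "AgeLastVerified_y": age_verified,
            "AgeMax_LiveOrDead_y": next(
                v for v in (age_death, age_living, age_verified)
                if v is not None),
            "N_known_offspring": 0,
        })
    df = pd.DataFrame(rows)
    for col in ["DOB", "Estimated_Concep", "Dam_DOB", "Sire_DOB", "DOD"]:
        df[col] = pd.to_datetime(df[col])
    counts = demography.count_offspring(df)
    df["N_known_offspring"] = df["DLC_ID"].map(counts).astype(int)
    return df


def _mass_series(p: ColonyParams, a: _Animal, dates: pd.DatetimeIndex,
                 pregnancies: list[tuple[pd.Timestamp, pd.Timestamp]],
                 rng: np.random.Generator) -> np.ndarray:
    age_y = np.array([(d - a.true_dob).days for d in dates]) / DAYS_PER_YEAR
    asym = p.growth_asymptote_g * (p.obesity_multiplier if a.obese else 1.0)
    m = asym - (asym - p.neonate_mass_g) * np.exp(-p.growth_rate_per_y * age_y)
    doy = dates.dayofyear.to_numpy()
    m = m * (1 + p.seasonal_mass_amplitude
             * np.cos(2 * np.pi * (doy - 15) / 365))
    for concep, birth in pregnancies:
        frac = (np.array([(d - concep).days for d in dates])
                / max((birth - concep).days, 1))
        preg = (frac >= 0) & (frac < 1)
        m[preg] *= 1 + p.pregnancy_gain_frac * frac[preg]
    if a.death is not None:
        dbd = np.array([(a.death - d).days for d in dates], dtype=float)
        term = (dbd >= 0) & (dbd < 60)
        m[term] *= 1 - p.terminal_decline_frac * (1 - dbd[term] / 60)
    m = m * (1 + rng.normal(0, p.measurement_cv, size=m.size))
    return np.round(np.maximum(m, 1.0), 1)


def _emit_weight_frame(p: ColonyParams, animals: list[_Animal],
                       rng: np.random.Generator) -> pd.DataFrame:
    start = pd.Timestamp(p.start_year, 1, 1)
    end = start + pd.Timedelta(days=p.years_simulated * DAYS_PER_YEAR)
    preg_by_dam: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for a in animals:
        if a.dam is not None and a.dam != "WILD" and not a.founder:
            preg_by_dam.setdefault(a.dam, []).append(
                (a.true_dob - pd.Timedelta(days=p.gestation_d), a.true_dob))
    frames = []
    for a in animals:
        first = a.true_dob if not a.founder else start
        last = min(x for x in (a.death, a.transfer, end) if x is not None)
        if last < first:
            continue
        offsets: list[int] = []
        if not a.founder:
            offsets.append(0)  # neonates are weighed on the day of birth
            if rng.random() < 0.7:
                offsets.append(1)
        base = (first - a.true_dob).days
        offsets.extend(range(base + p.weighing_interval_d,
                             (last - a.true_dob).days + 1,
                             p.weighing_interval_d))
        offsets = sorted(set(o for o in offsets
                             if 0 <= o <= (last - a.true_dob).days))
        if not offsets:
            continue
        dates = pd.DatetimeIndex(
            [a.true_dob + pd.Timedelta(days=o) for o in offsets])
        pregnancies = sorted(set(preg_by_dam.get(a.id, [])))
        grams = _mass_series(p, a, dates, pregnancies, rng)
        frames.append(pd.DataFrame({
            "Taxon": p.taxon, "DLC_ID": a.id,
            "Weight_g": grams, "Weight_Date": dates,
        }))
    if not frames:
        return pd.DataFrame(columns=["Taxon", "DLC_ID", "Weight_g",
                                     "Weight_Date"])
    return pd.concat(frames, ignore_index=True)


def simulate_colony(params: Sequence[ColonyParams] | ColonyParams,
                    seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one or more taxa; returns (animal list, weight file, truth).

    Output frames are fully schema-valid: derived columns are filled by the
    same pipeline functions that process real files, so every rule the
    derivation applies is exercised by the synthetic data.  Identical
    parameters and seed reproduce the output exactly.
    """
    if isinstance(params, ColonyParams):
        params = [params]
    for p in params:
        p.validate()
    if len({p.taxon for p in params}) != len(params):
        raise ValueError("duplicate taxon codes in params")
    rng = np.random.default_rng(seed)
    registry = params_registry(params)

    animal_frames, weight_frames = [], []
    truth = GroundTruth()
    id_counter = [1000]
    for p in params:
        animals, taxon_truth = _simulate_taxon(p, rng, id_counter)
        truth.taxa[p.taxon] = taxon_truth
        animal_frames.append(_emit_animal_frame(p, animals))
        weight_frames.append(_emit_weight_frame(p, animals, rng))
    animal_df = pd.concat(animal_frames, ignore_index=True)
    raw_weights = pd.concat(weight_frames, ignore_index=True)

    litters = []
    min_dam: dict[str, Optional[float]] = {}
    for p in params:
        litters.extend(demography.build_litters(animal_df, p.taxon, registry))
        min_dam[p.taxon] = demography.parental_age_extremes(
            animal_df, p.taxon)["min_dam"]
    weight_df = mass.weight_derived_columns(
        raw_weights, animal_df, litters, min_dam)
    return animal_df, weight_df, truth


def truth_report(truth: GroundTruth, table: pd.DataFrame) -> pd.DataFrame:
    """Recovery errors: ground truth vs a derived life-history table.

    *table* is the analysis-layout table (taxa as rows, indexed by taxon).
    Returns one row per taxon with absolute/relative errors for the peak
    conception month, infant mortality, median longevity and adult mean
    mass.
    """
    rows = []
    for taxon, t in truth.taxa.items():
        if taxon not in table.index:
            raise KeyError(f"taxon {taxon} missing from table")
        row = table.loc[taxon]
        peak = row["R_Peak_Breeding_Month"]
        med = row["L_Median_All_Longevity_gt30d_y"]
        inf = row["L_Pct_All_InfMort_lt30d"]
        adult = row["M_Mean_All_AdultWeight_g"]
        n_inf = row["S_N_All_DLCBorn_Infant"]
        rows.append({
            "taxon": taxon,
            "peak_month_true": t.peak_conception_month,
            "peak_month_recovered": None if peak in (None, "0") else int(peak),
            "peak_month_error": (
                None if peak in (None, "0")
                else int(peak) - t.peak_conception_month),
            "median_longevity_true_y": t.median_longevity_y,
            "median_longevity_recovered_y": med,
            "median_longevity_error_y": (
                None if med is None or not math.isfinite(t.median_longevity_y)
                else float(med) - t.median_longevity_y),
            "infant_mortality_true": t.infant_mortality,
            "infant_mortality_recovered": inf,
            "infant_mortality_error": (
                None if inf is None else float(inf) - t.infant_mortality),
            "infant_mortality_binom_se": (
                math.sqrt(t.infant_mortality * (1 - t.infant_mortality)
                          / n_inf) if n_inf else None),
            "adult_mass_true_g": t.adult_mean_mass_g,
            "adult_mass_recovered_g": adult,
            "adult_mass_rel_error": (
                None if adult is None
                else float(adult) / t.adult_mean_mass_g - 1),
        })
    return pd.DataFrame(rows).set_index("taxon")
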