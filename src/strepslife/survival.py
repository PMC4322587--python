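"""Censored survivorship, weighted median longevity, infant mortality.

Longevity in a managed colony is right-censored: living residents and
animals last verified alive elsewhere contribute exposure time but no death
event.  Survivorship is therefore estimated with the product-limit
(Kaplan-Meier) estimator over death ages, after excluding deaths before 30
days of age (early infant mortality, including stillbirths, is reported as
its own variable and would otherwise dominate the curve).

The species' median longevity is the interpolation between the death ages
bracketing 50% survivorship, each weighted by how far the curve sits from
the 0.5 midpoint at that age:

    median = ((U - U*dU) + (L + L*dL)) / 2

where U is the first death age with S(U) <= 0.5, L the last death age with
S(L) > 0.5, dU = |S(U) - 0.5| and dL = S(L) - 0.5.  When the curve never
drops to 50% (few uncensored deaths yet), the median is undefined and
reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colony_io import DAYS_PER_YEAR, is_home_born

INFANT_CUTOFF_Y = 30 / DAYS_PER_YEAR  # deaths before 30 d are "infant mortality"


@dataclass
class SurvivorshipCurve:
    """Step survivorship: S(t) after each distinct uncensored death age."""

    event_ages_y: np.ndarray      # ascending distinct death ages
    survivorship: np.ndarray      # S just after each event age
    n_at_risk: np.ndarray         # risk-set size just before each event age
    n_deaths: np.ndarray          # deaths at each event age
    censored_ages_y: np.ndarray   # all censoring ages (unordered)

    @property
    def min_survivorship(self) -> float:
        return float(self.survivorship[-1]) if len(self.survivorship) else 1.0


def product_limit(durations: Sequence[float],
                  event_observed: Sequence[bool]) -> SurvivorshipCurve:
    """Kaplan-Meier estimate from durations and death indicators.

    At tied times deaths are processed before censorings (the censored
    individual is still in the risk set for a death at the same age).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    if t.size == 0:
        raise ValueError("empty risk set")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_ages = np.unique(t[e])
    n = t.size
    surv = np.empty(event_ages.size)
    at_risk = np.empty(event_ages.size, dtype=int)
    deaths = np.empty(event_ages.size, dtype=int)
    s = 1.0
    for i, age in enumerate(event_ages):
        # deaths-before-censorings: censored exactly at `age` still at risk
        r = int(np.sum((t > age) | ((t == age))))
        d = int(np.sum((t == age) & e))
        s *= 1.0 - d / r
        surv[i], at_risk[i], deaths[i] = s, r, d
    return SurvivorshipCurve(
        event_ages_y=event_ages, survivorship=surv, n_at_risk=at_risk,
        n_deaths=deaths, censored_ages_y=np.sort(t[~e]),
    )


def survival_inputs(animals: pd.DataFrame, taxon: str,
                    sex_filter: Optional[str] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(durations, event flags) for one taxon after the 30-day exclusion.

    Dead animals contribute their age at death; living ones are censored at
    their current age; animals of unknown status at the age they were last
    verified alive.  Individuals whose record ends before 30 days of age
    (death or censoring) are excluded: they have not survived the infant
    window the curve is conditioned on.
    """
    sub = animals[animals["Taxon"] == taxon]
    if sex_filter is not None:
        sub = sub[sub["Sex"] == sex_filter]
    dead = sub["AgeAtDeath_y"].notna()
    age = sub["AgeAtDeath_y"].where(
        dead, sub["AgeOfLiving_y"].fillna(sub["AgeLastVerified_y"]))
    keep = age.notna() & (age >= INFANT_CUTOFF_Y)
    return age[keep].to_numpy(float), dead[keep].to_numpy(bool)


def fit_survivorship(animals: pd.DataFrame, taxon: str,
                     sex_filter: Optional[str] = None) -> SurvivorshipCurve:
    """Product-limit survivorship for one taxon (optionally one sex)."""
    durations, events = survival_inputs(animals, taxon, sex_filter)
    return product_limit(durations, events)


def weighted_median_longevity(curve: SurvivorshipCurve) -> Optional[float]:
    """Distance-weighted median of a survivorship curve, in years.

    Returns ``None`` when survivorship never reaches 50% (undefined).
    """
    s = curve.survivorship
    ages = curve.event_ages_y
    below = np.nonzero(s <= 0.5)[0]
    if below.size == 0:
        return None
    i_u = int(below[0])
    upper = float(ages[i_u])
    d_u = abs(float(s[i_u]) - 0.5)
    if i_u == 0:
        lower, d_l = upper, d_u  # curve starts already at/below 0.5
    else:
        lower = float(ages[i_u - 1])
        d_l = float(s[i_u - 1]) - 0.5
    return ((upper - upper * d_u) + (lower + lower * d_l)) / 2


def median_longevity(animals: pd.DataFrame, taxon: str,
                     sex_filter: Optional[str] = None) -> Optional[float]:
    """Weighted median longevity for one taxon, or ``None`` if undefined."""
    try:
        curve = fit_survivorship(animals, taxon, sex_filter)
    except ValueError:
        return None
    return weighted_median_longevity(curve)


def survival_group_size(animals: pd.DataFrame, taxon: str,
                        sex_filter: Optional[str] = None) -> int:
    """Number of individuals that survived at least 30 days."""
    durations, _ = survival_inputs(animals, taxon, sex_filter)
    return int(durations.size)


def infant_mortality(animals: pd.DataFrame, taxon: str,
                     sex_filter: Optional[str] = None
                     ) -> tuple[Optional[float], int, int]:
    """Colony-born infant mortality: (proportion, n_died, n_born).

    Proportion of colony-born individuals (stillbirths included) that died
    before 30 days of age; ``None`` when the taxon has no colony-born
    individuals in the group.
    """
    sub = animals[(animals["Taxon"] == taxon) & is_home_born(animals)]
    if sex_filter is not None:
        sub = sub[sub["Sex"] == sex_filter]
    denom = len(sub)
    if denom == 0:
        return None, 0, 0
    died = int((sub["AgeAtDeath_y"] < INFANT_CUTOFF_Y).sum())
    return died / denom, died, denom


def max_age(animals: pd.DataFrame, taxon: str,
            sex_filter: Optional[str] = None) -> Optional[float]:
    """Oldest recorded age, living or dead, estimated birth dates included."""
    sub = animals[animals["Taxon"] == taxon]
    if sex_filter is not None:
        sub = sub[sub["Sex"] == sex_filter]
    ages = sub["AgeMax_LiveOrDead_y"].dropna()
    return float(ages.max()) if len(ages) else None
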