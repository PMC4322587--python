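# Methods

This note documents the models, rules and numerical choices behind the
derivation pipeline and the synthetic-colony generator, and what the
passing tests do and do not demonstrate about real colony data.

## Record model

The pipeline consumes two flat files. The *animal list* holds one row per
individual: identity (taxon code, colony ID, sex, hybrid status), origin
(captive-born CB, wild-born WB, unknown UNK; birth institution), dates
(birth, estimated conception, death), pedigree (dam/sire IDs, their birth
dates and ages at conception) and exactly one of three terminal ages —
age at death, age if living, or age when last verified alive elsewhere —
with a maximum-age column equal to whichever is populated. The *weight
file* holds one row per weighing event with derived age, change-since-
previous, days-before-death and pregnancy columns. All ages in years use
the divisor 365 with no leap correction, matching the files' own printed
formulas; dates are ISO-8601 on disk, and the reader also accepts
M/D/YYYY and the missing-value tokens `''`, `'.'`, `'NA'`.

Derived columns are recomputed on read and compared to the stored values
(tolerance 1e-6 for floats); disagreements are reported, not overwritten,
unless recompute mode is requested. This keeps provenance visible: a
stored pregnancy flag that cannot be reproduced from the two files (for
example, one set from an observed mating that the files do not record) is
surfaced by the validation report and by the table-comparison command
rather than silently replaced.

## Species constants (registry)

Per-taxon constants that cannot be derived from the record files ship in
a registry: expected gestation length (days) and its range, breeding
pattern (seasonal/non-seasonal), activity (nocturnal/diurnal), active-
breeding flag, banked-biosample counts, and the middle month of the
breeding season in the country of origin. The default registry covers the
27 strepsirrhine taxa of the source colony. The origin mid-month is
derived as the captive peak breeding month shifted by six months, because
the captive colony sits in the opposite hemisphere from the species'
native ranges; it is only used to anchor estimated birth dates of
wild-caught seasonal breeders.

## Derivation rules

**Conception.** Estimated conception = exact birth date − expected
gestation days. Infants that did not survive at least one day are excluded
from every conception-based statistic (their gestation may have been
truncated by prematurity, which would bias the estimate early); they are
*included* in litter-size statistics and in infant mortality.

**Litters.** The unit for litter and seasonality statistics is the litter
event, keyed by (dam ID, exact birth date) among colony-born individuals;
records with no dam recorded become singleton events. A stored litter-size
field that disagrees with the member count is logged and the member count
wins. Tied modal litter sizes are all reported, comma-joined ascending,
and the reported frequency of the most common size is the per-size
frequency (on a tie, the tied sizes share that value).

**Seasonality.** Events are histogrammed by calendar month. The peak month
is the modal month; ties are broken toward the tied month whose two
circular neighbours hold the most events, then the lowest month number.
The season grows from the peak in both circular directions, admitting a
month while it holds at least one third of the peak-month count or at
least 20% of all events, and stopping at the first failure per direction
(strict contiguity). Non-seasonal taxa print "0" in all four peak fields.
Note one property that may look intuitive but is false under this rule:
adding events to an in-season month can shrink the season, because the
one-third threshold scales with the peak count.

**Parental ages.** Ages at conception are (estimated conception − parent
birth date)/365. Minima admit only parents whose own colony record shows
an exact (captive-born, non-estimated) birth date; maxima also admit
estimated birth dates, which can only understate age. Offspring with
multiple possible sires (`MULT…`) or unknown sires are excluded from sire
statistics and counted for no candidate sire in per-individual offspring
counts.

**Survivorship and median longevity.** No-covariate product-limit
estimation, with deaths before 30 days excluded entirely (strict: exactly
30 days is retained), living animals censored at their current age,
unknown-status animals censored at the age last verified, and deaths
processed before censorings at tied ages. Censored records that end before
30 days are likewise excluded, so the survival-sample counts equal
"individuals that survived at least 30 days". The median is the
distance-weighted interpolation described in the README; it is reported
missing while survivorship never reaches 50%. The interpolation agrees
with an independent Kaplan–Meier implementation to 1e-9 on the step
values, and on uncensored exponential lifetimes its mean recovered median
across 20 replicates at n = 300 sits within 0.5 y of ln 2/λ. A per-replicate
bound at that size would be a test of sampling noise rather than of the
estimator: the sampling SE of a median estimate at n = 300 and median
7–10 y is ≈ 0.4–0.8 y.

**Body mass.** The exclusion cascade drops weights within 60 days of death
(strict inequality), weights of pregnant females (pregnancy attributed
when the weighing date falls in [conception, birth) of one of the dam's
litters), and weights of wild-born or unknown-origin animals at estimated
ages below the species' minimum dam age at conception. Age classes are
infant/juvenile below the minimum dam age m, young adult in [m, 2m), adult
at ≥ 2m; each weight contributes to the class it was taken in, so one
individual can appear in both adult summaries. Within an individual,
weights are averaged per calendar year-month and the individual's value is
the unweighted mean of its monthly means. Obesity is flagged in a single
pass per taxon and age class — strictly above mean + 2 sample standard
deviations (ddof = 1) of the individual means — and flagged individuals
are removed before species means, minima and maxima are taken. The sample
(n−1) SD convention and single-pass flagging are deliberate choices the
source formulas leave open; the published obesity tallies are sensitive to
them, and the comparison command exists to surface exactly such residual
differences. Neonate mass uses weights on day 0 and/or day 1 (averaged
when both exist) for individuals surviving at least one day.

**Assembly.** The 91 variables are computed per taxon by the modules
above; counts are integers, male:female ratios print to 3 decimals,
years/proportions/grams to 2; missing prints as `.`. Historic counts are
full per-taxon row counts of the animal list. Gestation fields, the
active-breeding flag, activity and biosample counts pass through from the
registry (gestation is a species summary, not a per-file computation).
The reference layout is the exact cell-for-cell transpose of the analysis
layout after formatting, and rebuilding from the same inputs is
bit-identical.

## Synthetic colony generator

The generator exists so that every rule above can be exercised against
known truth. Per taxon it simulates:

* founders entering as adults (a configurable fraction wild-born, whose
  *emitted* birth dates go through the same estimation rule the pipeline
  applies, while true dates drive the dynamics);
* managed yearly breeding: eligible dams (alive, present, within the
  [min, max] dam-age window, not pregnant) are paired with random eligible
  sires, capped at `max_litters_per_year` (default 14) — real colonies are
  held near constant size by management, and an uncapped colony grows
  exponentially; conception months are drawn from the taxon's 12-vector
  pmf with mid-month days (3–27), so birth month = conception month +
  gestation at whole-month offsets; a small fraction of litters get
  multiple-sire attribution;
* infant mortality as a Bernoulli draw (default 0.25; the published
  per-taxon range is roughly 0.06–0.69) with deaths uniform on days 0–29,
  one fifth of them day-0 stillbirths, and half of early deaths emitted
  with undetermined sex;
* adult mortality as an exponential hazard beyond 30 days (default
  0.08/y, median ≈ 8.7 y, within the published 7–25 y span), founders
  carrying the memoryless residual beyond their entry age;
* right-censoring of two kinds: alive at the end of the simulated window,
  and transfer out with status "last verified alive". The candidate
  transfer date is drawn *independently* of the death date and takes
  effect only if the animal is alive then; drawing it bounded by death
  would be informative censoring and was measured to bias median recovery
  upward by ~0.7–1.3 y;
* mass as asymptotic growth m(t) = A − (A − m0)e^(−kt) with the default
  rate k chosen so animals reach ~90% of the plateau at the minimum
  breeding age and ~99% at twice it (the young-adult mean then sits
  visibly below the adult mean, as colony data show), multiplied by a
  sinusoidal seasonal cycle (default amplitude 5%, winter peak), a
  pregnancy ramp (default +15% at term), a terminal decline (default −20%
  over the final 60 days), an obesity multiplier on the asymptote for a
  configurable fraction of individuals, and 2% multiplicative measurement
  noise, rounded to 0.1 g.

Ground truth (pmf mode, ln 2/hazard, infant mortality rate, growth
plateau, obese and censored IDs) is emitted alongside, and
`truth_report` tabulates recovery errors against a derived table.

What the generator does *not* emulate: inter-institution transfer chains,
pedigree-driven pairing decisions and reproductive-success heterogeneity,
sex dimorphism in mass, litter-size dependence on dam age, and secular
husbandry trends. Passing recovery tests therefore demonstrate that the
derivation rules measure what they claim under the stated statistical
structure — not that real colony data satisfy that structure. One
structural feature is shared with real data and kept deliberately:
founders enter as adults and are left-truncated, which the no-entry-time
product-limit estimator ignores; with colony-born individuals dominating
(≥ 300 per taxon) the measured effect on median recovery is within the
0.5 y recovery tolerance.

## Problem sizes and determinism

Recovery tests run at a few hundred colony-born individuals per taxon
(the regime where binomial and median sampling errors are comfortably
inside the stated tolerances), with weighing thinned where mass is not
under test; full simulations of the three-taxon demonstration colony
(~1 900 animals, ~115 000 weighings) complete in seconds. All randomness
flows from a single integer seed through `numpy.random.default_rng`;
identical parameters and seed reproduce output files byte-for-byte.

## Known limitations

* The published breeding season of one taxon is non-contiguous
  ("1.3.12"), which the stated contiguous-expansion rule cannot produce;
  the rule is implemented as stated rather than special-cased.
* The obesity tally and a minority of pregnancy flags in the deposited
  files depend on conventions (SD divisor, observed matings) the file
  formulas leave open; recomputation differences are reported by
  `strepslife compare`, not absorbed.
* The weighted-median interpolation is a published convention, not a
  standard quantile estimator; it is reproduced exactly, including its
  behaviour when the curve starts at or below 0.5 (both bracket ages
  collapse to the first event age).
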