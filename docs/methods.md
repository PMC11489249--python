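# Methods

## Risk model

The assessment follows the IPCC (2014) decomposition of climate risk
into hazard, exposure and vulnerability, with vulnerability a function
of sensitivity and adaptive capacity. All quantities are dimensionless
scores on [0, 1]. The composition used throughout is

    V    = mean(S, 1 − AC)
    Risk = mean(mean(H, E), V) = mean(H, E, S, 1 − AC)

This is the **table-consistent** form: it is the unique simple
composition that reproduces the published per-community composites from
their published components (e.g. Mafia's resource vulnerability
(0.415 + (1 − 0.635))/2 = 0.390 and ecological risk
mean(mean(0.450, 0.713), 0.390) = 0.486, and likewise the published
final index for Mafia, 0.520). The additive form
`mean(H, E) + (S − AC)` that the framework is sometimes written as does
not stay in [0, 1] and does not reproduce those composites; it remains
available as `equation_mode="literal"` for comparison, documented as
such, and the run manifest records which mode produced an output.

Three of the four published final indices (Pemba 0.574, Tanga 0.484,
Unguja 0.602) are not recoverable from the published *dimension* indices
under any simple composition — they were evidently computed from
unrounded intermediates — so only Mafia's final index and the
ecological-risk values are used as exact regression targets; the test
suite asserts exactly those.

## Ecological risk to resource

Five functional seafood groups are scored from the life-history traits
of their main constituent families. Each trait is banded low / moderate /
high and the bands map to {0, 0.5, 1}; a group's indicator score is the
unweighted mean over its families, and each component (exposure RE,
sensitivity RS, adaptive capacity RAC) is the mean of its two indicator
scores. Banding criteria, with **boundary values falling in the moderate
band** (the published criteria write moderate as a closed interval, which
overlaps the adjacent bands at the boundary; the closed-interval reading
is adopted consistently):

| code | trait | low | moderate | high |
|------|-------|-----|----------|------|
| EE1 | depth/habitat | below 50 m | above 50 m | reef-associated or fully pelagic |
| EE2 | feeding mode | higher predator | macro-invertebrate feeder | filter feeder |
| ES1 | age at first maturity | < 2 y | 2–10 y | > 10 y |
| ES2 | trophic level | < 2 | 2–4 | > 4 |
| EA1 | latitudinal range | < 45° | 45–90° | > 90° |
| EA2 | resilience to fisheries | vulnerability > 66 | 33–66 | < 33 |

EA2 bands the raw 0–100 vulnerability-to-fisheries score with inverted
polarity (high vulnerability ⇒ low resilience); no numeric 100 − x
transform is applied first. Note the published group-score table prints
the EA1/EA2 row titles swapped relative to the criteria table; this
package follows the criteria table's code assignment (EA1 = range,
EA2 = resilience) and maps published rows by title.

Community-level RE/RS/RAC are consumption-weighted means over groups
(proportions must sum to 1 within 1e-6). Resource hazard RH is shared by
all groups and communities: one index of variability per climate
variable,

    IV = (μ_FUT − μ_REF) / σ_REF,

with σ_REF the **sample (n − 1)** standard deviation of the monthly
reference-window values (the reference window is a sample of climate
variability), windows inclusive of both end years and allowed to share
the boundary year (2001–2011 vs 2011–2021). IV is location/scale
equivariant and undefined for a constant reference window (an error, not
a silent zero). |IV| maps to a hazard score through a configurable
piecewise-linear curve with default knots (0, 0) → (1, 0.5) → (2, 1),
saturating at 1: no shift scores 0, a one-sigma shift scores 0.5. The
published hazard scores (SST 0.350, productivity 0.550) cannot be
back-solved to a mapping, so a fixture mode passes externally assessed
scores through unchanged; the shipped default uses the fixture so the
published-table reproduction does not depend on raw climate data.

## Social indicators

Survey answers encode onto [0, 1]: yes/no → 1/0, Likert 1–4 →
(x − 1)/3, proportions unchanged, counts saturated at a per-question cap
(default 10), categories through a registry-supplied ordinal map
(education: none 0, primary 1/3, secondary 2/3, university 1). Community
question scores are means over non-missing answers — for yes/no
questions exactly the proportion answering "yes". Missing or
out-of-range answers are excluded **per question** (complete-case per
question), since respondents skip different questions and all community
indicators are per-question summaries. Indicators average their
sub-questions with equal weights; two composites are computed per
respondent first to preserve within-respondent coupling:

* **Direct dependence (SS3)**: DWF / TDWP, the fraction of
  animal-protein days supplied by fish; respondents with TDWP = 0 or
  DWF > TDWP are excluded and flagged.
* **Asset wealth index (SA4)**: mean of a respondent's encoded asset
  answers, then the community mean.

The nutrition indicator SS4 (consumption-weighted mean protein content,
g/100 g, from ≥ 5 species per group) and the optional SA1
life-expectancy constant are the only indicators with physical units;
they are min–max normalized across communities
((x − min)/(max − min); a degenerate range maps everything to 0.5 with a
warning). All other indicators are natively unit-scaled, matching the
published community tables, which print raw proportions.

Adaptive-capacity questions are capacity-increasing ("protective") and
are *not* flipped at encoding; the inversion happens once, in
`1 − AC` inside the vulnerability composition. Reversed questionnaire
items are re-oriented at registry level, where per-item polarity is
configuration (the original instrument's polarity is not published for
every item).

Dimension indices average indicator *groups* (e.g. social sensitivity =
mean of the sea-level-rise, storm, direct-dependence and
indirect-dependence groups; social adaptive capacity = mean of seven
groups: flexibility, assets, social organization, learning, equity,
social cognition, agency), and each group averages its member
indicators — equal weights at every level.

## Confidence

Each indicator carries a 0–3 data-quality grade: empirical/modelled 3,
limited estimate 2, survey/expert 1, not assessed 0. Propagation is a
plain unweighted mean at every level. Resource-side defaults follow the
published leaf grades (hazard 3.0, exposure 1.0, sensitivity 2.8 —
fractional because family data mixed empirical and expert sources —
adaptive capacity 3.0), which propagate to the published
resource-vulnerability grade mean(2.8, 3.0) = 2.9. Several published
*aggregate* grades (1.950, 1.500, 1.250, 1.154, 1.293) follow no single
propagation rule from their printed children and are not asserted.

## Risk profiles

Communities classify into quadrants on (exposure-hazard, vulnerability),
where exposure-hazard = mean(H, E), consistent with the risk
composition. Thresholds default to the scale midpoint 0.5/0.5 — the
framework states no numeric cut-offs — are configurable, and are always
reported with the labels; values exactly at a threshold classify as
high. Under the defaults the published scores place the three island
communities in "greatest concern" and Tanga, with the smallest
max-coordinate, on the boundary of the low-risk corner.

## Synthetic data

The generator emulates the study design: four communities with 90, 49,
52 and 102 respondents (293 total), per-question answer distributions
(Bernoulli, categorical Likert, Beta proportions, Poisson counts; the
protein-days pair drawn jointly as TDWP ~ U{4..7}, DWF | TDWP ~
Binomial(TDWP, p_fish)), monthly climate series N(μ, σ) with a
configured standardized shift added from the future window on, and a
deterministic family trait table whose banded group means reproduce
every published group-score cell exactly (family names are real WIO
families; the trait values are synthetic back-constructions, as the
family-level source data are not public). One integer seed drives
everything through `numpy` `SeedSequence.spawn` (child 0 survey,
child 1 climate). Default scenario parameters are tuned so demo
community scores land near the published values; this is illustrative
calibration, not a reproduction.

What the generator does **not** emulate: correlation between a
respondent's answers across questions (beyond the protein-days pair),
non-response patterns, within-community village structure, seasonality
or autocorrelation in the climate series. Passing recovery tests
therefore shows correct estimation under independent sampling, not
robustness to real survey or climate dependence structure.

## Numerical choices

* Published tables round half-up to 3 decimals; the package reproduces
  table cells with decimal half-up rounding (not banker's), and the
  published component "average" rows are means of the *already rounded*
  indicator rows (e.g. mean(0.167, 1.000) = 0.5835 → 0.584). Internal
  pipeline computation is full precision; `--precision full` disables
  output rounding.
* Monthly aggregation takes the arithmetic mean of a month's
  observations; months with no data are absent, never zero-filled.
* Degenerate inputs fail loudly: empty communities, all-missing
  questions, constant reference windows, proportions not summing to 1.
* Problem sizes in the shipped tests and analyses — 293-respondent
  surveys, 240–252-month series, 100-replicate Monte-Carlo recovery
  runs, ~10⁴-point composition grids — were chosen to give stable
  third-decimal estimates while keeping any single check under a few
  seconds.

## Limitations

Equal weighting everywhere is an assumption of the framework, not a
finding; expert-elicited or PCA weights are deliberately out of scope.
A single area-wide hazard ignores within-region climate gradients. The
IV → hazard-score map is a package default, not a published calibration.
Survey-derived hazard perception (SH2/SH3) is an imperfect proxy for
physical hazard trends, a caveat the framework itself acknowledges.
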