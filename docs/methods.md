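# Methods

`rhizophb` implements a pipeline for studying polyhydroxybutyrate (PHB)
storage as a life-history trait of nodule-forming rhizobia: how much PHB
cells acquire during symbiosis (measured by calibrated flow cytometry), how
heritable that acquisition is across isolates, and what the stored polymer
is worth to a cell once it leaves the host — either as fuel for short-term
reproduction in starvation culture or as a maintenance budget for months to
centuries of dormancy in soil. No raw data for this system are publicly
deposited, so a first-class synthetic-data module generates inputs with the
statistical structure each analysis assumes, and every estimator is tested
against its matched generator.

## Flow-cytometry calibration

Per-cell measurements are (fluorescence, forward scatter, side scatter)
triples in arbitrary instrument units. Debris is removed by a deterministic
gate — a rectangular box on the two scatter channels plus a fluorescence
floor — chosen over interactive cloud-selection so gating is reproducible
and testable. Gated fluorescence is summarised by the geometric mean, which
is robust to the heavy right tail of stain intensities, and converted to pg
PHB per cell through a least-squares standard curve fitted to six reference
standards whose PHB content was established independently (gas
chromatography). The curve is fitted in the log-log domain by default:
staining noise is multiplicative, and a power-law response preserves
positivity; a linear-domain option exists, where negative predictions are
clamped to zero and flagged. Standards are rerun with every instrument
batch, so curves are fitted per batch and never pooled. Conversions outside
the fluorescence range spanned by the standards are flagged as
extrapolated. Samples whose true signal sits near the gate floor lose a
biased (low) tail to the gate and are recovered with upward bias — the
calibration demo (analysis/01) shows this at the lowest panel level;
precision is genuinely worse at the extremes of the working range.

## Survival model

A non-growing cell respires carbon at a temperature- and state-dependent
rate, log10(m) = alpha*T + beta, with m in g C respired per g structural
biomass C per day. Five states are modelled:

| state | alpha (/degC) | beta |
| --- | --- | --- |
| full somatic maintenance (FSM) | 0.099 | -5.14 |
| 10% of FSM | 0.099 | -6.14 |
| 1% of FSM | 0.099 | -7.14 |
| 0.1% of FSM | 0.099 | -8.14 |
| deep dormancy | 0.084 | -8.17 |

The FSM and dormancy lines come from a published compilation of prokaryote
metabolic rates; the intermediates are exact decade offsets of FSM (shared
slope, beta - 1, -2, -3), an invariant the tests check at machine precision.
The source table typesets the slopes as "9.9 x 10^2" and "8.4 x 10^2",
which would give rates of 10^2475 at 25 degC; they are used here as
9.9e-2 and 8.4e-2 per degC, the magnitude that reproduces the documented
thousand-fold FSM/dormancy span at 0 degC (10^3.03) and year-to-century
survival horizons. Because dormancy has a shallower slope, its line crosses
the 0.1%-FSM line just below -2 degC; integrated annual budgets still order
strictly (dormancy cheapest), which is the form in which the ordering is
asserted. A per-state intercept offset (default 0) is provided as a
calibration hook, since the published coefficients were digitised from a
figure and the original values are not recoverable; with the coefficients
as read, one pg of PHB funds FSM for about ten years rather than the
roughly ten months the source narrative suggests, and this discrepancy is
deliberately left visible rather than absorbed.

The daily PHB cost converts respiration to polymer mass:
phb/day = m * b * C_b / C_phb, with structural biomass b = 0.5 pg
(bacteroid-scale), C_b = 96/150 from the biomass formula C8H8O2N1 and
C_phb = 48/86 from C4H6O2 (integer atomic masses). Soil temperature follows
an annual sinusoid T(d) = (Tmax+Tmin)/2 + (Tmax-Tmin)/2 sin(2pi(d-delta)/365)
fitted to monthly means (Tmax 25 degC, Tmin -3 degC, delta = day 121 for
southern-Minnesota soil at 20 cm); temperature is evaluated once per integer
calendar day on a 365-day year, leap days ignored, and "20 months" is
round(20 x 365/12) = 608 days from 15 September (day 258). The fit grid-searches
delta over integer days with closed-form midpoint/amplitude given delta; a
constant series is flagged degenerate. Because the temperature cycle is
periodic, the cumulative budget over whole years is start-day independent,
and `phb_required`/`days_supported` evaluate arbitrarily long horizons in
O(365) while agreeing with a naive per-day accumulation to <= 1e-12 relative
error. `days_supported` is the exact integer generalized inverse of
`phb_required` (a relative tolerance of 1e-9 absorbs float round-off in the
budget comparison; a day's cost is many orders of magnitude larger), and
horizons beyond `max_days` are censored, not extrapolated.

## Heritability

The phenotype is a nodule's mean PHB per cell; nodules are nested in plants
and plants in isolates. Broad-sense heritability is
H2 = V_isolate / (V_isolate + V_plant + V_residual) from the two-level
nested random-effects model. For balanced designs the variance components
are exact constrained REML: the likelihood factors over the three ANOVA
strata, the unconstrained maximisers are the observed mean squares, and
ordering violations are resolved by pooling adjacent strata weighted by
degrees of freedom (pool-adjacent-violators); at interior solutions this
coincides with the expected-mean-squares estimator, which the tests use as
an independent oracle. Unbalanced designs go through statsmodels MixedLM
(REML). Negative raw component estimates are reported as zero with a
truncation flag.

Uncertainty is resampling-based, mirroring how such data are analysed:

- **Bootstrap** (default 10,000 replicates): plants are resampled with
  replacement within isolate, each carrying all its nodules, keeping the
  isolate panel and the estimand fixed. A plant drawn more than once
  re-enters the fit under its original identity — its nodules appear with
  multiplicity — rather than as a fictitious new plant. This choice matters:
  treating duplicates as distinct plants deflates the within-isolate plant
  variance and inflates the bootstrap-mean H2 by roughly +0.09 at a true
  fraction of 0.63 in this design, whereas identity-preserving resampling
  leaves the bootstrap mean centred (bias about -0.02, the ratio-estimator
  bias). The fast path evaluates each weighted replicate with closed-form
  Henderson method-III components computed from per-plant sufficient
  statistics (validated against MixedLM REML refits of the duplicated data);
  replicates with no identifiable or all-zero variance are counted as
  degenerate and dropped from summaries. The confidence interval is the
  2.5-97.5 percentile band.
- **Permutation null** (default 10,000): plant-to-isolate assignments are
  shuffled (plants keep their nodules); p = (1 + #{H2_null >= H2_obs}) /
  (n_perm + 1), and "significant" follows the 95th-percentile rejection
  rule.
- **Two-group contrast**: group means of plant-averaged values (averaging
  within plant first avoids pseudoreplication), tested by a two-sided
  permutation test that enumerates all label assignments exactly when there
  are at most 1e5 of them, Monte-Carlo with the add-one correction
  otherwise.

Because the bootstrap conditions on the isolate panel, its CI quantifies
uncertainty about the heritability *realized by that panel*, not about a
fresh draw of isolate effects; simulation confirms ~91-92% coverage of the
realized isolate-variance fraction at nominal 95% (and much lower coverage
of the superpopulation fraction, whose isolate-draw variability no
plant-level resampling can see). The generator therefore exposes the
realized variance decomposition of each simulated dataset, and coverage is
tested against it.

## Starvation analytics

Rhizobia divide asymmetrically under starvation, retaining PHB in the
old-pole (parental) cell, so growing cultures develop bimodal per-cell PHB
distributions. `split_phb_subgroups` locates the minimum-density valley
between the two most prominent modes of a smoothed histogram of log10(pg)
(Gaussian smoothing, peak detection on a log-compressed, zero-padded
density so minority and boundary modes are resolved). A split is accepted
only if the valley drops below half the smaller mode and both subgroups
hold at least 2% of events; otherwise the distribution is declared
unimodal with frac_high = 1 by convention. A fixed-threshold mode
reproduces any chosen cut exactly; the analysis driver locates the valley
once per culture and applies it as a fixed cut across sampling days, the
way a single dotted line separates subgroups on a density plot. Subgroup
means are geometric by default (arithmetic available), with values below a
1e-3 pg detection floor clipped before log-transforming.

PHB-use rates are (mean_start - mean_end)/days within the high subgroup,
assuming that subgroup does not grow (daughters are ignored); net
accumulation returns a flagged negative rate rather than an error, and
adjacent-interval rates combine to the whole-interval rate as a
days-weighted average. Rates are expressed relative to theoretical state
requirements at a reference temperature (26 degC, the growth-chamber
setting, held constant rather than seasonal). Note a resolution limit: a
dormancy-scale trickle (~1e-6 pg/day) is smaller than the
subgroup-composition noise of geometric means at a few thousand cells, so
final-phase rates at these problem sizes bound, rather than measure, the
residual use. Relative population size is cfu(day)/cfu(0) per replicate
combined by geometric mean (ratios; invariant to dilution factors), and the
growth-versus-use relation across isolates is ordinary least squares with
an F-test of the slope (df 1, n-2), optionally excluding isolates with net
negative growth (fold < 1) as is done when a shrinking population makes
"growth funded by PHB" meaningless.

## Synthetic data

All generators are deterministic functions of their seed.

- **Instrument model**: fluorescence = 200 x pg (a unit-slope log-log
  curve); measurement noise is multiplicative lognormal with unit median,
  so geometric-mean summaries are unbiased on the log scale. Standards span
  0.05-2.5 pg (six levels; a literal zero standard has no log-log
  representation). Debris events sit below the scatter gate with near-zero
  fluorescence — the minimal structure the gate can act on — and make up an
  exact fraction of events.
- **Nodule studies**: balanced isolate x plant x nodule designs with
  variance fractions that sum to one. Default fractions put 0.63 on the
  isolate level (the split-root point estimate used as generator truth)
  with the remainder split evenly. Lognormal mode (default) adds effects on
  the natural-log scale, reproducing the right-skewed nodule distributions
  seen in field samples; normal mode adds effects on the pg scale, making
  the fractions raw-scale estimands — recovery benchmarks use normal mode
  with grand mean 1.0 pg and total SD 0.3 pg so values stay positive.
- **Starvation cultures**: an individual-based model. Each cell's PHB
  declines on a biphasic schedule (default 0.024 pg/day for the first
  month — about 70% of a 1 pg endowment — then 6e-6 pg/day, roughly ten
  times the dormancy requirement at 26 degC). Cells divide with probability
  0.25/day (giving roughly ten-fold first-month growth at low density)
  while carrying capacity (default 1e6 CFU/ml) allows and either an
  external supplement budget (default 4-fold growth without PHB, emulating
  residual resources that washing cannot remove) or the cell's own PHB
  (0.02 pg per division) pays for it. The parent keeps
  (1 - daughter_phb_fraction) of its PHB, default 1.0 of it (fully
  asymmetric old-pole retention), so daughters appear at the background
  staining floor (0.06 pg equivalents, just above the debris gate) and
  bimodality emerges only when the population grows. No synthesis occurs:
  total PHB mass is non-increasing by construction, which is asserted as an
  invariant.

What the generators deliberately do not emulate: mixed-strain nodules,
contaminant taxa in starvation tubes, instrument drift within a batch,
spectral effects, diurnal or interannual temperature variability, and any
PHB contribution to reproduction inside the survival model (the model is a
pure maintenance budget). Passing tests therefore demonstrate estimator
correctness under the stated statistical structure, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Recovery benchmarks use 100 replicate datasets with 1,000 bootstrap
resamples each (the full 10,000 is used in the analysis drivers); type-I
error and CI coverage use 200 datasets with 300 permutations / 400
resamples. These sizes give Monte-Carlo standard errors comfortably inside
the tolerances they are tested against. Histogram splitting defaults to 64
bins with sigma = 2 bins of smoothing. Quantiles are linear-interpolation
percentiles throughout. Ties in the permutation tests are compared with a
small relative tolerance so float round-off cannot flip the add-one count.
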