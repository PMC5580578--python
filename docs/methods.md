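# Methods

`hf183` implements a regional monitoring analysis for the HF183
human-associated *Bacteroides* fecal marker measured by qPCR in triplicate
reactions, from raw plate tables to ranked site priorities. This note
records the models, the defaults, and the design decisions that were
genuinely open.

## Master calibration

Each lab's standard points (Cq against log10 copies/reaction, pooled over
all of that lab's plates) are fit by ordinary least squares, the master-curve
approach: one regression per lab rather than per plate, which stabilizes the
slope and makes between-lab differences explicit. Outliers are removed by
the externally studentized residual rule (|t| > 3). The removal is
iterative — the single worst point is dropped and the model refit until no
point exceeds the threshold — because one-at-a-time removal avoids the
masking that a single-pass rule suffers when two gross errors inflate the
residual variance together. A single-pass mode is retained behind the
`iterative=False` flag for sensitivity analysis. Removal stops if fewer
than four points would remain, since an externally studentized residual
needs at least n = p + 2 observations for a two-parameter line.

Amplification efficiency is `E = 10^(-1/slope) - 1` (E = 1 is perfect
doubling; typical assays run 0.9-1.0).

Detection limits follow the plate design, a 6-point 10-fold dilution series
whose lowest level is 1 copy/reaction:

- **LOD** = 1 copy/reaction, expressed per lab as the *mean observed Cq* of
  the amplified 1-copy standards. The observed mean is used rather than the
  fitted prediction at log10 = 0 because the low end of a standard curve
  often bends away from the global line, and the limit should describe what
  a 1-copy reaction actually looks like.
- **LLOQ** = 10 copies/reaction, expressed as the mean 10-copy Cq plus two
  sample standard deviations, so a Cq must clear the noise band of the
  lowest fully-amplifying level before it counts as quantifiable.

Every fitted curve must satisfy `lloq_cq < lod_cq` (more template amplifies
earlier); violation raises immediately.

## Censored quantification

A replicate with quantification cycle Cq converts to copies/reaction by
inverting the lab's curve, `10^((Cq - intercept)/slope)`, and to copies per
100 mL of source water by

    conc = copies x (elution volume / template volume) x (100 / volume filtered).

The default volumes give a composite factor of 78.9 at 100 mL filtered, so
1 and 10 copies/reaction correspond to 79 and 789 copies/100 mL. Only the
composite matters to every downstream number; the constituent defaults
(157.8 µL elution, 2 µL template) are one representative factorization and
both are exposed in `VolumeConfig` for assays run with other chemistry.

Censor classes, by estimated copies/reaction: **ND** (no amplification),
**DBLOD** (< 1), **DNQ** (1-10), **QUANT** (>= 10). Interval boundaries are
closed on the more-quantifiable side: exactly 1 copy is DNQ and exactly 10
copies is QUANT. The sample-mean positivity rule (below) treats a geometric
mean *numerically equal* to the LOD as not exceeding it, with a 1e-9
relative tolerance absorbing round-trip float error.

Censored replicates are never zeroed. Under the default **POISSON** scheme
the sample's per-reaction template mean λ is estimated and substituted:

- If any replicate sits at >= 1 copy (DNQ or QUANT), λ is the geometric
  mean of those replicates' copy numbers — the direct measurements are the
  best available information about the sample.
- Otherwise λ comes from the amplification pattern alone. The probability
  a replicate amplifies under Poisson subsampling is `1 - e^(-λ)`, giving
  the classic most-probable-number likelihood `(1-e^(-λ))^k (e^(-λ))^(n-k)`
  for k amplified of n replicates. The MLE is `-ln(1 - k/n)`, but it is 0
  at k = 0 and infinite at k = n, so for substitution we use the posterior
  mean under a uniform prior on [0, 10] copies/reaction (10 = LLOQ: a
  sample with no quantifiable replicate is by construction below the
  quantifiable range). The posterior mean is computed by adaptive
  quadrature to better than 1e-6 relative accuracy and cached per pattern.
- **ND** replicates receive λ (the unconditional Poisson mean); **DBLOD**
  replicates receive `λ / (1 - e^(-λ))`, the mean copy number conditional
  on at least one copy being present — a DBLOD reaction is known to have
  received template, so its substitute always exceeds the ND substitute
  and is always >= 1.

The conventional **HALF_LOD** scheme (ND ← LOD/2, DBLOD ← LOD) is retained
as a sensitivity alternative.

The model assumes a reaction amplifies whenever at least one template copy
is present; extraction loss and PCR inhibition, which lower the real-world
detection probability, are monitored by QC (sketa22) but not modeled in
the estimator.

## Site metrics

Seven positivity definitions: AMPk (at least k of 3 replicates amplified,
k = 1..3), DETk (at least k replicates at or above the LOD), and
MEANGT_LOD (sample geometric mean with ND ← LOD/2, DBLOD ← LOD exceeds
the LOD). The primary metric is AMP1 — any amplification counts — the most
health-protective choice. MEANGT_LOD compares in copies/100 mL; under a
fixed conversion factor this is equivalent to comparing in copies/reaction.

The site average concentration is the geometric mean over all replicate
concentrations pooled across the site's samples (arithmetic mean at log10
scale, back-transformed), after substitution. The sample-level mean in
MEANGT_LOD is likewise geometric, matching the log-scale averaging used
everywhere else.

Enterococcus metrics: percent of samples above the single sample maximum
(SSM, 104 per 100 mL), percent above 100x the SSM, and the geometric mean.
CFU and MPN values are pooled without conversion. Samples without an
Enterococcus value leave only the Enterococcus denominators; zero counts
are floored at 1 per 100 mL before the geometric mean.

## Ranking and concordance

Rank 1 is the most contaminated site. Sorting is descending by the chosen
metric with a deterministic tie policy: the complementary secondary metric
(concentration when ranking by frequency, and vice versa), then site id.
Concordance between rankings is Spearman's rho — ranks are its native
scale — plus per-site rank shifts (rank_b − rank_a, summing to zero), the
count of shifted sites, and the site with the largest absolute shift.
Dry-wet comparisons re-rank within the shared site subset; sites sampled
in only one stratum are excluded.

## Weather stratification and QC

A wet event requires >= 0.10 inches of rain accumulated since rain onset,
after at least three consecutive observed dry days; samples within 72 h of
the qualifying accumulation are wet-weather samples. Choices the trigger
rule leaves open, fixed here as conventions:

- A "dry day" is a daily total below 0.01 in. (trace rain does not break a
  dry spell at most gauges' reporting resolution).
- Accumulation runs over consecutive wet days; a dry day before the
  threshold is reached abandons the accumulation.
- History before the series start is unknown, so the first three days of a
  record can never qualify an event.
- DRY additionally requires a 72-h buffer after the event window (storm
  tails should not contaminate dry-weather summaries) and a date inside
  the recreational season (1 April - 31 October). WET is accepted
  year-round; everything else is EXCLUDED.

Event windows for one gauge can never overlap: the next onset needs three
dry days, which is already the window length.

QC: negative-control cleanliness is pooled over no-template and negative
extraction controls (percent of control reactions with no amplification,
each amplified control listed). Inhibition is flagged when a sample's
sketa22 sample-processing-control Cq is delayed more than 3.0 cycles
relative to the reference (configurable; the threshold is a convention —
the assay literature uses 1-3 cycle criteria), or absent. Site-stratum
cells with ten or fewer samples are excluded from ranking.

## Synthetic campaigns

The generator exists so every stage is testable end-to-end without any
external data. Per sample: contamination is Bernoulli (site- and
stratum-specific prevalence); given contamination the concentration is
lognormal (site log10 mean and SD; wet weather multiplies concentration by
`wet_multiplier`); expected copies/reaction is concentration divided by
the conversion factor; each of three replicates draws copies ~ Poisson;
a replicate with >= 1 copy amplifies at Cq = intercept + slope·log10(copies)
+ N(0, σ) under its plate lab's true curve (σ = 0.3 cycles by default).
Standards amplify deterministically with the same Cq noise. Negative
controls are clean unless a contamination rate is configured. Enterococcus
is lognormal with a latent Gaussian coupling ρ to the HF183 concentration
draw (ρ = 0 makes the indicators independent); 5% of samples lack a value.
Samples are packed 22 to a plate in chronological order with labs assigned
round-robin.

The default scenario (`default_study_like_scenario`) is 22 sites x 50
samples per stratum x 8 labs: two zero-prevalence sites, fifteen sites with
dry prevalence 0.15-0.38, five at 0.5-1.0 with one at 1.0; concentration
scale 10^(2.3 + 1.8·prevalence) copies/100 mL with SD 0.6 log10, so
persistent sources also run hotter (the coupling that makes frequency- and
concentration-based rankings agree); lab efficiencies evenly spaced in
[0.91, 0.975]. Wet prevalence is generally higher than dry except at three
designated sites. Rain is a single daily gauge with 18 isolated winter
storms eight days apart; wet samples sit at +6/+30/+54 h after storm
onset, dry samples weekly inside the season. The scenario's seed (2017) is
part of its definition; `simulate_campaign` is byte-deterministic given a
config.

What the generator does *not* emulate: spatial gauge-to-site variation
(one shared gauge), inhibition and extraction loss, control contamination
(default rate 0), marker decay and transport, sample-volume clogging
(all samples filter 100 mL), and summer storms. Passing tests therefore
demonstrate the correctness and internal consistency of the estimators
and the pipeline under the stated model — not robustness of the assay to
field conditions the model omits.

## Numerical choices and problem sizes

- OLS via statsmodels; externally studentized residuals from its influence
  diagnostics.
- Posterior means by `scipy.integrate.quad`, relative tolerance 1e-10,
  checked in tests against Simpson's rule on 200,001 nodes.
- MPN MLE checked against grid search at step 1e-4 for all patterns n <= 5.
- The DBLOD conditional-mean substitute is checked against 1e5 conditioned
  Monte-Carlo draws within three standard errors.
- Calibration recovery uses 200 simulated plates at Cq noise SD 0.2;
  ranking recovery uses 20 sites x 50 samples; the weather classifier is
  compared with a brute-force day-by-day oracle on 1000 random series.
  These sizes give stable statistics while keeping the full suite around
  half a minute.

## Known limitations

- The Poisson substitution is this package's concrete instantiation of
  MPN-style censored substitution; other reasonable choices (e.g., a
  different prior upper bound) shift all-ND site geomeans by a bounded,
  scheme-documented amount. The HALF_LOD alternative quantifies that
  sensitivity.
- LOD/LLOQ are fixed at the 1- and 10-copy plate levels; assays whose
  curves span different ranges need a different plate description.
- Sample-to-gauge matching is an input column, not a spatial computation.
- Only the HF183 channel of the duplex assay is modeled; the internal
  BacR287 structure and inhibition-corrected quantification are out of
  scope.
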