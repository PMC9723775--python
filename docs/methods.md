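# Methods

This note documents the models behind `isoprime`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Microcosm kinetics and the flux simulator

Each vial holds `soil_mass` (default 10 g) dry soil in a
`vial_volume` = 120 mL serum vial (headspace = vial volume minus soil
volume at bulk density 1 g mL⁻¹, i.e. 110 mL). The headspace is sampled
and flushed with CO₂-scrubbed air on a fixed schedule (default every 24 h
for 7 days), so each reading reflects only the CO₂ emitted in the
preceding interval and cumulative emission is a plain running sum.

Degrader biomass follows logistic growth with specific rate
`mu_degrader` (default 0.22 h⁻¹, the pure-culture growth rate of the
dominant *p*HB degrader on the substrate) from an inoculum of 10⁻³ of
carrying capacity. Substrate is consumed at
`vmax_consumption · B(t)/K` (default 0.65 µmol C g⁻¹ h⁻¹ at full
biomass), which exhausts the standard 0.5 mg C g⁻¹ dose
(41.63 µmol C g⁻¹) around day 4 — peak respiration on days 1–4 and
near-complete mineralization by day 7, matching the observed course. A
fraction `respired_fraction` of consumed C is emitted as CO₂ at the
substrate atom fraction (defaults 0.96 for *p*HB and 0.665 for glucose,
the midpoints of the 93–100 % and 62–71 % recovery ranges); the rest is
routed to biomass, so the closed-form truth satisfies carbon conservation
(respired + residual substrate + biomass C = dose) to machine precision.
Both the logistic integral and cumulative consumption have closed forms
(checked against numerical quadrature in the tests), which is what makes
exact-recovery tests possible.

SOC respires at `soc_baseline_rate` (default 21.3 µmol C g⁻¹ day⁻¹) at
natural-abundance ¹³C, modulated by the priming term
`(1 + pc · a(t))` where `a(t)` is substrate consumption rate relative to
its plateau maximum. The default rate makes a 7-day water-control total of
≈ 149 µmol C g⁻¹, so an injected +13 µmol C g⁻¹ of priming equals 8.7 %
extra SOC mineralization — consistent with the magnitudes the experiment
is designed around. `priming_coefficient_for_target` inverts the closed
form so scenarios can inject an exact cumulative primed C; the default
scenario injects +13 (pHB, the strongest plantation) and −5.5 (glucose,
midpoint of the −3 to −8 range).

Measurement noise is multiplicative lognormal on each ppm channel
independently (default CV 0.05), keeping readings strictly positive with a
simple CV parameterization. The two m/z channels are treated as
independent measurements; a shared injection-volume error component is not
modeled.

## GC/MS quantification

Calibration is an OLS line of detector response on ppm (standards
1000–40 000 ppm; queries outside the standard range are flagged
extrapolated, negative back-calculated ppm are clipped to zero with a
flag). Mixing ratios convert to moles by the ideal gas law at
298.15 K / 101.325 kPa (both config-exposed, since chamber conditions at
sampling are rarely recorded). m/z 45 is treated as pure ¹³C¹⁶O₂; the
¹²C¹⁷O¹⁶O isobar (~0.08 % of CO₂) is ignored, which biases the
natural-abundance baseline by well under the noise level and cancels in
control subtraction.

## Partitioning and priming estimation

The two-pool mixing line is unidentifiable when the substrate atom
fraction does not exceed the baseline; that case raises. Noise can push
the measured atom fraction outside the mixing line, so the mixing fraction
is clamped to [0, 1] with a flag rather than discarded — this keeps
conservation while preserving diagnostics. The partition defines the
carbon accounting, so `total_c` is stored as `c_sub + c_soc` (within one
ulp of the measured total), making the conservation identity exact by
construction.

The natural-abundance baseline is the mean CO₂ atom fraction of unlabeled
controls, stratified per ecoplot by default (pooling is available); with
no usable controls it falls back to 0.0111 with a warning, but measured
controls are always preferred. Per-timepoint significance of SOC
respiration against water controls uses a Welch two-sample test (the
simplest test robust to unequal variances in n = 4 designs). Negative
primed values are reported as negative priming, not truncated. Treatment
comparisons are one-way ANOVA with Tukey HSD pairwise p-values from the
studentized-range distribution (Tukey–Kramer form for unbalanced designs)
and a compact letter display built from maximal cliques of the
not-significantly-different graph.

The integration horizon is whatever sampling times the data carry; the
default scenario stops at day 7, where the cumulative priming figures are
defined.

## Gradient simulator and the SIP caller

Unlabeled DNA bands at ρ = 1.660 + 0.098 · GC (g mL⁻¹); full ¹³C labeling
adds `delta_rho_max` = 0.036 g mL⁻¹, scaled by a taxon's atom excess.
Community GC is drawn from N(0.60, 0.05) clipped to [0.45, 0.72]; labeled
taxa (default 12 of 300) draw GC from N(0.615, 0.015), the
Burkholderiaceae range typical of the degraders this design targets, and
their abundance is multiplied by a bloom factor (default 5) because
degraders grow on the amendment in both the ¹³C and ¹²C dosings. Atom
excess is uniform on [0.5, 1]. Each taxon's DNA spreads across the twenty
collected fractions (1.77 → 1.70 g mL⁻¹) as a Gaussian in density with
`density_sigma` = 0.006 g mL⁻¹, a typical band width for sheared genomic
DNA in CsCl. Libraries are built for the pools F1-2, F3…F8, F9-10, F11-12
(pooled libraries carry the mean density of their members) and counts are
multinomial at `library_depth` = 10⁴, so library sums equal the depth
exactly.

The caller normalizes counts (counts-per-thousand by default;
median-of-ratios size factors — the estimator DESeq2 uses — as an
alternative, with the log2 + pseudocount variant available as the
variance-stabilizing transform), averages over heavy-window libraries per
arm, and applies `log2((m13 + pc)/(m12 + pc)) ≥ 3` with pseudocount
pc = 0.5 normalized units; the eightfold boundary counts as enriched. The
window is selectable by fraction ids or density bounds, and the two are
equivalent on the same sample sheet (tested).

A `background_fraction` knob smears a share of every taxon's DNA uniformly
across fractions, emulating the contamination real gradients show. It
defaults to 0: under smear, an abundant degrader's own background in the
¹²C heavy window inflates the fold-change denominator and the categorical
eightfold rule loses sensitivity rapidly (at 1 % smear, most labeled taxa
drop below eightfold). This is a real limitation of fold-change SIP
calling, not of the simulator; passing operating-characteristic tests on
the clean model therefore says nothing about heavily smeared gradients.

## Indicator-value analysis

IndVal uses the group-equalized specificity A (means, not sums, so
unbalanced designs are tolerated) times fidelity B. Because the reported
group is selected as the per-phylotype maximum, the default permutation
statistic is the across-group *maximum* IndVal recomputed per permuted
labeling, which keeps the type-I error of emitted p-values at the nominal
level (calibrated on null data in the tests). A "best" mode that
recomputes only the observed best group's IndVal is provided for
compatibility with fixed-hypothesis use; it attains the minimum p of
1/(N+1) on exhaustive designs but is anti-conservative (~2× at α = 0.05
for two groups) when the group is data-selected. Monte-Carlo p-values use
(1 + count)/(N + 1) and are never zero; designs whose distinct labelings
do not exceed the requested permutation count are enumerated exhaustively.
Benjamini–Hochberg q-values are reported alongside raw p-values; responder
lists use raw p < 0.05 by default.

## qPCR

Standard curves are OLS of Ct on log10(copies) (≥ 3 points spanning ≥ 2
decades); efficiency 10^(−1/slope) − 1 outside (0.8, 1.1) is flagged.
Copies below the detection limit (default 300 copies µL⁻¹) are censored,
never zeroed — downstream ratios involving a censored target are censored
too. Simulated plates use slope −3.3219 (100 % efficiency), intercept 37,
additive Gaussian Ct noise (sd 0.15).

## Orchestration and determinism

All stage randomness derives from the single pipeline seed via
`default_rng([stage_index, seed])`; fixed-seed runs produce byte-identical
report bundles (tested end to end). TSV is the canonical table dialect;
the JSON summary records seeds and parameters and carries injected truth
next to estimates for synthetic runs. The pipeline's indicator stage
groups heavy-window libraries by isotope arm, which on gradient data makes
most phylotypes indicators of one arm (a compositional effect); with real
rRNA treatment profiles the stage is run with treatment groups instead.

## What the generator does not emulate

No sequence-level simulation (no reads, chimeras, or error models), no
taxonomy misclassification, no replicate-level community variation beyond
multinomial sampling, no gradient smear by default (see above), no isotope
fractionation, and no SOC pool structure beyond the two-source mixture.
Passing tests demonstrate correctness of the estimators under these
conditions, not robustness to every artifact of real data.

## Problem sizes used in the test and acceptance runs

Priming recovery uses 100 simulated experiments per regime at CV 0.05 with
n = 4 replicates; SIP operating characteristics use 20 gradient seeds
(plus 20 null seeds); IndVal calibration uses 1000 null phylotypes at 999
permutations; these sizes give Monte-Carlo standard errors comfortably
inside the tested tolerances while keeping a full run in seconds.
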