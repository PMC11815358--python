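# Methods

`pulsechase` implements the quantitative chain of an in-situ ¹³CO₂
pulse-chase experiment on a long-term warming × summer-precipitation
field trial: raw isotope, extract, biomarker and chamber measurements →
carbon-pool stocks → labelling-derived (excess) ¹³C stocks → a
split-plot repeated-measures mixed model. This note records the models,
the defaults and why, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Isotope arithmetic

δ¹³C (‰ vs. VPDB) and atom% ¹³C are interconverted through the isotope
ratio R = R_VPDB·(δ/1000 + 1) with R_VPDB = 0.0111802, AT% =
100·R/(1+R). The VPDB ratio is the community constant for ¹³C work; it
is a module-level constant, not a config knob, because changing it
silently would break comparability. Conversions are exact inverses
(property-tested to 1e−10 relative over δ ∈ [−100, 10⁴] ‰).

Soil concentrations (µg C g⁻¹ dry soil) scale to per-area stocks with

    stock [g C m⁻²] = conc × bulk_density × depth × 10⁴ cm² m⁻²,

defaults bulk density 1.21 g cm⁻³ and depth 20 cm (the sampled 0–20 cm
core). Excess ¹³C of a pool is

    excess [mg ¹³C m⁻²] = (AT%_sample − AT%_natural)/100 × C_pool,

with the natural-abundance reference taken from the unlabelled area of
the *same plot and day* — pairing is by the full experimental key and a
missing reference raises; there is no silent global default. Negative
excess (sample below its reference, i.e. within measurement noise) is
flagged and retained: truncation at zero would bias treatment means
upward.

The first labelling event used a 99 atom% label, the later two a
20 atom% label; excess values from the first event are divided by 5 to
put all events on one scale. The factor 5 is applied exactly as
defined for the experiment — it is not re-derived from the nominal
label strengths, which would give ≈5.2 in excess terms. Normalization
is recorded in a flag so it cannot be applied twice.

## Fumigation extraction and the extract mixing model

Microbial biomass C is the chloroform flush divided by the extraction
efficiency, C_mic = (C_f − C_nf)/k_EC with k_EC = 0.45; the
non-fumigated extract is the extractable-organic-C (EOC) pool. A
non-positive flush is kept as an explicit missing C_mic (flagged), so
the mixed model sees missingness instead of a silently dropped plot.
The atom% of microbial biomass comes from two-member mixing:

    AT%_Cmic = (AT%_f·C_f − AT%_nf·C_nf)/(C_f − C_nf).

Mass balance holds to machine precision by construction; AT%_Cmic may
legitimately exceed AT%_f and is never clamped. Flushes below a
configurable floor (default 5 µg C g⁻¹) flag the estimate as unstable
because the denominator amplifies extract measurement error. k_EC
cancels in the mixing model; the k_EC-corrected C_mic stock is the pool
size used in the excess equation.

## PLFA biomarkers

Marker → group assignment ships as an editable plain-text registry:
gram-positive a15:0, i15:0, i16:0, i17:0; gram-negative cy17:0, cy19:0;
fungal 18:2ω6,9; 16:1ω5 shared between bacteria and fungi. The shared
marker is monoenoic and its chromatographic fractions are discarded
before isotope analysis, so it contributes to total PLFA-C but never to
excess ¹³C — an intentional asymmetry. Unknown markers go to an
`unassigned` bucket with a warning, never silently dropped.

FAME δ¹³C is corrected for the methanol-derived carbon by single-carbon
mass balance, δ_PLFA = ((n+1)·δ_FAME − δ_MeOH)/n with n the PLFA carbon
number from the registry. The derivatization methanol default is
−40 ‰, a typical value that must be overridden with the lab's measured
methanol — it is deliberately a loud config constant, not a hidden one.

## Chamber fluxes

CO₂ flux is the OLS slope of the 0/10/20/30-min concentration series
converted with the ideal-gas molar density:
flux = slope·10⁻⁶ · P/(R·T) · V/A · 60 · M_C (mg C m⁻² h⁻¹), chamber
defaults V = 4850 cm³, A = 270 cm². Air temperature and pressure
default to 298.15 K and 101325 Pa when not recorded; both are
overridable. The atom% of respired CO₂ uses only the 0- and 30-min
endpoints in the gas analogue of the extract mixing model — the two
intermediate points inform the flux, not the isotopes, matching the
measurement protocol. No accumulation (c₃₀ ≤ c₀) leaves the respired
atom% undefined rather than extrapolated; negative slopes are retained
and flagged.

## The split-plot repeated-measures model

For each response y (log-transformed by default, since pools are
positive and effects multiplicative):

    y_hijk = µ + b_h + T_i + P_j + D_k + TD + PD + TP + TPD
             + p_hi + e_hijk

with random blocks b_h, random main-plot errors p_hi (block ×
temperature), and residuals correlated across the three days within a
subplot. Residual structures: iid, AR(1) with common day variance,
AR(1) with day-specific variances. The AR(1) lag is the ordered day
index (adjacent labelling events), not calendar time: day enters the
analysis as an ordered factor, and the 57-day and 2-day calendar gaps
would otherwise need a continuous-time model that a 3-point series
cannot support.

Estimation is REML with fixed effects profiled out: the objective is
maximized over log-variances and atanh(ρ) with a bounded quasi-Newton
optimizer, started from the closed-form expected-mean-squares ANOVA
estimators (ρ = 0) plus seed-controlled jittered restarts. If no
restart improves the start by more than 1e−9 the start is returned
unchanged — on balanced complete data with iid errors the ANOVA
estimators *are* the REML solution (when interior), and this rule makes
the classical equivalence exact instead of optimizer-precision. Zero
variance estimates are flagged (`boundary_variance`), not fatal.

Wald F tests use containment denominator degrees of freedom: the
warming main effect is tested in the main-plot stratum with
(n_blocks−1)(n_T−1) = 3 df; every other fixed term in the residual
stratum with n − rank([X Z]) df (30 for the complete design). This is a
deliberate, closed-form choice; Kenward–Roger-style adjustments would
tie results to a specific package's implementation. On balanced iid
data these F statistics reproduce the classical split-plot ANOVA table
exactly (tested to 1e−8).

Covariance structures are compared by REML AIC = −2ℓ_R + 2q with q the
number of variance–covariance parameters (including the block and
main-plot variances: 3/4/6), fixed effects held constant across
candidates so the REML likelihoods are comparable. Backward elimination
then drops, at each step, the least significant currently droppable
fixed term (no remaining higher-order interaction contains it; ties
broken by higher interaction order first, then larger p) until all
droppable terms have p ≤ α = 0.05. Blocks and the main-plot error are
structural and never dropped; the degenerate end state is intercept +
blocks.

A note on power observed in the shipped simulations: with 16 subplots ×
3 days, the 2-parameter AIC penalty of the heterogeneous-AR(1)
structure is overcome in about three quarters of replicates when the
true day variances differ 4:1 (ρ = 0.4), and in essentially all
replicates at 16:1. Model selection at this design size is honest but
not sharp; single-dataset structure choices should be read accordingly.

## Synthetic data generator

The generator emulates the field design — 4 blocks, warming on main
plots, precipitation history on subplots, three labelling days — with a
multiplicative (lognormal) response model: latent value = calibrated
cell mean × exp(block + main-plot + AR(1) day effects). Multiplicative
noise is the natural choice because every response is positive and all
reported effects are ratios, which then become *exact* generator
parameters. Defaults: σ_block = σ_mainplot = 0.08, σ_resid = 0.15 (log
scale ≈ CV), ρ = 0.4, seed 20210426 (the drought start date).

The calibrated effect table encodes the reported field responses:
respiration −35% at peak drought, +30%/+70% (ambient/warmed) after
rewetting; gram-positive PLFA-C −15% at drought and +20% after
rewetting; EOC +80% at drought; microbial-biomass excess ¹³C halved by
reduced-precipitation history; fungal excess ¹³C −85% at drought and
−70% under warming; root sugars +110% under warming before drought;
soil warming offsets 2.1/1.5/1.1 °C at 4/15/30 cm. Where a range was
reported (e.g. C_mic +10–25%) the midpoint is used. Within-treatment
variability of plant ¹³C uptake is not reported anywhere; plant-pool
CVs are free parameters and share the response-level defaults.

Raw observables are produced by *inverting* each analysis stage from
the latent truths: C_nf = EOC, C_f = C_nf + k_EC·C_mic; extract and gas
atom% chosen so the mixing equations return exactly the latent excess;
FAME δ¹³C via inverse methyl correction; chamber series via the inverse
flux formula. All randomness sits at the latent biological level, so
the stage inversions are exact and `analysis(generate(truth)) = truth`
holds identically — with variance components at zero this is the
zero-noise identity test (≤1e−8 relative across all 48 cells and all
response families). An instrument-noise knob (`measurement_cv`) exists
and defaults to 0. Raw D1 observables are emitted at 5× the normalized
latent excess so the analysis-side ÷5 reproduces the truth scale.
Atom% values outside (0, 100) trigger a logged resample (never reached
at default settings).

What the generator does *not* emulate: instrument drift and calibration
error, detection limits, chromatographic co-elution, missing plots,
within-plot spatial heterogeneity, non-lognormal error shapes, and any
mechanistic soil-water or photosynthesis dynamics (the microclimate
series are descriptive piecewise curves). Passing recovery tests
therefore demonstrate correctness of the computational chain under the
declared stochastic model, not robustness to real-world measurement
pathology.

## Problem sizes and seeds

The shipped calibration checks use: 200 generated datasets for headline
effect recovery (mean recovered effect within ±5 points of the
calibrated truth), 500 Gaussian null replicates for type-I calibration
(exact binomial 95% interval around 0.05), 200 replicates per scenario
for covariance-selection frequencies, and 50 balanced datasets for the
ANOVA-equivalence identity. All random streams derive from explicit
integer seeds; reruns are byte-identical.

## Known limitations

* Denominator df by containment can differ from asreml/Kenward–Roger
  p-values on unbalanced data.
* With 4 blocks, block and main-plot variance estimates rest on 3 df
  each; they are reported but individually very noisy, and boundary
  (zero) estimates are common when the true components are small.
* The REML optimizer uses numerical gradients; likelihood agreement
  between nested structures is guaranteed only to ~1e−7.
* The backward-elimination trace is a description of the fitted path,
  not an inferential procedure with controlled error rates.
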