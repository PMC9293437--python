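# Methods

This note documents the models, numerical choices and known limitations
behind `isoroot`, in the order the pipeline runs them.

## Calibration of vapour-phase δ¹⁸O

Probe networks deliver water vapour in isotopic equilibrium with soil or
xylem water to a laser spectrometer. Three corrections turn the raw
stream into liquid-equivalent δ¹⁸O:

1. **Concentration dependence.** Spectrometer readings are biased at low
   water-vapour concentration. The bias model is a four-parameter
   logistic, `f(ppm) = lower + (upper − lower)/(1 + (ppm/inflection)^slope)`,
   fitted by least squares to a laboratory dilution series of reference
   water (default −8.2 ‰) spanning 1000–30 000 ppm; the additive
   correction is `known − f(ppm)`. The 4PL family was chosen because it
   nests simpler sigmoids while exposing interpretable coefficients; a
   fit R² below 0.99 raises a warning. Readings above the working floor
   (6000 ppm) receive only a small correction; readings below it are
   QC-flagged (`LOW_PPM`) but still corrected and carried.
2. **Two-point standard calibration.** Each ~130-min measurement cycle
   includes two standards of known liquid δ¹⁸O (−4.4 / −19.5 ‰).
   Because the standards are measured as vapour, their knowns are
   converted to vapour-equivalents at the container temperature before
   the linear map (measured → known) is estimated and applied to the
   cycle's samples. Cycles missing a usable standard pair inherit the
   nearest-in-time calibration and are flagged. Applying the calibration
   twice is the identity (idempotence), which the tests check.
3. **Liquid–vapour equilibrium.** δ_l = (δ_v + 1000)·α(T) − 1000 with
   the Majoube (1971) liquid–vapour coefficients,
   1000·ln α = 1.137·10⁶/T² − 0.4156·10³/T − 2.0667 (T in kelvin),
   valid for −10…50 °C. Soil probes use the soil temperature at their
   depth; xylem probes use the stem sapwood temperature.

**Order of corrections** is concentration → standards → equilibrium:
the standards pass through the same optical path as the samples, so the
two-point map absorbs whatever bias the concentration correction leaves
behind. The order is configurable because the alternative (standards
first) is defensible too.

Quality control flags (`LOW_PPM` below 6000 ppm, `CONTAMINATED` when the
spectral residual exceeds the standards' mean + 1 SD) annotate readings;
daily summaries exclude flagged readings by default but a fully flagged
probe-day is reported with n = 0 rather than silently dropped.

## Tree water status

- **VPD** uses the Magnus-type saturation curve
  e_s(T) = 0.6108·exp(17.27·T/(T + 237.3)) kPa; the constants are
  configurable.
- **TWD** follows the zero-growth concept: the running maximum of stem
  radius is the growth envelope; any excursion below it is reversible
  water-deficit shrinkage, TWD_t = max_{s≤t} SR_s − SR_t ≥ 0. The
  running maximum carries across data gaps; SR itself is never
  interpolated, and no temperature correction is applied to the
  dendrometer signal.
- **Transpiration** integrates FD × SA (l s⁻¹) over each calendar day
  and divides by crown projection area (1 l m⁻² = 1 mm). Days missing
  more than a configurable fraction of steps are flagged.
- **Drought segmentation**: onset is the first day any tree's daily
  mean TWD exceeds 100 µm *while* topsoil VWC is below 0.12 (the VWC
  conjunct can be disabled — the observational definition motivates
  both criteria without stating their logical combination); the window
  closes at the first subsequent ≥ 20 mm/24 h rain event (the
  campaign's drought-ending event was 39 mm). All thresholds are
  configuration defaults, not literals.

## The mixing model

Daily, independent fits (no temporal smoothing — a deliberate scope
boundary): for K soil layers,

    p ~ Dirichlet(α),  ξ ~ Uniform(0, ξ_max),
    p′_k = p_k c_k / Σ_j p_j c_j,
    x_i | p, ξ ~ Normal(Σ_k p′_k μ_k, ξ·Σ_k p′²_k σ²_k).

- **Prior.** The fine-root biomass profile (5-cm bins) is integrated
  over the probe-depth layers (boundaries at probe midpoints 0–10,
  10–22.5, 22.5–37.5, 37.5–50 cm, configurable because the field
  grouping is instrumentation-specific); α_k = K·r_k keeps Σα = K, so
  the informative prior carries exactly the weight of a flat
  Dirichlet(1,…,1). A layer with zero root mass is rejected — it would
  forbid a source outright.
- **Concentration dependence** weights proportions by the layers' daily
  mean volumetric water content before forming the mixture.
- **Error structure.** The source-propagated ("process") variance is
  scaled by a free multiplicative residual factor ξ with a generous
  uniform prior (0, 20); a floor of 10⁻⁶ ‰² guards the ξ→0 / σ→0
  corner. The model reports the Dirichlet-distributed p (the
  conventional mixing-model output); the concentration-adjusted p′ is
  exposed alongside and a config switch selects which one the pipeline
  tabulates.
- **Sampler.** Multi-chain random-walk Metropolis on the additive
  log-ratio transform z ∈ ℝ^{K−1} (p = softmax([z, 0]); the Jacobian
  Σ_k log p_k is included in the target), with a Gaussian walk on ξ
  rejected outside its bounds. Proposal scales adapt toward ~30 %
  acceptance during burn-in only, so the post-burn-in kernel is a fixed,
  valid Metropolis kernel. Field-campaign defaults: 100 000 iterations,
  50 000 burn-in, thinning 50, three chains (1000 retained draws per
  chain); per-parameter Gelman–Rubin R̂ with a 1.1 warning threshold.
  Chains start over-dispersed from prior draws. Reducing chain length
  for tests changes Monte-Carlo error only, never the target.
- **Validation.** The sampler is checked against brute-force
  simplex-grid integration (step 0.01, ξ on a 50-point grid) for K ≤ 3
  — agreement within 0.02 — and against the two-source closed form
  p₁ = (δ_x − δ₂)/(δ₁ − δ₂). A subtlety worth recording: a naive grid
  mask (`a + b < 1`) admits float-roundoff points with p_k ≈ 10⁻¹⁶,
  whose Dirichlet density diverges when α_k < 1 and silently dominates
  the sum; the oracle keeps a half-step margin off the boundary.

## Uptake partitioning and season statistics

Absolute uptake U_k = p̄_k · E conserves Σ_k U_k = E by construction;
posterior SDs propagate first-order (SD·E) in the summary table, with
draw-wise propagation available while draws are retained. Short gaps in
the proportion series are filled by linear interpolation of the flanking
days, renormalised to the simplex, flagged, and never extrapolated past
the data boundary. Weekly periods (first drought week, last drought
week, a 7-day post-drought window anchored by default to the last
observed week) are compared by one-way repeated-measures ANOVA
(subject = tree) with Tukey HSD on the within-subject error term and a
compact letter display at α = 0.05; per-tree weekly values are assumed
(three subjects). Pearson correlation tables (depths × total
transpiration, during/after drought) carry two-sided p-values with
stars at 0.01 and 0.001.

## The synthetic season generator

The generator emulates the study design the instruments describe: a
130-day season (10 May–16 Sept), three trees, four probe depths
(5/15/30/45 cm) in two soil profiles, 10-min logging, a drought window
(29 Jun–23 Aug) with suppressed rainfall ended by a single 39 mm/24 h
event of −7.9 ‰, precipitation δ¹⁸O uniform on −8.7…−1.4 ‰, and 0.3 ‰
instrument noise.

- **Soil.** A layered bucket: infiltration mixes rain into the top
  layer volume-weighted; excess above field capacity drains downward
  displacing water and its δ; uptake is non-fractionating and floored
  at residual moisture; evaporation (top layer only) removes water and
  enriches the remaining pool by a fixed ‰ per mm evaporated (0.4 by
  default). This linear-enrichment rule replaces a Craig–Gordon model
  on purpose: only the observed pattern (several-‰ topsoil enrichment
  during drought, stable deep layers) matters downstream, and the
  simple rule keeps the water and isotope balances auditable — the
  season-long water balance closes to < 10⁻⁶ mm and the tests assert it.
- **Trees.** Daily transpiration responds to demand and topsoil
  moisture, E = E_max·(1 − e^{−VPD/s})·(floor + (1−floor)·wetness); TWD
  combines a VPD term and a dryness term. The coefficients were chosen
  once so the season reproduces the regimes the design describes —
  pre-drought TWD around 40 µm with one tree first crossing 100 µm
  inside the drought window, transpiration dropping by a factor ≈ 2.2,
  topsoil VWC below 0.12 through the drought.
- **Uptake truth.** Daily proportions follow a piecewise-linear path
  through three anchor compositions — (0.54, 0.23, 0.15, 0.08)
  pre-drought, (0.16, 0.32, 0.29, 0.23) at the drought end,
  (0.34, 0.35, 0.20, 0.11) three weeks after rewetting — the regime the
  recovery tests must probe. Xylem δ¹⁸O is the concentration-weighted
  mixture of the soil sources under the day's true proportions plus a
  small per-tree deviation (0.15 ‰).
- **Instruments.** The emitter inverts the calibration chain: liquid →
  vapour at the probe temperature, per-cycle slope/offset drift, a 4PL
  concentration bias that the correction fit must recover, and
  Gaussian noise. Dendrometer traces are built from a growth envelope
  frozen whenever the stem sits below its historical maximum, so the
  zero-growth extraction recovers the prescribed TWD; sap-flux series
  are shaped so daily integration recovers the prescribed E exactly.
- **Reproducibility.** One root seed feeds named child streams
  (forcing, trees, observations, lab calibration), so regeneration is
  byte-identical and adding a component never perturbs the others.

What the generator does *not* emulate — Craig–Gordon kinetic
fractionation, Richards-equation soil physics, root-profile dynamics,
leaf-level enrichment, organic spectral contamination events — bounds
what passing tests show: they demonstrate that the inference machinery
recovers known truth under the stated noise and drift model, not that
field data meet those assumptions.

## Numerical choices and test scales

- Variance floor 10⁻⁶ ‰² in the likelihood; R̂ floored at 1; calibration
  maps require distinct measured standards (degenerate pairs raise).
- Test and acceptance runs use scaled-down chains (8000–10 000
  iterations, burn-in half, thinning 4–5) and a 30-day subsample of the
  season for parameter recovery, sized so Monte-Carlo error stays well
  below the tolerances being asserted; the pipeline's end-to-end checks
  run on a 40-day season with proportionally lowered drought thresholds
  (a 20-day window cannot accumulate a month-scale water deficit).
- Known behaviour: with a single tracer and four sources the likelihood
  constrains one direction of the simplex; the remaining directions are
  prior-dominated, and the residual factor ξ widens the mixture
  variance further, so 95 % credible intervals are conservative — on
  synthetic recovery runs they cover the truth on essentially all days
  (~99–100 %), while the posterior-mean RMSE stays below 0.08. Interval
  widths should therefore be read as cautious bounds, not calibrated
  frequentist intervals — typical of underdetermined mixing models.
- Repeated standard readings, taken through the full chain back to
  liquid equivalents, show a season-long SD of ≈ 0.32 ‰: the 0.3 ‰
  instrument noise plus small per-cycle drift, matching the precision
  the instrument class reports.
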