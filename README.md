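# isoroot

Depth-resolved root water uptake of trees, inferred from high-frequency
in-situ water-isotope monitoring.

`isoroot` is a Python library and command-line tool for ecohydrologists
who run laser-spectrometer (IRIS) probe networks in forest soil and tree
xylem. It turns raw vapour-phase δ¹⁸O readings, dendrometer traces,
sap-flux densities and soil-moisture series into daily estimates of how
much water trees extract from each soil layer — through a
drought–recovery season, with full uncertainty propagation.

## What it computes

**Signal processing.** Raw vapour δ¹⁸O is corrected for its
water-vapour-concentration dependence (four-parameter logistic fit to a
laboratory dilution series), calibrated per ~2-h measurement cycle
against two on-site standards of known composition (−4.4 and −19.5 ‰),
and converted to liquid-equivalent values via the temperature-dependent
liquid–vapour equilibrium fractionation (Majoube coefficients,
1000·ln α = 1.137·10⁶/T² − 0.4156·10³/T − 2.0667). Readings below
6000 ppm or with elevated spectral residuals are flagged, never deleted.

**Tree water status.** Stem-radius series are split into irreversible
growth and tree water deficit (TWD) under the zero-growth concept
(TWD_t = running-max(SR) − SR_t); transpiration is sap flux density ×
sapwood area, normalised by crown projection area to mm d⁻¹; a drought
window is segmented from TWD, topsoil water content and precipitation
thresholds.

**Bayesian isotope mixing model.** For each day, the proportions
p = (p₁,…,p_K) of xylem water drawn from K soil layers follow

    p  ~ Dirichlet(α),        α_k = K · r_k   (fine-root fraction r_k)
    ξ  ~ Uniform(0, 20)
    p′_k = p_k c_k / Σ_j p_j c_j              (c_k = layer water content)
    x_i ~ Normal( Σ_k p′_k μ_k ,  ξ · Σ_k p′²_k σ²_k )

with (μ_k, σ_k) the day's per-layer source δ¹⁸O summaries and x_i the
per-tree xylem values. Sampling is multi-chain random-walk Metropolis on
the log-ratio transform of the simplex, with Gelman–Rubin R̂ convergence
diagnostics. Posterior proportions × transpiration give the absolute
uptake per layer (mm d⁻¹), and the season-level analyses (weekly period
comparisons by repeated-measures ANOVA with Tukey letters, Pearson
correlation tables against total transpiration) follow.

**Synthetic season.** Because every stage needs a known answer to be
testable, `isoroot.synthetic_data` generates a full ~130-day
drought–recovery season — forcing, a layered soil bucket with isotope
mass balance and evaporative topsoil enrichment, prescribed daily uptake
proportions, and raw instrument streams produced by inverting the whole
calibration chain (13-probe × 10-min cycles, per-cycle drift,
concentration bias, 0.3 ‰ noise).

## Worked example

Fit one mid-drought day: four soil layers with an evaporatively enriched
topsoil (−3.1 ‰ at 5 cm vs −11.0 ‰ at 45 cm), dry topsoil (VWC 0.07),
three xylem observations around −8.5 ‰:

```python
import numpy as np, pandas as pd
from isoroot import SourceDay, MCMCSettings, build_prior, fit_day
from isoroot.synthetic_data import default_root_profile

prior = build_prior(default_root_profile(), (0, 10, 22.5, 37.5, 50))
sources = SourceDay(
    date=pd.Timestamp("2018-07-20"),
    mu=np.array([-3.1, -8.6, -10.2, -11.0]),
    sigma=np.array([0.35, 0.30, 0.28, 0.30]),
    concentration=np.array([0.07, 0.13, 0.24, 0.28]),
)
post = fit_day([-8.42, -8.65, -8.38], sources, prior, MCMCSettings(seed=42))
print("posterior mean p:", post.mean)
print("posterior sd   :", post.sd)
print("R-hat          :", post.rhat)
```

prints

```
posterior mean p: [0.35  0.386 0.192 0.072]
posterior sd   : [0.129 0.22  0.132 0.081]
R-hat          : [1.001 1.    1.001 1.006 1.   ]
```

Read: on this day the trees drew ~35 % of their water from the 0–10 cm
layer (despite its enrichment, the dry topsoil's low water content
down-weights it), ~39 % from 10–22.5 cm, and progressively less from
depth; all R̂ ≈ 1 so the three chains agree. Multiplying by that day's
transpiration (say 1.6 mm d⁻¹) gives absolute uptake of ≈ 0.56 mm d⁻¹
from the topsoil.

The same analysis runs end-to-end from the shell:

```
isoroot all --seed 1 --outdir run1
```

which simulates a season (or processes your CSVs), calibrates, segments
the drought, fits every day and writes tidy CSV outputs plus a JSON
manifest with per-file checksums.

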