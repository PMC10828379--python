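# Methods and design notes

## Scope and model

The package estimates annual CH₄-C balances of peatland microforms from
sparse manual chamber campaigns. The causal picture it encodes: methane
production rises exponentially with soil temperature at 5 cm (TS₅), and the
fraction escaping oxidation rises with the water table (WL, metres relative
to the peat surface, negative below). The working model is

    CH4 = (c + d·WL) · exp(b·TS5)        [mg CH4-C m⁻² h⁻¹, TS5 in °C]

affine in WL at fixed temperature and exponential in temperature at fixed
WL. `(c + d·WL)` may go negative: small uptake fluxes occur in the field and
are deliberately not clamped. The temperature-only alternative is the
Lloyd–Taylor respiration form

    CH4 = R_ref · exp[ e0 · (1/(T_ref − T0) − 1/(T_K − T0)) ]

with the canonical parenthesization and constants T₀ = 227.13 K,
T_ref = 283.15 K, so the prediction at T_ref equals R_ref for every e₀ (this
identity is unit-tested). The typeset form of this equation is ambiguous
about the parenthesization of the inverse-temperature differences; the
canonical form is the one consistent with the stated constants.

## Flux engine

Per closure: trim the leading 10 % of samples (chamber-placement
artifacts); screen the first-difference distribution for one-sample jumps
larger than max(6 × robust noise SD, 0.02 ppm) — an automated stand-in for
visual ebullition screening; slide a window of `window_length(date)` seconds
in 1-s steps; per window compute the OLS slope, R², chamber ΔT and relative
PAR change; drop windows with ΔT > 1.5 °C or PAR change > 10 % (the PAR
screen applies to transparent chambers only — opaque chambers carry no PAR
signal); among survivors require R² ≥ 0.8 unless the CH₄ increase across the
window is below 3 % of the window-mean concentration (the waiver is applied
at window level; whole-trace increase would be the alternative reading);
select the max-R² window, ties broken toward the earliest start
(deterministic). Window length is linear in solar declination,
w = round(50 − 10·δ/23.44) s, giving 40 s at the summer solstice, 60 s at
the winter solstice and 50 s at the equinoxes.

Slope → mass flux uses the ideal gas law at the window-mean chamber
temperature and a configurable pressure (default 101.325 kPa), on a CH₄-C
basis (molar mass 12.011 g mol⁻¹). An invalid record carries exactly one
machine-readable rejection reason; when no window survives, the reason is
the screen that rejected the most windows (temperature > PAR > R² on ties).

**Minimum detectable flux.** The MDF is the flux equivalent of the smallest
slope distinguishable from analyzer noise over one window: for i.i.d.
Gaussian noise of SD σ on a regular n-point grid with spacing Δt the OLS
slope standard error is σ·√(12/(n(n²−1)))/Δt; the MDF applies a 1.96
coverage factor and σ = 0.8 ppb by default. The formula and constants sit in
the QC config so an alternative policy can be swapped in. Below-MDF fluxes
are flagged, never removed, to avoid biasing the dataset.

**Morning filter.** A flux is removed only when all three conditions hold:
closure start concentration above 3 ppm, the plot's highest flux of the
day, and the plot's first measurement of the day before 08:00. Timestamps
are naive local time; the 08:00 threshold and 3 ppm level are configurable.

**Known behaviour: selection bias.** Choosing the max-R² window slightly
favours windows where noise steepens the apparent slope. Numerically, a
fixed-window estimate is unbiased while max-R² selection adds
≈ +0.001–0.002 mg CH₄-C m⁻² h⁻¹ at 0.8 ppb noise (larger for the short
summer windows) — roughly a tenth of the MDF and proportional to the noise
scale, so metrologically irrelevant but statistically detectable in very
large synthetic ensembles. The test suite bounds it against the MDF rather
than pretending it is zero.

## Campaign medians and gap-filling

Opaque and transparent fluxes pool (their difference is testable with the
built-in Mann–Whitney suite: two-sided U tests per group pair × season,
seasons by meteorological month, groups with n < 3 skipped). One median
(flux, TS₅, WL) triple per plot × campaign drives all fitting: the median
damps episodic high emissions. TS₅ is the site's daily median soil
temperature (per-site, not per-plot; configurable), WL the plot's value on
the campaign day.

Nonlinear fits use multi-start least squares: e₀ ∈ {50, 200, 400} with
R_ref from the mean flux; b ∈ {0.05, 0.1, 0.2} with (c, d) solved linearly
at each b (at fixed b the model is linear in (c, d)), best converged RSS
wins; tolerances 1e-14 so exact synthetic data recovers parameters to
machine precision. Bootstrap and cross-validation refits start from the
full-data solution and fall back to the multi-start search if that fails.
Daily predictions are flagged (not suppressed) on days whose drivers fall
outside the calibration range; mg h⁻¹ → g d⁻¹ is ×24/1000.

The linear method builds a jackknife × bootstrap ensemble: each of 2000
replicates picks one plot median per campaign at random; within a replicate
each campaign is left out in turn and the rest interpolate linearly to a
daily series, extended flat beyond the first/last campaign (the edge
handling had to be chosen; constant extension is the least-structured
option). The reported balance is the median over all jackknife sums; the SE
is the SD over replicates, each replicate summarised by the mean of its
jackknife sums.

## Validation and balances

Cross-validation: random 80/20 splits at the level of individual median
records, sampled without replacement per bootstrap (campaign-level splits
are a reasonable alternative; record-level was chosen as the plain reading
of "80 % of the median fluxes"). R² is the squared Pearson correlation of
predicted vs. observed (bounded [0, 1]; a constant prediction scores 0);
RMSE and bias = mean(predicted − observed) are averaged over bootstraps,
R² by its median, each with the SD of the bootstrap distribution as its SE.
AIC = n·ln(RSS/n) + 2k with k = parameters + 1 for the error variance, from
the full-data fit; only differences between methods on the same medians are
meaningful, and the linear interpolation has no AIC by construction.

Annual balances: full-data fit predicts daily fluxes which are summed over
the balance year (1 Nov–31 Oct by default); the SE is the SD of annual sums
over 2000 refits on medians resampled with replacement; refit failures are
skipped, and more than 20 % of them abort the computation. Site totals
weight microform balances by transect areal fractions (pooled per-cm share;
SD across transects). Error propagation treats fractions and balances as
independent: SE² = Σ (aᵢ·SE_Fᵢ)² + (Fᵢ·SE_aᵢ)². The fraction uncertainty
entering the propagation defaults to SD/√n_transects (the layout stores the
SD; the propagation call accepts any explicit uncertainty instead).

CO₂ equivalents: g CH₄-C m⁻² yr⁻¹ × (16/12) × GWP × 10⁴/10⁶ → t CO₂-eq
ha⁻¹ yr⁻¹, GWP 28 (100-year horizon). The 16/12 molar ratio is the integer
convention; the exact 16.043/12.011 ratio is available via the
`mass_ratio` argument and shifts totals by ~0.2 %.

Tree branches: leaf-area fluxes × LAI give ground-area fluxes, run through
the linear ensemble; stem emissions are out of scope. Eriophorum LAI
follows blade density × mean green-blade height × leaf area per blade
length, share-weighted over plot sections.

## Synthetic campaign generator

The generator supplies ground truth for every downstream stage. It
emulates: a temperate-oceanic year (annual + diurnal soil-temperature
sinusoids with AR(1) day-to-day noise, mean ≈ 10 °C, daily medians spanning
≈ 0–22 °C); daily precipitation (wet-day probability 0.45, gamma amounts,
≈ 680 mm yr⁻¹); water levels from a linear-reservoir bucket (rise with
precipitation × response factor, exponential recession toward a dry
asymptote, ponding cap) with additive per-microform offsets — hummocks
0.10–0.16 m below their hollows; two sites, the open one wetter (hollow
mean WL ≈ −0.03 m) and the treed one drier and flashier; true fluxes from
the WL + ST law with per-microform parameters chosen so annual sums land at
tens of g CH₄-C m⁻² yr⁻¹ on the wet site and below ten on the drier one;
campaigns every 4 weeks in November–February and every 3 weeks in
March–October, ≥ 4 closures per chamber type per plot per campaign between
06:00 and 18:00; traces exactly linear at the slope implied by the true
flux and chamber geometry (0.49 × 0.49 × 0.64 m box with surface-offset
volume correction), ambient ≈ 2 ppm, i.i.d. Gaussian analyzer noise at the
0.8 ppb precision scale; and injected artifacts recorded as ground truth —
ebullition steps (+0.2 ppm), chamber-heating ramps (6 °C, steep enough that
every window exceeds the 1.5 °C screen), continuous 50 % PAR swings, and
stable-morning enrichment (first closure of the day starting ≥ 3 ppm with
an inflated flux). Every generator is a pure function of (config, seed),
with per-generator streams split deterministically from one top-level seed.

It does not emulate: correlated analyzer noise or drift, real instrument
file formats, diurnal flux cycles (the flux law has no PAR term — no PAR
dependence is part of the design), snow/flooding volume displacement,
vegetation succession, or water chemistry. Passing tests therefore
demonstrate the correctness of the computation chain under known dynamics,
not the realism of any particular field site; in particular the true flux
field is exactly the WL + ST law, so model-selection tests show the
machinery can detect a WL effect where one exists, not that real hollows
obey the law.

Ambient pressure (101.325 kPa) and ambient CH₄ (2 ppm) are config
parameters; neither is observable from the balance outputs at realistic
perturbations.

## Problem sizes and numerical choices

Bootstrap defaults are 1000 (cross-validation) and 2000 (balances),
matching the reporting conventions above. The statistical test-suite checks
run smaller, as a deliberate sizing choice for a routine test cycle:
cross-validation direction checks use 150 bootstraps per campaign over 50
campaigns, and the coverage check uses 300 balance bootstraps per campaign
over 100 campaigns (a 300-replicate SD estimates the SE to ~4 %, ample for
a ±2 SE coverage check). Degenerate inputs are handled explicitly: constant
fluxes drive e₀ → 0 (Lloyd–Taylor) and d → 0 (WL + ST); zero-variance
observations or predictions score R² = 0; empty campaigns, label
mismatches, non-monotone timestamps, gap days and non-positive volumes
raise with the offending item named.

## Known limitations

* The ebullition screen is a statistical jump detector, not the visual
  inspection it replaces; its false-positive rate on clean traces is
  reported by the test suite (≈ 0 at default thresholds).
* Water-level interpolation between campaigns is the generator's concern
  here; with real diver + dip-well data the per-plot offset interpolation
  would need its own validation.
* The AIC uses the Gaussian RSS form; absolute values are not comparable
  across datasets.
* Bootstrap SEs treat campaign medians as exchangeable; serial correlation
  between campaigns is ignored, as in the underlying field protocol.
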