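# mireflux

Closed-chamber CH₄ flux analysis for rewetted peatlands: from raw chamber
concentration traces to QC'd fluxes, gap-filled daily series, annual
balances per bog microform (hummock / hollow), and areally weighted site
totals with propagated uncertainty — plus a synthetic campaign generator
with known ground truth so the entire chain is testable without field data.

It is aimed at greenhouse-gas flux groups working with manual static
chambers on peatland microtopography, where campaigns are sparse
(every 3–4 weeks), fluxes are strongly temperature- and water-table-driven,
and annual budgets must be interpolated from a handful of campaign medians.

## What it computes

**Flux engine.** Each chamber closure (CH₄ mole fraction vs. time, 120–180 s
at 1 Hz) is reduced to one flux by ordinary least squares on a moving window:
window length follows solar declination (40 s at the summer solstice, 60 s in
winter), the first 10 % of samples are trimmed, windows with chamber
temperature change > 1.5 °C or PAR change > 10 % (transparent chambers) are
discarded, the max-R² window wins (R² ≥ 0.8 required unless the CH₄ increase
is below 3 % of the mean concentration, so near-zero fluxes are kept).
Slopes convert to mass fluxes by the ideal gas law at chamber temperature,
reported as mg CH₄-C m⁻² h⁻¹. Every flux is compared against the minimum
detectable flux implied by the analyzer precision (0.8 ppb default) and
flagged — never removed — when below it. Dataset-level screens remove
ebullition-type step discontinuities and stable-morning enrichment
artifacts (closure starting above 3 ppm that is the plot's first and
highest flux of the day, before 08:00).

**Gap-filling.** Valid fluxes pool (opaque + transparent) into one median per
plot and campaign. Two nonlinear models are fitted per microform,
statsmodels-style (`Model.from_medians(...).fit()` → results with
parameters, standard errors, AIC, `summary()`, `predict_daily()`):

* temperature response (Lloyd–Taylor form), with T in kelvin:

  CH₄ = R_ref · exp[ e₀ · ( 1/(T_ref − T₀) − 1/(TS₅ − T₀) ) ],
  T₀ = 227.13 K, T_ref = 283.15 K

* water level + soil temperature (WL + ST), TS₅ in °C, WL in m
  (negative below surface):

  CH₄ = (c + d·WL) · exp(b·TS₅)

and a jackknife × bootstrap **linear interpolation** ensemble (one random
plot median per campaign, 2000 replicates, each campaign left out in turn).

**Model selection.** Bootstrap 80/20 cross-validation (1000 splits) scores
each method by median R² (squared Pearson correlation of predicted vs.
observed), mean RMSE and mean bias (predicted − observed), with AIC
(n·ln(RSS/n) + 2k) for the nonlinear fits.

**Annual balances.** Daily predictions (site median TS₅ + plot water level)
are summed over the balance year; uncertainty comes from refitting on 2000
resamples of the medians. Transect surveys (per-cm microform sequences)
give areal fractions; site totals are Σᵢ aᵢFᵢ with Gaussian error
propagation √(Σ (aᵢ·SE_Fᵢ)² + (Fᵢ·SE_aᵢ)²), and convert to CO₂ equivalents
(×16/12 × GWP 28). Tree-branch fluxes scale by leaf area index into a
ground-area term via the linear machinery.

## Worked example

Upscaling an open bog site from its two microforms, with the hollow
balance 37 ± 3.2 g CH₄-C m⁻² yr⁻¹, hummock 34.9 ± 3.0, and transect
fractions 56.5 % / 43.5 % (± 2.2 % over 5 transects):

```python
import mireflux as mf

layout = mf.MicroformLayout({"open_hol": 0.565, "open_hum": 0.435},
                            {"open_hol": 0.022, "open_hum": 0.022}, n_transects=5)
balances = {
    "open_hol": mf.AnnualBalance("open_hol", 37.0, 3.2, "wlst"),
    "open_hum": mf.AnnualBalance("open_hum", 34.9, 3.0, "wlst"),
}
site = mf.upscale_site(balances, layout)
print(f"site balance: {site.balance:.1f} +/- {site.se:.1f} g CH4-C m-2 yr-1")
print(f"hollow share: {100 * site.extras['shares']['open_hol']:.0f} %")
print(f"CO2 equivalents: {mf.co2_equivalents(site.balance):.2f} t CO2-eq ha-1 yr-1")
```

prints

```
site balance: 36.1 +/- 2.3 g CH4-C m-2 yr-1
hollow share: 58 %
CO2 equivalents: 13.47 t CO2-eq ha-1 yr-1
```

i.e. the hollows dominate the site's methane budget (58 % of 36.1 g CH₄-C
m⁻² yr⁻¹), which corresponds to ~13.5 t CO₂-equivalents per hectare and
year at a 100-year GWP of 28.

The full pipeline also runs from the shell on a synthetic campaign:

```
mireflux run --seed 1 --outdir run1
mireflux report --outdir run1
```

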