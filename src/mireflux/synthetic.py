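"""Synthetic chamber-campaign generator with known ground truth.

Emulates a one-year closed-chamber CH4 campaign on a rewetted bog with two
sites (an open, wet site and a drier, birch-encroached site), each split
into hummock/hollow microforms with three replicate plots.  The generator
produces:

* driver series — soil temperature at 5 cm (annual + diurnal sinusoid with
  AR(1) day-to-day noise), daily precipitation, and per-plot water level
  from a linear-reservoir bucket (rise with precipitation, exponential
  recession, per-microform offsets);
* true daily fluxes from the water-level + soil-temperature law
  (c + d*WL) * exp(b*TS5) with per-microform parameters;
* chamber concentration traces that are exactly linear with the slope
  implied by the true flux and chamber geometry, plus Gaussian analyzer
  noise and optional injected artifacts (ebullition step, chamber-heating
  ramp, PAR step, stable-morning enrichment), all recorded as ground truth;
* per-cm microform transect strings for areal-fraction estimation.

Every generator is a pure function of (config, seed); seeds are split
deterministically per generator from the single top-level seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chamber import ChamberGeometry, Trace, effective_volume, flux_to_slope
from .models import WLSTParams

WINTER_MONTHS = (11, 12, 1, 2)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """Climate and hydrology of one site."""

    name: str
    temp_mean_c: float = 10.2
    temp_amp_annual_c: float = 10.5
    temp_amp_diurnal_c: float = 2.0
    temp_ar1_rho: float = 0.8
    temp_noise_sd_c: float = 1.0
    wl_min_m: float = -0.33          # deep-recession asymptote of the bucket
    wl_tau_days: float = 40.0        # recession time constant
    wl_response_m_per_mm: float = 0.004
    wl_max_m: float = 0.06           # ponding cap
    wl_init_m: float = -0.15


@dataclass(frozen=True)
class MicroformSpec:
    """One microform: WL offset from the site base curve and true flux law."""

    name: str
    site: str
    wl_offset_m: float
    true_params: WLSTParams
    n_plots: int = 3


def _default_sites() -> tuple[SiteSpec, ...]:
    return (
        SiteSpec(name="open", wl_min_m=-0.33, wl_tau_days=40.0,
                 wl_response_m_per_mm=0.004, wl_max_m=0.06),
        SiteSpec(name="tree", temp_mean_c=9.8, temp_amp_annual_c=9.5,
                 wl_min_m=-0.34, wl_tau_days=25.0,
                 wl_response_m_per_mm=0.005, wl_max_m=0.05),
    )


def _default_microforms() -> tuple[MicroformSpec, ...]:
    # per-microform flux laws chosen so annual sums land at tens of
    # g CH4-C m-2 yr-1 on the wet site and below ten on the drier one
    return (
        MicroformSpec("open_hol", "open", 0.00, WLSTParams(b=0.115, c=1.40, d=6.0)),
        MicroformSpec("open_hum", "open", -0.10, WLSTParams(b=0.130, c=1.70, d=5.0)),
        MicroformSpec("tree_nT_hol", "tree", -0.01, WLSTParams(b=0.100, c=0.45, d=1.8)),
        MicroformSpec("tree_nT_hum", "tree", -0.12, WLSTParams(b=0.110, c=0.65, d=1.5)),
        MicroformSpec("tree_T_hol", "tree", 0.01, WLSTParams(b=0.100, c=0.42, d=1.2)),
        MicroformSpec("tree_T_hum", "tree", -0.16, WLSTParams(b=0.110, c=0.55, d=1.0)),
    )


@dataclass(frozen=True)
class CampaignConfig:
    """Full simulation settings, seeded."""

    start: str = "2020-11-01"
    end: str = "2021-10-31"
    sites: tuple[SiteSpec, ...] = field(default_factory=_default_sites)
    microforms: tuple[MicroformSpec, ...] = field(default_factory=_default_microforms)
    precip_wet_prob: float = 0.45
    precip_mean_wet_mm: float = 4.15      # ~680 mm yr-1
    wl_noise_sd_m: float = 0.005
    winter_spacing_days: int = 28
    veg_spacing_days: int = 21
    closures_per_type: int = 4
    closure_s: float = 150.0
    sample_dt_s: float = 1.0
    ambient_ch4_ppm: float = 2.0
    noise_ppb: float = 0.8
    pressure_kpa: float = 101.325
    p_ebullition: float = 0.02
    p_dt_ramp: float = 0.02
    p_par_swing: float = 0.02
    p_morning: float = 0.04               # per plot-day
    wl_bounds: tuple[float, float] = (-1.0, 0.3)
    ts5_bounds: tuple[float, float] = (-5.0, 30.0)
    seed: int = 0

    def plots(self) -> pd.DataFrame:
        rows = []
        for mf in self.microforms:
            for i in range(mf.n_plots):
                rows.append({"plot_id": f"{mf.name}_{i + 1}",
                             "microform": mf.name, "site": mf.site,
                             "wl_offset_m": mf.wl_offset_m})
        return pd.DataFrame(rows)

    def true_params(self) -> dict[str, WLSTParams]:
        return {mf.name: mf.true_params for mf in self.microforms}


def default_config(seed: int = 0, **overrides) -> CampaignConfig:
    return dataclasses.replace(CampaignConfig(seed=seed), **overrides)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    # deterministic per-generator seed split off the single top-level seed
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(config_seed), spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

@dataclass
class Drivers:
    """Generated driver series with per-plot registry."""

    daily_ts5_df: pd.DataFrame      # index date, one column per site, degC
    hourly_ts5_df: pd.DataFrame     # index hourly datetime, one column per site
    precip_mm: pd.Series            # index date
    wl_df: pd.DataFrame             # index date, one column per plot, m
    plots: pd.DataFrame             # plot_id, microform, site, wl_offset_m

    def daily_ts5(self, site: str, date) -> float:
        d = pd.Timestamp(date).normalize()
        try:
            return float(self.daily_ts5_df.loc[d, site])
        except KeyError:
            raise ValueError(f"no TS5 driver for site {site!r} on {d.date()}")

    def plot_wl(self, plot_id: str, date) -> float:
        d = pd.Timestamp(date).normalize()
        try:
            return float(self.wl_df.loc[d, plot_id])
        except KeyError:
            raise ValueError(f"no WL driver for plot {plot_id!r} on {d.date()}")

    def site_ts5_series(self, site: str) -> pd.Series:
        return self.daily_ts5_df[site]

    def microform_wl_series(self, microform: str) -> pd.Series:
        cols = self.plots.loc[self.plots["microform"] == microform, "plot_id"]
        return self.wl_df[list(cols)].mean(axis=1)

    def plot_drivers(self, site: str | None = None, axes=None):
        """Quick-look panel: precipitation, water level, soil temperature."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        axes[0].bar(self.precip_mm.index, self.precip_mm.values, width=1.0)
        axes[0].set_ylabel("precip [mm d-1]")
        for col in self.wl_df.columns:
            axes[1].plot(self.wl_df.index, self.wl_df[col], lw=0.6, alpha=0.6)
        axes[1].axhline(0.0, color="grey", lw=0.8)
        axes[1].set_ylabel("WL [m]")
        cols = [site] if site else self.daily_ts5_df.columns
        for c in cols:
            axes[2].plot(self.daily_ts5_df.index, self.daily_ts5_df[c], label=c)
        axes[2].set_ylabel("TS5 [degC]")
        axes[2].legend()
        return axes


def gen_drivers(config: CampaignConfig) -> Drivers:
    """Generate soil temperature, precipitation and per-plot water levels."""
    start, end = pd.Timestamp(config.start), pd.Timestamp(config.end)
    if end <= start:
        raise ValueError(f"period end {end.date()} is not after start {start.date()}")
    dates = pd.date_range(start, end, freq="D")
    nd = len(dates)

    rng_p = _rng(config.seed, 1)
    wet = rng_p.random(nd) < config.precip_wet_prob
    amounts = rng_p.gamma(0.7, config.precip_mean_wet_mm / 0.7, size=nd)
    precip = pd.Series(np.where(wet, amounts, 0.0), index=dates, name="precip_mm")

    hours = pd.date_range(start, end + pd.Timedelta(hours=23), freq="h")
    doy_h = hours.dayofyear.to_numpy() + hours.hour.to_numpy() / 24.0
    hourly = {}
    daily = {}
    rng_t = _rng(config.seed, 2)
    for site in config.sites:
        base = (site.temp_mean_c
                + site.temp_amp_annual_c * np.sin(2 * np.pi * (doy_h - 110) / 365.0)
                + site.temp_amp_diurnal_c * np.sin(2 * np.pi * (hours.hour.to_numpy() - 10) / 24.0))
        e = np.zeros(nd)
        z = rng_t.standard_normal(nd)
        for i in range(1, nd):
            e[i] = site.temp_ar1_rho * e[i - 1] + site.temp_noise_sd_c * np.sqrt(
                1 - site.temp_ar1_rho**2) * z[i]
        day_idx = (hours.normalize() - start).days.to_numpy()
        ts = base + e[day_idx]
        lo, hi = config.ts5_bounds
        ts = np.clip(ts, lo, hi)
        hourly[site.name] = ts
        daily[site.name] = pd.Series(ts, index=hours).resample("D").median()

    rng_w = _rng(config.seed, 3)
    site_wl = {}
    for site in config.sites:
        w = np.empty(nd)
        w_prev = site.wl_init_m
        decay = np.exp(-1.0 / site.wl_tau_days)
        for i in range(nd):
            w_prev = (site.wl_min_m + (w_prev - site.wl_min_m) * decay
                      + site.wl_response_m_per_mm * precip.iloc[i])
            w_prev = min(w_prev, site.wl_max_m)
            w[i] = w_prev
        site_wl[site.name] = w

    plots = CampaignConfig.plots(config)
    wl_cols = {}
    lo, hi = config.wl_bounds
    for _, p in plots.iterrows():
        noise = np.zeros(nd)
        if config.wl_noise_sd_m > 0:
            z = rng_w.standard_normal(nd)
            for i in range(1, nd):
                noise[i] = 0.9 * noise[i - 1] + config.wl_noise_sd_m * np.sqrt(1 - 0.81) * z[i]
        wl_cols[p["plot_id"]] = np.clip(
            site_wl[p["site"]] + p["wl_offset_m"] + noise, lo, hi)

    return Drivers(
        daily_ts5_df=pd.DataFrame(daily, index=dates),
        hourly_ts5_df=pd.DataFrame(hourly, index=hours),
        precip_mm=precip,
        wl_df=pd.DataFrame(wl_cols, index=dates),
        plots=plots,
    )


# ---------------------------------------------------------------------------
# true fluxes
# ---------------------------------------------------------------------------

def gen_true_fluxes(
    params_by_microform: dict[str, WLSTParams],
    drivers: Drivers,
) -> pd.DataFrame:
    """Forward-model true fluxes: (c + d*WL) * exp(b*TS5) per plot-day.

    Returns a long frame (plot_id, microform, site, date, true_flux) in
    mg CH4-C m-2 h-1, bit-reproducible from the stored params and drivers.
    """
    frames = []
    for _, p in drivers.plots.iterrows():
        mf = p["microform"]
        if mf not in params_by_microform:
            raise ValueError(f"no parameters for microform {mf!r}")
        prm = params_by_microform[mf]
        ts5 = drivers.daily_ts5_df[p["site"]]
        wl = drivers.wl_df[p["plot_id"]]
        flux = (prm.c + prm.d * wl.to_numpy()) * np.exp(prm.b * ts5.to_numpy())
        if not np.all(np.isfinite(flux)):
            bad = ts5.index[~np.isfinite(flux)][0]
            raise ValueError(f"non-finite true flux on {bad.date()}")
        frames.append(pd.DataFrame({
            "plot_id": p["plot_id"], "microform": mf, "site": p["site"],
            "date": ts5.index, "true_flux": flux,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# schedule and traces
# ---------------------------------------------------------------------------

def gen_schedule(config: CampaignConfig) -> pd.DataFrame:
    """Campaign dates and within-day closure times per plot.

    Campaigns are spaced ~4 weeks in November-February and ~3 weeks in
    March-October.  Each plot gets ``closures_per_type`` opaque and
    transparent closures spread over 06:00-18:00 (opaque round first,
    transparent ~45 min later, small per-plot stagger).
    """
    start, end = pd.Timestamp(config.start), pd.Timestamp(config.end)
    camp_dates = []
    d = start
    while d <= end:
        camp_dates.append(d)
        step = (config.winter_spacing_days if d.month in WINTER_MONTHS
                else config.veg_spacing_days)
        d = d + pd.Timedelta(days=step)
    plots = config.plots()
    rows = []
    for ci, cdate in enumerate(camp_dates):
        for pi, (_, p) in enumerate(plots.iterrows()):
            for k in range(config.closures_per_type):
                base = cdate + pd.Timedelta(hours=6, minutes=int(k * 180 + pi * 7))
                for ctype, off in (("opaque", 0), ("transparent", 45)):
                    rows.append({
                        "campaign": ci, "date": cdate,
                        "plot_id": p["plot_id"], "microform": p["microform"],
                        "site": p["site"],
                        "time": base + pd.Timedelta(minutes=off),
                        "chamber_type": ctype,
                    })
    return pd.DataFrame(rows)


def gen_trace(
    true_flux: float,
    geometry: ChamberGeometry,
    *,
    start: pd.Timestamp,
    chamber_type: str,
    plot_id: str = "plot",
    microform: str = "mf",
    air_temp_c: float = 10.0,
    par_umol: float = 800.0,
    ambient_ppm: float = 2.0,
    noise_ppb: float = 0.8,
    pressure_kpa: float = 101.325,
    duration_s: float = 150.0,
    dt_s: float = 1.0,
    artifacts: tuple[str, ...] = (),
    rng: np.random.Generator | None = None,
) -> Trace:
    """One chamber closure trace for a known true flux.

    The noiseless, artifact-free trace is exactly linear with the slope
    implied by ``true_flux`` and the chamber geometry, so the flux engine
    recovers the truth to numerical precision.  Injected artifacts
    ("ebullition", "dt_ramp", "par_swing", "morning") are recorded in
    ``meta['artifacts']`` as ground truth for QC tests.
    """
    if not (120.0 <= duration_s <= 180.0):
        raise ValueError("closure duration must be within 120-180 s")
    rng = rng or np.random.default_rng(0)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    vol = effective_volume(geometry)
    slope = flux_to_slope(true_flux, vol, geometry.base_area, air_temp_c, pressure_kpa)
    y = ambient_ppm + slope * t
    if noise_ppb > 0:
        y = y + rng.normal(0.0, noise_ppb * 1e-3, size=len(t))
    temp = np.full(len(t), air_temp_c)
    par = None
    if chamber_type == "transparent":
        par = np.full(len(t), par_umol)
        if noise_ppb > 0:
            par = par + rng.normal(0.0, 0.005 * par_umol, size=len(t))

    arts = tuple(artifacts)
    if "ebullition" in arts:
        j = int(rng.integers(len(t) // 4, 3 * len(t) // 4))
        y[j:] += 0.2
    if "dt_ramp" in arts:
        # strong chamber heating: steep enough that every QC window sees
        # more than the 1.5 degC screen
        temp = temp + np.linspace(0.0, 6.0, len(t))
    if "par_swing" in arts and par is not None:
        # cloud passage: continuous 50 % PAR decline spanning every window
        par = par * np.linspace(1.0, 0.5, len(t))
    if "morning" in arts:
        shift = max(0.0, 3.4 - ambient_ppm)
        y = y + shift

    return Trace(
        times_s=t, ch4_ppm=y, chamber_temp_c=temp, par=par,
        chamber_type=chamber_type, plot_id=plot_id, microform=microform,
        start=pd.Timestamp(start),
        meta={"true_flux": float(true_flux), "artifacts": list(arts),
              "air_temp_c": air_temp_c, "ambient_ppm": ambient_ppm},
    )


@dataclass
class SimulatedCampaign:
    """Bundle of everything a downstream stage needs, with ground truth."""

    config: CampaignConfig
    drivers: Drivers
    schedule: pd.DataFrame
    traces: list
    truth: pd.DataFrame             # one row per closure, with true_flux + artifacts
    geometries: dict[str, ChamberGeometry]
    true_daily: pd.DataFrame        # per plot-day forward-model fluxes


def simulate_campaign(config: CampaignConfig | None = None,
                      seed: int | None = None) -> SimulatedCampaign:
    """Generate drivers, schedule, geometries and all closure traces."""
    if config is None:
        config = default_config(seed if seed is not None else 0)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    drivers = gen_drivers(config)
    schedule = gen_schedule(config)
    true_daily = gen_true_fluxes(config.true_params(), drivers)
    true_map = true_daily.set_index(["plot_id", "date"])["true_flux"]

    rng_g = _rng(config.seed, 4)
    geometries = {}
    for _, p in drivers.plots.iterrows():
        shift = -0.05 if p["microform"].endswith("hum") else 0.05
        offsets = tuple(np.round(shift + rng_g.normal(0, 0.02, size=20), 4))
        geometries[p["plot_id"]] = ChamberGeometry(surface_offsets=offsets)

    rng_a = _rng(config.seed, 5)
    rng_n = _rng(config.seed, 6)
    traces, truth_rows = [], []

    morning_days = {}
    for (cdate, plot), _ in schedule.groupby(["date", "plot_id"]):
        morning_days[(cdate, plot)] = rng_a.random() < config.p_morning

    for _, row in schedule.sort_values(["date", "plot_id", "time"]).iterrows():
        plot, site, mf = row["plot_id"], row["site"], row["microform"]
        tf = float(true_map.loc[(plot, row["date"])])
        hour = row["time"].hour
        air = drivers.hourly_ts5_df.loc[
            row["time"].floor("h"), site] + 3.0
        par = max(50.0, 1200.0 * np.sin(np.pi * (hour - 5) / 14))
        arts = []
        is_first = morning_days.get((row["date"], plot), False) and hour < 8 and (
            row["time"] == schedule[(schedule["date"] == row["date"])
                                    & (schedule["plot_id"] == plot)]["time"].min())
        if is_first:
            arts.append("morning")
            tf = tf * 3.0 + 1.0      # stable-morning enrichment inflates the flux
        else:
            if rng_a.random() < config.p_ebullition:
                arts.append("ebullition")
            if rng_a.random() < config.p_dt_ramp:
                arts.append("dt_ramp")
            if row["chamber_type"] == "transparent" and rng_a.random() < config.p_par_swing:
                arts.append("par_swing")
        tr = gen_trace(
            tf, geometries[plot], start=row["time"],
            chamber_type=row["chamber_type"], plot_id=plot, microform=mf,
            air_temp_c=float(air), par_umol=par,
            ambient_ppm=config.ambient_ch4_ppm, noise_ppb=config.noise_ppb,
            pressure_kpa=config.pressure_kpa, duration_s=config.closure_s,
            dt_s=config.sample_dt_s, artifacts=tuple(arts), rng=rng_n,
        )
        tr.meta["campaign"] = int(row["campaign"])
        traces.append(tr)
        truth_rows.append({
            "plot_id": plot, "microform": mf, "site": site,
            "campaign": int(row["campaign"]), "start": row["time"],
            "chamber_type": row["chamber_type"], "true_flux": tf,
            "artifacts": ";".join(arts),
        })
    return SimulatedCampaign(config=config, drivers=drivers, schedule=schedule,
                             traces=traces, truth=pd.DataFrame(truth_rows),
                             geometries=geometries, true_daily=true_daily)


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def gen_transects(
    layout_truth: dict[str, float],
    n_transects: int = 5,
    length_cm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Per-cm categorical transect sequences drawn from true areal fractions."""
    labels = list(layout_truth)
    fracs = np.array([layout_truth[k] for k in labels], dtype=float)
    if np.any(fracs < 0) or np.any(fracs > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [np.array(labels, dtype=object)[rng.choice(len(labels), size=length_cm, p=fracs)]
            for _ in range(n_transects)]
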