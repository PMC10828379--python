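"""Closed-chamber CH4 flux computation with moving-window regression QC.

A closure trace (CH4 mole fraction vs. time inside a static chamber) is
reduced to a single flux by ordinary least squares on the best sub-window
of the trace.  Window length follows solar declination (40 s in summer,
60 s in winter), windows are screened for chamber heating, PAR swings and
poor linearity, and every retained flux is compared against the minimum
detectable flux implied by the analyzer precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

R_GAS = 8.314462618          # J mol-1 K-1
MOLAR_MASS_C = 12.011        # g mol-1, fluxes are reported on a CH4-C basis
EARTH_OBLIQUITY_DEG = 23.44

SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxQCConfig:
    """Thresholds of the flux QC chain.

    All stage code reads thresholds from here; none are hard-coded in the
    algorithm itself.
    """

    r2_min: float = 0.8                # linearity screen
    dt_max_c: float = 1.5              # max chamber temperature change per window, degC
    par_max_frac: float = 0.10         # max relative PAR change per window (transparent)
    low_increase_frac: float = 0.03    # CH4 increase below this fraction of the
                                       # window mean waives the R2 screen
    trim_frac: float = 0.10            # leading fraction of samples discarded
    window_min_s: int = 40             # summer window
    window_max_s: int = 60             # winter window
    duration_bounds_s: tuple[float, float] = (60.0, 600.0)
    min_samples: int = 30
    precision_ppb: float = 0.8         # analyzer precision used for the MDF
    mdf_coverage_k: float = 1.96
    jump_sigma: float = 6.0            # ebullition screen: jump > k * noise SD
    jump_floor_ppm: float = 0.02       # ...but never below this absolute step
    pressure_kpa: float = 101.325
    par_absorption: float = 0.05       # chamber material absorbs 5 % of ambient PAR
    morning_hour: int = 8              # local time threshold of the morning filter
    morning_start_ppm: float = 3.0


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber box geometry with the surface-height correction.

    ``surface_offsets`` are frame-to-ground distances (m, up to 20 points per
    plot); their mean corrects the nominal chamber height.  ``displaced_volume``
    removes flood water or snow standing inside the frame.
    """

    base_area: float = 0.49 * 0.49      # m2
    nominal_height: float = 0.64        # m
    surface_offsets: tuple[float, ...] = (0.0,)
    displaced_volume: float = 0.0       # m3

    def __post_init__(self) -> None:
        if self.base_area <= 0:
            raise ValueError("base_area must be positive")
        if self.displaced_volume < 0:
            raise ValueError("displaced_volume must be >= 0")
        if len(self.surface_offsets) < 1:
            raise ValueError("at least one surface offset is required")


@dataclass
class Trace:
    """One chamber closure: concentration time series plus metadata."""

    times_s: np.ndarray              # seconds since closure start, strictly increasing
    ch4_ppm: np.ndarray              # dry mole fraction
    chamber_temp_c: np.ndarray
    par: np.ndarray | None           # umol m-2 s-1, transparent chambers only
    chamber_type: str                # "opaque" | "transparent"
    plot_id: str
    microform: str
    start: pd.Timestamp
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        self.chamber_temp_c = np.asarray(self.chamber_temp_c, dtype=float)
        if self.par is not None:
            self.par = np.asarray(self.par, dtype=float)
        if self.chamber_type not in ("opaque", "transparent"):
            raise ValueError(f"unknown chamber_type {self.chamber_type!r}")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass
class FluxRecord:
    """One QC'd flux with its window diagnostics."""

    plot_id: str
    microform: str
    chamber_type: str
    start: pd.Timestamp
    valid: bool
    reason: str | None = None        # machine-readable rejection reason
    flux: float = np.nan             # mg CH4-C m-2 h-1
    slope: float = np.nan            # ppm s-1
    r2: float = np.nan
    win_start_s: float = np.nan
    win_end_s: float = np.nan
    window_s: int = 0
    mdf: float = np.nan
    below_mdf: bool = False
    start_ppm: float = np.nan
    n_samples: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def records_to_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in records])
    if not df.empty:
        df["start"] = pd.to_datetime(df["start"])
    return df


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def solar_declination(date) -> float:
    """Solar declination (degrees) via the standard cosine approximation."""
    doy = pd.Timestamp(date).dayofyear
    return -EARTH_OBLIQUITY_DEG * math.cos(2.0 * math.pi * (doy + 10) / 365.0)


def window_length(date, qc: FluxQCConfig = FluxQCConfig()) -> int:
    """Regression window length in seconds for a calendar day.

    Linear in solar declination: 40 s at the summer solstice, 60 s at the
    winter solstice, 50 s at the equinoxes.
    """
    delta = solar_declination(date)
    half = 0.5 * (qc.window_min_s + qc.window_max_s)
    span = 0.5 * (qc.window_max_s - qc.window_min_s)
    w = int(round(half - span * delta / EARTH_OBLIQUITY_DEG))
    return int(np.clip(w, qc.window_min_s, qc.window_max_s))


def effective_volume(geometry: ChamberGeometry) -> float:
    """Chamber volume corrected for surface height and displaced water/snow."""
    v = geometry.base_area * (
        geometry.nominal_height + float(np.mean(geometry.surface_offsets))
    ) - geometry.displaced_volume
    if v <= 0:
        raise ValueError(f"effective chamber volume is non-positive ({v:.4g} m3)")
    return v


def slope_to_flux(
    slope_ppm_s: float,
    volume_m3: float,
    area_m2: float,
    air_temp_c: float,
    pressure_kpa: float = 101.325,
) -> float:
    """Convert a concentration slope to a CH4-C mass flux.

    Ideal-gas conversion at the measured chamber air temperature:
    mol air in the chamber n = pV/RT, so a slope in ppm s-1 corresponds to
    slope*1e-6*n mol CH4 s-1, reported as mg CH4-C m-2 h-1.
    """
    if not np.all(np.isfinite([slope_ppm_s, volume_m3, area_m2, air_temp_c, pressure_kpa])):
        raise ValueError("non-finite input to slope_to_flux")
    if volume_m3 <= 0 or area_m2 <= 0:
        raise ValueError("volume and area must be positive")
    if air_temp_c <= -50.0:
        raise ValueError("implausible air temperature")
    t_k = air_temp_c + 273.15
    n_mol = (pressure_kpa * 1000.0) * volume_m3 / (R_GAS * t_k)
    mol_ch4_per_s = slope_ppm_s * 1e-6 * n_mol
    return mol_ch4_per_s * MOLAR_MASS_C * 3600.0 * 1000.0 / area_m2


def flux_to_slope(
    flux_mg_m2_h: float,
    volume_m3: float,
    area_m2: float,
    air_temp_c: float,
    pressure_kpa: float = 101.325,
) -> float:
    """Inverse of :func:`slope_to_flux` (used by the trace generator)."""
    unit = slope_to_flux(1.0, volume_m3, area_m2, air_temp_c, pressure_kpa)
    return flux_mg_m2_h / unit


def minimum_detectable_flux(
    n_window: int,
    dt_s: float,
    volume_m3: float,
    area_m2: float,
    air_temp_c: float,
    pressure_kpa: float = 101.325,
    precision_ppb: float = 0.8,
    coverage_k: float = 1.96,
) -> float:
    """Smallest flux distinguishable from analyzer noise over one window.

    The OLS slope standard error under i.i.d. Gaussian noise of SD sigma on a
    regular grid of n points with spacing dt is sigma*sqrt(12/(n*(n^2-1)))/dt;
    the MDF is the flux equivalent of ``coverage_k`` times that slope.
    Fluxes below the MDF are flagged, never removed.
    """
    if n_window < 3:
        raise ValueError("window must contain at least 3 samples")
    if dt_s <= 0:
        raise ValueError("sample interval must be positive")
    sigma_ppm = precision_ppb * 1e-3
    s_min = coverage_k * sigma_ppm * math.sqrt(12.0 / (n_window * (n_window**2 - 1.0))) / dt_s
    return abs(slope_to_flux(s_min, volume_m3, area_m2, air_temp_c, pressure_kpa))


# ---------------------------------------------------------------------------
# the flux computation
# ---------------------------------------------------------------------------

def _window_stats(y: np.ndarray, x: np.ndarray, m: int, step: int):
    """Slope and R2 for every window of m samples, strided by ``step``."""
    from numpy.lib.stride_tricks import sliding_window_view

    yw = sliding_window_view(y, m)[::step]
    xw = sliding_window_view(x, m)[::step]
    xm = xw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((xw - xm) ** 2).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    sxy = ((xw - xm) * (yw - ym)).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    return slope, r2, yw, xw


def _invalid(trace: Trace, reason: str, window_s: int = 0) -> FluxRecord:
    return FluxRecord(
        plot_id=trace.plot_id, microform=trace.microform,
        chamber_type=trace.chamber_type, start=trace.start,
        valid=False, reason=reason, window_s=window_s,
        start_ppm=float(trace.ch4_ppm[0]), n_samples=len(trace.ch4_ppm),
    )


def compute_flux(
    trace: Trace,
    geometry: ChamberGeometry,
    qc: FluxQCConfig = FluxQCConfig(),
) -> FluxRecord:
    """Reduce one closure trace to a QC'd flux.

    Algorithm: (1) drop the leading ``trim_frac`` of samples (chamber
    placement artifacts); (2) flag step discontinuities (ebullition) from the
    first-difference distribution; (3) slide a window of
    ``window_length(date)`` seconds in 1-s steps; (4) per window compute the
    OLS slope, R2, chamber temperature change and relative PAR change;
    (5) discard windows with dT > 1.5 degC or PAR change > 10 % (transparent
    only); (6) of the survivors require R2 >= 0.8 unless the CH4 increase over
    the window is below 3 % of its mean concentration; (7) take the max-R2
    window (ties -> earliest) and convert its slope to a mass flux.
    """
    n = len(trace.ch4_ppm)
    if n < qc.min_samples:
        return _invalid(trace, "too_few_samples")
    if not np.all(np.diff(trace.times_s) > 0):
        return _invalid(trace, "non_monotone_time")
    lo, hi = qc.duration_bounds_s
    if not (lo <= trace.duration_s <= hi):
        return _invalid(trace, "duration_out_of_bounds")

    w_s = window_length(trace.start, qc)

    # ebullition screen: one-sample jump far outside the noise of the diffs
    d = np.diff(trace.ch4_ppm)
    resid = d - np.median(d)
    sigma_d = 1.4826 * np.median(np.abs(resid))
    thresh = max(qc.jump_sigma * sigma_d, qc.jump_floor_ppm)
    if np.max(np.abs(resid)) > thresh:
        return _invalid(trace, "ebullition", w_s)

    k = int(math.floor(qc.trim_frac * n))
    t = trace.times_s[k:]
    y = trace.ch4_ppm[k:]
    temp = trace.chamber_temp_c[k:]
    par = trace.par[k:] if trace.par is not None else None

    dt = float(np.median(np.diff(t)))
    m = int(round(w_s / dt)) + 1
    if m > len(y) or m < 3:
        return _invalid(trace, "too_short_after_trim", w_s)
    step = max(1, int(round(1.0 / dt)))

    slope, r2, yw, _ = _window_stats(y, t, m, step)
    from numpy.lib.stride_tricks import sliding_window_view

    tw = sliding_window_view(temp, m)[::step]
    d_temp = tw.max(axis=1) - tw.min(axis=1)
    pass_t = d_temp <= qc.dt_max_c

    if trace.chamber_type == "transparent" and par is not None:
        pw = sliding_window_view(par, m)[::step]
        pmean = pw.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_chg = np.where(pmean > 0, (pw.max(axis=1) - pw.min(axis=1)) / pmean, 0.0)
        pass_p = p_chg <= qc.par_max_frac
    else:
        pass_p = np.ones_like(pass_t, dtype=bool)

    increase = np.abs(yw[:, -1] - yw[:, 0])
    low_inc = increase < qc.low_increase_frac * yw.mean(axis=1)
    pass_r2 = (r2 >= qc.r2_min) | low_inc

    ok = pass_t & pass_p & pass_r2
    if not ok.any():
        fails = {
            "temperature_change": int((~pass_t).sum()),
            "par_change": int((~pass_p).sum()),
            "r2": int((~pass_r2).sum()),
        }
        reason = max(fails, key=lambda kk: (fails[kk],
                     ["r2", "par_change", "temperature_change"].index(kk)))
        return _invalid(trace, reason, w_s)

    r2_masked = np.where(ok, r2, -np.inf)
    best = int(np.argmax(r2_masked))          # argmax takes the earliest tie
    i0 = best * step
    win_t = temp[i0:i0 + m]
    vol = effective_volume(geometry)
    flux = slope_to_flux(float(slope[best]), vol, geometry.base_area,
                         float(win_t.mean()), qc.pressure_kpa)
    mdf = minimum_detectable_flux(m, dt, vol, geometry.base_area,
                                  float(win_t.mean()), qc.pressure_kpa,
                                  qc.precision_ppb, qc.mdf_coverage_k)
    return FluxRecord(
        plot_id=trace.plot_id, microform=trace.microform,
        chamber_type=trace.chamber_type, start=trace.start,
        valid=True, flux=flux, slope=float(slope[best]), r2=float(r2[best]),
        win_start_s=float(t[i0]), win_end_s=float(t[i0 + m - 1]), window_s=w_s,
        mdf=mdf, below_mdf=bool(abs(flux) < mdf),
        start_ppm=float(trace.ch4_ppm[0]), n_samples=n,
    )


def compute_fluxes(
    traces: Iterable[Trace],
    geometries: dict[str, ChamberGeometry] | ChamberGeometry,
    qc: FluxQCConfig = FluxQCConfig(),
) -> pd.DataFrame:
    """Vector version of :func:`compute_flux` over many closures."""
    records = []
    for tr in traces:
        geom = geometries[tr.plot_id] if isinstance(geometries, dict) else geometries
        records.append(compute_flux(tr, geom, qc))
    return records_to_frame(records)


# ---------------------------------------------------------------------------
# dataset-level screens and statistics
# ---------------------------------------------------------------------------

def morning_filter(fluxes: pd.DataFrame, qc: FluxQCConfig = FluxQCConfig()) -> pd.Series:
    """Flag stable-morning enrichment artifacts for removal.

    A flux is flagged iff ALL of: its closure started above 3 ppm CH4, it is
    the highest flux of its plot that day, and it is the plot's first
    measurement of the day, before 08:00 local time.  Returns a boolean
    Series aligned with ``fluxes`` (True = remove).
    """
    flag = pd.Series(False, index=fluxes.index)
    valid = fluxes[fluxes["valid"]] if "valid" in fluxes else fluxes
    start = pd.to_datetime(valid["start"])
    for (_, _), grp in valid.groupby([valid["plot_id"], start.dt.date]):
        g_start = pd.to_datetime(grp["start"])
        first_idx = g_start.idxmin()
        row = grp.loc[first_idx]
        t = g_start.loc[first_idx]
        if (
            row["start_ppm"] > qc.morning_start_ppm
            and row["flux"] == grp["flux"].max()
            and t.hour < qc.morning_hour
        ):
            flag.loc[first_idx] = True
    return flag


def pair_chamber_types(fluxes: pd.DataFrame, max_gap_min: float = 60.0) -> pd.DataFrame:
    """Pair each transparent flux with the nearest opaque flux on its plot.

    Greedy nearest-in-time within +/- ``max_gap_min`` minutes; each opaque
    record is used at most once; ties broken toward the earlier opaque record.
    Unpaired transparent records are kept with NaN opaque columns.
    """
    out = []
    df = fluxes[fluxes.get("valid", True) == True]  # noqa: E712
    for plot, grp in df.groupby("plot_id"):
        trans = grp[grp["chamber_type"] == "transparent"].sort_values("start")
        opaque = grp[grp["chamber_type"] == "opaque"].sort_values("start")
        used: set = set()
        for ti, trow in trans.iterrows():
            tt = pd.Timestamp(trow["start"])
            best_idx, best_gap = None, None
            for oi, orow in opaque.iterrows():
                if oi in used:
                    continue
                gap = abs((pd.Timestamp(orow["start"]) - tt).total_seconds()) / 60.0
                if gap > max_gap_min:
                    continue
                if best_gap is None or gap < best_gap:
                    best_idx, best_gap = oi, gap
            rec = {
                "plot_id": plot,
                "transparent_idx": ti,
                "transparent_start": tt,
                "transparent_flux": trow["flux"],
            }
            if best_idx is not None:
                used.add(best_idx)
                rec.update(
                    opaque_idx=best_idx,
                    opaque_start=pd.Timestamp(opaque.loc[best_idx, "start"]),
                    opaque_flux=opaque.loc[best_idx, "flux"],
                    gap_min=best_gap,
                )
            else:
                rec.update(opaque_idx=np.nan, opaque_start=pd.NaT,
                           opaque_flux=np.nan, gap_min=np.nan)
            out.append(rec)
    return pd.DataFrame(out)


def season_of(when) -> str:
    return SEASON_BY_MONTH[pd.Timestamp(when).month]


def mann_whitney_suite(
    fluxes: pd.DataFrame,
    group_col: str,
    flux_col: str = "flux",
    time_col: str = "start",
    min_n: int = 3,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests per (group pair x season).

    Groups with fewer than ``min_n`` records in a season are skipped with a
    note.  Seasons follow the meteorological month convention (DJF winter,
    MAM spring, JJA summer, SON autumn).
    """
    df = fluxes[fluxes.get("valid", True) == True].copy()  # noqa: E712
    if df.empty or df[group_col].nunique() < 2:
        raise ValueError("need at least two non-empty groups")
    df["season"] = pd.to_datetime(df[time_col]).map(season_of)
    groups = sorted(df[group_col].dropna().unique())
    rows = []
    for season, sgrp in df.groupby("season"):
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = sgrp.loc[sgrp[group_col] == ga, flux_col].dropna()
                b = sgrp.loc[sgrp[group_col] == gb, flux_col].dropna()
                row = {"season": season, "group_a": ga, "group_b": gb,
                       "n_a": len(a), "n_b": len(b)}
                if len(a) < min_n or len(b) < min_n:
                    row.update(u=np.nan, p=np.nan, note="skipped: n < 3")
                else:
                    res = sps.mannwhitneyu(a, b, alternative="two-sided")
                    row.update(u=float(res.statistic), p=float(res.pvalue), note="")
                rows.append(row)
    return pd.DataFrame(rows)
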