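"""Annual CH4 balances: per-microform sums, bootstrap uncertainty, areal
upscaling to the site, tree-branch contribution and CO2-equivalent output.

Per-microform annual balances are daily model predictions summed over the
balance year.  Their uncertainty comes from refitting on medians resampled
with replacement (nonlinear methods) or from the jackknife x bootstrap
ensemble (linear interpolation).  Site totals weight microform balances by
transect-derived areal fractions, with Gaussian error propagation combining
both uncertainty sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    FluxFitResults,
    LinearEnsemble,
    LloydTaylorModel,
    WLSTModel,
    fit_lloyd_taylor,
    fit_wlst,
    linear_interp_ensemble,
)

MASS_RATIO_CH4_C = 16.0 / 12.0      # CH4 mass per CH4-C mass


@dataclass
class MicroformLayout:
    """Areal fractions per microform with their SD across transects."""

    fractions: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    n_transects: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")

    def frac_se(self, label: str) -> float:
        """Default uncertainty of a fraction: SD across transects / sqrt(n)."""
        sd = self.sds.get(label, 0.0)
        return sd / np.sqrt(self.n_transects) if self.n_transects > 0 else sd


@dataclass
class AnnualBalance:
    """One annual sum with its standard error."""

    label: str
    balance: float           # g CH4-C m-2 yr-1
    se: float
    method: str
    period: tuple = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be >= 0")


# ---------------------------------------------------------------------------
# sums and bootstrap uncertainty
# ---------------------------------------------------------------------------

def annual_sum(daily: pd.DataFrame, period: tuple | None = None) -> float:
    """Sum a gap-free daily series (g CH4-C m-2 d-1) over the period."""
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    if period is None:
        period = (dates.min(), dates.max())
    expected = pd.date_range(period[0], period[1], freq="D")
    missing = expected.difference(pd.DatetimeIndex(dates))
    if len(missing):
        shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:5])
        raise ValueError(f"daily series has gaps ({len(missing)} days, e.g. {shown})")
    mask = dates.isin(expected)
    return float(daily.loc[mask.to_numpy(), "flux_g_m2_d"].sum())


def _fit_and_sum(method: str, medians: pd.DataFrame, ts5_daily: pd.Series,
                 wl_daily: pd.Series | None, start=None) -> tuple[float, FluxFitResults] | None:
    if method == "wlst":
        model = WLSTModel.from_medians(medians)
    elif method == "lloyd_taylor":
        model = LloydTaylorModel.from_medians(medians)
    else:
        raise ValueError("method must be 'wlst' or 'lloyd_taylor'")
    from .validation import _warm_fit

    res = _warm_fit(model, start)
    if not res.converged:
        return None
    daily = res.predict_daily(ts5_daily, wl_daily if method == "wlst" else None)
    return annual_sum(daily), res


def bootstrap_balance_se(
    medians: pd.DataFrame,
    method: str,
    ts5_daily: pd.Series,
    wl_daily: pd.Series | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    label: str = "",
    max_fail_frac: float = 0.2,
) -> AnnualBalance:
    """Annual balance from the full fit; SE from bootstrap refits.

    Medians are resampled with replacement, the model refit (started at the
    full-data solution) and the daily prediction re-summed; the SE is the
    standard deviation of the replicate annual sums.  Failed refits are
    skipped and counted; more than ``max_fail_frac`` of them raise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = _fit_and_sum(method, medians, ts5_daily, wl_daily)
    if full is None:
        raise RuntimeError(f"full-data {method} fit did not converge")
    balance, full_fit = full
    start = full_fit.params.to_numpy()
    n = len(medians)
    sums = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = medians.iloc[idx].reset_index(drop=True)
        try:
            out = _fit_and_sum(method, boot, ts5_daily, wl_daily, start=start)
        except Exception:
            out = None
        if out is None or not np.isfinite(out[0]):
            n_failed += 1
            continue
        sums.append(out[0])
    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
    se = float(np.std(np.asarray(sums), ddof=1)) if len(sums) > 1 else np.nan
    period = (pd.Timestamp(ts5_daily.index.min()), pd.Timestamp(ts5_daily.index.max()))
    return AnnualBalance(label=label, balance=balance, se=se, method=method,
                         period=period,
                         extras={"n_boot": n_boot, "n_failed": n_failed,
                                 "fit": full_fit})


def linear_balance(ensemble: LinearEnsemble, label: str = "") -> AnnualBalance:
    """Balance and SE of the jackknife x bootstrap linear interpolation.

    The balance is the median over all jackknife-replicate annual sums; the
    SE is the standard deviation over bootstrap replicates (each replicate
    summarised by the mean of its jackknife sums).
    """
    if ensemble.sums.size == 0:
        raise ValueError("empty ensemble")
    balance = float(np.median(ensemble.sums))
    per_rep = ensemble.sums.mean(axis=1)
    se = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0
    return AnnualBalance(label=label, balance=balance, se=se, method="linear",
                         period=ensemble.period,
                         extras={"n_boot": ensemble.n_boot})


# ---------------------------------------------------------------------------
# areal fractions and site upscaling
# ---------------------------------------------------------------------------

def areal_fractions(transects: list[np.ndarray],
                    known_labels: set | None = None) -> MicroformLayout:
    """Microform areal fractions from per-cm transect surveys.

    The fraction is the pooled per-cm share over all transects; its SD is
    the standard deviation of the per-transect fractions.
    """
    if len(transects) < 2:
        raise ValueError("need at least 2 transects")
    labels = sorted({str(x) for tr in transects for x in tr})
    if known_labels is not None:
        unknown = set(labels) - set(known_labels)
        if unknown:
            raise ValueError(f"unknown category labels: {sorted(unknown)}")
    total = sum(len(tr) for tr in transects)
    fractions, sds = {}, {}
    for lab in labels:
        per = np.array([np.mean(np.asarray(tr, dtype=object) == lab) for tr in transects])
        fractions[lab] = sum(int(np.sum(np.asarray(tr, dtype=object) == lab))
                             for tr in transects) / total
        sds[lab] = float(np.std(per, ddof=1))
    return MicroformLayout(fractions=fractions, sds=sds, n_transects=len(transects))


def upscale_site(
    balances: dict[str, AnnualBalance],
    layout: MicroformLayout,
    frac_se: dict[str, float] | None = None,
    label: str = "site",
) -> AnnualBalance:
    """Areal-weighted site balance with Gaussian error propagation.

    site = sum_i a_i * F_i;
    SE = sqrt(sum_i (a_i * SE_Fi)^2 + (F_i * SE_ai)^2).
    ``frac_se`` overrides the default per-fraction uncertainty
    (SD across transects / sqrt(n_transects)).
    """
    missing = set(balances) - set(layout.fractions)
    if missing:
        raise ValueError(f"layout lacks fractions for: {sorted(missing)}")
    total = 0.0
    var = 0.0
    contributions = {}
    for lab, bal in balances.items():
        a = layout.fractions[lab]
        sa = frac_se[lab] if frac_se is not None else layout.frac_se(lab)
        contrib = a * bal.balance
        total += contrib
        var += (a * bal.se) ** 2 + (bal.balance * sa) ** 2
        contributions[lab] = contrib
    shares = {lab: (c / total if total != 0 else np.nan)
              for lab, c in contributions.items()}
    return AnnualBalance(label=label, balance=total, se=float(np.sqrt(var)),
                         method="upscaled",
                         extras={"contributions": contributions, "shares": shares})


def weighted_site_wl(layout: MicroformLayout, mean_wl: dict[str, float]) -> float:
    """Areal-weighted mean water level of a site, m."""
    missing = set(mean_wl) - set(layout.fractions)
    if missing:
        raise ValueError(f"layout lacks fractions for: {sorted(missing)}")
    return float(sum(layout.fractions[lab] * wl for lab, wl in mean_wl.items()))


def co2_equivalents(balance_g_c_m2: float, gwp: float = 28.0,
                    mass_ratio: float = MASS_RATIO_CH4_C) -> float:
    """Convert g CH4-C m-2 yr-1 to t CO2-eq ha-1 yr-1.

    CH4-C mass -> CH4 mass (x16/12) -> CO2-equivalent mass (x GWP), then
    g m-2 -> t ha-1 (x 1e4 / 1e6).
    """
    if gwp <= 0:
        raise ValueError("gwp must be positive")
    return balance_g_c_m2 * mass_ratio * gwp * 1e4 / 1e6


# ---------------------------------------------------------------------------
# vegetation terms
# ---------------------------------------------------------------------------

def eriophorum_lai(
    blade_counts: list[float],
    mean_heights_m: list[float],
    area_per_length_m2_cm: float,
    section_shares: list[float],
    frame_area_m2: float = 0.05 * 0.05,
) -> float:
    """Plot LAI of Eriophorum from blade counts in small frames.

    Per section: blade density (count / frame area) times mean green-blade
    height times the leaf area per unit blade length; the plot LAI is the
    section-share-weighted sum.
    """
    counts = np.asarray(blade_counts, dtype=float)
    heights = np.asarray(mean_heights_m, dtype=float)
    shares = np.asarray(section_shares, dtype=float)
    if np.any(counts < 0) or np.any(heights < 0) or np.any(shares < 0) \
            or area_per_length_m2_cm < 0 or frame_area_m2 <= 0:
        raise ValueError("negative inputs are not allowed")
    density = counts / frame_area_m2                       # blades m-2
    per_blade = heights * 100.0 * area_per_length_m2_cm    # m2 leaf per blade
    return float(np.sum(shares * density * per_blade))


def tree_contribution(
    branch_medians: pd.DataFrame,
    lai_series: pd.Series,
    period: tuple | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> AnnualBalance:
    """Annual ground-area balance of tree branch fluxes.

    Leaf-area branch fluxes (mg CH4-C m-2 leaf h-1, campaign medians) are
    multiplied by the tree LAI at each campaign date to give ground-area
    fluxes, then run through the jackknife x bootstrap linear-interpolation
    machinery.
    """
    if (lai_series < 0).any():
        raise ValueError("LAI must be >= 0")
    med = branch_medians.copy()
    lai = pd.Series(lai_series).copy()
    lai.index = pd.to_datetime(lai.index)
    dates = pd.to_datetime(med["date"])
    x = (lai.index - pd.Timestamp("2000-01-01")).days.to_numpy(float)
    xt = (dates - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
    med["flux"] = med["flux"].to_numpy() * np.interp(xt, x, lai.to_numpy())
    ens = linear_interp_ensemble(med, period=period, n_boot=n_boot, seed=seed)
    return linear_balance(ens, label="tree_branch")
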