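"""Gap-filling models for campaign-median CH4 fluxes.

Chamber fluxes are aggregated to one median per plot and campaign; those
medians drive three interpolation methods used to build gap-free daily flux
series over a balance year:

* an exponential-in-inverse-temperature respiration model
  (``LloydTaylorModel``): CH4 = R_ref * exp(e0 * (1/(T_ref - T0) - 1/(T - T0)))
  with T in kelvin, T0 = 227.13 K and T_ref = 283.15 K;
* a water-level + soil-temperature model (``WLSTModel``):
  CH4 = (c + d*WL) * exp(b*TS5) with TS5 in degC and WL in metres
  (negative below surface);
* a jackknife/bootstrap linear interpolation ensemble
  (:func:`linear_interp_ensemble`).

Both model classes follow the Model -> fit() -> Results pattern: the Results
object carries parameter estimates, standard errors, RSS/AIC, a summary
table, point prediction and daily prediction over driver series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

T_REF_K = 283.15
T0_K = 227.13


@dataclass(frozen=True)
class LloydTaylorParams:
    """Fitted coefficients: rate at the reference temperature and sensitivity."""
    r_ref: float   # mg CH4-C m-2 h-1
    e0: float      # K


@dataclass(frozen=True)
class WLSTParams:
    """Fitted coefficients of the water-level + soil-temperature model."""
    b: float       # per degC
    c: float       # mg CH4-C m-2 h-1
    d: float       # mg CH4-C m-2 h-1 per m of water level


# ---------------------------------------------------------------------------
# campaign medians
# ---------------------------------------------------------------------------

def campaign_medians(
    fluxes: pd.DataFrame,
    drivers,
    schedule: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One median (flux, TS5, WL) triple per plot and campaign.

    Opaque and transparent fluxes are pooled.  ``fluxes`` must carry a
    ``campaign`` column (merged from the schedule if given).  TS5 is the
    site's daily median soil temperature on the campaign date; WL the plot's
    interpolated water level that day.  Plot-campaigns without a valid flux
    are omitted.
    """
    df = fluxes.copy()
    if "campaign" not in df.columns:
        if schedule is None:
            raise ValueError("fluxes lack a 'campaign' column and no schedule given")
        key = schedule[["plot_id", "time", "campaign"]].rename(columns={"time": "start"})
        df = df.merge(key, on=["plot_id", "start"], how="left")
    df = df[df["valid"]]
    rows = []
    for (plot, camp), grp in df.groupby(["plot_id", "campaign"]):
        date = pd.Timestamp(pd.to_datetime(grp["start"]).dt.date.min())
        site = grp["microform"].iloc[0].split("_")[0]
        rows.append({
            "plot_id": plot,
            "microform": grp["microform"].iloc[0],
            "site": site,
            "campaign": camp,
            "date": date,
            "flux": float(grp["flux"].median()),
            "ts5_c": drivers.daily_ts5(site, date),
            "wl_m": drivers.plot_wl(plot, date),
            "n_fluxes": len(grp),
        })
    return pd.DataFrame(rows).sort_values(["campaign", "plot_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# results object shared by both nonlinear models
# ---------------------------------------------------------------------------

@dataclass
class FluxFitResults:
    """Nonlinear least-squares fit of a flux gap-filling model."""

    model: object
    params: pd.Series
    rss: float
    n: int
    converged: bool
    cov: np.ndarray | None = None
    n_starts_tried: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        # error variance counts as a parameter in the AIC
        return len(self.params) + 1

    @property
    def bse(self) -> pd.Series:
        if self.cov is None:
            return pd.Series(np.nan, index=self.params.index)
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def aic(self) -> float:
        """Gaussian RSS-based AIC; only differences between fits on the same
        data are meaningful."""
        if self.rss <= 0:
            return -np.inf
        return self.n * math.log(self.rss / self.n) + 2 * self.k

    def predict(self, *args, **kwargs):
        return self.model.predict(self.params, *args, **kwargs)

    def predict_daily(self, ts5_daily: pd.Series, wl_daily: pd.Series | None = None,
                      flag_extrapolation: bool = True) -> pd.DataFrame:
        """Daily flux series in g CH4-C m-2 d-1 from daily drivers.

        Days whose drivers fall outside the calibration range are flagged
        (``extrapolated``) but still predicted.
        """
        return self.model.predict_daily(self, ts5_daily, wl_daily,
                                        flag_extrapolation=flag_extrapolation)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit  (n = {self.n}, "
            f"converged = {self.converged})",
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        bse = self.bse
        for name in self.params.index:
            lines.append(f"{name:>8} {self.params[name]:>12.5g} {bse[name]:>12.4g}")
        lines.append(f"RSS = {self.rss:.6g}   AIC = {self.aic:.4g}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted fluxes (1:1 diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = np.asarray(self.model.endog)
        fit = self.model._predict_training(self.params)
        ax.scatter(obs, fit, s=18)
        lim = [min(obs.min(), fit.min()), max(obs.max(), fit.max())]
        ax.plot(lim, lim, "k-", lw=0.8)
        ax.set_xlabel("observed flux [mg CH4-C m-2 h-1]")
        ax.set_ylabel("fitted flux [mg CH4-C m-2 h-1]")
        return ax


def _finish_fit(model, best, n, names, n_tried) -> FluxFitResults:
    if best is None:
        return FluxFitResults(model=model,
                              params=pd.Series(np.nan, index=names),
                              rss=np.nan, n=n, converged=False,
                              n_starts_tried=n_tried)
    rss = float(2.0 * best.cost)
    dof = max(n - len(names), 1)
    s2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = None
    return FluxFitResults(model=model, params=pd.Series(best.x, index=names),
                          rss=rss, n=n, converged=True, cov=cov,
                          n_starts_tried=n_tried)


def _multistart(residual, starts, n, names, model) -> FluxFitResults:
    best = None
    tried = 0
    for x0 in starts:
        tried += 1
        try:
            res = least_squares(residual, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=4000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    return _finish_fit(model, best, n, names, tried)


# ---------------------------------------------------------------------------
# Lloyd & Taylor temperature-response model
# ---------------------------------------------------------------------------

class LloydTaylorModel:
    """Exponential temperature-response model fitted to campaign medians.

    CH4 = R_ref * exp(e0 * (1/(T_ref - T0) - 1/(T_K - T0))), the canonical
    parenthesization with T0 = 227.13 K and T_ref = 283.15 K; at
    T_K = T_ref the prediction equals R_ref for any e0.
    """

    param_names = ("r_ref", "e0")

    def __init__(self, flux, ts5_c):
        self.endog = np.asarray(flux, dtype=float)
        self.ts5_c = np.asarray(ts5_c, dtype=float)
        if len(self.endog) < 4:
            raise ValueError("need at least 4 medians")
        if np.ptp(self.ts5_c) < 5.0:
            raise ValueError("medians must span at least 5 degC of TS5")

    @classmethod
    def from_medians(cls, medians: pd.DataFrame) -> "LloydTaylorModel":
        return cls(medians["flux"], medians["ts5_c"])

    @staticmethod
    def predict(params, ts5_c):
        if isinstance(params, LloydTaylorParams):
            r_ref, e0 = params.r_ref, params.e0
        elif isinstance(params, (tuple, list, np.ndarray)):
            r_ref, e0 = params[0], params[1]
        else:
            r_ref, e0 = params["r_ref"], params["e0"]
        t_k = np.asarray(ts5_c, dtype=float) + 273.15
        return r_ref * np.exp(e0 * (1.0 / (T_REF_K - T0_K) - 1.0 / (t_k - T0_K)))

    def _predict_training(self, params):
        return self.predict(params, self.ts5_c)

    def fit(self, e0_starts=(50.0, 200.0, 400.0),
            extra_starts: list | None = None) -> FluxFitResults:
        y, t = self.endog, self.ts5_c
        r0 = float(np.mean(np.abs(y))) or 1.0

        def residual(x):
            return self.predict(x, t) - y

        starts = [np.asarray(s, dtype=float) for s in (extra_starts or [])]
        starts += [np.array([r0, e0]) for e0 in e0_starts]
        return _multistart(residual, starts, len(y), list(self.param_names), self)

    def predict_daily(self, results, ts5_daily, wl_daily=None, flag_extrapolation=True):
        ts5 = pd.Series(ts5_daily).astype(float)
        flux_mg_h = self.predict(results.params, ts5.to_numpy())
        out = pd.DataFrame({
            "date": pd.to_datetime(ts5.index),
            "flux_g_m2_d": flux_mg_h * 24.0 / 1000.0,
        })
        if flag_extrapolation:
            out["extrapolated"] = (ts5.to_numpy() < self.ts5_c.min()) | (
                ts5.to_numpy() > self.ts5_c.max())
        return out


def fit_lloyd_taylor(medians: pd.DataFrame) -> FluxFitResults:
    return LloydTaylorModel.from_medians(medians).fit()


# ---------------------------------------------------------------------------
# water-level + soil-temperature model
# ---------------------------------------------------------------------------

class WLSTModel:
    """Water-level + soil-temperature flux model fitted to campaign medians.

    CH4 = (c + d*WL) * exp(b*TS5): affine in water level at fixed
    temperature, exponential in temperature at fixed water level.  Negative
    (c + d*WL) is allowed — small negative fluxes occur in the field and are
    not clamped.
    """

    param_names = ("b", "c", "d")

    def __init__(self, flux, ts5_c, wl_m):
        self.endog = np.asarray(flux, dtype=float)
        self.ts5_c = np.asarray(ts5_c, dtype=float)
        self.wl_m = np.asarray(wl_m, dtype=float)
        if len(self.endog) < 5:
            raise ValueError("need at least 5 medians")
        if np.ptp(self.wl_m) <= 0:
            raise ValueError("water level must vary across medians")

    @classmethod
    def from_medians(cls, medians: pd.DataFrame) -> "WLSTModel":
        return cls(medians["flux"], medians["ts5_c"], medians["wl_m"])

    @staticmethod
    def predict(params, ts5_c, wl_m):
        p = params
        if isinstance(p, WLSTParams):
            b, c, d = p.b, p.c, p.d
        elif isinstance(p, (tuple, list, np.ndarray)):
            b, c, d = p[0], p[1], p[2]
        else:
            b, c, d = p["b"], p["c"], p["d"]
        return (c + d * np.asarray(wl_m, dtype=float)) * np.exp(
            b * np.asarray(ts5_c, dtype=float))

    def _predict_training(self, params):
        return self.predict(params, self.ts5_c, self.wl_m)

    def _linear_start(self, b: float) -> np.ndarray:
        # at fixed b the model is linear in (c, d): exp(b*T) * [1, WL]
        g = np.exp(b * self.ts5_c)
        X = np.column_stack([g, g * self.wl_m])
        coef, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        return np.array([b, coef[0], coef[1]])

    def fit(self, b_starts=(0.05, 0.1, 0.2),
            extra_starts: list | None = None) -> FluxFitResults:
        y = self.endog

        def residual(x):
            return self.predict(x, self.ts5_c, self.wl_m) - y

        starts = [np.asarray(s, dtype=float) for s in (extra_starts or [])]
        starts += [self._linear_start(b) for b in b_starts]
        return _multistart(residual, starts, len(y), list(self.param_names), self)

    def predict_daily(self, results, ts5_daily, wl_daily, flag_extrapolation=True):
        if wl_daily is None:
            raise ValueError("WLSTModel.predict_daily requires a daily WL series")
        ts5 = pd.Series(ts5_daily).astype(float)
        wl = pd.Series(wl_daily).astype(float).reindex(ts5.index)
        if wl.isna().any():
            missing = list(pd.to_datetime(wl.index[wl.isna()]).strftime("%Y-%m-%d")[:3])
            raise ValueError(f"missing WL driver days, e.g. {missing}")
        flux_mg_h = self.predict(results.params, ts5.to_numpy(), wl.to_numpy())
        out = pd.DataFrame({
            "date": pd.to_datetime(ts5.index),
            "flux_g_m2_d": flux_mg_h * 24.0 / 1000.0,
        })
        if flag_extrapolation:
            out["extrapolated"] = (
                (ts5.to_numpy() < self.ts5_c.min()) | (ts5.to_numpy() > self.ts5_c.max())
                | (wl.to_numpy() < self.wl_m.min()) | (wl.to_numpy() > self.wl_m.max())
            )
        return out


def fit_wlst(medians: pd.DataFrame) -> FluxFitResults:
    return WLSTModel.from_medians(medians).fit()


# ---------------------------------------------------------------------------
# linear interpolation ensemble (jackknife x bootstrap)
# ---------------------------------------------------------------------------

@dataclass
class LinearEnsemble:
    """Annual sums of a jackknife x bootstrap linear-interpolation ensemble.

    ``sums`` has shape (n_boot, n_campaigns): replicate r with campaign j
    left out, in g CH4-C m-2 yr-1 over the period.
    """

    sums: np.ndarray
    campaign_dates: pd.DatetimeIndex
    period: tuple[pd.Timestamp, pd.Timestamp]
    n_boot: int


def linear_interp_ensemble(
    medians: pd.DataFrame,
    period: tuple | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    campaigns: list | None = None,
) -> LinearEnsemble:
    """Jackknife + bootstrap linear interpolation of campaign medians.

    Each of ``n_boot`` replicates picks one plot median per campaign at
    random; within a replicate each campaign is left out in turn and the
    remaining medians are linearly interpolated to a daily series (flat
    extension beyond the first/last campaign), then summed over the period.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    camps = sorted(campaigns) if campaigns is not None else sorted(
        medians["campaign"].unique())
    values, dates = [], []
    for c in camps:
        grp = medians[medians["campaign"] == c]
        if grp.empty:
            raise ValueError(f"campaign {c!r} has no medians")
        values.append(grp["flux"].to_numpy())
        dates.append(pd.Timestamp(grp["date"].iloc[0]))
    dates = pd.DatetimeIndex(dates)
    if period is None:
        period = (dates.min(), dates.max())
    p0, p1 = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    days = pd.date_range(p0, p1, freq="D")
    day_num = (days - p0).days.to_numpy(dtype=float)
    camp_num = (dates - p0).days.to_numpy(dtype=float)

    n_camp = len(camps)
    if n_camp < 3:
        raise ValueError("need at least 3 campaigns")
    # replicate value matrix: one randomly chosen plot median per campaign
    V = np.empty((n_boot, n_camp))
    for j, v in enumerate(values):
        V[:, j] = v[rng.integers(0, len(v), size=n_boot)]

    # annual sum of the interpolated daily series is linear in the campaign
    # values: precompute, per left-out campaign, the weight of each kept one
    sums = np.empty((n_boot, n_camp))
    for j in range(n_camp):
        keep = np.delete(np.arange(n_camp), j)
        xs = camp_num[keep]
        W = np.empty(len(keep))
        for i in range(len(keep)):
            unit = np.zeros(len(keep))
            unit[i] = 1.0
            W[i] = np.interp(day_num, xs, unit).sum()
        sums[:, j] = (V[:, keep] @ W) * 24.0 / 1000.0
    return LinearEnsemble(sums=sums, campaign_dates=dates, period=(p0, p1),
                          n_boot=n_boot)
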