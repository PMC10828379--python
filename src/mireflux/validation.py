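"""Bootstrap cross-validation of the gap-filling methods.

Each method is judged by repeated random 80/20 splits of the campaign
medians: fit (or interpolate) on the training records, predict the held-out
records, and score R2 (squared Pearson correlation of predicted vs
observed), RMSE and bias (mean of predicted - observed).  Across bootstraps
the median R2, mean RMSE and mean bias are reported with the standard
deviation of the bootstrap distribution as their standard errors; AIC comes
from the full-data fit (nonlinear methods only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import LloydTaylorModel, WLSTModel, fit_lloyd_taylor, fit_wlst

METHODS = ("wlst", "lloyd_taylor", "linear")


@dataclass
class ModelValidation:
    """Cross-validation scores of one method on one median set."""

    method: str
    label: str
    r2_median: float
    r2_se: float
    rmse_mean: float
    rmse_se: float
    bias_mean: float
    bias_se: float
    aic: float | None
    n_boot: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _r2_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if len(obs) < 2 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0          # constant prediction carries no correlation
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def _warm_fit(model, warm: np.ndarray | None):
    """Refit starting from the full-data solution, falling back to the
    multi-start search when the warm start does not converge."""
    if warm is not None:
        if isinstance(model, WLSTModel):
            res = model.fit(b_starts=(), extra_starts=[warm])
        else:
            res = model.fit(e0_starts=(), extra_starts=[warm])
        if res.converged:
            return res
    return model.fit()


def _fit_predict(method: str, train: pd.DataFrame, test: pd.DataFrame,
                 full_params: np.ndarray | None):
    if method == "wlst":
        model = WLSTModel.from_medians(train)
        res = _warm_fit(model, full_params)
        if not res.converged:
            return None
        return model.predict(res.params, test["ts5_c"].to_numpy(),
                             test["wl_m"].to_numpy())
    if method == "lloyd_taylor":
        model = LloydTaylorModel.from_medians(train)
        res = _warm_fit(model, full_params)
        if not res.converged:
            return None
        return model.predict(res.params, test["ts5_c"].to_numpy())
    if method == "linear":
        # daily interpolant through the training medians, evaluated at the
        # held-out dates (flat extension beyond the edges)
        tr = train.sort_values("date")
        by_date = tr.groupby("date")["flux"].median()
        x = (pd.to_datetime(by_date.index) - pd.Timestamp("2000-01-01")).days.to_numpy(float)
        xt = (pd.to_datetime(test["date"]) - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
        return np.interp(xt, x, by_date.to_numpy())
    raise ValueError(f"unknown method {method!r}")


def cross_validate(
    method: str,
    medians: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    test_frac: float = 0.2,
    label: str = "",
    max_fail_frac: float = 0.2,
) -> ModelValidation:
    """Bootstrap 80/20 cross-validation of one method.

    Splits are at the level of individual median records, sampled without
    replacement.  Bootstraps whose fit fails are skipped and counted; more
    than ``max_fail_frac`` failures raise.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(medians) < 10:
        raise ValueError("need at least 10 medians for cross-validation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    full_params = None
    aic = None
    if method in ("wlst", "lloyd_taylor"):
        full = fit_wlst(medians) if method == "wlst" else fit_lloyd_taylor(medians)
        aic = full.aic if full.converged else None
        full_params = full.params.to_numpy() if full.converged else None

    n = len(medians)
    n_test = max(1, int(round(test_frac * n)))
    r2s, rmses, biases = [], [], []
    n_failed = 0
    for _ in range(n_boot):
        perm = rng.permutation(n)
        test = medians.iloc[perm[:n_test]]
        train = medians.iloc[perm[n_test:]]
        try:
            pred = _fit_predict(method, train, test, full_params)
        except Exception:
            pred = None
        if pred is None or not np.all(np.isfinite(pred)):
            n_failed += 1
            continue
        obs = test["flux"].to_numpy()
        err = pred - obs
        r2s.append(_r2_pearson(pred, obs))
        rmses.append(float(np.sqrt(np.mean(err**2))))
        biases.append(float(np.mean(err)))
    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap fits failed for method {method!r}")
    r2s, rmses, biases = map(np.asarray, (r2s, rmses, biases))
    return ModelValidation(
        method=method, label=label,
        r2_median=float(np.median(r2s)), r2_se=float(np.std(r2s, ddof=1)),
        rmse_mean=float(np.mean(rmses)), rmse_se=float(np.std(rmses, ddof=1)),
        bias_mean=float(np.mean(biases)), bias_se=float(np.std(biases, ddof=1)),
        aic=aic, n_boot=n_boot, n_failed=n_failed,
    )


def aic_table(fits: dict[str, object]) -> pd.DataFrame:
    """AIC per converged nonlinear fit: n*ln(RSS/n) + 2k, k = params + 1.

    Linear interpolation has no likelihood here and is excluded by
    construction; non-converged fits are excluded with a note.
    """
    rows = []
    for name, fit in fits.items():
        if getattr(fit, "converged", False):
            rows.append({"method": name, "aic": fit.aic, "rss": fit.rss,
                         "n": fit.n, "k": fit.k, "note": ""})
        else:
            rows.append({"method": name, "aic": np.nan, "rss": np.nan,
                         "n": getattr(fit, "n", np.nan), "k": np.nan,
                         "note": "not converged"})
    return pd.DataFrame(rows)


def validation_table(
    medians: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Per-microform cross-validation table across all three methods."""
    rows = []
    for i, (mf, grp) in enumerate(sorted(medians.groupby("microform"))):
        for j, method in enumerate(methods):
            mv = cross_validate(method, grp.reset_index(drop=True), n_boot=n_boot,
                                seed=np.random.default_rng([seed, i, j]), label=mf)
            rows.append(mv.__dict__)
    return pd.DataFrame(rows)
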