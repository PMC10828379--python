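import numpy as np
import pandas as pd
import pytest

import mireflux as mf
from mireflux.models import WLSTModel, WLSTParams


@pytest.fixture(scope="session")
def geometry():
    return mf.ChamberGeometry()


@pytest.fixture(scope="session")
def qc():
    return mf.FluxQCConfig()


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic campaign (one site, 2 microforms) shared by tests."""
    cfg = mf.default_config(
        123,
        microforms=(
            mf.MicroformSpec("open_hol", "open", 0.0, WLSTParams(0.115, 1.4, 6.0)),
            mf.MicroformSpec("open_hum", "open", -0.10, WLSTParams(0.13, 1.7, 5.0)),
        ),
        closures_per_type=2,
    )
    return mf.simulate_campaign(cfg)


@pytest.fixture(scope="session")
def small_fluxes(small_sim):
    fl = mf.compute_fluxes(small_sim.traces, small_sim.geometries)
    fl["campaign"] = [tr.meta["campaign"] for tr in small_sim.traces]
    removed = mf.morning_filter(fl)
    fl.loc[removed, "valid"] = False
    fl.loc[removed, "reason"] = "morning_artifact"
    return fl


@pytest.fixture(scope="session")
def small_medians(small_sim, small_fluxes):
    return mf.campaign_medians(small_fluxes, small_sim.drivers)


def make_medians(params: WLSTParams, n_campaigns: int = 18, n_plots: int = 3,
                 noise_frac: float = 0.0, seed: int = 0,
                 wl_range=(-0.25, 0.05), ts5_range=(0.5, 21.0)) -> pd.DataFrame:
    """Synthetic campaign-median records drawn from a known flux law."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2020-11-01", "2021-10-31", periods=n_campaigns)
    doy = dates.dayofyear.to_numpy()
    mid = 0.5 * (ts5_range[0] + ts5_range[1])
    amp = 0.5 * (ts5_range[1] - ts5_range[0])
    ts5 = mid + amp * np.sin(2 * np.pi * (doy - 110) / 365.0)
    rows = []
    for p in range(n_plots):
        wl = rng.uniform(*wl_range, size=n_campaigns)
        flux = WLSTModel.predict(params, ts5, wl)
        rows.append(pd.DataFrame({
            "plot_id": f"p{p}", "microform": "mf", "site": "s",
            "campaign": np.arange(n_campaigns), "date": dates,
            "flux": flux, "ts5_c": ts5, "wl_m": wl,
        }))
    med = pd.concat(rows, ignore_index=True)
    if noise_frac > 0:
        med["flux"] += rng.normal(0, noise_frac * med["flux"].abs().mean(),
                                  size=len(med))
    return med
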