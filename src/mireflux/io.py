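"""CSV schemas and readers/writers for every pipeline artifact.

All files are UTF-8 CSV with documented headers and ISO-8601 timestamps.
Readers are header-keyed (column order does not matter), validate their
schema, and drop malformed rows with a warning naming the offending lines
rather than failing the whole file.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import ChamberGeometry, Trace
from .synthetic import Drivers

TRACE_COLUMNS = ["closure_id", "plot_id", "microform", "chamber_type", "start",
                 "time_s", "ch4_ppm", "chamber_temp_c", "par"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _drop_malformed(df: pd.DataFrame, numeric_cols: list[str], path) -> pd.DataFrame:
    coerced = df.copy()
    for c in numeric_cols:
        coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
    bad = coerced[numeric_cols].isna().all(axis=1) | coerced[
        [c for c in numeric_cols if c != "par"]].isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 0-base
        warnings.warn(f"{path}: dropped {int(bad.sum())} malformed row(s), "
                      f"e.g. line(s) {lines}")
    return coerced[~bad]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces(traces: list[Trace], path) -> None:
    rows = []
    for i, tr in enumerate(traces):
        n = len(tr.times_s)
        rows.append(pd.DataFrame({
            "closure_id": i,
            "plot_id": tr.plot_id,
            "microform": tr.microform,
            "chamber_type": tr.chamber_type,
            "start": tr.start.isoformat(),
            "time_s": tr.times_s,
            "ch4_ppm": tr.ch4_ppm,
            "chamber_temp_c": tr.chamber_temp_c,
            "par": tr.par if tr.par is not None else np.full(n, np.nan),
            "campaign": tr.meta.get("campaign", -1),
            "artifacts": ";".join(tr.meta.get("artifacts", [])),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[Trace]:
    df = pd.read_csv(path, dtype={"artifacts": str})
    _require_columns(df, TRACE_COLUMNS, path)
    df = _drop_malformed(df, ["time_s", "ch4_ppm", "chamber_temp_c", "par"], path)
    traces = []
    for cid, grp in df.groupby("closure_id", sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(float)
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{path}: closure {cid} has non-monotone timestamps")
        par = grp["par"].to_numpy(float)
        meta = {"campaign": int(grp["campaign"].iloc[0]) if "campaign" in grp else -1,
                "artifacts": [a for a in str(grp["artifacts"].iloc[0] or "").split(";") if a]
                if "artifacts" in grp else []}
        traces.append(Trace(
            times_s=t,
            ch4_ppm=grp["ch4_ppm"].to_numpy(float),
            chamber_temp_c=grp["chamber_temp_c"].to_numpy(float),
            par=None if np.all(np.isnan(par)) else par,
            chamber_type=str(grp["chamber_type"].iloc[0]),
            plot_id=str(grp["plot_id"].iloc[0]),
            microform=str(grp["microform"].iloc[0]),
            start=pd.Timestamp(grp["start"].iloc[0]),
            meta=meta,
        ))
    return traces


# ---------------------------------------------------------------------------
# geometries, drivers, tables
# ---------------------------------------------------------------------------

def write_geometries(geometries: dict[str, ChamberGeometry], path) -> None:
    rows = []
    for plot, g in geometries.items():
        rows.append({"plot_id": plot, "base_area": g.base_area,
                     "nominal_height": g.nominal_height,
                     "displaced_volume": g.displaced_volume,
                     "surface_offsets": ";".join(f"{o:.5f}" for o in g.surface_offsets)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_geometries(path) -> dict[str, ChamberGeometry]:
    df = pd.read_csv(path)
    _require_columns(df, ["plot_id", "base_area", "nominal_height",
                          "displaced_volume", "surface_offsets"], path)
    out = {}
    for _, r in df.iterrows():
        offsets = tuple(float(x) for x in str(r["surface_offsets"]).split(";"))
        out[str(r["plot_id"])] = ChamberGeometry(
            base_area=float(r["base_area"]),
            nominal_height=float(r["nominal_height"]),
            surface_offsets=offsets,
            displaced_volume=float(r["displaced_volume"]))
    return out


def write_drivers(drivers: Drivers, outdir) -> None:
    outdir = Path(outdir)
    drivers.daily_ts5_df.rename_axis("date").to_csv(outdir / "drivers_ts5_daily.csv")
    drivers.hourly_ts5_df.rename_axis("datetime").to_csv(outdir / "drivers_ts5_hourly.csv")
    drivers.precip_mm.rename_axis("date").to_csv(outdir / "drivers_precip.csv")
    drivers.wl_df.rename_axis("date").to_csv(outdir / "drivers_wl.csv")
    drivers.plots.to_csv(outdir / "plots.csv", index=False)


def read_drivers(outdir) -> Drivers:
    outdir = Path(outdir)
    daily = pd.read_csv(outdir / "drivers_ts5_daily.csv", index_col="date",
                        parse_dates=True)
    hourly = pd.read_csv(outdir / "drivers_ts5_hourly.csv", index_col="datetime",
                         parse_dates=True)
    precip = pd.read_csv(outdir / "drivers_precip.csv", index_col="date",
                         parse_dates=True)["precip_mm"]
    wl = pd.read_csv(outdir / "drivers_wl.csv", index_col="date", parse_dates=True)
    plots = pd.read_csv(outdir / "plots.csv")
    return Drivers(daily_ts5_df=daily, hourly_ts5_df=hourly, precip_mm=precip,
                   wl_df=wl, plots=plots)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required: list[str] | None = None,
               parse_dates: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        _require_columns(df, required, path)
    for c in parse_dates or []:
        df[c] = pd.to_datetime(df[c])
    return df


def write_report(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
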