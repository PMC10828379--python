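"""Stage orchestration: simulate -> fluxes -> medians -> fit -> validate -> balance.

Every stage reads its inputs from, and writes its outputs to, one artifact
directory.  A ``run_meta.json`` records the configuration hash and seed;
stages refuse to run on artifacts produced under a different configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance as bal
from . import io as mio
from .chamber import compute_fluxes, morning_filter
from .config import PipelineConfig
from .models import campaign_medians, fit_lloyd_taylor, fit_wlst, linear_interp_ensemble
from .synthetic import gen_transects, simulate_campaign
from .validation import validation_table

log = logging.getLogger("mireflux")

STAGES = ("simulate", "fluxes", "medians", "fit", "validate", "balance")


def _check_meta(cfg: PipelineConfig, outdir: Path, stage: str) -> None:
    meta_path = outdir / "run_meta.json"
    if not meta_path.exists():
        raise ValueError(
            f"stage '{stage}' needs artifacts in {outdir}; run 'simulate' first")
    meta = mio.read_report(meta_path)
    if meta.get("config_hash") != cfg.config_hash():
        raise ValueError(
            f"stage '{stage}': artifacts in {outdir} were produced under a "
            f"different configuration (hash {meta.get('config_hash')} != "
            f"{cfg.config_hash()}); re-run upstream stages")


def _require(outdir: Path, fname: str, stage: str, produced_by: str) -> Path:
    p = outdir / fname
    if not p.exists():
        raise ValueError(f"stage '{stage}' is missing {fname}; "
                         f"run stage '{produced_by}' first")
    return p


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = simulate_campaign(cfg.synthetic)
    mio.write_traces(sim.traces, outdir / "traces.csv")
    mio.write_drivers(sim.drivers, outdir)
    mio.write_geometries(sim.geometries, outdir / "geometries.csv")
    mio.write_table(sim.schedule, outdir / "schedule.csv")
    mio.write_table(sim.truth, outdir / "truth.csv")
    rows = []
    for site, truth in cfg.layouts.items():
        for i, tr in enumerate(gen_transects(truth, cfg.n_transects[site],
                                             cfg.transect_length_cm,
                                             seed=np.random.default_rng(
                                                 [cfg.seed, 7, hash(site) % 2**16]))):
            rows.append({"site": site, "transect": i, "sequence": ",".join(tr)})
    pd.DataFrame(rows).to_csv(outdir / "transects.csv", index=False)
    mio.write_report({"config_hash": cfg.config_hash(), "seed": cfg.seed},
                     outdir / "run_meta.json")
    log.info("simulate: %d traces, %d plots", len(sim.traces), len(sim.geometries))


def stage_fluxes(cfg: PipelineConfig, outdir: Path) -> None:
    _check_meta(cfg, outdir, "fluxes")
    traces = mio.read_traces(_require(outdir, "traces.csv", "fluxes", "simulate"))
    geoms = mio.read_geometries(_require(outdir, "geometries.csv", "fluxes", "simulate"))
    fluxes = compute_fluxes(traces, geoms, cfg.qc)
    camp = [tr.meta.get("campaign", -1) for tr in traces]
    fluxes["campaign"] = camp
    removed = morning_filter(fluxes, cfg.qc)
    fluxes.loc[removed, "valid"] = False
    fluxes.loc[removed, "reason"] = "morning_artifact"
    mio.write_table(fluxes, outdir / "fluxes.csv")
    summary = {
        "n_total": int(len(fluxes)),
        "n_valid": int(fluxes["valid"].sum()),
        "n_below_mdf": int(fluxes.loc[fluxes["valid"], "below_mdf"].sum()),
        "rejections": fluxes.loc[~fluxes["valid"], "reason"].value_counts().to_dict(),
    }
    mio.write_report(summary, outdir / "qc_summary.json")
    log.info("fluxes: %(n_valid)d valid of %(n_total)d", summary)


def stage_medians(cfg: PipelineConfig, outdir: Path) -> None:
    _check_meta(cfg, outdir, "medians")
    fluxes = mio.read_table(_require(outdir, "fluxes.csv", "medians", "fluxes"),
                            parse_dates=["start"])
    drivers = mio.read_drivers(outdir)
    med = campaign_medians(fluxes, drivers)
    mio.write_table(med, outdir / "medians.csv")
    log.info("medians: %d records", len(med))


def stage_fit(cfg: PipelineConfig, outdir: Path) -> None:
    _check_meta(cfg, outdir, "fit")
    med = mio.read_table(_require(outdir, "medians.csv", "fit", "medians"),
                         parse_dates=["date"])
    rows, diags = [], {}
    for mf, grp in med.groupby("microform"):
        for name, fitter in (("wlst", fit_wlst), ("lloyd_taylor", fit_lloyd_taylor)):
            res = fitter(grp)
            rec = {"microform": mf, "method": name, "converged": res.converged,
                   "rss": res.rss, "n": res.n, "aic": res.aic}
            rec.update({f"param_{k}": v for k, v in res.params.items()})
            rows.append(rec)
            diags[f"{mf}/{name}"] = {
                "params": res.params.to_dict(), "bse": res.bse.to_dict(),
                "rss": res.rss, "aic": res.aic, "converged": res.converged,
                "n_starts_tried": res.n_starts_tried,
            }
    mio.write_table(pd.DataFrame(rows), outdir / "params.csv")
    mio.write_report(diags, outdir / "params.json")


def stage_validate(cfg: PipelineConfig, outdir: Path) -> None:
    _check_meta(cfg, outdir, "validate")
    med = mio.read_table(_require(outdir, "medians.csv", "validate", "medians"),
                         parse_dates=["date"])
    table = validation_table(med, n_boot=cfg.n_boot_validation, seed=cfg.seed)
    mio.write_table(table, outdir / "validation.csv")


def stage_balance(cfg: PipelineConfig, outdir: Path) -> None:
    _check_meta(cfg, outdir, "balance")
    med = mio.read_table(_require(outdir, "medians.csv", "balance", "medians"),
                         parse_dates=["date"])
    drivers = mio.read_drivers(outdir)
    transects = pd.read_csv(outdir / "transects.csv")
    period = (pd.Timestamp(cfg.synthetic.start), pd.Timestamp(cfg.synthetic.end))

    balances: dict[str, bal.AnnualBalance] = {}
    rng = np.random.default_rng([cfg.seed, 11])
    for mf, grp in med.groupby("microform"):
        site = grp["site"].iloc[0]
        b = bal.bootstrap_balance_se(
            grp.reset_index(drop=True), "wlst",
            drivers.site_ts5_series(site),
            drivers.microform_wl_series(mf),
            n_boot=cfg.n_boot_balance, seed=rng, label=mf)
        balances[mf] = b

    report = {"microforms": {}, "sites": {}}
    rows = []
    for mf, b in balances.items():
        report["microforms"][mf] = {"balance": b.balance, "se": b.se,
                                    "method": b.method}
        rows.append({"label": mf, "level": "microform", "balance": b.balance,
                     "se": b.se, "method": b.method})
    for site in sorted({s for s in med["site"].unique()}):
        seqs = [np.array(s.split(","), dtype=object)
                for s in transects.loc[transects["site"] == site, "sequence"]]
        layout = bal.areal_fractions(seqs)
        site_bal = bal.upscale_site(
            {mf: b for mf, b in balances.items() if mf in layout.fractions},
            layout, label=site)
        mean_wl = {mf: float(drivers.microform_wl_series(mf).mean())
                   for mf in layout.fractions}
        report["sites"][site] = {
            "balance": site_bal.balance, "se": site_bal.se,
            "co2_eq_t_ha_yr": bal.co2_equivalents(site_bal.balance, cfg.gwp),
            "weighted_mean_wl_m": bal.weighted_site_wl(layout, mean_wl),
            "shares": site_bal.extras["shares"],
            "areal_fractions": layout.fractions,
        }
        rows.append({"label": site, "level": "site", "balance": site_bal.balance,
                     "se": site_bal.se, "method": "upscaled"})
    mio.write_table(pd.DataFrame(rows), outdir / "balance.csv")
    mio.write_report(report, outdir / "balance.json")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fluxes": stage_fluxes,
    "medians": stage_medians,
    "fit": stage_fit,
    "validate": stage_validate,
    "balance": stage_balance,
}


def run_pipeline(cfg: PipelineConfig, outdir, stages: tuple[str, ...] | None = None) -> Path:
    """Execute the selected stages in dependency order; returns the artifact dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = STAGES if stages is None else tuple(s for s in STAGES if s in stages)
    unknown = set(stages or ()) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for stage in todo:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, outdir)
    return outdir
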