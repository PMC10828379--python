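"""Pipeline configuration: one object holding every threshold and count.

The QC thresholds, bootstrap counts, GWP, site layouts and the synthetic
campaign settings all live here, round-trip losslessly through TOML, and
are hashed so pipeline stages can refuse to mix artifacts from different
configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .chamber import FluxQCConfig
from .models import WLSTParams
from .synthetic import CampaignConfig, MicroformSpec, SiteSpec


def _default_layouts() -> dict:
    # true areal fractions used by the transect generator, per site
    return {
        "open": {"open_hol": 0.565, "open_hum": 0.435},
        "tree": {"tree_nT_hol": 0.193, "tree_nT_hum": 0.312,
                 "tree_T_hol": 0.188, "tree_T_hum": 0.307},
    }


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one serializable object."""

    qc: FluxQCConfig = field(default_factory=FluxQCConfig)
    synthetic: CampaignConfig = field(default_factory=CampaignConfig)
    layouts: dict = field(default_factory=_default_layouts)
    n_transects: dict = field(default_factory=lambda: {"open": 5, "tree": 10})
    transect_length_cm: int = 1000
    n_boot_validation: int = 1000
    n_boot_balance: int = 2000
    gwp: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot_validation < 1 or self.n_boot_balance < 1:
            raise ValueError("bootstrap counts must be >= 1")
        if self.gwp <= 0:
            raise ValueError("gwp must be positive")

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=seed)
        return cfg

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        qc = dict(d.pop("qc", {}))
        if "duration_bounds_s" in qc:
            qc["duration_bounds_s"] = tuple(qc["duration_bounds_s"])
        syn = dict(d.pop("synthetic", {}))
        if "sites" in syn:
            syn["sites"] = tuple(SiteSpec(**s) for s in syn["sites"])
        if "microforms" in syn:
            syn["microforms"] = tuple(
                MicroformSpec(**{**m, "true_params": WLSTParams(**m["true_params"])})
                for m in syn["microforms"])
        for key in ("wl_bounds", "ts5_bounds"):
            if key in syn:
                syn[key] = tuple(syn[key])
        return cls(qc=FluxQCConfig(**qc), synthetic=CampaignConfig(**syn), **d)

    def to_toml(self) -> str:
        return dumps_toml(self.to_dict())

    @classmethod
    def from_toml(cls, text: str) -> "PipelineConfig":
        import tomllib

        return cls.from_dict(tomllib.loads(text))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_toml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_toml(fh.read())

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# minimal TOML emitter (tomllib only reads)
# ---------------------------------------------------------------------------

def _fmt_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_scalar(x) for x in v) + "]"
    if isinstance(v, dict):
        inner = ", ".join(f"{k} = {_fmt_scalar(x)}" for k, x in v.items())
        return "{ " + inner + " }"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _is_table_list(v) -> bool:
    return isinstance(v, (list, tuple)) and len(v) > 0 and all(
        isinstance(x, dict) for x in v)


def dumps_toml(d: dict, prefix: str = "") -> str:
    lines: list[str] = []
    tables: list[str] = []
    for key, v in d.items():
        full = f"{prefix}.{key}" if prefix else key
        if isinstance(v, dict):
            body = dumps_toml(v, full)
            tables.append(f"[{full}]\n{body}" if not v else f"[{full}]\n{body}")
        elif _is_table_list(v):
            for item in v:
                flat = {k: x for k, x in item.items()}
                body_lines = [f"{k} = {_fmt_scalar(x)}" for k, x in flat.items()]
                tables.append(f"[[{full}]]\n" + "\n".join(body_lines))
        else:
            lines.append(f"{key} = {_fmt_scalar(v)}")
    out = "\n".join(lines)
    if tables:
        out = out + ("\n\n" if out else "") + "\n\n".join(tables)
    return out + ("\n" if not prefix else "")
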