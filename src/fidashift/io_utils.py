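"""CSV readers/writers and the run configuration.

File formats (see FORMATS.md):
  * Taylorgram CSV: header ``time_s,signal_au``, UTF-8, '.' decimals.
  * Binding-curve CSV: header ``conc,unit,r_app_nm,replicate``.
  * Cohort CSV: one row per sample with the analysis columns.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import BindingCurve
from .fitting import FitConfig
from .physics import CapillarySetup, Taylorgram
from .synthetic_data import GeneratorConfig, GroupProfile, default_profiles

__all__ = [
    "read_taylorgram",
    "write_taylorgram",
    "read_binding_curve",
    "write_binding_curve",
    "read_cohort",
    "write_cohort",
    "RunConfig",
    "load_config",
    "save_config",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Taylorgram CSV
# ---------------------------------------------------------------------------

def read_taylorgram(path: str | Path, meta: dict | None = None) -> Taylorgram:
    """Read a ``time_s,signal_au`` CSV into a validated Taylorgram."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["time_s", "signal_au"]:
            raise ParseError(
                f"{path}: line 1: expected header 'time_s,signal_au', got {header!r}"
            )
        times: list[float] = []
        signals: list[float] = []
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}: line {lineno}: time not strictly increasing"
                )
            times.append(t)
            signals.append(s)
    try:
        return Taylorgram(np.array(times), np.array(signals), meta or {})
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_taylorgram(tg: Taylorgram, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": tg.time, "signal_au": tg.signal})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# binding-curve CSV
# ---------------------------------------------------------------------------

def read_binding_curve(path: str | Path) -> BindingCurve:
    """Read ``conc,unit,r_app_nm,replicate`` rows into a BindingCurve."""
    df = pd.read_csv(path)
    required = {"conc", "unit", "r_app_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ParseError(f"{path}: mixed concentration units {list(units)}")
    return BindingCurve(conc=df["conc"].to_numpy(float),
                        r_app=df["r_app_nm"].to_numpy(float),
                        unit=str(units[0]))


def write_binding_curve(curve: BindingCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "conc": curve.conc, "unit": curve.unit, "r_app_nm": curve.r_app,
        "replicate": np.arange(1, curve.conc.size + 1),
    })
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "sample_id", "group", "r_capmix", "r_capdis", "sofa", "ventilated",
    "survived", "crp", "lcms_frac_hsa", "lcms_frac_hdl",
)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "group", "r_capmix", "r_capdis"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad = (df["lcms_frac_hsa"].dropna().lt(0).any()
           or df["lcms_frac_hsa"].dropna().gt(1).any()
           or df["lcms_frac_hdl"].dropna().lt(0).any()
           or df["lcms_frac_hdl"].dropna().gt(1).any())
    if bad:
        raise ParseError(f"{path}: LC-MS fractions must lie in [0, 1]")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full configuration of a pipeline run; YAML round-trippable.

    ``provenance`` carries a short note per numeric default saying whether it
    is an instrument/protocol constant or a chosen modelling default.
    """

    seed: int = 0
    capillary: CapillarySetup = field(default_factory=CapillarySetup)
    fitting: FitConfig = field(default_factory=FitConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    profiles: dict[str, GroupProfile] = field(default_factory=default_profiles)
    hdl_positive_delta: bool = True
    simulate_taylorgrams: bool = False
    provenance: dict = field(default_factory=lambda: {
        "capillary.r_c": "chosen (instrument geometry not published)",
        "capillary.length_to_detector": "chosen (instrument geometry not published)",
        "capillary.temperature": "protocol constant (capillary at 37 C)",
        "capillary.viscosity": "water at 37 C",
        "capillary.t_r": "chosen, bounded by the 400 mbar / 200 s mobilization",
        "generator.*": "group medians from the reported cohort; couplings chosen",
    })

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "capillary": dataclasses.asdict(self.capillary),
            "fitting": dataclasses.asdict(self.fitting),
            "generator": dataclasses.asdict(self.generator),
            "profiles": {k: dataclasses.asdict(v) for k, v in self.profiles.items()},
            "hdl_positive_delta": self.hdl_positive_delta,
            "simulate_taylorgrams": self.simulate_taylorgrams,
            "provenance": dict(self.provenance),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        profiles = {
            k: GroupProfile(**{**v, "sofa_iqr": tuple(v["sofa_iqr"])
                               if v.get("sofa_iqr") else None})
            for k, v in d.get("profiles", {}).items()
        } or default_profiles()
        return cls(
            seed=int(d.get("seed", 0)),
            capillary=CapillarySetup(**d["capillary"]) if "capillary" in d
            else CapillarySetup(),
            fitting=FitConfig(**d["fitting"]) if "fitting" in d else FitConfig(),
            generator=GeneratorConfig(**d["generator"]) if "generator" in d
            else GeneratorConfig(),
            profiles=profiles,
            hdl_positive_delta=bool(d.get("hdl_positive_delta", True)),
            simulate_taylorgrams=bool(d.get("simulate_taylorgrams", False)),
            provenance=dict(d.get("provenance", {})),
        )


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def dump_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, float) and math.isnan(o):  # pragma: no cover
            return None
        raise TypeError(f"not JSON serializable: {type(o)}")

    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default, allow_nan=True)
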