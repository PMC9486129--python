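"""Flat-file plumbing: parameter configs (YAML key-value) and CSV tables.

All tables are desk-scale, so plain CSV with explicit header columns is
used throughout: (ligand_nM, phi_b) for dose-response curves,
(time_s, value) for kinetic traces, (ligand_nM, signal[, sd]) for
titrations and (label, kd_nM, temperature_K[, dg_kcal_mol]) for energy
ledgers.  Parameter sets are flat YAML mappings with one key per rate
constant plus ``variant``, ``model`` and a ``units`` declaration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .estimate import TitrationData
from .model import RateConstants, ReducedRateConstants
from .simulate import DoseResponseCurve, KineticTrace
from .thermo import EnergyLedger

__all__ = [
    "save_rates",
    "load_rates",
    "save_dose_response",
    "load_dose_response",
    "save_trace",
    "load_trace",
    "save_titration",
    "load_titration",
    "save_ledger",
    "load_ledger",
]

_UNITS = "concentration=nM time=s"


def save_rates(rates, path, variant: str = "full") -> None:
    """Write a parameter set as a flat YAML mapping."""
    payload = {
        "model": "reduced" if isinstance(rates, ReducedRateConstants) else "full",
        "variant": variant,
        "units": _UNITS,
    }
    payload.update(rates.as_dict())
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_rates(path):
    """Read a parameter set; returns (rates, variant)."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a flat key-value mapping")
    model = payload.pop("model", "full")
    variant = payload.pop("variant", "full")
    payload.pop("units", None)
    cls = ReducedRateConstants if model == "reduced" else RateConstants
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise SchemaError(f"{path}: unknown parameter keys {sorted(unknown)}")
    missing = fields - set(payload)
    if missing:
        raise SchemaError(f"{path}: missing parameter keys {sorted(missing)}")
    return cls(**{k: float(v) for k, v in payload.items()}), variant


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def save_dose_response(curve: DoseResponseCurve, path, precision: int = 10) -> None:
    df = pd.DataFrame({"ligand_nM": curve.ligand_nM, "phi_b": curve.phi_b})
    df.to_csv(path, index=False, float_format=f"%.{precision}g")


def load_dose_response(path, variant: str = "full") -> DoseResponseCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["ligand_nM", "phi_b"], path)
    return DoseResponseCurve(
        ligand_nM=df["ligand_nM"].to_numpy(),
        phi_b=df["phi_b"].to_numpy(),
        variant=variant,
    )


def save_trace(trace: KineticTrace, path, precision: int = 10) -> None:
    """Trace CSV plus a small YAML metadata sidecar (<path>.meta.yaml)."""
    path = Path(path)
    cols = {"time_s": trace.time_s, "value": trace.value}
    if trace.sd is not None:
        cols["sd"] = trace.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format=f"%.{precision}g")
    meta = {
        "observable": trace.observable,
        "window": trace.window,
        "ligand_nM": trace.ligand_nM,
        "receptor_nM": trace.receptor_nM,
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def load_trace(path) -> KineticTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "value"], path)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return KineticTrace(
        time_s=df["time_s"].to_numpy(),
        value=df["value"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df.columns else None,
        observable=meta.get("observable", "intensity"),
        window=meta.get("window", "custom"),
        ligand_nM=meta.get("ligand_nM"),
        receptor_nM=meta.get("receptor_nM"),
    )


def save_titration(data: TitrationData, path, precision: int = 10) -> None:
    cols = {"ligand_nM": data.ligand_nM, "signal": data.signal}
    if data.sd is not None:
        cols["sd"] = data.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format=f"%.{precision}g")


def load_titration(path) -> TitrationData:
    df = pd.read_csv(path)
    _require_columns(df, ["ligand_nM", "signal"], path)
    return TitrationData(
        ligand_nM=df["ligand_nM"].to_numpy(),
        signal=df["signal"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df.columns else None,
    )


def save_ledger(ledger: EnergyLedger, path) -> None:
    df = pd.DataFrame(
        {
            "label": [e.label for e in ledger],
            "kd_nM": [e.kd_nM for e in ledger],
            "temperature_K": [e.temperature_K for e in ledger],
            "dg_kcal_mol": [e.dg_kcal_mol for e in ledger],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def load_ledger(path, name: str = "") -> EnergyLedger:
    df = pd.read_csv(path)
    _require_columns(df, ["label", "kd_nM"], path)
    temps = (
        df["temperature_K"].to_numpy()
        if "temperature_K" in df.columns
        else np.full(len(df), 298.15)
    )
    return EnergyLedger.from_kds(
        kds_nM=df["kd_nM"].tolist(),
        labels=df["label"].tolist(),
        temperatures_K=list(map(float, temps)),
        name=name,
    )
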