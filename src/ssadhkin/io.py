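"""CSV dialects, configuration, and fit reports.

All assay tables travel as plain CSV:

* rate tables — header ``ssa_um,nad_um,rate,rate_units,ph,temp_c,
  enzyme_um,replicate`` with ``rate_units`` in {per_s, um_per_s};
* pH series — ``ph,value,sd,kind``;
* quench titrations — ``ligand_um,quench`` preceded by ``#key=value``
  metadata lines (enzyme_um, ph, buffer);
* stopped-flow traces — ``time_s,a340`` with ``#enzyme_um=``/``#path_cm=``
  metadata.

Malformed rate rows are collected into a rejects list rather than
aborting the read.  Fit reports serialise to JSON with provenance
(input hashes, seeds, package version).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .fit_engine import (INHIBITORY_MIN_UM, SUBINHIBITORY_MAX_UM,
                         RateDataset)
from .ligand_binding import QuenchTitration
from .ph_ionization import PHSeries
from .presteady_state import StoppedFlowTrace
from .rate_laws import RateObservation

__all__ = [
    "RATE_CSV_COLUMNS",
    "RunConfig",
    "Report",
    "read_rate_csv",
    "write_rate_csv",
    "read_ph_csv",
    "write_ph_csv",
    "read_quench_csv",
    "write_quench_csv",
    "read_trace_csv",
    "write_trace_csv",
]

RATE_CSV_COLUMNS = ["ssa_um", "nad_um", "rate", "rate_units", "ph",
                    "temp_c", "enzyme_um", "replicate"]


def _require_columns(df: pd.DataFrame, required: List[str], path):
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")


def read_rate_csv(path) -> Tuple[RateDataset, List[dict]]:
    """Read a rate table; returns (dataset, rejected rows).

    Rows whose values violate the observation invariants (negative
    concentrations, non-positive enzyme, pH outside [0, 14], unknown
    units) are skipped and reported in the rejects list with a reason.
    """
    df = pd.read_csv(path)
    _require_columns(df, RATE_CSV_COLUMNS[:3], path)
    obs, rejects = [], []
    for idx, row in df.iterrows():
        try:
            obs.append(RateObservation(
                ssa_um=float(row["ssa_um"]),
                nad_um=float(row["nad_um"]),
                rate=float(row["rate"]),
                rate_units=str(row.get("rate_units", "per_s")),
                ph=float(row.get("ph", 8.0)),
                temperature_c=float(row.get("temp_c", 25.0)),
                enzyme_um=float(row.get("enzyme_um", 0.008)),
                replicate_id=str(row.get("replicate", "")),
            ))
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(idx), "reason": str(exc)})
    return RateDataset(obs, design={"source": str(path)}), rejects


def write_rate_csv(path, d: RateDataset) -> None:
    rows = [{
        "ssa_um": o.ssa_um, "nad_um": o.nad_um, "rate": o.rate,
        "rate_units": o.rate_units, "ph": o.ph, "temp_c": o.temperature_c,
        "enzyme_um": o.enzyme_um, "replicate": o.replicate_id,
    } for o in d.observations]
    pd.DataFrame(rows, columns=RATE_CSV_COLUMNS).to_csv(path, index=False)


def read_ph_csv(path) -> PHSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["ph", "value", "kind"], path)
    sd = df["sd"].to_numpy(float) if "sd" in df and df["sd"].notna().all() else None
    return PHSeries(ph=df["ph"].to_numpy(float),
                    value=df["value"].to_numpy(float),
                    sd=sd, kind=str(df["kind"].iloc[0]))


def write_ph_csv(path, s: PHSeries) -> None:
    df = pd.DataFrame({"ph": s.ph, "value": s.value,
                       "sd": s.sd if s.sd is not None else np.nan,
                       "kind": s.kind})
    df.to_csv(path, index=False)


def _read_metadata_lines(path) -> Tuple[dict, str]:
    meta, body = {}, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    return meta, "".join(body)


def read_quench_csv(path) -> QuenchTitration:
    meta, body = _read_metadata_lines(path)
    df = pd.read_csv(_io.StringIO(body))
    _require_columns(df, ["ligand_um", "quench"], path)
    return QuenchTitration(
        ligand_um=df["ligand_um"].to_numpy(float),
        quench=df["quench"].to_numpy(float),
        enzyme_um=float(meta.get("enzyme_um", 0.1)),
        ph=float(meta.get("ph", 8.0)),
        buffer=meta.get("buffer", "potassium phosphate"),
    )


def write_quench_csv(path, t: QuenchTitration) -> None:
    with open(path, "w") as fh:
        fh.write(f"#enzyme_um={t.enzyme_um}\n#ph={t.ph}\n#buffer={t.buffer}\n")
        pd.DataFrame({"ligand_um": t.ligand_um,
                      "quench": t.quench}).to_csv(fh, index=False)


def read_trace_csv(path) -> StoppedFlowTrace:
    meta, body = _read_metadata_lines(path)
    df = pd.read_csv(_io.StringIO(body))
    _require_columns(df, ["time_s", "a340"], path)
    return StoppedFlowTrace(
        time_s=df["time_s"].to_numpy(float),
        a340=df["a340"].to_numpy(float),
        enzyme_um=float(meta["enzyme_um"]),
        path_cm=float(meta.get("path_cm", 1.0)),
    )


def write_trace_csv(path, tr: StoppedFlowTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"#enzyme_um={tr.enzyme_um}\n#path_cm={tr.path_cm}\n")
        pd.DataFrame({"time_s": tr.time_s,
                      "a340": tr.a340}).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Configuration and reporting

_CONFIG_KEYS = {
    "model", "regime", "sub_max_um", "inhib_min_um", "weighting",
    "n_starts", "seed", "bootstrap_n", "rate_csv", "ph_csv", "quench_csv",
    "trace_csvs", "out_json", "bell_form", "direction",
}


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys are rejected."""

    model: str = "eq5"
    regime: str = "auto"
    sub_max_um: float = SUBINHIBITORY_MAX_UM
    inhib_min_um: float = INHIBITORY_MIN_UM
    weighting: str = "none"
    n_starts: int = 10
    seed: int = 0
    bootstrap_n: int = 500
    rate_csv: Optional[str] = None
    ph_csv: Optional[str] = None
    quench_csv: Optional[str] = None
    trace_csvs: tuple = ()
    out_json: Optional[str] = None
    bell_form: str = "standard"
    direction: str = "as_printed"

    def __post_init__(self):
        if not (0 < self.sub_max_um < self.inhib_min_um):
            raise ValueError("need 0 < sub_max_um < inhib_min_um")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "trace_csvs" in raw:
            raw["trace_csvs"] = tuple(raw["trace_csvs"])
        return cls(**raw)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class Report:
    """Consolidated, JSON-serialisable pipeline report."""

    stages: Dict[str, dict] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    def add_stage(self, name: str, payload: dict):
        self.stages[name] = payload

    def add_input(self, label: str, path):
        self.provenance.setdefault("inputs", {})[label] = {
            "path": str(path), "sha256_16": _hash_file(path)}

    def to_json(self, path=None) -> str:
        from . import __version__
        self.provenance["package_version"] = __version__
        text = json.dumps({"stages": self.stages, "warnings": self.warnings,
                           "provenance": self.provenance}, indent=2,
                          default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "Report":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        raw = json.loads(text)
        return cls(stages=raw["stages"], warnings=raw["warnings"],
                   provenance=raw["provenance"])


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
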