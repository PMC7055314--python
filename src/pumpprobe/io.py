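"""Serialization: parameter files, dataset tables, and annotated CSV output.

Parameter documents are flat YAML/JSON mappings with explicit unit strings so
that unit conventions travel with the numbers.  Tabular outputs carry a
``#``-prefixed metadata header (tool version, configuration hash, seed) above
the CSV body.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .inference import (
    ExperimentDataset,
    Observation,
    RecoveryDesign,
    SupernatantAssay,
)
from .model_core import ModelParameters
from .protocols import BioassayDesign, StimulationDesign

PARAM_UNITS = {
    "v_max": "molecules/min",
    "K_M": "mol/L",
    "pi": "molecules/min",
    "f": "dimensionless",
    "lambda_e": "1/min",
    "lambda_i": "1/min",
    "mu": "1/min",
    "V_e": "L",
    "V_i": "L",
    "EC50": "mol/L",
    "n": "dimensionless",
    "O_max": "dimensionless",
    "FRET0": "fraction",
    "dFRET": "fraction",
}


def params_to_dict(params: ModelParameters, units: bool = True) -> dict:
    d = asdict(params)
    if units:
        return {k: {"value": v, "unit": PARAM_UNITS[k]} for k, v in d.items()}
    return d


def params_from_dict(doc: dict) -> ModelParameters:
    values = {}
    for k, v in doc.items():
        values[k] = v["value"] if isinstance(v, dict) else v
    return ModelParameters(**values)


def save_params(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    doc = params_to_dict(params)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_params(path: str | Path) -> ModelParameters:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return params_from_dict(doc)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# pumpprobe {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    # round-trip parsing so written floats reload bit-identically
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Dataset tables

_DESIGN_COLUMNS = [
    "kind", "c_stim_M", "c_comp_M", "od", "v_e_L", "t_s_min", "grow",
    "v_s_L", "v_cells_L", "t_b_min", "od_equiv", "t_min", "mu_per_min",
]


def _design_row(design) -> dict:
    row = dict.fromkeys(_DESIGN_COLUMNS, "")
    if isinstance(design, SupernatantAssay):
        row.update(
            kind="bioassay",
            c_stim_M=design.stim.c_stim, c_comp_M=design.stim.c_comp,
            od=design.stim.od, v_e_L=design.stim.v_e, t_s_min=design.stim.t_s,
            grow=design.stim.grow, v_s_L=design.bio.v_s,
            v_cells_L=design.bio.v_cells, t_b_min=design.bio.t_b,
            od_equiv=design.bio.od_equiv,
        )
    elif isinstance(design, RecoveryDesign):
        row.update(
            kind="recovery", c_stim_M=design.c_stim, od=design.od,
            v_e_L=design.v_e, t_min=design.t, mu_per_min=design.mu,
        )
    elif isinstance(design, StimulationDesign):
        row.update(
            kind="stimulation", c_stim_M=design.c_stim, c_comp_M=design.c_comp,
            od=design.od, v_e_L=design.v_e, t_s_min=design.t_s, grow=design.grow,
        )
    else:
        raise TypeError(f"cannot serialize design type {type(design).__name__}")
    return row


def _design_from_row(row: pd.Series):
    kind = row["kind"]
    if kind == "stimulation":
        return StimulationDesign(
            c_stim=float(row["c_stim_M"]), c_comp=float(row["c_comp_M"] or 0.0),
            od=float(row["od"]), v_e=float(row["v_e_L"]),
            t_s=float(row["t_s_min"]), grow=bool(row["grow"]),
        )
    if kind == "bioassay":
        stim = StimulationDesign(
            c_stim=float(row["c_stim_M"]), c_comp=float(row["c_comp_M"] or 0.0),
            od=float(row["od"]), v_e=float(row["v_e_L"]),
            t_s=float(row["t_s_min"]), grow=bool(row["grow"]),
        )
        bio = BioassayDesign(
            v_s=float(row["v_s_L"]), v_cells=float(row["v_cells_L"]),
            t_b=float(row["t_b_min"]), od_equiv=float(row["od_equiv"]),
        )
        return SupernatantAssay(stim=stim, bio=bio)
    if kind == "recovery":
        return RecoveryDesign(
            t=float(row["t_min"]), c_stim=float(row["c_stim_M"]),
            od=float(row["od"]), v_e=float(row["v_e_L"]),
            mu=float(row["mu_per_min"]),
        )
    raise ValueError(f"unknown design kind {kind!r}")


def datasets_to_frame(datasets: list[ExperimentDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for ob in ds.observations:
            row = {"tag": ds.tag}
            row.update(_design_row(ob.design))
            row.update(fret_mean=ob.fret_mean, fret_sd=ob.fret_sd, n_e=ob.n_e)
            rows.append(row)
    return pd.DataFrame(rows)


def datasets_from_frame(df: pd.DataFrame) -> list[ExperimentDataset]:
    df = df.fillna("")
    datasets = []
    for tag, group in df.groupby("tag", sort=False):
        observations = [
            Observation(
                design=_design_from_row(row),
                fret_mean=float(row["fret_mean"]),
                fret_sd=float(row["fret_sd"]),
                n_e=int(row["n_e"]),
            )
            for _, row in group.iterrows()
        ]
        datasets.append(ExperimentDataset(observations=observations, tag=str(tag)))
    return datasets


def save_datasets(datasets, path, meta=None) -> None:
    write_table(datasets_to_frame(datasets), path, meta)


def load_datasets(path) -> list[ExperimentDataset]:
    return datasets_from_frame(read_table(path))
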