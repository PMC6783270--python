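"""CSV readers/writers and run configuration.

Formats (plain CSV, one header row):

* ThT curves: ``time_h, signal_au, conc_uM, replicate``
* Titration: ``residue, conc_uM, delta_H_ppm, delta_N_ppm`` or a
  precombined ``residue, conc_uM, ddelta_ppm``
* Decays: ``abscissa, intensity, kind``

All readers validate the schema up front and raise :class:`SchemaError`
naming the offending column/row.  Writers use full float precision so a
write/read round trip is exact to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nmr
from .kinetics import ThTCurve

__all__ = [
    "SchemaError",
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_tht_csv",
    "write_tht_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_decay_csv",
    "write_decay_csv",
    "write_ground_truth",
    "read_ground_truth",
]


class SchemaError(ValueError):
    """A tabular input does not match the expected schema."""


class ConfigError(ValueError):
    """A run configuration contains unknown or invalid keys."""


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: no data rows")
    return frame


def _numeric(frame: pd.DataFrame, path, columns) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: non-numeric value in column "
                              f"{col!r} at row {row}")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
        frame[col] = converted
    return frame


def read_tht_csv(path) -> list[ThTCurve]:
    """Read ThT curves, grouped by (conc_uM, replicate), row order preserved."""
    frame = _read_table(path, ("time_h", "signal_au", "conc_uM", "replicate"))
    frame = _numeric(frame, path, ("time_h", "signal_au", "conc_uM", "replicate"))
    curves = []
    for (conc, rep), grp in frame.groupby(["conc_uM", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(ThTCurve(times=grp["time_h"].to_numpy(),
                               signal=grp["signal_au"].to_numpy(),
                               total_monomer=float(conc), replicate=int(rep)))
    return curves


def write_tht_csv(path, curves) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.signal):
            rows.append({"time_h": t, "signal_au": s,
                         "conc_uM": c.total_monomer, "replicate": c.replicate})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path) -> nmr.TitrationSeries:
    """Read a titration table; combines raw 1H/15N shifts when present."""
    frame = _read_table(path, ("residue", "conc_uM"))
    if "ddelta_ppm" in frame.columns:
        frame = _numeric(frame, path, ("residue", "conc_uM", "ddelta_ppm"))
        frame["_dd"] = frame["ddelta_ppm"]
    elif {"delta_H_ppm", "delta_N_ppm"} <= set(frame.columns):
        frame = _numeric(frame, path,
                         ("residue", "conc_uM", "delta_H_ppm", "delta_N_ppm"))
        frame["_dd"] = nmr.combined_shift(frame["delta_H_ppm"].to_numpy(),
                                          frame["delta_N_ppm"].to_numpy())
    else:
        raise SchemaError(f"{path}: need ddelta_ppm or delta_H_ppm+delta_N_ppm")
    pivot = frame.pivot_table(index="residue", columns="conc_uM", values="_dd")
    concs = np.sort(pivot.columns.to_numpy(dtype=float))
    pivot = pivot.loc[:, concs]
    pivot.index = [int(r) for r in pivot.index]
    pivot.columns = list(concs)
    return nmr.TitrationSeries(concs, pivot)


def write_titration_csv(path, series: nmr.TitrationSeries) -> None:
    rows = []
    for residue in series.residues:
        for conc in series.concentrations:
            rows.append({"residue": residue, "conc_uM": conc,
                         "ddelta_ppm": series.shifts.loc[residue, conc]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay_csv(path) -> list[nmr.DecayCurve]:
    """Read decay curves grouped by their ``kind`` label."""
    frame = _read_table(path, ("abscissa", "intensity", "kind"))
    frame = _numeric(frame, path, ("abscissa", "intensity"))
    curves = []
    for kind, grp in frame.groupby("kind", sort=False):
        grp = grp.sort_values("abscissa")
        curves.append(nmr.DecayCurve(abscissa=grp["abscissa"].to_numpy(),
                                     intensity=grp["intensity"].to_numpy(),
                                     kind=str(kind)))
    return curves


def write_decay_csv(path, curves) -> None:
    rows = []
    for c in curves:
        for x, y in zip(c.abscissa, c.intensity):
            rows.append({"abscissa": x, "intensity": y, "kind": c.kind})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth(path, truth: dict) -> None:
    """Serialize a generator's ground-truth sidecar as YAML."""
    def clean(value):
        if isinstance(value, dict):
            return {k: clean(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [clean(v) for v in value]
        if isinstance(value, (np.floating, np.integer)):
            return value.item()
        return value

    Path(path).write_text(yaml.safe_dump(clean(truth), sort_keys=True))


def read_ground_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


@dataclass
class RunConfig:
    """Validated key-value configuration for CLI runs."""

    variant: str = "hexamer_addition"
    kd_dimer: float = 50.0            # μM
    kd_hexamer: float = 10.0e-9       # M^2
    n_ladder: int = 200
    seed_length: int = 200
    seed_monomer_equiv: float = 20.0
    seed: int = 0
    n_starts: int = 10
    verbosity: int = 1
    rate_constants: dict | None = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration key(s): {sorted(unknown)}; "
                f"valid keys are {sorted(known)}")
        return cls(**mapping)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return RunConfig.from_mapping(raw)
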