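"""CSV readers/writers and run configuration.

Tabular dialect: RFC 4180 CSV, UTF-8, '.' decimal, header required; per-mil
columns carry no unit suffix.  Output tables carry a provenance header of
``#``-prefixed comment lines (tool version, seed, config hash) which the
readers skip.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigError, SchemaError
from .gas_partition import VesselGeometry
from .iso_core import (
    IsotopoculeMeasurement,
    SubstrateReference,
    complete_isotopocule,
)
from .errors import InconsistencyError, InsufficientDataError
from .nitrogen_budget import CultureTimeSeries

__all__ = [
    "IsotopeTable",
    "read_isotope_table",
    "write_isotope_table",
    "read_timeseries_table",
    "write_timeseries_table",
    "provenance_header",
    "RunConfig",
    "read_run_config",
]

ISOTOPE_COLUMNS = ["sample_id", "strain", "substrate", "day", "replicate",
                   "d15N_alpha", "d15N_bulk", "d18O", "SP"]
_ISO_FIELD_BY_COLUMN = {
    "d15N_alpha": "d15n_alpha",
    "d15N_beta": "d15n_beta",
    "d15N_bulk": "d15n_bulk",
    "d18O": "d18o",
    "SP": "sp",
}
TIMESERIES_COLUMNS = ["bottle_id", "strain", "substrate", "time_h", "od600",
                      "no3_mM", "no2_mM", "nh4_mM", "n2o_umol",
                      "v_liquid_mL", "v_headspace_mL", "temperature_C", "bunsen_alpha"]


def provenance_header(seed: Optional[int] = None, config_path: Optional[str] = None) -> str:
    """Comment block recording tool version, seed and config hash."""
    parts = [f"# n2oiso {__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
        parts.append(f"# config_sha256={digest}")
    return "\n".join(parts) + "\n"


def _parse_cell(value, column: str, line_no: int):
    if value is None or (isinstance(value, float) and value != value) or str(value).strip() == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"line {line_no}: non-numeric value {value!r} in column {column!r}") from None


@dataclass
class IsotopeTable:
    """Parsed isotope table: completed records plus per-row consistency flags.

    Rows failing consistency beyond tolerance are kept as supplied and listed
    in ``flagged`` as (row index, residual ‰); under-determined rows are kept
    uncompleted.
    """

    measurements: list[IsotopoculeMeasurement] = field(default_factory=list)
    flagged: list[tuple[int, float]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)


def read_isotope_table(path) -> IsotopeTable:
    """Read an isotope CSV into typed, validated records.

    Mandatory columns: sample_id, strain, substrate, day, replicate,
    d15N_alpha, d15N_bulk, d18O, SP (blank cells = absent; an optional
    ``referenced`` 0/1 column and a ``d15N_beta`` column are honoured).
    Each row with at least two ¹⁵N quantities is completed; inconsistent rows
    are flagged, not dropped.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    table = IsotopeTable()
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        iso_kwargs = {
            f: _parse_cell(row.get(c), c, line_no) for c, f in _ISO_FIELD_BY_COLUMN.items() if c in df.columns
        }
        day = _parse_cell(row["day"], "day", line_no)
        replicate = _parse_cell(row["replicate"], "replicate", line_no)
        referenced = False
        if "referenced" in df.columns and str(row["referenced"]).strip() not in {"", "0", "False", "false"}:
            referenced = True
        meas = IsotopoculeMeasurement(
            sample_id=row["sample_id"],
            strain=row["strain"],
            substrate=row["substrate"],
            day=day if day is not None else 1.0,
            replicate=int(replicate) if replicate is not None else 1,
            referenced=referenced,
            **iso_kwargs,
        )
        try:
            meas = complete_isotopocule(meas)
        except InsufficientDataError:
            pass  # keep the partial record as supplied
        except InconsistencyError as err:
            table.flagged.append((i, err.residual))
        table.measurements.append(meas)
    return table


def write_isotope_table(
    measurements: Iterable[IsotopoculeMeasurement],
    path,
    seed: Optional[int] = None,
    config_path: Optional[str] = None,
) -> None:
    rows = []
    for m in measurements:
        rows.append(
            {
                "sample_id": m.sample_id,
                "strain": m.strain,
                "substrate": m.substrate,
                "day": m.day,
                "replicate": m.replicate,
                "d15N_alpha": m.d15n_alpha,
                "d15N_beta": m.d15n_beta,
                "d15N_bulk": m.d15n_bulk,
                "d18O": m.d18o,
                "SP": m.sp,
                "referenced": int(m.referenced),
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed=seed, config_path=config_path))
        df.to_csv(fh, index=False)


def read_timeseries_table(path) -> list[CultureTimeSeries]:
    """Read a culture time-series CSV into one series per bottle.

    Long format, one row per (bottle, time); geometry travels in per-row
    columns so the file is self-contained.  Rows are grouped by ``bottle_id``
    in order of first appearance; time must be strictly increasing within a
    bottle (the offending bottle is named otherwise).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    out: list[CultureTimeSeries] = []
    for bottle_id in df["bottle_id"].drop_duplicates():
        sub = df[df["bottle_id"] == bottle_id]
        first = sub.iloc[0]
        geom = VesselGeometry(
            v_liquid=float(first["v_liquid_mL"]),
            v_headspace=float(first["v_headspace_mL"]),
            temperature=float(first["temperature_C"]),
            bunsen_alpha=float(first["bunsen_alpha"]),
        )
        data = sub[["time_h", "od600", "no3_mM", "no2_mM", "nh4_mM", "n2o_umol"]].reset_index(drop=True)
        out.append(
            CultureTimeSeries(
                bottle_id=str(bottle_id),
                strain=str(first["strain"]),
                substrate=str(first["substrate"]),
                data=data,
                geometry=geom,
            )
        )
    return out


def write_timeseries_table(
    series: Sequence[CultureTimeSeries],
    path,
    seed: Optional[int] = None,
    config_path: Optional[str] = None,
) -> None:
    frames = []
    for ts in series:
        if ts.geometry is None:
            raise ConfigError(f"bottle {ts.bottle_id!r}: geometry required to write a series")
        block = ts.data.copy()
        block.insert(0, "bottle_id", ts.bottle_id)
        block.insert(1, "strain", ts.strain)
        block.insert(2, "substrate", ts.substrate)
        block["v_liquid_mL"] = ts.geometry.v_liquid
        block["v_headspace_mL"] = ts.geometry.v_headspace
        block["temperature_C"] = ts.geometry.temperature
        block["bunsen_alpha"] = ts.geometry.bunsen_alpha
        frames.append(block)
    df = pd.concat(frames, ignore_index=True)[TIMESERIES_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed=seed, config_path=config_path))
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Declarative run configuration parsed from TOML.

    Sections mirror the pipeline's types: ``[geometry]``, ``[references.NO3]``
    / ``[references.NO2]``, ``[mc]`` (n_draws, seed — the seed must be
    explicit: no silent nondeterminism), ``[paths]`` (zones file), and
    ``[reporting]``.
    """

    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    references: dict[str, SubstrateReference] = field(default_factory=dict)
    n_draws: int = 100_000
    seed: Optional[int] = None
    zones_path: Optional[str] = None
    decimals: int = 1

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("config must set [mc].seed explicitly (no silent nondeterminism)")
        return self.seed


def read_run_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    cfg = RunConfig()
    if "geometry" in doc:
        g = doc["geometry"]
        cfg.geometry = VesselGeometry(
            v_liquid=float(g.get("v_liquid_mL", 20.0)),
            v_headspace=float(g.get("v_headspace_mL", 30.0)),
            temperature=float(g.get("temperature_C", 25.0)),
            bunsen_alpha=float(g.get("bunsen_alpha", 0.544)),
            pressure_atm=float(g.get("pressure_atm", 1.0)),
        )
    for species, ref in doc.get("references", {}).items():
        cfg.references[species] = SubstrateReference(
            species=species,
            d15n=float(ref["d15N"]),
            d18o=float(ref["d18O"]),
            d15n_sd=float(ref.get("d15N_sd", 0.0)),
            d18o_sd=float(ref.get("d18O_sd", 0.0)),
        )
    mc = doc.get("mc", {})
    cfg.n_draws = int(mc.get("n_draws", cfg.n_draws))
    cfg.seed = mc.get("seed")
    paths = doc.get("paths", {})
    zones = paths.get("zones")
    if zones is not None:
        zones = str(Path(path).parent / zones) if not Path(zones).is_absolute() else zones
        if not Path(zones).exists():
            raise ConfigError(f"zones file {zones!r} referenced by config does not exist")
        cfg.zones_path = zones
    cfg.decimals = int(doc.get("reporting", {}).get("decimals", 1))
    return cfg
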