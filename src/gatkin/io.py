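"""Canonical file formats and run configuration.

All files are plain text.  Units are fixed package-wide (mV, s, nA, nC; see
:mod:`gatkin.constants`) with no per-file overrides.  Formats:

sweep CSV
    ``#``-prefixed header lines carry ``key = value`` metadata
    (condition_label, holding_mV, step_start_s, step_duration_s,
    sample_rate_hz, plus a JSON ``meta`` line recording seed and generator
    parameters); the table has a ``time_s`` column and one ``I_<V>mV``
    column per test potential.  Floats are written with 17 significant
    digits so write -> read round trips bit-exactly.
condition manifest CSV
    file_path, condition_label, blocker, gaba_uM, betaine_mM, cell_id,
    batch_id; exactly one blocker condition per batch.
dose-response CSV
    concentration, unit, mean_current_nA, sem_nA, n_cells, n_batches.
competition long CSV
    gaba_uM, betaine_mM, current_nA, cell_id, batch_id.
efflux CSV
    well_id, condition, dose, dose_unit, monensin, fraction_index,
    released_counts; the row with fraction_index = -1 carries the counts
    remaining in the cells at the end of the run.
report JSON
    a common envelope validated by :mod:`gatkin.schema`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, InputDomainError
from .protocol import RecordingSet, Sweep, VoltageStepProtocol
from .schema import REPORT_KINDS, validate_report
from .simulate import (EffluxTimeCourse, generator_params_dict,
                       generator_params_from_dict)

__all__ = [
    "RunConfig", "write_sweep_csv", "read_sweep_csv", "write_manifest",
    "read_manifest", "write_dose_csv", "read_dose_csv", "write_competition_csv",
    "read_competition_csv", "write_efflux_csv", "read_efflux_csv",
    "write_report", "read_report", "write_generator_config",
    "read_generator_config",
]

_F = "%.17g"  # lossless float formatting for doubles


def _fmt(x: float) -> str:
    return _F % float(x)


# --------------------------------------------------------------------------- #
# run configuration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; every default equals the package's
    canonical protocol/analysis value."""

    holding_mV: float = -60.0
    step_start_s: float = 0.1
    step_duration_s: float = 0.8
    test_potentials_mV: tuple = tuple(float(v) for v in range(-140, 41, 20))
    sample_rate_hz: float = 1000.0
    post_step_s: float = 0.1
    voltage_range_mV: tuple = (-120.0, 20.0)
    fit_window_start_offset_s: float = 0.005
    fit_window_end_offset_s: Optional[float] = None
    tail_s: float = 0.1
    plateau_threshold: float = 0.1
    n_basal_fractions: int = 4
    sd_current_nA: float = 0.0
    sd_rel: float = 0.0
    seed: Optional[int] = None
    out_dir: str = "."          # not part of the semantic hash
    log_level: str = "INFO"     # not part of the semantic hash

    _NON_SEMANTIC = ("out_dir", "log_level")

    def __post_init__(self):
        try:
            self.protocol()  # validates timing fields
        except InputDomainError as e:
            raise ConfigError(str(e)) from e
        if not (self.voltage_range_mV[0] < self.voltage_range_mV[1]):
            raise ConfigError("voltage_range_mV must be (low, high) with low < high")
        if self.plateau_threshold <= 0:
            raise ConfigError("plateau_threshold must be > 0")
        if self.sd_current_nA < 0 or self.sd_rel < 0:
            raise ConfigError("noise standard deviations must be >= 0")

    def protocol(self) -> VoltageStepProtocol:
        return VoltageStepProtocol(
            holding_mV=self.holding_mV, step_start_s=self.step_start_s,
            step_duration_s=self.step_duration_s,
            test_potentials_mV=self.test_potentials_mV,
            sample_rate_hz=self.sample_rate_hz, post_step_s=self.post_step_s)

    def semantic_dict(self) -> dict:
        d = asdict(self)
        for k in self._NON_SEMANTIC:
            d.pop(k)
        d["test_potentials_mV"] = list(d["test_potentials_mV"])
        d["voltage_range_mV"] = list(d["voltage_range_mV"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("test_potentials_mV", "voltage_range_mV"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.semantic_dict() | {"out_dir": self.out_dir,
                                                   "log_level": self.log_level}, fh)


# --------------------------------------------------------------------------- #
# sweep CSV
# --------------------------------------------------------------------------- #

_REQUIRED_META = ("condition_label", "holding_mV", "step_start_s",
                  "step_duration_s", "sample_rate_hz")


def write_sweep_csv(path, rec: RecordingSet) -> None:
    """Write one condition's sweeps as the canonical sweep CSV."""
    path = Path(path)
    pots = rec.potentials()
    cols = [rec.sweep_at(v).current_nA for v in pots]
    t = rec.sweep_at(pots[0]).time_s
    with open(path, "w") as fh:
        fh.write("# gatkin-sweep v1\n")
        fh.write(f"# condition_label = {rec.condition_label}\n")
        for k, v in rec.protocol.timing_fields().items():
            fh.write(f"# {k} = {_fmt(v)}\n")
        meta = {"solution": rec.solution, **rec.meta}
        fh.write(f"# meta = {json.dumps(meta, sort_keys=True)}\n")
        fh.write("time_s," + ",".join(f"I_{_fmt(v)}mV" for v in pots) + "\n")
        for i in range(t.size):
            fh.write(_fmt(t[i]) + "," + ",".join(_fmt(c[i]) for c in cols) + "\n")


def read_sweep_csv(path) -> RecordingSet:
    """Read a canonical sweep CSV back into a :class:`RecordingSet`.

    Potential columns are reordered ascending on load.  Malformed files
    (missing metadata, duplicate potentials, ragged or non-numeric rows,
    non-uniform time grid) raise :class:`FormatError` naming the offence.
    """
    path = Path(path)
    meta, header, n_header = {}, None, 0
    with open(path) as fh:
        for line in fh:
            n_header += 1
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
            else:
                header = line
                break
    if header is None:
        raise FormatError(f"{path}: no column header found")
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata key(s) {missing}")

    names = header.split(",")
    if names[0] != "time_s":
        raise FormatError(f"{path}: first column must be time_s, got {names[0]!r}")
    pots = []
    for j, name in enumerate(names[1:], start=2):
        if not (name.startswith("I_") and name.endswith("mV")):
            raise FormatError(f"{path}: column {j} name {name!r} is not I_<V>mV")
        pots.append(float(name[2:-2]))
    if len(set(pots)) != len(pots):
        raise FormatError(f"{path}: duplicate potential columns {pots}")

    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if ln <= n_header:
                continue
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(names):
                raise FormatError(
                    f"{path}: row {ln} has {len(parts)} fields, expected {len(names)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as e:
                raise FormatError(f"{path}: row {ln}: {e}") from e
    if len(rows) < 2:
        raise FormatError(f"{path}: needs >= 2 data rows")
    data = np.asarray(rows, float)
    t = data[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise FormatError(f"{path}: time grid is not uniform/increasing")

    fs = float(meta["sample_rate_hz"])
    step_end = float(meta["step_start_s"]) + float(meta["step_duration_s"])
    post = max(t[-1] + 1.0 / fs - step_end, 1.0 / fs)
    protocol = VoltageStepProtocol(
        holding_mV=float(meta["holding_mV"]),
        step_start_s=float(meta["step_start_s"]),
        step_duration_s=float(meta["step_duration_s"]),
        test_potentials_mV=tuple(sorted(pots)),
        sample_rate_hz=fs, post_step_s=post)

    order = np.argsort(pots)
    sweeps = {float(pots[j]): Sweep(float(pots[j]), t, data[:, 1 + j]) for j in order}
    extra = json.loads(meta.get("meta", "{}"))
    return RecordingSet(meta["condition_label"], extra.pop("solution", {}),
                        sweeps, protocol, meta=extra)


# --------------------------------------------------------------------------- #
# tabular formats
# --------------------------------------------------------------------------- #

def _write_table(path, df: pd.DataFrame, columns) -> None:
    df = df.loc[:, list(columns)]
    df.to_csv(path, index=False, float_format=_F)


def _read_table(path, required) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as e:
        raise FormatError(f"{path}: {e}") from e
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


MANIFEST_COLUMNS = ("file_path", "condition_label", "blocker", "gaba_uM",
                    "betaine_mM", "cell_id", "batch_id")


def write_manifest(path, df: pd.DataFrame) -> None:
    _write_table(path, df, MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = _read_table(path, MANIFEST_COLUMNS)
    if df["file_path"].duplicated().any():
        dup = df.loc[df["file_path"].duplicated(), "file_path"].iloc[0]
        raise FormatError(f"{path}: duplicate file_path {dup!r}")
    df["blocker"] = df["blocker"].astype(bool)
    for batch, grp in df.groupby("batch_id"):
        n_blk = int(grp["blocker"].sum())
        if n_blk != 1:
            raise FormatError(
                f"{path}: batch {batch!r} has {n_blk} blocker conditions; exactly 1 required")
    return df


DOSE_COLUMNS = ("concentration", "unit", "mean_current_nA", "sem_nA",
                "n_cells", "n_batches")


def write_dose_csv(path, df: pd.DataFrame) -> None:
    _write_table(path, df, [c for c in DOSE_COLUMNS if c in df.columns])


def read_dose_csv(path) -> pd.DataFrame:
    return _read_table(path, ("concentration", "unit", "mean_current_nA",
                              "sem_nA", "n_cells"))


COMPETITION_COLUMNS = ("gaba_uM", "betaine_mM", "current_nA", "cell_id", "batch_id")


def write_competition_csv(path, df: pd.DataFrame) -> None:
    _write_table(path, df, COMPETITION_COLUMNS)


def read_competition_csv(path) -> pd.DataFrame:
    return _read_table(path, COMPETITION_COLUMNS)


EFFLUX_COLUMNS = ("well_id", "condition", "dose", "dose_unit", "monensin",
                  "fraction_index", "released_counts")


def write_efflux_csv(path, wells: dict) -> None:
    """``wells``: mapping well_id -> :class:`EffluxTimeCourse`."""
    rows = []
    for well_id, tc in wells.items():
        cond = tc.condition
        base = {"well_id": well_id,
                "condition": cond.get("condition", "drug"),
                "dose": cond.get("dose", np.nan),
                "dose_unit": cond.get("dose_unit", "mM"),
                "monensin": bool(cond.get("monensin", False))}
        for i, c in enumerate(tc.released_counts):
            rows.append({**base, "fraction_index": i, "released_counts": c})
        rows.append({**base, "fraction_index": -1,
                     "released_counts": tc.remaining_counts})
    _write_table(path, pd.DataFrame(rows), EFFLUX_COLUMNS)


def read_efflux_csv(path, fraction_minutes: float = 2.0) -> dict:
    df = _read_table(path, EFFLUX_COLUMNS)
    wells = {}
    for well_id, grp in df.groupby("well_id", sort=False):
        rem = grp[grp["fraction_index"] < 0]
        if len(rem) != 1:
            raise FormatError(
                f"{path}: well {well_id!r} needs exactly one remaining-counts row "
                f"(fraction_index = -1), found {len(rem)}")
        fr = grp[grp["fraction_index"] >= 0].sort_values("fraction_index")
        wells[well_id] = EffluxTimeCourse(
            fraction_minutes=fraction_minutes,
            released_counts=fr["released_counts"].to_numpy(float),
            remaining_counts=float(rem["released_counts"].iloc[0]),
            condition={"condition": str(fr["condition"].iloc[0]),
                       "dose": float(fr["dose"].iloc[0]),
                       "dose_unit": str(fr["dose_unit"].iloc[0]),
                       "monensin": bool(fr["monensin"].iloc[0])})
    return wells


# --------------------------------------------------------------------------- #
# report JSON
# --------------------------------------------------------------------------- #

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(path, kind: str, payload: dict, seed: Optional[int] = None,
                 config_hash: Optional[str] = None) -> dict:
    """Write a schema-validated report JSON and return the document."""
    if kind not in REPORT_KINDS:
        raise InputDomainError(f"unknown report kind {kind!r}; one of {REPORT_KINDS}")
    doc = {"format": "gatkin-report", "version": 1, "kind": kind,
           "seed": seed, "config_hash": config_hash, "payload": _jsonable(payload)}
    validate_report(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc


def read_report(path) -> dict:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: {e}") from e
    validate_report(doc)
    return doc


# --------------------------------------------------------------------------- #
# generator parameter config
# --------------------------------------------------------------------------- #

def write_generator_config(path, **param_sets) -> None:
    """Serialize generator parameter sets (charge-movement, cell, transport,
    efflux, noise — pass any subset as keyword arguments named cm_params,
    cell, transport, efflux, noise) to one YAML file."""
    d = generator_params_dict(
        cm_params=param_sets.get("cm_params"), cell=param_sets.get("cell"),
        transport=param_sets.get("transport"), efflux=param_sets.get("efflux"),
        noise=param_sets.get("noise"))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_generator_config(path) -> dict:
    """Load a generator config written by :func:`write_generator_config`;
    returns the parameter dataclasses keyed by set name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: generator config must hold a mapping")
    try:
        return generator_params_from_dict(raw)
    except (TypeError, InputDomainError) as e:
        raise FormatError(f"{path}: {e}") from e
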