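"""Reading and writing melt-curve tables, plate metadata, models and calls.

Two plain-text melt-table layouts are supported:

* wide — first column is temperature (°C), every other column is one well,
  the header row carries well IDs (the shape of LightCycler480-style exports);
* long — columns ``well,temperature,fluorescence`` (optionally ``plate``).

Plate metadata lives in a separate sheet (``well,plate,sample,role,genotype``)
rather than being encoded in column headers, matching how plate layouts are
actually managed. Trained models serialize to a versioned, human-readable
JSON document so a clinical-adjacent classifier stays auditable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    MetadataError,
    ModelVersionError,
    ParseError,
)

WellKey = Tuple[str, str]  # (plate_id, well_id)

MODEL_SCHEMA_VERSION = 1

NO_CALL = "NO_CALL"


class Role(str, Enum):
    POSITIVE_CONTROL = "positive_control"
    TRAINING = "training"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class WellMeta:
    """Plate-layout record for a single well."""

    well_id: str
    plate_id: str
    sample_id: str
    role: Role
    genotype_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role == Role.TRAINING and not self.genotype_label:
            raise MetadataError(
                f"well {self.plate_id}/{self.well_id}: training wells must carry a "
                "genotype label"
            )
        if self.role != Role.TRAINING and self.genotype_label:
            object.__setattr__(self, "genotype_label", None)

    @property
    def key(self) -> WellKey:
        return (self.plate_id, self.well_id)


@dataclass
class Trace:
    """Raw fluorescence-vs-temperature readings for one well."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise FormatError("temperature and fluorescence arrays differ in length")
        if self.temperatures.size < 2:
            raise EmptyInputError("trace needs at least 2 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise FormatError("temperatures must be strictly increasing")


@dataclass
class MeltDataset:
    """Per-well traces plus plate metadata, keyed by (plate_id, well_id)."""

    traces: Dict[WellKey, Trace] = field(default_factory=dict)
    meta: Dict[WellKey, WellMeta] = field(default_factory=dict)

    def plate_order(self) -> List[str]:
        """Plates in order of first appearance in the metadata."""
        seen: List[str] = []
        for key in self.meta:
            if key in self.traces and key[0] not in seen:
                seen.append(key[0])
        return seen

    def wells_with_role(self, role: Role) -> List[WellKey]:
        return [k for k, m in self.meta.items() if m.role == role and k in self.traces]

    def validate_join(self) -> None:
        """Every trace must have metadata and vice versa."""
        missing = [k for k in self.traces if k not in self.meta]
        if missing:
            raise MetadataError(f"traces without metadata: {missing[:5]}")
        orphans = [k for k in self.meta if k not in self.traces]
        if orphans:
            raise MetadataError(f"metadata without traces: {orphans[:5]}")

    @staticmethod
    def assemble(
        traces_by_plate: Dict[str, Dict[str, Trace]], meta: Sequence[WellMeta]
    ) -> "MeltDataset":
        """Join per-plate trace tables with a metadata sheet."""
        ds = MeltDataset()
        for m in meta:
            ds.meta[m.key] = m
        for plate_id, wells in traces_by_plate.items():
            for well_id, trace in wells.items():
                ds.traces[(plate_id, well_id)] = trace
        ds.validate_join()
        return ds


# ---------------------------------------------------------------------------
# melt-table readers


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty")
    return df

def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
            f"data row {row}"
        )
    if vals.isna().any():
        row = int(np.nonzero(vals.isna().to_numpy())[0][0])
        raise ParseError(f"{path}: missing value in column {col!r}, data row {row}")
    return vals.to_numpy(dtype=float)


def _collapse_sort(t: np.ndarray, cols: Dict[str, np.ndarray]):
    """Sort ascending in T, collapsing duplicate temperatures by the mean."""
    order = np.argsort(t, kind="stable")
    t = t[order]
    cols = {k: v[order] for k, v in cols.items()}
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(uniq) != len(t):
        collapsed = {}
        for k, v in cols.items():
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, v)
            collapsed[k] = sums / counts
        return uniq, collapsed
    return t, cols


def read_melt_wide(
    path, column_map: Optional[Dict[str, str]] = None, plate_id: str = "plate1"
) -> MeltDataset:
    """Read a wide melt table: one temperature column plus one column per well.

    ``column_map`` may name the temperature column ({"temperature": <header>});
    by default the first column is temperature. Rows are sorted ascending in
    temperature and duplicate temperature rows are collapsed by the mean.
    The returned dataset carries no metadata; attach a sheet with
    :func:`read_plate_meta` and :meth:`MeltDataset.assemble`.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a temperature column plus at least one well column")
    temp_col = (column_map or {}).get("temperature", df.columns[0])
    if temp_col not in df.columns:
        raise FormatError(f"{path}: temperature column {temp_col!r} not found")
    if len(df) < 2:
        raise EmptyInputError(f"{path}: fewer than 2 data rows")
    t = _numeric_column(df, temp_col, path)
    well_cols = [c for c in df.columns if c != temp_col]
    cols = {c: _numeric_column(df, c, path) for c in well_cols}
    t, cols = _collapse_sort(t, cols)
    ds = MeltDataset()
    for well_id, f in cols.items():
        ds.traces[(plate_id, str(well_id))] = Trace(t.copy(), f)
    return ds


def read_melt_long(path, plate_id: str = "plate1") -> MeltDataset:
    """Read a long melt table with columns well, temperature, fluorescence.

    An optional ``plate`` column overrides ``plate_id`` per row. Wells may sit
    on different (ragged) temperature grids; resampling happens downstream.
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"well", "temperature", "fluorescence"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: long format requires columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    t_all = _numeric_column(df, "temperature", path)
    f_all = _numeric_column(df, "fluorescence", path)
    plates = df["plate"].astype(str).to_numpy() if "plate" in df.columns else np.full(len(df), plate_id)
    wells = df["well"].astype(str).to_numpy()
    ds = MeltDataset()
    frame = pd.DataFrame({"plate": plates, "well": wells, "t": t_all, "f": f_all})
    for (p, w), grp in frame.groupby(["plate", "well"], sort=False):
        t, cols = _collapse_sort(grp["t"].to_numpy(), {"f": grp["f"].to_numpy()})
        ds.traces[(str(p), str(w))] = Trace(t, cols["f"])
    return ds


def write_melt_wide(dataset: MeltDataset, path, plate_id: str) -> None:
    """Write one plate of a dataset as a wide melt table (shared grid required)."""
    keys = [k for k in dataset.traces if k[0] == plate_id]
    if not keys:
        raise FormatError(f"no traces for plate {plate_id}")
    t0 = dataset.traces[keys[0]].temperatures
    data = {"temperature": t0}
    for k in keys:
        tr = dataset.traces[k]
        if not np.array_equal(tr.temperatures, t0):
            raise FormatError("wide export requires all wells on one temperature grid")
        data[k[1]] = tr.fluorescence
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plate metadata


def read_plate_meta(path) -> List[WellMeta]:
    """Read the plate metadata sheet (columns well, plate, sample, role, genotype)."""
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"well", "plate", "sample", "role"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: metadata requires columns {sorted(required)} (+ optional genotype)"
        )
    out: List[WellMeta] = []
    for i, row in df.iterrows():
        role_raw = str(row["role"]).strip().lower()
        try:
            role = Role(role_raw)
        except ValueError:
            raise MetadataError(
                f"{path} row {i}: unknown role {row['role']!r} "
                f"(expected one of {[r.value for r in Role]})"
            )
        genotype = row.get("genotype") if "genotype" in df.columns else None
        if genotype is not None and (pd.isna(genotype) or str(genotype).strip() == ""):
            genotype = None
        out.append(
            WellMeta(
                well_id=str(row["well"]).strip(),
                plate_id=str(row["plate"]).strip(),
                sample_id=str(row["sample"]).strip(),
                role=role,
                genotype_label=str(genotype).strip() if genotype is not None else None,
            )
        )
    keys = [m.key for m in out]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise MetadataError(f"{path}: duplicate (plate, well) rows: {dupes[:5]}")
    return out


def write_plate_meta(meta: Sequence[WellMeta], path) -> None:
    pd.DataFrame(
        {
            "well": [m.well_id for m in meta],
            "plate": [m.plate_id for m in meta],
            "sample": [m.sample_id for m in meta],
            "role": [m.role.value for m in meta],
            "genotype": [m.genotype_label or "" for m in meta],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model serialization (JSON, versioned)


def _curve_to_doc(curve) -> Optional[dict]:
    if curve is None:
        return None
    return {
        "grid_start": curve.grid_start,
        "grid_step": curve.grid_step,
        "values": np.asarray(curve.values, dtype=float).tolist(),
        "well_ref": list(curve.well_ref) if curve.well_ref else None,
        "applied_shift": curve.applied_shift,
        "stages": list(curve.stages),
    }


def _curve_from_doc(doc: Optional[dict]):
    from .preprocess import DerivativeCurve

    if doc is None:
        return None
    return DerivativeCurve(
        grid_start=float(doc["grid_start"]),
        grid_step=float(doc["grid_step"]),
        values=np.asarray(doc["values"], dtype=float),
        well_ref=tuple(doc["well_ref"]) if doc.get("well_ref") else None,
        applied_shift=float(doc.get("applied_shift", 0.0)),
        stages=tuple(doc.get("stages", ())),
    )


def write_model(model, path) -> None:
    """Serialize a trained GenotypeModel to a versioned JSON document."""
    from .preprocess import PreprocessConfig  # noqa: F401

    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "meltcall-genotype-model",
        "labels": list(model.labels),
        "anckg": {g: _curve_to_doc(c) for g, c in model.anckg.items()},
        "mu": {g: np.asarray(v, dtype=float).tolist() for g, v in model.mu.items()},
        "cov": {g: np.asarray(v, dtype=float).tolist() for g, v in model.cov.items()},
        "n_train": {g: int(n) for g, n in model.n_train.items()},
        "priors": {g: float(p) for g, p in model.priors.items()},
        "ridge": {g: float(e) for g, e in model.ridge.items()},
        "t_range": list(model.t_range),
        "reference_pc": _curve_to_doc(model.reference_pc),
        "preprocess": {
            "grid_step": model.preprocess.grid_step,
            "savgol_window": model.preprocess.savgol_window,
            "savgol_polyorder": model.preprocess.savgol_polyorder,
            "shift_search_halfwidth": model.preprocess.shift_search_halfwidth,
            "classification_range": list(model.t_range),
        },
        "posterior_min": model.posterior_min,
        "ellipsoid_coverage": model.ellipsoid_coverage,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path):
    """Load a GenotypeModel from JSON, checking the schema version."""
    from .preprocess import PreprocessConfig
    from .train import GenotypeModel

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: not a valid model document ({exc})")
    if not isinstance(doc, dict) or doc.get("kind") != "meltcall-genotype-model":
        raise ParseError(f"{path}: not a meltcall model document")
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"{path}: model schema version {doc.get('schema_version')} is not "
            f"supported (this build reads version {MODEL_SCHEMA_VERSION})"
        )
    pp = doc["preprocess"]
    config = PreprocessConfig(
        grid_step=float(pp["grid_step"]),
        savgol_window=float(pp["savgol_window"]),
        savgol_polyorder=int(pp["savgol_polyorder"]),
        shift_search_halfwidth=float(pp["shift_search_halfwidth"]),
        classification_range=tuple(pp["classification_range"]),
    )
    return GenotypeModel(
        labels=list(doc["labels"]),
        anckg={g: _curve_from_doc(c) for g, c in doc["anckg"].items()},
        mu={g: np.asarray(v, dtype=float) for g, v in doc["mu"].items()},
        cov={g: np.asarray(v, dtype=float) for g, v in doc["cov"].items()},
        n_train={g: int(n) for g, n in doc["n_train"].items()},
        priors={g: float(p) for g, p in doc["priors"].items()},
        ridge={g: float(e) for g, e in doc.get("ridge", {}).items()},
        t_range=tuple(doc["t_range"]),
        reference_pc=_curve_from_doc(doc["reference_pc"]),
        preprocess=config,
        posterior_min=float(doc["posterior_min"]),
        ellipsoid_coverage=float(doc["ellipsoid_coverage"]),
    )


# ---------------------------------------------------------------------------
# calls output


def write_calls(calls: Sequence, path) -> None:
    """Write genotype calls as CSV: one row per well.

    Columns: well, plate, sample, one posterior per genotype, call (label or
    NO_CALL), no-call reason, max posterior, and the winner's squared
    Mahalanobis distance with the coverage quantile it was compared against.
    """
    labels: List[str] = list(calls[0].posteriors.keys()) if calls else []
    rows = []
    for c in calls:
        row = {
            "well": c.well_id,
            "plate": c.plate_id,
            "sample": c.sample_id,
        }
        for g in labels:
            row[f"posterior_{g}"] = c.posteriors[g]
        row["call"] = c.call if c.call is not None else NO_CALL
        row["no_call_reason"] = c.no_call_reason or ""
        row["max_posterior"] = c.max_posterior
        row["winner_mahalanobis_sq"] = c.d2[c.best_label]
        row["containment_quantile"] = c.containment_quantile
        rows.append(row)
    cols = ["well", "plate", "sample"] + [f"posterior_{g}" for g in labels] + [
        "call", "no_call_reason", "max_posterior", "winner_mahalanobis_sq",
        "containment_quantile",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
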