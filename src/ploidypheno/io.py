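"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: long-format TSV for curves (``well_id, time_h,
od``), a per-well metadata TSV, a strains x traits TSV with a JSON sidecar
for column metadata and replicate counts, Newick for dendrograms, and a
JSON manifest tying outputs to inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import GrowthCurve

__all__ = [
    "SchemaError",
    "write_curves",
    "read_curves",
    "write_meta",
    "read_meta",
    "write_trait_matrix",
    "read_trait_matrix",
    "write_newick",
    "read_wide_plate_csv",
    "file_sha256",
    "write_manifest",
]

CURVE_COLUMNS = ["well_id", "time_h", "od"]
META_COLUMNS = [
    "well_id", "strain_id", "species", "population", "source",
    "ploidy", "mating_type", "environment", "run_id", "is_standard",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A table file does not match its expected schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def write_curves(curves: Sequence[GrowthCurve], path: PathLike) -> None:
    from .synthetic import curves_to_frame

    frame = curves_to_frame(curves)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_curves(
    path: PathLike, meta: Optional[pd.DataFrame] = None
) -> list[GrowthCurve]:
    """Read long-format curves; annotate from a metadata frame if given.

    Raises :class:`SchemaError` naming missing columns, and a ValueError
    with 1-based line numbers for rows that fail numeric parsing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"well_id": str})
    _check_columns(df, CURVE_COLUMNS, path)
    for col in ("time_h", "od"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric '{col}' at line(s) {lines}")
        df[col] = parsed
    if df[["time_h", "od"]].isna().any().any():
        bad = df.index[df[["time_h", "od"]].isna().any(axis=1)]
        lines = [int(i) + 2 for i in bad[:5]]
        raise SchemaError(f"{path}: empty numeric field at line(s) {lines}")

    meta_by_well = {}
    if meta is not None:
        meta_by_well = meta.set_index("well_id").to_dict("index")
    curves = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        m = meta_by_well.get(well_id, {})
        curves.append(
            GrowthCurve(
                well_id=str(well_id),
                strain_id=str(m.get("strain_id", "unknown")),
                ploidy=str(m.get("ploidy", "haploid")),
                mating_type=str(m.get("mating_type", "a")),
                environment=str(m.get("environment", "unknown")),
                run_id=str(m.get("run_id", "run1")),
                times=grp["time_h"].to_numpy(),
                od=grp["od"].to_numpy(),
                is_standard=bool(m.get("is_standard", False)),
            )
        )
    return curves


def write_meta(meta: pd.DataFrame, path: PathLike) -> None:
    _check_columns(meta, META_COLUMNS, path)
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"well_id": str, "strain_id": str})
    _check_columns(df, META_COLUMNS, path)
    df["is_standard"] = df["is_standard"].astype(bool)
    return df


def write_trait_matrix(
    matrix: pd.DataFrame, path: PathLike, counts: Optional[pd.DataFrame] = None
) -> None:
    """Write a trait matrix TSV plus a JSON sidecar (``<path>.json``).

    Columns are flattened to ``environment::component``; the sidecar keeps
    the column metadata and per-cell replicate counts.
    """
    flat = matrix.copy()
    flat.columns = [f"{e}::{c}" for e, c in matrix.columns]
    flat.to_csv(path, sep="\t", float_format="%.10g")
    sidecar = {
        "index_names": list(matrix.index.names),
        "columns": [{"environment": e, "component": c} for e, c in matrix.columns],
    }
    if counts is not None:
        sidecar["replicate_counts"] = {
            f"{e}::{c}": counts[(e, c)].tolist() for e, c in counts.columns
        }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trait_matrix(path: PathLike) -> pd.DataFrame:
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    index_col = list(range(len(sidecar["index_names"]))) if sidecar else [0, 1, 2]
    flat = pd.read_csv(path, sep="\t", index_col=index_col)
    flat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("::", 1)) for c in flat.columns],
        names=["environment", "component"],
    )
    return flat


def write_newick(newick: str, path: PathLike) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def read_wide_plate_csv(path: PathLike, time_column: str = "time_h") -> pd.DataFrame:
    """Convert a wide plate-reader export (one column per well) to long form.

    The first column (or ``time_column``) holds times in hours; every other
    column is a well whose header becomes ``well_id``.
    """
    wide = pd.read_csv(path)
    if time_column not in wide.columns:
        time_column = wide.columns[0]
    long = wide.melt(id_vars=[time_column], var_name="well_id", value_name="od")
    long = long.rename(columns={time_column: "time_h"})
    return long[["well_id", "time_h", "od"]]


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: PathLike, **fields) -> None:
    """Write a JSON manifest (seed, versions, stage row counts, hashes)."""
    import ploidypheno

    payload = {"package": "ploidypheno", "version": ploidypheno.__version__}
    payload.update({k: _jsonable(v) for k, v in fields.items()})
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
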