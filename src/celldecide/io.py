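"""Reading, validating and writing long-format single-cell tables.

The canonical on-disk format is a headered CSV (or TSV) with columns

    cell_id, genotype, dose_ng_ml, time_min, response

one row per (cell, time point).  A MATLAB ``.mat`` adapter maps archive
arrays onto the same long format through an explicit, user-supplied field
mapping, since ``.mat`` archives carry no standard condition metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as sio

from .models import CellDecideError

__all__ = [
    "CANONICAL_COLUMNS",
    "read_measurements",
    "write_measurements",
    "validate_table",
    "read_mat_measurements",
]

CANONICAL_COLUMNS = ["cell_id", "genotype", "dose_ng_ml", "time_min", "response"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the table invariants; return the validated (typed) table."""
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise CellDecideError(
            f"missing required columns {missing}; expected {CANONICAL_COLUMNS}"
        )
    df = table[CANONICAL_COLUMNS].copy()
    for col in ("dose_ng_ml", "time_min", "response"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CellDecideError(f"column {col!r} is not numeric: {exc}") from exc
    if not np.all(np.isfinite(df["response"])):
        raise CellDecideError("non-finite response values present")
    if (df["dose_ng_ml"] < 0).any():
        raise CellDecideError("negative dose found; doses must be >= 0 ng/mL")
    if (df["time_min"] <= 0).any():
        raise CellDecideError("non-positive time point found; times must be > 0 min")
    dup = df.duplicated(subset=["cell_id", "genotype", "dose_ng_ml", "time_min"])
    if dup.any():
        raise CellDecideError(
            f"{int(dup.sum())} duplicate (cell_id, genotype, dose, time) rows"
        )
    return df


def read_measurements(path, format: str | None = None) -> pd.DataFrame:
    """Read a measurement table from CSV, TSV or MAT.

    ``format`` defaults to the file extension.  MAT input requires the
    adapter in :func:`read_mat_measurements`; calling this with a ``.mat``
    path raises with instructions, because the field mapping cannot be
    guessed.
    """
    path = Path(path)
    if not path.exists():
        raise CellDecideError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif fmt == "mat":
        raise CellDecideError(
            "MAT input needs an explicit field mapping: use "
            "read_mat_measurements(path, field_map)"
        )
    else:
        raise CellDecideError(f"unknown format {fmt!r}; expected csv, tsv or mat")
    return validate_table(df)


def write_measurements(table: pd.DataFrame, path, format: str | None = None) -> None:
    """Write a validated table as CSV or TSV."""
    path = Path(path)
    df = validate_table(table)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise CellDecideError(f"unknown output format {fmt!r}")


def read_mat_measurements(
    path, field_map: Sequence[Mapping]
) -> pd.DataFrame:
    """Adapt a MATLAB ``.mat`` archive to the canonical long format.

    ``field_map`` is a list of entries, one per archive variable::

        {"var": "wt_30min_8ngml",    # variable name in the archive
         "dose_ng_ml": 8.0,
         "time_min": 30.0,           # or [30.0, 240.0] for an (n, 2) array
         "genotype": "WT"}           # optional, default "WT"

    A 1-D variable holds one response per cell for a single condition; an
    (n, 2) variable holds paired per-cell responses for the two listed
    time points (cells keep a shared id across the pair).  The mapping is
    deliberately explicit — archive internals differ between studies and
    should be inspected, not assumed.
    """
    path = Path(path)
    if not path.exists():
        raise CellDecideError(f"no such file: {path}")
    mat = sio.loadmat(path, squeeze_me=True)
    frames = []
    for k, entry in enumerate(field_map):
        var = entry.get("var")
        if var is None or var not in mat:
            raise CellDecideError(
                f"field_map entry {k}: variable {var!r} not found in archive "
                f"(available: {[n for n in mat if not n.startswith('__')]})"
            )
        values = np.atleast_1d(np.asarray(mat[var], dtype=float))
        genotype = entry.get("genotype", "WT")
        dose = float(entry["dose_ng_ml"])
        times = entry["time_min"]
        if np.isscalar(times):
            if values.ndim != 1:
                raise CellDecideError(
                    f"variable {var!r}: scalar time_min needs a 1-D array, "
                    f"got shape {values.shape}"
                )
            ids = [f"{genotype}_m{k}_c{i:05d}" for i in range(values.size)]
            frames.append(pd.DataFrame({
                "cell_id": ids, "genotype": genotype, "dose_ng_ml": dose,
                "time_min": float(times), "response": values,
            }))
        else:
            times = [float(t) for t in times]
            if values.ndim != 2 or values.shape[1] != len(times):
                raise CellDecideError(
                    f"variable {var!r}: expected shape (n, {len(times)}) for "
                    f"paired time points, got {values.shape}"
                )
            ids = [f"{genotype}_m{k}_c{i:05d}" for i in range(values.shape[0])]
            for j, t in enumerate(times):
                frames.append(pd.DataFrame({
                    "cell_id": ids, "genotype": genotype, "dose_ng_ml": dose,
                    "time_min": t, "response": values[:, j],
                }))
    if not frames:
        raise CellDecideError("field_map is empty")
    return validate_table(pd.concat(frames, ignore_index=True))
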