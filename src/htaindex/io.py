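"""Reading and writing of spot tables, label matrices, and result bundles.

Canonical on-disk formats are plain text: TSV/CSV for tabular data and dense
label matrices, JSON for metadata (combination decoding, map specs, results).

Label-matrix convention: the first array axis is written as TSV rows, the
second as columns; empty positions are written as a configurable sentinel
(default: empty cell). 3D matrices are written as consecutive 2D z-slices
separated by a ``# z=k`` comment line. A JSON sidecar records shape, C and
the combination decoding, enabling lossless round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .trait_calling import NONE_LABEL, SpotTable, TraitCombinationMatrix

_COORD_NAMES = ("x", "y", "z")


def read_spot_table(path: str | Path, dialect: str | None = None) -> SpotTable:
    """Parse a delimited spot table into a :class:`SpotTable`.

    The file must have a header; columns named x, y (optionally z) —
    case-insensitively — are the integer grid coordinates, every other column
    is a trait. ``dialect`` forces the delimiter (``"\\t"`` or ``","``);
    by default it is sniffed.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if dialect is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=dialect)
    lower = {c.lower(): c for c in df.columns}
    coord_cols = [lower[a] for a in _COORD_NAMES if a in lower]
    if len(coord_cols) < 2:
        raise InputError(
            f"{path}: coordinate columns x, y (optional z) not found in header "
            f"{list(df.columns)}"
        )
    trait_cols = [c for c in df.columns if c not in coord_cols]
    if not trait_cols:
        raise InputError(f"{path}: no trait columns beside the coordinates")

    coords = df[coord_cols].to_numpy()
    if not np.allclose(coords, np.round(coords)):
        raise InputError(f"{path}: coordinates must be integers")
    coords = np.round(coords).astype(np.int64)
    dup = pd.Series(map(tuple, coords)).duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # +1 header, +1 one-based
        raise InputError(
            f"{path}: duplicate coordinates {tuple(coords[dup.idxmax()])} at line {line}"
        )
    values = np.empty((len(df), len(trait_cols)))
    for j, c in enumerate(trait_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise InputError(f"{path}: non-numeric value in column {c!r} at line {line}")
        values[:, j] = col.to_numpy()
    return SpotTable(coordinates=coords, values=values, trait_names=trait_cols)


def write_label_matrix(
    matrix: TraitCombinationMatrix,
    path: str | Path,
    sidecar: str | Path | None = None,
    sentinel: str = "",
) -> None:
    """Write a label matrix as TSV (+ optional JSON sidecar with the decoding)."""
    path = Path(path)
    labels = matrix.labels
    with open(path, "w") as fh:
        slices = labels[..., np.newaxis] if labels.ndim == 2 else labels
        for k in range(slices.shape[2]):
            if labels.ndim == 3:
                fh.write(f"# z={k}\n")
            for row in slices[:, :, k]:
                fh.write(
                    "\t".join(sentinel if v == NONE_LABEL else str(int(v)) for v in row)
                )
                fh.write("\n")
    if sidecar is not None:
        meta = {
            "shape": list(matrix.shape),
            "C": matrix.C,
            "combination_decoding": {
                str(k): list(v) for k, v in sorted(matrix.decoding.items())
            },
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_label_matrix(
    path: str | Path,
    sidecar: str | Path | None = None,
    sentinel: str = "",
) -> TraitCombinationMatrix:
    """Read a TSV label matrix written by :func:`write_label_matrix`.

    Without a sidecar, C defaults to the number of distinct labels present and
    the decoding to placeholder single-trait names.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    slices: list[list[list[int]]] = []
    current: list[list[int]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if current:
                    slices.append(current)
                    current = []
                continue
            if line == "":
                continue
            row = []
            for cell in line.split("\t"):
                if cell == sentinel or cell == "":
                    row.append(NONE_LABEL)
                else:
                    try:
                        row.append(int(cell))
                    except ValueError as exc:
                        raise InputError(f"{path}: non-integer label {cell!r}") from exc
            current.append(row)
    if current:
        slices.append(current)
    if not slices:
        raise InputError(f"{path}: empty label matrix")
    arrays = [np.asarray(s, dtype=np.int64) for s in slices]
    if len({a.shape for a in arrays}) != 1:
        raise InputError(f"{path}: z-slices have inconsistent shapes")
    labels = arrays[0] if len(arrays) == 1 else np.stack(arrays, axis=2)

    if sidecar is not None:
        with open(sidecar) as fh:
            meta = json.load(fh)
        C = int(meta["C"])
        decoding = {
            int(k): tuple(v) for k, v in meta["combination_decoding"].items()
        }
        labels = labels.reshape(tuple(meta["shape"]))
    else:
        present = np.unique(labels)
        present = present[present != NONE_LABEL]
        C = max(int(present.size), 1)
        decoding = {int(l): (f"label_{int(l)}",) for l in present}
    return TraitCombinationMatrix(labels=labels, decoding=decoding, C=C)


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministically serialized JSON (sorted keys, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
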