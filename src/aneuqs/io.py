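"""TSV copy-number matrices, unit tables, and validated run configuration.

The on-disk carrier for single-cell copy-number profiles is a plain TSV:
header ``cell_id<TAB>unit1<TAB>unit2...``, one row per cell, non-negative
integer entries only.  Unit definitions live in a two-column TSV
(``unit_id``, ``length``).  Run configuration is a flat YAML mapping with a
per-command schema; unknown keys are rejected.  Anything this module
writes, it can read back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .units import ChromosomeUnit, validate_unit_set

__all__ = [
    "CopyNumberFormatError",
    "ConfigError",
    "read_cn_matrix",
    "write_cn_matrix",
    "read_unit_table",
    "write_unit_table",
    "ConfigField",
    "load_config",
]


class CopyNumberFormatError(ValueError):
    """Malformed copy-number matrix file."""


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


def read_cn_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a copy-number TSV; returns (matrix, unit_ids, cell_ids).

    Cell order is preserved.  Negative or non-integer entries are rejected
    with the offending cell and unit named; ragged rows are a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    except pd.errors.ParserError as exc:
        raise CopyNumberFormatError(f"{path}: ragged or unparseable TSV: {exc}") from exc
    if df.shape[1] < 1 or df.columns[0] != "cell_id":
        raise CopyNumberFormatError(f"{path}: first header column must be 'cell_id'")
    unit_ids = list(df.columns[1:])
    cell_ids = df["cell_id"].astype(str).tolist()
    if df.isna().any().any():
        raise CopyNumberFormatError(f"{path}: missing entries (ragged rows?)")
    body = df.iloc[:, 1:]
    matrix = np.zeros((len(cell_ids), len(unit_ids)), dtype=np.int64)
    for j, unit in enumerate(unit_ids):
        col = body.iloc[:, j].str.strip()
        ok = col.str.fullmatch(r"\d+")
        if not ok.all():
            i = int(np.nonzero(~ok.to_numpy())[0][0])
            raise CopyNumberFormatError(
                f"{path}: entry {col.iloc[i]!r} at cell {cell_ids[i]!r}, "
                f"unit {unit!r} is not a non-negative integer"
            )
        matrix[:, j] = col.astype(np.int64)
    return matrix, unit_ids, cell_ids


def write_cn_matrix(
    matrix: np.ndarray,
    unit_ids: Sequence[str],
    cell_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a copy-number matrix as a newline-terminated TSV.

    Column order follows ``unit_ids``; output bytes are deterministic for
    identical input.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape != (len(cell_ids), len(unit_ids)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(cell_ids)} cells x {len(unit_ids)} units"
        )
    if not np.issubdtype(matrix.dtype, np.integer):
        raise ValueError("matrix must be integer-typed")
    if (matrix < 0).any():
        raise ValueError("matrix entries must be non-negative")
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("cell_id\t" + "\t".join(unit_ids) + "\n")
        for cid, row in zip(cell_ids, matrix):
            fh.write(str(cid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_unit_table(path: str | Path) -> list[ChromosomeUnit]:
    """Read a unit-definition TSV with header ``unit_id<TAB>length``."""
    df = pd.read_csv(path, sep="\t", header=0)
    if list(df.columns) != ["unit_id", "length"]:
        raise CopyNumberFormatError(
            f"{path}: unit table header must be 'unit_id<TAB>length'"
        )
    units = [ChromosomeUnit(str(r.unit_id), float(r.length)) for r in df.itertuples()]
    validate_unit_set(units)
    return units


def write_unit_table(units: Sequence[ChromosomeUnit], path: str | Path) -> None:
    validate_unit_set(units)
    with Path(path).open("w", newline="\n") as fh:
        fh.write("unit_id\tlength\n")
        for u in units:
            fh.write(f"{u.unit_id}\t{u.length:g}\n")


@dataclass(frozen=True)
class ConfigField:
    """One schema entry: a caster/validator and an optional default."""

    cast: Callable[[Any], Any]
    default: Any = ...  # Ellipsis marks a required field

    @property
    def required(self) -> bool:
        return self.default is ...


def load_config(
    path: str | Path, schema: Mapping[str, ConfigField]
) -> dict[str, Any]:
    """Load a flat YAML config against a schema; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    out: dict[str, Any] = {}
    for key, fieldspec in schema.items():
        if key in raw:
            try:
                out[key] = fieldspec.cast(raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: bad value for {key!r}: {exc}") from exc
        elif fieldspec.required:
            raise ConfigError(f"{path}: missing required config key {key!r}")
        else:
            out[key] = fieldspec.default
    return out
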