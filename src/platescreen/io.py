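"""CSV dialects for every table the pipeline reads or writes.

All files are UTF-8, "." decimal, comma-separated, with an optional leading
comment block of ``#``-prefixed lines (used to embed the seed and config hash
of the producing run).  Readers validate structure and report offending
1-based line numbers.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError
from .synthetic import (
    N_COLS,
    ROW_LABELS,
    WELL_COLUMNS,
    WELL_TYPES,
)

TRUTH_COLUMNS = ["gene_id", "true_class", "effect"]
ANNOTATION_COLUMNS = ["gene_id", "category"]
EXPRESSION_COLUMNS = [
    "gene_id", "condition", "replicate", "gene_intensity", "housekeeping_intensity",
]
INTENSITY_COLUMNS = [
    "sample_id", "condition", "replicate", "target_signal", "control_signal",
]


def _header_lines(seed: int | None, config_hash: str | None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return f"# {' '.join(parts)}\n" if parts else ""


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write any tidy table in the shared dialect (deterministic bytes)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(seed, config_hash))
        df.to_csv(fh, index=False)


def read_table(path: str | Path, required_columns=None) -> pd.DataFrame:
    """Generic reader: skips comment lines, checks required columns."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"unparseable CSV: {exc}") from exc
    if required_columns is not None:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise TableFormatError(f"missing columns: {sorted(missing)}")
    return df


def write_well_table(df, path, seed=None, config_hash=None) -> None:
    write_table(df[WELL_COLUMNS], path, seed=seed, config_hash=config_hash)


def read_well_table(path: str | Path) -> pd.DataFrame:
    """Strict well-table reader.

    Validates field counts, well coordinates (rows A-H, columns 1-12), well
    types, and numeric fields row by row, naming the offending line.
    """
    valid_rows = set(ROW_LABELS)
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = None
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (fields[0].startswith("#")):
                continue
            if header is None:
                header = [f.strip() for f in fields]
                if header != WELL_COLUMNS:
                    raise TableFormatError(
                        f"header must be {','.join(WELL_COLUMNS)}", line=lineno
                    )
                continue
            if len(fields) != len(WELL_COLUMNS):
                raise TableFormatError(
                    f"expected {len(WELL_COLUMNS)} fields, got {len(fields)}",
                    line=lineno,
                )
            rep_s, plate_s, row, col_s, well_type, gene_id, signal_s = fields
            try:
                rep = int(rep_s)
                plate = int(plate_s)
                col = int(col_s)
            except ValueError:
                raise TableFormatError(
                    "replicate, plate and col must be integers", line=lineno
                ) from None
            if rep < 1 or plate < 1:
                raise TableFormatError("replicate and plate are 1-based", line=lineno)
            if row not in valid_rows or not 1 <= col <= N_COLS:
                raise TableFormatError(
                    f"well coordinate {row}{col} outside the "
                    f"{len(ROW_LABELS)}x{N_COLS} geometry",
                    line=lineno,
                )
            if well_type not in WELL_TYPES:
                raise TableFormatError(
                    f"unknown well_type {well_type!r}", line=lineno
                )
            if signal_s.strip() == "":
                signal = np.nan
            else:
                try:
                    signal = float(signal_s)
                except ValueError:
                    raise TableFormatError(
                        f"signal {signal_s!r} is not numeric", line=lineno
                    ) from None
            records.append((rep, plate, row, col, well_type, gene_id, signal))
        if header is None:
            raise TableFormatError("empty file: no header found")
    df = pd.DataFrame(records, columns=WELL_COLUMNS)
    df["signal"] = df["signal"].astype(float)
    return df


def read_truth_table(path) -> pd.DataFrame:
    return read_table(path, TRUTH_COLUMNS)


def read_bscore_table(path) -> pd.DataFrame:
    return read_table(path, ["gene_id", "replicate", "plate", "b_score"])


def read_rankprod_table(path) -> pd.DataFrame:
    from .rankprod import RANKPROD_COLUMNS

    return read_table(path, RANKPROD_COLUMNS)


def read_annotation_table(path) -> pd.DataFrame:
    return read_table(path, ANNOTATION_COLUMNS)


def read_expression_table(path) -> pd.DataFrame:
    return read_table(path, EXPRESSION_COLUMNS)


def read_intensity_table(path) -> pd.DataFrame:
    return read_table(path, INTENSITY_COLUMNS)


def frame_bytes(df: pd.DataFrame) -> bytes:
    """Canonical CSV bytes of a table (used for determinism checks)."""
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue().encode()
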