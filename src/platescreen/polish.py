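"""Per-plate B-score normalization via two-way median polish.

B-score(i, j) = residual(i, j) / (1.4826 * median|residuals over sample wells|)

The polish decomposes each plate into overall + row + column effects plus
residuals using alternating row/column median sweeps (Tukey's two-way polish,
the construction behind the B-score).  Sweeps are initialized at the two-way
least-squares fit: the LS fit is exactly equivariant under additive row,
column and plate offsets, which pins the (otherwise non-unique) polish fixed
point to a canonical solution so that B-scores are invariant to those offsets.
Pass ``init="zero"`` for the textbook cold-start sweep.

Control wells participate in the spatial fit (their rows/columns would
otherwise be under-determined) but are excluded from the MAD so their extreme
values cannot inflate the scale.  This is a convention: the source procedure
does not state how controls were handled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, InputValidationError
from .synthetic import (
    N_COLS,
    N_ROWS,
    ROW_LABELS,
    WELL_COLUMNS,
    WELL_EMPTY,
    WELL_SAMPLE,
)

MAD_CONSISTENCY = 1.4826

BSCORE_COLUMNS = ["gene_id", "replicate", "plate", "b_score"]


@dataclass
class PolishDecomposition:
    """Additive decomposition of one plate grid."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        """overall + row + column + residual; NaN where the input was missing."""
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


@dataclass
class PlateGrid:
    """One physical plate: signal matrix plus aligned well annotations."""

    plate_id: int
    replicate_id: int
    signals: np.ndarray  # (n_rows, n_cols), NaN = missing/empty
    well_type: np.ndarray  # object array, same shape
    gene_id: np.ndarray  # object array, same shape; "" for non-gene wells

    def __post_init__(self):
        if self.signals.shape != self.well_type.shape or self.signals.shape != self.gene_id.shape:
            raise InputValidationError("plate annotation shapes do not match signals")
        sample = (self.well_type == WELL_SAMPLE) & ~np.isnan(self.signals)
        if (np.asarray(self.gene_id)[sample] == "").any():
            raise InputValidationError("sample wells must carry a gene_id")

    @property
    def sample_mask(self) -> np.ndarray:
        return (self.well_type == WELL_SAMPLE) & ~np.isnan(self.signals)

    @classmethod
    def from_frame(cls, wells: pd.DataFrame) -> "PlateGrid":
        """Build from the long-format rows of a single (replicate, plate)."""
        reps = wells["replicate"].unique()
        plates = wells["plate"].unique()
        if len(reps) != 1 or len(plates) != 1:
            raise InputValidationError("from_frame expects exactly one (replicate, plate)")
        signals = np.full((N_ROWS, N_COLS), np.nan)
        wtype = np.full((N_ROWS, N_COLS), WELL_EMPTY, dtype=object)
        gene = np.full((N_ROWS, N_COLS), "", dtype=object)
        ridx = {lab: i for i, lab in enumerate(ROW_LABELS)}
        for rec in wells.itertuples(index=False):
            i, j = ridx[rec.row], rec.col - 1
            signals[i, j] = rec.signal
            wtype[i, j] = rec.well_type
            gene[i, j] = rec.gene_id or ""
        return cls(int(plates[0]), int(reps[0]), signals, wtype, gene)


def median_polish(
    grid: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    init: str = "least_squares",
) -> PolishDecomposition:
    """Two-way median polish of a matrix with missing-value (NaN) support.

    Alternating row/column median sweeps run until the largest absolute change
    in any effect drops below ``tol`` or ``max_iter`` is reached (the latter
    raises a warning, not an error: the sweep can cycle).  The reconstruction
    identity ``overall + row + col + residual == input`` holds to float
    precision at every iteration by construction.
    """
    z = np.array(grid, dtype=float)
    if z.ndim != 2:
        raise InputValidationError("median_polish expects a 2-D matrix")
    if np.isinf(z).any():
        raise InputValidationError("non-finite (inf) values in plate matrix")
    obs = ~np.isnan(z)
    row_counts = obs.sum(axis=1)
    col_counts = obs.sum(axis=0)
    if (row_counts < 2).any() or (col_counts < 2).any():
        bad_r = np.flatnonzero(row_counts < 2).tolist()
        bad_c = np.flatnonzero(col_counts < 2).tolist()
        raise DegeneratePlateError(
            f"rows {bad_r} / columns {bad_c} have fewer than 2 observations"
        )
    if init not in ("least_squares", "zero"):
        raise InputValidationError(f"unknown init {init!r}")

    n_rows, n_cols = z.shape
    overall = 0.0
    row = np.zeros(n_rows)
    col = np.zeros(n_cols)
    if init == "least_squares":
        overall = float(np.nanmean(z))
        row = np.nanmean(z, axis=1) - overall
        col = np.nanmean(z - row[:, None], axis=0) - overall
        z = z - overall - row[:, None] - col[None, :]

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rdelta = np.nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        shift_c = float(np.median(col))
        col -= shift_c
        overall += shift_c
        cdelta = np.nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        shift_r = float(np.median(row))
        row -= shift_r
        overall += shift_r
        delta = max(
            float(np.max(np.abs(rdelta))),
            float(np.max(np.abs(cdelta))),
            abs(shift_c),
            abs(shift_r),
        )
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"median polish did not converge in {max_iter} iterations "
            f"(last delta {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PolishDecomposition(overall, row, col, z, iterations, converged)


def b_score_plate(
    plate: PlateGrid, tol: float = 1e-6, max_iter: int = 100, init: str = "least_squares"
) -> tuple[np.ndarray, PolishDecomposition]:
    """B-scores for every measured well of one plate.

    The polish fits on all measured wells (samples and controls); the MAD
    denominator uses sample-well residuals only.  Returns the per-well
    b-score matrix (NaN for missing wells) and the decomposition.
    """
    decomp = median_polish(plate.signals, tol=tol, max_iter=max_iter, init=init)
    sample = plate.sample_mask
    if not sample.any():
        raise DegeneratePlateError(
            f"plate {plate.plate_id} replicate {plate.replicate_id}: no sample wells"
        )
    mad = float(np.median(np.abs(decomp.residuals[sample])))
    sig = plate.signals[sample]
    raw_mad = float(np.median(np.abs(sig - np.median(sig))))
    # raw_mad == 0 means the majority of sample wells are identical; a residual
    # MAD negligible against the raw spread means the polish explained the
    # plate exactly (duplicated/additive layout).  Both leave no usable scale.
    if mad == 0.0 or raw_mad == 0.0 or mad < 1e-9 * raw_mad:
        raise DegeneratePlateError(
            f"plate {plate.plate_id} replicate {plate.replicate_id}: "
            "zero MAD of sample-well residuals (constant or duplicated plate)"
        )
    return decomp.residuals / (MAD_CONSISTENCY * mad), decomp


def b_score_screen(
    wells: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 100,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Apply per-plate B-scoring to a whole screen.

    Returns a table ``gene_id, replicate, plate, b_score`` covering every
    sample well.  Degenerate plates either abort (``on_degenerate="raise"``,
    listing all failures) or are skipped with a warning (``"skip"``); skipped
    plates are recorded in ``result.attrs["degenerate_plates"]``.  Genes
    missing from some replicates are flagged via a ``complete`` column.
    """
    if on_degenerate not in ("raise", "skip"):
        raise InputValidationError("on_degenerate must be 'raise' or 'skip'")
    missing_cols = set(WELL_COLUMNS) - set(wells.columns)
    if missing_cols:
        raise InputValidationError(f"well table missing columns: {sorted(missing_cols)}")
    records = []
    failures = []
    for (rep, plate_id), sub in wells.groupby(["replicate", "plate"], sort=True):
        grid = PlateGrid.from_frame(sub)
        try:
            scores, _ = b_score_plate(grid, tol=tol, max_iter=max_iter)
        except DegeneratePlateError as exc:
            failures.append((int(rep), int(plate_id), str(exc)))
            continue
        mask = grid.sample_mask
        for i, j in zip(*np.nonzero(mask)):
            records.append(
                (grid.gene_id[i, j], int(rep), int(plate_id), float(scores[i, j]))
            )
    if failures and on_degenerate == "raise":
        detail = "; ".join(f"replicate {r} plate {p}: {m}" for r, p, m in failures)
        raise DegeneratePlateError(f"{len(failures)} degenerate plate(s): {detail}")
    out = pd.DataFrame(records, columns=BSCORE_COLUMNS)
    if failures:
        warnings.warn(
            f"skipped {len(failures)} degenerate plate(s)", RuntimeWarning, stacklevel=2
        )
    n_rep = out["replicate"].nunique() if len(out) else 0
    counts = out.groupby("gene_id")["replicate"].nunique() if len(out) else pd.Series(dtype=int)
    incomplete = set(counts[counts < n_rep].index)
    out["complete"] = ~out["gene_id"].isin(incomplete)
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} gene(s) missing from some replicates",
            RuntimeWarning,
            stacklevel=2,
        )
    out.attrs["degenerate_plates"] = failures
    return out
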