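"""Readout-normalization arithmetic for secretion and expression assays.

Covers the conventions used around plate screens: dividing a target signal by
a loading control (actin, housekeeping mRNA, nuclei count), fold change of
condition means against a reference condition, and mean +/- SEM replicate
summaries.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InputValidationError


def normalized_signal(target_signal: float, control_signal: float) -> float:
    """Target divided by its loading control (must be positive)."""
    if not (math.isfinite(target_signal) and math.isfinite(control_signal)):
        raise InputValidationError("signals must be finite")
    if control_signal <= 0:
        raise InputValidationError("control_signal must be > 0")
    if target_signal < 0:
        raise InputValidationError("target_signal must be >= 0")
    return target_signal / control_signal


def relative_fold_change(samples, reference) -> float:
    """mean(samples) / mean(reference) of normalized signals."""
    samples = np.asarray(samples, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if samples.size == 0 or reference.size == 0:
        raise InputValidationError("samples and reference must be non-empty")
    ref_mean = float(np.mean(reference))
    if ref_mean == 0:
        raise InputValidationError("reference mean is zero; fold change undefined")
    return float(np.mean(samples)) / ref_mean


def replicate_summary(values) -> tuple[float, float]:
    """(mean, SEM); SEM = SD/sqrt(n) with n-1 SD, NaN when n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputValidationError("empty replicate vector")
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, float("nan")
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size))
    return mean, sem


def summarize_intensities(
    table: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Tidy per-condition summary of an intensity table.

    ``table`` columns: ``sample_id, condition, replicate, target_signal,
    control_signal``.  Each row is control-normalized, conditions are
    summarized as mean +/- SEM, and fold change is the ratio of condition
    means against the reference condition.
    """
    required = {"sample_id", "condition", "replicate", "target_signal", "control_signal"}
    if not required <= set(table.columns):
        raise InputValidationError(f"intensity table needs columns {sorted(required)}")
    if reference_condition not in set(table["condition"]):
        raise InputValidationError(
            f"reference condition {reference_condition!r} absent from table"
        )
    norm = [
        normalized_signal(t, c)
        for t, c in zip(table["target_signal"], table["control_signal"])
    ]
    work = table.assign(normalized=norm)
    ref_values = work.loc[work["condition"] == reference_condition, "normalized"]
    rows = []
    for cond, sub in work.groupby("condition", sort=True):
        mean, sem = replicate_summary(sub["normalized"].to_numpy())
        fold = relative_fold_change(sub["normalized"].to_numpy(), ref_values.to_numpy())
        rows.append((cond, len(sub), mean, sem, fold))
    return pd.DataFrame(
        rows, columns=["condition", "n", "mean", "sem", "fold_change_vs_reference"]
    )
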