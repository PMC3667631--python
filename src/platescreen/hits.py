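"""Hit classification: primary B-score thresholding, validation z-scoring
against a mock band, and the annotation/expression triage filters.

Primary stage: a gene is hyposecretory when its median B-score across
replicates is strictly below -threshold, hypersecretory strictly above
+threshold (default 1.5), otherwise none.  Rank-product statistics annotate
but never gate the call.

Validation stage: signals are z-scored platewise, z = (x - mean(xn)) / SD(xn)
over a plate's measured wells (sample SD, n-1).  A gene validates when its
mean z across replicates falls outside mean(mock z) +/- n_sd * SD(mock z)
(default 2 SD; +PMA mock-transfected wells define the band).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .errors import (
    DegenerateControlError,
    DegeneratePlateError,
    InputValidationError,
)
from .synthetic import WELL_EMPTY, WELL_MOCK_PLUS

CLASS_HYPO = "hyposecretory"
CLASS_HYPER = "hypersecretory"
CLASS_NONE = "none"

PRIMARY_COLUMNS = ["gene_id", "median_b", "n_replicates", "complete", "hit_class"]
VALIDATION_COLUMNS = ["gene_id", "mean_z", "n_replicates", "validated_class"]


def classify_primary(
    b_table: pd.DataFrame,
    threshold: float = 1.5,
    rp_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Median-B-score hit classification (strict inequality at the threshold)."""
    if threshold <= 0:
        raise InputValidationError("threshold must be > 0")
    required = {"gene_id", "replicate", "b_score"}
    if not required <= set(b_table.columns):
        raise InputValidationError(f"b-score table needs columns {sorted(required)}")
    if len(b_table) == 0:
        raise InputValidationError("empty b-score table")
    grouped = b_table.groupby("gene_id")["b_score"]
    med = grouped.median()
    n_rep = grouped.size()
    out = pd.DataFrame(
        {
            "gene_id": med.index,
            "median_b": med.to_numpy(),
            "n_replicates": n_rep.to_numpy(),
        }
    )
    out["complete"] = out["n_replicates"] == out["n_replicates"].max()
    cls = np.full(len(out), CLASS_NONE, dtype=object)
    cls[out["median_b"].to_numpy() < -threshold] = CLASS_HYPO
    cls[out["median_b"].to_numpy() > threshold] = CLASS_HYPER
    out["hit_class"] = cls
    if rp_table is not None:
        out = out.merge(rp_table, on="gene_id", how="left")
    return out.reset_index(drop=True)


def z_score_platewise(signals, xi: float) -> float:
    """(xi - mean(xn)) / SD(xn) with the sample (n-1) standard deviation."""
    signals = np.asarray(signals, dtype=float)
    if signals.size < 2:
        raise InputValidationError("need at least 2 wells to z-score")
    if not np.isfinite(signals).all() or not np.isfinite(xi):
        raise InputValidationError("non-finite signal in z-score input")
    sd = float(np.std(signals, ddof=1))
    if sd == 0.0:
        raise DegeneratePlateError("zero SD across plate wells")
    return (float(xi) - float(np.mean(signals))) / sd


def validation_z_table(wells: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Platewise z-scores for a validation screen.

    xn is each plate's full measured population (sample and mock wells).
    Returns per-sample-well z-scores (``gene_id, replicate, plate, z``) and
    the pooled z-scores of the +PMA mock wells across all plates.
    """
    z_records = []
    mock_z = []
    measured = wells[(wells["well_type"] != WELL_EMPTY) & wells["signal"].notna()]
    for (rep, plate_id), sub in measured.groupby(["replicate", "plate"], sort=True):
        x = sub["signal"].to_numpy(dtype=float)
        if len(x) < 2:
            raise DegeneratePlateError(
                f"replicate {rep} plate {plate_id}: fewer than 2 measured wells"
            )
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise DegeneratePlateError(
                f"replicate {rep} plate {plate_id}: zero SD across wells"
            )
        z = (x - float(np.mean(x))) / sd
        types = sub["well_type"].to_numpy()
        genes = sub["gene_id"].to_numpy()
        for zi, t, g in zip(z, types, genes):
            if t == "sample":
                z_records.append((g, int(rep), int(plate_id), float(zi)))
            elif t == WELL_MOCK_PLUS:
                mock_z.append(float(zi))
    return (
        pd.DataFrame(z_records, columns=["gene_id", "replicate", "plate", "z"]),
        np.asarray(mock_z),
    )


def classify_validation(
    z_table: pd.DataFrame, mock_z, n_sd: float = 2.0
) -> pd.DataFrame:
    """Mock-band classification of validation z-scores.

    hyposecretory  if mean_z < mean(mock_z) - n_sd * SD(mock_z)
    hypersecretory if mean_z > mean(mock_z) + n_sd * SD(mock_z)
    """
    if n_sd <= 0:
        raise InputValidationError("n_sd must be > 0")
    mock_z = np.asarray(mock_z, dtype=float)
    if mock_z.size < 2:
        raise InputValidationError("need at least 2 mock measurements")
    sd_mock = float(np.std(mock_z, ddof=1))
    if sd_mock == 0.0:
        raise DegenerateControlError("zero SD among mock z-scores")
    mean_mock = float(np.mean(mock_z))
    lo = mean_mock - n_sd * sd_mock
    hi = mean_mock + n_sd * sd_mock
    grouped = z_table.groupby("gene_id")["z"]
    mean_z = grouped.mean()
    out = pd.DataFrame(
        {
            "gene_id": mean_z.index,
            "mean_z": mean_z.to_numpy(),
            "n_replicates": grouped.size().to_numpy(),
        }
    )
    cls = np.full(len(out), CLASS_NONE, dtype=object)
    cls[out["mean_z"].to_numpy() < lo] = CLASS_HYPO
    cls[out["mean_z"].to_numpy() > hi] = CLASS_HYPER
    out["validated_class"] = cls
    out.attrs["mean_mock_z"] = mean_mock
    out.attrs["sd_mock_z"] = sd_mock
    return out.reset_index(drop=True)


def filter_by_annotation(
    hits: pd.DataFrame, annotations: pd.DataFrame, blocklist
) -> pd.DataFrame:
    """Drop hits whose annotation categories intersect the blocklist.

    Matching is case-insensitive and any-match: one blocked category removes
    the gene.  Unannotated genes are retained and flagged
    (``annotated = False``).
    """
    blocked = {str(c).strip().lower() for c in blocklist}
    required = {"gene_id", "category"}
    if not required <= set(annotations.columns):
        raise InputValidationError(f"annotation table needs columns {sorted(required)}")
    cats = (
        annotations.assign(category=annotations["category"].str.strip().str.lower())
        .groupby("gene_id")["category"]
        .agg(set)
    )
    annotated = hits["gene_id"].isin(cats.index)
    removed = hits["gene_id"].map(
        lambda g: bool(cats.get(g, set()) & blocked)
    )
    out = hits[~removed].copy()
    out["annotated"] = annotated[~removed].to_numpy()
    return out.reset_index(drop=True)


def expression_filter(
    calls: pd.DataFrame, detection_floor: float = 0.05, alpha: float = 0.05
) -> pd.DataFrame:
    """Housekeeping-normalized expression detection and regulation calls.

    ``calls`` columns: ``gene_id, condition, replicate, gene_intensity,
    housekeeping_intensity`` with condition in {nonstarved, starved}.
    Relative expression per condition = mean of per-replicate
    gene/housekeeping ratios; a gene is detected when that exceeds the floor
    in either condition.  Regulation is up/down when a two-sided Welch test
    on the two ratio vectors gives p < alpha (requires >= 2 replicates per
    condition), else unchanged.
    """
    required = {
        "gene_id", "condition", "replicate", "gene_intensity", "housekeeping_intensity",
    }
    if not required <= set(calls.columns):
        raise InputValidationError(f"expression table needs columns {sorted(required)}")
    hk = calls["housekeeping_intensity"]
    if hk.isna().any() or (hk <= 0).any():
        raise InputValidationError("housekeeping intensities must be present and > 0")
    bad_cond = set(calls["condition"]) - {"nonstarved", "starved"}
    if bad_cond:
        raise InputValidationError(f"unknown conditions: {sorted(bad_cond)}")
    work = calls.assign(ratio=calls["gene_intensity"] / hk)
    rows = []
    for gene, sub in work.groupby("gene_id"):
        ns = sub.loc[sub["condition"] == "nonstarved", "ratio"].to_numpy()
        st = sub.loc[sub["condition"] == "starved", "ratio"].to_numpy()
        rel_ns = float(np.mean(ns)) if len(ns) else np.nan
        rel_st = float(np.mean(st)) if len(st) else np.nan
        detected = bool(
            (len(ns) and rel_ns > detection_floor)
            or (len(st) and rel_st > detection_floor)
        )
        regulation = "unchanged"
        pval = np.nan
        if len(ns) >= 2 and len(st) >= 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = ttest_ind(st, ns, equal_var=False)
            pval = float(stat.pvalue)
            if np.isfinite(pval) and pval < alpha:
                regulation = "up" if rel_st > rel_ns else "down"
        rows.append(
            (gene, rel_ns, rel_st, detected, pval, regulation)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "relative_nonstarved",
            "relative_starved",
            "detected",
            "p_value",
            "regulation",
        ],
    )
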