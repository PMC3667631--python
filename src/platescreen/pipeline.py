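"""End-to-end orchestration: simulate -> B-score -> rank product -> primary
selection -> annotation filter -> validation rescreen -> report.

A run is a pure function of its :class:`RunConfig`; every stage artifact is
written as CSV with the seed and config hash embedded in a header comment,
and the report summarizes the hit funnel plus (when simulation truth exists)
a confusion matrix per stage.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import hits as hitmod
from . import io as pio
from .errors import InputValidationError
from .polish import b_score_screen
from .rankprod import rank_product_analysis
from .synthetic import (
    EffectModel,
    ScreenDesign,
    WELL_MOCK_MINUS,
    WELL_MOCK_PLUS,
    simulate_screen,
    simulate_validation_screen,
)


@dataclass
class RunConfig:
    """Every knob of a pipeline run; serializable to/from YAML."""

    seed: int = 0
    # screen design
    n_genes: int = 2000
    n_replicates: int = 3
    sample_wells_per_plate: int = 88
    mock_plus_wells: int = 4
    mock_minus_wells: int = 4
    # effect model
    baseline_signal: float = 1000.0
    minus_pma_fraction: float = 0.3
    plate_effect_sd: float = 0.1
    row_effect_sd: float = 0.05
    col_effect_sd: float = 0.05
    noise_cv: float = 0.1
    hypo_fraction: float = 0.05
    hyper_fraction: float = 0.02
    hypo_effect: float = 0.25
    hyper_effect: float = 2.5
    # normalization
    bscore_tol: float = 1e-6
    bscore_max_iter: int = 100
    # selection
    primary_threshold: float = 1.5
    n_perm: int = 100
    validation_n_sd: float = 2.0
    detection_floor: float = 0.05
    blocklist: list[str] = field(default_factory=list)
    annotation_file: str | None = None
    expression_file: str | None = None
    # stage toggles
    do_rank_product: bool = True
    do_validation: bool = True

    def __post_init__(self):
        for name in ("primary_threshold", "validation_n_sd", "bscore_tol"):
            if getattr(self, name) <= 0:
                raise InputValidationError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def design(self) -> ScreenDesign:
        return ScreenDesign(
            n_genes=self.n_genes,
            n_replicates=self.n_replicates,
            sample_wells_per_plate=self.sample_wells_per_plate,
            controls_per_plate={
                WELL_MOCK_PLUS: self.mock_plus_wells,
                WELL_MOCK_MINUS: self.mock_minus_wells,
            },
            seed=self.seed,
        )

    def effects(self) -> EffectModel:
        return EffectModel(
            baseline_signal=self.baseline_signal,
            minus_pma_fraction=self.minus_pma_fraction,
            plate_effect_sd=self.plate_effect_sd,
            row_effect_sd=self.row_effect_sd,
            col_effect_sd=self.col_effect_sd,
            noise_cv=self.noise_cv,
            hypo_fraction=self.hypo_fraction,
            hyper_fraction=self.hyper_fraction,
            hypo_effect=self.hypo_effect,
            hyper_effect=self.hyper_effect,
        )


def _confusion(called: pd.DataFrame, class_col: str, truth: pd.DataFrame) -> dict:
    """Direction-aware confusion counts against the truth table.

    A call is a true positive only when its direction matches the spiked
    class; wrong-direction calls count as false positives.
    """
    truth_map = dict(zip(truth["gene_id"], truth["true_class"]))
    match = {hitmod.CLASS_HYPO: "hypo", hitmod.CLASS_HYPER: "hyper"}
    tp = fp = fn = tn = 0
    for gene, call in zip(called["gene_id"], called[class_col]):
        true_cls = truth_map.get(gene, "null")
        if call in match:
            if match[call] == true_cls:
                tp += 1
            else:
                fp += 1
        else:
            if true_cls == "null":
                tn += 1
            else:
                fn += 1
    n_true = tp + fn
    n_called = tp + fp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / n_true if n_true else None,
        "fdr": fp / n_called if n_called else None,
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured run; writes all stage CSVs plus report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, config.config_hash()

    def _write(df: pd.DataFrame, name: str) -> None:
        pio.write_table(df, outdir / name, seed=seed, config_hash=chash)

    design = config.design()
    effects = config.effects()
    wells, truth = simulate_screen(design, effects)
    pio.write_well_table(wells, outdir / "wells.csv", seed=seed, config_hash=chash)
    _write(truth, "truth.csv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        b_table = b_score_screen(
            wells,
            tol=config.bscore_tol,
            max_iter=config.bscore_max_iter,
            on_degenerate="skip",
        )
    degenerate = list(b_table.attrs.get("degenerate_plates", []))
    _write(b_table, "bscores.csv")

    rp_table = None
    if config.do_rank_product:
        rp_table = rank_product_analysis(
            b_table, n_perm=config.n_perm, seed=config.seed
        )
        _write(rp_table, "rankprod.csv")

    primary = hitmod.classify_primary(
        b_table, threshold=config.primary_threshold, rp_table=rp_table
    )
    _write(primary, "primary_hits.csv")
    primary_hits = primary[primary["hit_class"] != hitmod.CLASS_NONE]

    filtered_hits = primary_hits
    if config.annotation_file:
        annotations = pio.read_annotation_table(config.annotation_file)
        filtered_hits = hitmod.filter_by_annotation(
            primary_hits, annotations, config.blocklist
        )
    _write(filtered_hits, "filtered_hits.csv")

    report: dict = {
        "seed": seed,
        "config_hash": chash,
        "degenerate_plates": [
            {"replicate": r, "plate": p, "reason": m} for r, p, m in degenerate
        ],
        "funnel": {
            "screened": int(truth["gene_id"].nunique()),
            "primary_hyposecretory": int(
                (primary["hit_class"] == hitmod.CLASS_HYPO).sum()
            ),
            "primary_hypersecretory": int(
                (primary["hit_class"] == hitmod.CLASS_HYPER).sum()
            ),
            "after_annotation_filter": int(len(filtered_hits)),
        },
        "confusion": {"primary": _confusion(primary, "hit_class", truth)},
    }

    if config.do_validation and len(filtered_hits) > 0:
        vwells = simulate_validation_screen(
            filtered_hits["gene_id"].tolist(), truth, effects, design
        )
        pio.write_well_table(
            vwells, outdir / "validation_wells.csv", seed=seed, config_hash=chash
        )
        z_table, mock_z = hitmod.validation_z_table(vwells)
        validated = hitmod.classify_validation(
            z_table, mock_z, n_sd=config.validation_n_sd
        )
        _write(validated, "validation_hits.csv")
        report["funnel"]["validated_hyposecretory"] = int(
            (validated["validated_class"] == hitmod.CLASS_HYPO).sum()
        )
        report["funnel"]["validated_hypersecretory"] = int(
            (validated["validated_class"] == hitmod.CLASS_HYPER).sum()
        )
        report["confusion"]["validation"] = _confusion(
            validated, "validated_class", truth
        )

    if config.expression_file:
        calls = pio.read_expression_table(config.expression_file)
        expressed = hitmod.expression_filter(
            calls, detection_floor=config.detection_floor
        )
        _write(expressed, "expression_calls.csv")
        report["funnel"]["expressed"] = int(expressed["detected"].sum())

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def write_config_yaml(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
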