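"""Synthetic 96-well screen generator.

Produces long-format well tables with the statistical structure the downstream
stages assume: multiplicative plate effects, additive (log-scale) row/column
gradients, lognormal per-well noise, mock control wells at two levels, and
spiked hypo-/hyper-secretory genes with a ground-truth table.

All signals are strictly positive.  The generative model for a sample well of
gene ``g`` at row ``i``, column ``j`` of plate ``p`` is::

    signal = baseline * plate_mult_p * exp(row_i + col_j) * effect_g * noise

where ``noise`` is lognormal with unit mean and coefficient of variation
``noise_cv``.  Mock wells use ``effect = 1`` (+PMA) or ``minus_pma_fraction``
(-PMA).  A single integer seed drives everything; per-(replicate, plate)
substreams keep output independent of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, InputValidationError

N_ROWS = 8
N_COLS = 12
ROW_LABELS = "ABCDEFGH"
CONTROL_COL = N_COLS  # 1-based column holding mock wells

WELL_SAMPLE = "sample"
WELL_MOCK_PLUS = "mock_plusPMA"
WELL_MOCK_MINUS = "mock_minusPMA"
WELL_EMPTY = "empty"
WELL_TYPES = (WELL_SAMPLE, WELL_MOCK_PLUS, WELL_MOCK_MINUS, WELL_EMPTY)

WELL_COLUMNS = ["replicate", "plate", "row", "col", "well_type", "gene_id", "signal"]

# RNG stream tags: distinct substreams per purpose so layouts/noise never alias.
_TAG_TRUTH = 11
_TAG_PRIMARY = 17
_TAG_VALIDATION = 29


@dataclass(frozen=True)
class ScreenDesign:
    """Plate layout and replication parameters of a screen."""

    n_genes: int
    wells_per_plate: int = 96
    sample_wells_per_plate: int = 88
    n_replicates: int = 3
    controls_per_plate: Mapping[str, int] = field(
        default_factory=lambda: {WELL_MOCK_PLUS: 4, WELL_MOCK_MINUS: 4}
    )
    seed: int = 0

    def __post_init__(self):
        if self.wells_per_plate != N_ROWS * N_COLS:
            raise DesignError(
                f"only {N_ROWS}x{N_COLS} plates are supported "
                f"(got wells_per_plate={self.wells_per_plate})"
            )
        if self.n_genes < 0:
            raise DesignError("n_genes must be >= 0")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        max_sample = N_ROWS * (N_COLS - 1)
        if not 1 <= self.sample_wells_per_plate <= max_sample:
            raise DesignError(
                f"sample_wells_per_plate must be in [1, {max_sample}]"
            )
        unknown = set(self.controls_per_plate) - {WELL_MOCK_PLUS, WELL_MOCK_MINUS}
        if unknown:
            raise DesignError(f"unknown control labels: {sorted(unknown)}")
        n_controls = sum(self.controls_per_plate.values())
        if any(v < 0 for v in self.controls_per_plate.values()):
            raise DesignError("control counts must be >= 0")
        if n_controls > N_ROWS:
            raise DesignError(
                f"at most {N_ROWS} control wells fit in column {CONTROL_COL}"
            )
        if self.sample_wells_per_plate + n_controls > self.wells_per_plate:
            raise DesignError("sample + control wells exceed plate capacity")

    @property
    def n_plates(self) -> int:
        return max(1, math.ceil(self.n_genes / self.sample_wells_per_plate))


@dataclass(frozen=True)
class EffectModel:
    """Generative parameters: artifact magnitudes, noise, and spiked effects."""

    baseline_signal: float = 1000.0
    minus_pma_fraction: float = 0.3
    plate_effect_sd: float = 0.1
    row_effect_sd: float = 0.05
    col_effect_sd: float = 0.05
    noise_cv: float = 0.1
    hypo_fraction: float = 0.0
    hyper_fraction: float = 0.0
    hypo_effect: float = 0.25
    hyper_effect: float = 2.5

    def __post_init__(self):
        if self.baseline_signal <= 0:
            raise InputValidationError("baseline_signal must be > 0")
        if not 0 < self.minus_pma_fraction < 1:
            raise InputValidationError("minus_pma_fraction must be in (0, 1)")
        for name in ("plate_effect_sd", "row_effect_sd", "col_effect_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise InputValidationError(f"{name} must be >= 0")
        if not (0 <= self.hypo_fraction < 1 and 0 <= self.hyper_fraction < 1):
            raise InputValidationError("hit fractions must be in [0, 1)")
        if self.hypo_fraction + self.hyper_fraction >= 1:
            raise InputValidationError("hypo_fraction + hyper_fraction must be < 1")
        if not 0 < self.hypo_effect < 1:
            raise InputValidationError("hypo_effect must be in (0, 1)")
        if self.hyper_effect <= 1:
            raise InputValidationError("hyper_effect must be > 1")


def gene_ids(n: int) -> list[str]:
    return [f"gene_{i:05d}" for i in range(n)]


def make_truth_table(design: ScreenDesign, effects: EffectModel) -> pd.DataFrame:
    """Assign hypo/hyper/null classes to genes; counts follow the requested
    fractions (rounded), membership is drawn from the design seed."""
    n = design.n_genes
    ids = gene_ids(n)
    n_hypo = round(n * effects.hypo_fraction)
    n_hyper = round(n * effects.hyper_fraction)
    rng = np.random.default_rng([design.seed, _TAG_TRUTH])
    order = rng.permutation(n)
    cls = np.full(n, "null", dtype=object)
    eff = np.ones(n)
    cls[order[:n_hypo]] = "hypo"
    eff[order[:n_hypo]] = effects.hypo_effect
    cls[order[n_hypo:n_hypo + n_hyper]] = "hyper"
    eff[order[n_hypo:n_hypo + n_hyper]] = effects.hyper_effect
    return pd.DataFrame({"gene_id": ids, "true_class": cls, "effect": eff})


def _sample_positions(design: ScreenDesign) -> list[tuple[int, int]]:
    # diagonal fill over the 8x11 sample region (column 12 is reserved):
    # j -> (j mod 8, j mod 11) is a bijection (gcd(8, 11) = 1), so partially
    # filled plates stay evenly covered in both rows and columns
    pos = [(j % N_ROWS, j % (N_COLS - 1)) for j in range(N_ROWS * (N_COLS - 1))]
    return pos[: design.sample_wells_per_plate]


def _layout(genes: Sequence[str], design: ScreenDesign) -> pd.DataFrame:
    """Full plate layout for a gene list: every well of every plate gets a row.

    Genes go round-robin across plates (gene i -> plate i mod P), filling
    sample positions row-major; controls sit in fixed rows of the last column.
    """
    n = len(genes)
    n_plates = max(1, math.ceil(n / design.sample_wells_per_plate))
    positions = _sample_positions(design)
    grid_type = np.full((n_plates, N_ROWS, N_COLS), WELL_EMPTY, dtype=object)
    grid_gene = np.full((n_plates, N_ROWS, N_COLS), "", dtype=object)
    for i, g in enumerate(genes):
        p = i % n_plates
        j = i // n_plates
        if j >= len(positions):
            raise DesignError(f"gene {g} does not fit the layout")
        r, c = positions[j]
        grid_type[p, r, c] = WELL_SAMPLE
        grid_gene[p, r, c] = g
    ctrl_row = 0
    for label in (WELL_MOCK_PLUS, WELL_MOCK_MINUS):
        for _ in range(design.controls_per_plate.get(label, 0)):
            grid_type[:, ctrl_row, CONTROL_COL - 1] = label
            ctrl_row += 1
    plates, rows, cols = np.meshgrid(
        np.arange(n_plates), np.arange(N_ROWS), np.arange(N_COLS), indexing="ij"
    )
    return pd.DataFrame(
        {
            "plate": plates.ravel() + 1,
            "row": np.array(list(ROW_LABELS))[rows.ravel()],
            "col": cols.ravel() + 1,
            "well_type": grid_type.ravel(),
            "gene_id": grid_gene.ravel(),
        }
    )


def plate_artifacts(
    seed: int, replicate: int, plate: int, effects: EffectModel, stream: str = "primary"
) -> tuple[float, np.ndarray, np.ndarray]:
    """Systematic artifacts of one physical plate: (plate multiplier,
    log-scale row effects, log-scale column effects).

    Deterministic in (seed, replicate, plate); ``simulate_screen`` draws the
    same values, so tests can recover the injected spatial gradients.
    """
    tag = _TAG_PRIMARY if stream == "primary" else _TAG_VALIDATION
    rng = _plate_rng(seed, tag, replicate, plate)
    plate_mult = float(np.exp(rng.normal(0.0, effects.plate_effect_sd)))
    row_eff = rng.normal(0.0, effects.row_effect_sd, N_ROWS)
    col_eff = rng.normal(0.0, effects.col_effect_sd, N_COLS)
    return plate_mult, row_eff, col_eff


def _plate_rng(seed: int, tag: int, replicate: int, plate: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, replicate, plate])


def _simulate_wells(
    layout: pd.DataFrame,
    effect_of: Mapping[str, float],
    design: ScreenDesign,
    effects: EffectModel,
    seed: int,
    tag: int,
) -> pd.DataFrame:
    sigma = math.sqrt(math.log1p(effects.noise_cv**2))
    frames = []
    n_plates = int(layout["plate"].max())
    stream = "primary" if tag == _TAG_PRIMARY else "validation"
    for rep in range(1, design.n_replicates + 1):
        for p in range(1, n_plates + 1):
            sub = layout[layout["plate"] == p].copy()
            plate_mult, row_eff, col_eff = plate_artifacts(
                seed, rep, p, effects, stream=stream
            )
            rng = _plate_rng(seed, tag, rep, p)
            # skip the artifact draws so noise continues the same stream
            rng.normal(0.0, effects.plate_effect_sd)
            rng.normal(0.0, effects.row_effect_sd, N_ROWS)
            rng.normal(0.0, effects.col_effect_sd, N_COLS)
            ridx = sub["row"].map({lab: i for i, lab in enumerate(ROW_LABELS)}).to_numpy()
            cidx = sub["col"].to_numpy() - 1
            mult = np.array(
                [
                    effect_of[g]
                    if t == WELL_SAMPLE
                    else (1.0 if t == WELL_MOCK_PLUS
                          else (effects.minus_pma_fraction if t == WELL_MOCK_MINUS else np.nan))
                    for t, g in zip(sub["well_type"], sub["gene_id"])
                ]
            )
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, len(sub)))
            signal = (
                effects.baseline_signal
                * plate_mult
                * np.exp(row_eff[ridx] + col_eff[cidx])
                * mult
                * noise
            )
            sub.insert(0, "replicate", rep)
            sub["signal"] = signal
            frames.append(sub)
    wells = pd.concat(frames, ignore_index=True)
    return wells[WELL_COLUMNS]


def simulate_screen(
    design: ScreenDesign, effects: EffectModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full primary screen.

    Returns
    -------
    wells : DataFrame
        One row per (replicate, plate, well) with columns
        ``replicate, plate, row, col, well_type, gene_id, signal``.
        Empty wells carry NaN signal.
    truth : DataFrame
        ``gene_id, true_class, effect`` ground-truth labels.
    """
    truth = make_truth_table(design, effects)
    layout = _layout(truth["gene_id"].tolist(), design)
    effect_of = dict(zip(truth["gene_id"], truth["effect"]))
    wells = _simulate_wells(layout, effect_of, design, effects, design.seed, _TAG_PRIMARY)
    return wells, truth


def simulate_validation_screen(
    genes: Sequence[str],
    truth: pd.DataFrame,
    effects: EffectModel,
    design: ScreenDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rescreen a gene subset: same generative model, fresh layout and noise.

    The layout is a deterministic function of the gene list and design only;
    a different ``seed`` redraws signals but not positions.
    """
    known = dict(zip(truth["gene_id"], truth["effect"]))
    missing = [g for g in genes if g not in known]
    if missing:
        raise LookupError(f"genes absent from truth table: {missing[:5]}")
    layout = _layout(list(genes), design)
    if seed is None:
        seed = design.seed
    return _simulate_wells(layout, known, design, effects, seed, _TAG_VALIDATION)
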