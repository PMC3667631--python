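import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from platescreen import (
    DegenerateControlError,
    DegeneratePlateError,
    EffectModel,
    InputValidationError,
    ScreenDesign,
    b_score_screen,
    classify_primary,
    classify_validation,
    expression_filter,
    filter_by_annotation,
    simulate_screen,
    simulate_validation_screen,
    validation_z_table,
    z_score_platewise,
)


def b_table_from_medians(medians):
    rows = [(f"g{i}", 1, m) for i, m in enumerate(medians)]
    return pd.DataFrame(rows, columns=["gene_id", "replicate", "b_score"])


class TestClassifyPrimary:
    def test_direct_rule(self):
        out = classify_primary(b_table_from_medians([-1.6, 1.6, 0.0]))
        assert out.hit_class.tolist() == [
            "hyposecretory", "hypersecretory", "none",
        ]

    def test_strict_boundary(self):
        out = classify_primary(b_table_from_medians([-1.5, 1.5]))
        assert out.hit_class.tolist() == ["none", "none"]

    def test_median_across_replicates(self):
        rows = [("g0", 1, -2.0), ("g0", 2, -1.0), ("g0", 3, -3.0)]
        table = pd.DataFrame(rows, columns=["gene_id", "replicate", "b_score"])
        out = classify_primary(table)
        assert out.median_b.iloc[0] == -2.0
        assert out.hit_class.iloc[0] == "hyposecretory"

    def test_incomplete_gene_flagged_but_classified(self):
        rows = [("g0", 1, -2.0), ("g0", 2, -2.0), ("g1", 1, -2.0)]
        table = pd.DataFrame(rows, columns=["gene_id", "replicate", "b_score"])
        out = classify_primary(table).set_index("gene_id")
        assert not out.loc["g1", "complete"]
        assert out.loc["g1", "hit_class"] == "hyposecretory"

    def test_empty_rejected(self):
        with pytest.raises(InputValidationError):
            classify_primary(
                pd.DataFrame(columns=["gene_id", "replicate", "b_score"])
            )

    def test_monotone_in_threshold(self):
        medians = np.linspace(-3, 3, 25)
        loose = classify_primary(b_table_from_medians(medians), threshold=1.0)
        strict = classify_primary(b_table_from_medians(medians), threshold=2.0)
        was_hit = set(strict[strict.hit_class != "none"].gene_id)
        now_hit = set(loose[loose.hit_class != "none"].gene_id)
        assert was_hit <= now_hit

    def test_rp_annotations_carried(self):
        table = b_table_from_medians([-2.0, 2.0])
        rp = pd.DataFrame({"gene_id": ["g0", "g1"], "rp_down": [1.0, 2.0]})
        out = classify_primary(table, rp_table=rp)
        assert "rp_down" in out.columns

    def test_simulation_recovery(self):
        design = ScreenDesign(n_genes=1000, seed=31)
        effects = EffectModel(
            noise_cv=0.05, hypo_fraction=0.05, hypo_effect=0.2
        )
        wells, truth = simulate_screen(design, effects)
        table = b_score_screen(wells)
        out = classify_primary(table)
        merged = out.merge(truth, on="gene_id")
        hypo = merged[merged.true_class == "hypo"]
        assert len(hypo) == 50
        assert (hypo.hit_class == "hyposecretory").sum() >= 45
        nulls = merged[merged.true_class == "null"]
        false_hypo = (nulls.hit_class != "none").sum()
        # false calls bounded by the tail mass of the null b-score
        # distribution beyond +/-1.5 (see acceptance suite for the exact
        # calibration test)
        assert false_hypo < 0.1 * len(nulls)


class TestZScorePlatewise:
    def test_at_mean(self):
        assert z_score_platewise([2, 4, 6], 4) == 0.0

    def test_hand_computation(self):
        # sample SD of {2,4,6} is 2
        assert z_score_platewise([2, 4, 6], 6) == pytest.approx(1.0)

    def test_location_invariance(self):
        base = [2.0, 4.0, 6.0]
        shifted = [x + 100 for x in base]
        for xi in base:
            assert z_score_platewise(base, xi) == pytest.approx(
                z_score_platewise(shifted, xi + 100)
            )

    def test_degenerate_sd(self):
        with pytest.raises(DegeneratePlateError):
            z_score_platewise([3.0, 3.0, 3.0], 3.0)

    def test_too_few_wells(self):
        with pytest.raises(InputValidationError):
            z_score_platewise([1.0], 1.0)


class TestClassifyValidation:
    def _z_table(self, mean_zs):
        rows = [(f"g{i}", 1, 1, z) for i, z in enumerate(mean_zs)]
        return pd.DataFrame(rows, columns=["gene_id", "replicate", "plate", "z"])

    def test_hypo_below_band(self):
        mock = [-0.1, 0.0, 0.1]  # mean 0, SD 0.1
        out = classify_validation(self._z_table([-0.5]), mock)
        assert out.validated_class.iloc[0] == "hyposecretory"

    def test_within_band_none(self):
        mock = [-0.1, 0.0, 0.1]
        out = classify_validation(self._z_table([0.15]), mock)
        assert out.validated_class.iloc[0] == "none"

    def test_hyper_above_band(self):
        mock = [-0.1, 0.0, 0.1]
        out = classify_validation(self._z_table([0.5]), mock)
        assert out.validated_class.iloc[0] == "hypersecretory"

    def test_mock_band_stats_exposed(self):
        mock = [-0.1, 0.0, 0.1]
        out = classify_validation(self._z_table([0.0]), mock)
        assert out.attrs["mean_mock_z"] == pytest.approx(0.0)
        assert out.attrs["sd_mock_z"] == pytest.approx(0.1)

    def test_degenerate_mocks(self):
        with pytest.raises(DegenerateControlError):
            classify_validation(self._z_table([0.0]), [1.0, 1.0, 1.0])
        with pytest.raises(InputValidationError):
            classify_validation(self._z_table([0.0]), [1.0])

    def test_two_stage_false_positive_suppression(self):
        # primary false positives survive validation less often than true hits
        design = ScreenDesign(n_genes=1500, seed=42)
        effects = EffectModel(hypo_fraction=0.04, hyper_fraction=0.02)
        wells, truth = simulate_screen(design, effects)
        table = b_score_screen(wells)
        primary = classify_primary(table).merge(truth, on="gene_id")
        called = primary[primary.hit_class != "none"]
        fp = called[called.true_class == "null"]
        tp = called[
            ((called.hit_class == "hyposecretory") & (called.true_class == "hypo"))
            | ((called.hit_class == "hypersecretory") & (called.true_class == "hyper"))
        ]
        assert len(fp) > 0 and len(tp) > 0
        vwells = simulate_validation_screen(
            called.gene_id.tolist(), truth, effects, design
        )
        z_table, mock_z = validation_z_table(vwells)
        validated = classify_validation(z_table, mock_z)
        val_class = dict(zip(validated.gene_id, validated.validated_class))
        fp_survive = np.mean([val_class[g] != "none" for g in fp.gene_id])
        tp_survive = np.mean([val_class[g] != "none" for g in tp.gene_id])
        assert fp_survive < tp_survive


class TestValidationZTable:
    def test_platewise_z_and_mock_collection(self):
        design = ScreenDesign(n_genes=30, seed=5)
        effects = EffectModel()
        wells, truth = simulate_screen(design, effects)
        z_table, mock_z = validation_z_table(wells)
        # z-scores of each plate's measured wells have mean ~0 (sample+mock)
        assert len(mock_z) == 4 * 3  # 4 +PMA mocks x 3 replicates x 1 plate
        assert z_table.gene_id.nunique() == 30
        for (_, _), sub in z_table.groupby(["replicate", "plate"]):
            assert abs(sub.z.mean()) < 1.0  # samples only, so not exactly 0

    def test_constant_plate_degenerate(self):
        rows = [
            (1, 1, "A", c, "sample", f"g{c}", 5.0) for c in range(1, 12)
        ]
        wells = pd.DataFrame(
            rows,
            columns=["replicate", "plate", "row", "col", "well_type", "gene_id", "signal"],
        )
        with pytest.raises(DegeneratePlateError):
            validation_z_table(wells)


class TestFilterByAnnotation:
    def _hits(self, genes):
        return pd.DataFrame({"gene_id": genes, "hit_class": ["hyposecretory"] * len(genes)})

    def test_empty_blocklist_identity(self):
        hits = self._hits(["a", "b"])
        ann = pd.DataFrame({"gene_id": ["a"], "category": ["nuclear"]})
        out = filter_by_annotation(hits, ann, set())
        assert out.gene_id.tolist() == ["a", "b"]

    def test_set_difference(self):
        hits = self._hits(["a", "b", "c", "d", "e"])
        ann = pd.DataFrame(
            {"gene_id": ["a", "b"], "category": ["nuclear", "nuclear"]}
        )
        out = filter_by_annotation(hits, ann, {"nuclear"})
        assert out.gene_id.tolist() == ["c", "d", "e"]

    def test_any_match_semantics(self):
        hits = self._hits(["a"])
        ann = pd.DataFrame(
            {"gene_id": ["a", "a"], "category": ["PM", "secreted"]}
        )
        out = filter_by_annotation(hits, ann, {"secreted"})
        assert len(out) == 0

    def test_case_insensitive(self):
        hits = self._hits(["a"])
        ann = pd.DataFrame({"gene_id": ["a"], "category": ["Nuclear"]})
        out = filter_by_annotation(hits, ann, {"NUCLEAR"})
        assert len(out) == 0

    def test_unannotated_retained_and_flagged(self):
        hits = self._hits(["a", "b"])
        ann = pd.DataFrame({"gene_id": ["a"], "category": ["cytosol"]})
        out = filter_by_annotation(hits, ann, {"nuclear"})
        flags = dict(zip(out.gene_id, out.annotated))
        assert flags == {"a": True, "b": False}


class TestExpressionFilter:
    def _calls(self, gene, ns, st_):
        rows = []
        for r, v in enumerate(ns, 1):
            rows.append((gene, "nonstarved", r, v, 1.0))
        for r, v in enumerate(st_, 1):
            rows.append((gene, "starved", r, v, 1.0))
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "condition", "replicate",
                "gene_intensity", "housekeeping_intensity",
            ],
        )

    def test_upregulated(self):
        out = expression_filter(self._calls("g", [1.0, 1.0, 1.0], [2.1, 1.9, 2.0]))
        row = out.iloc[0]
        assert row.detected
        assert row.regulation == "up"
        expected_p = ttest_ind(
            [2.1, 1.9, 2.0], [1.0, 1.0, 1.0], equal_var=False
        ).pvalue
        assert row.p_value == pytest.approx(expected_p)

    def test_all_zero_not_detected(self):
        out = expression_filter(
            self._calls("g", [0.0, 0.0], [0.0, 0.0]), detection_floor=0.05
        )
        assert not out.iloc[0].detected

    def test_identical_conditions_unchanged(self):
        out = expression_filter(self._calls("g", [1.2, 1.3, 1.1], [1.2, 1.3, 1.1]))
        assert out.iloc[0].regulation == "unchanged"

    def test_missing_housekeeping_rejected(self):
        calls = self._calls("g", [1.0, 1.0], [1.0, 1.0])
        calls.loc[0, "housekeeping_intensity"] = 0.0
        with pytest.raises(InputValidationError):
            expression_filter(calls)

    def test_single_replicate_no_regulation_call(self):
        out = expression_filter(self._calls("g", [1.0], [5.0]))
        assert out.iloc[0].regulation == "unchanged"
        assert out.iloc[0].detected
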