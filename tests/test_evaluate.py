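"""Evaluation machinery: metric, histograms, sweeps, comparison table."""

from __future__ import annotations

import numpy as np
import pytest

from strigacount.annotations import Box, GroundTruthCount
from strigacount.detect import Detection
from strigacount.evaluate import (
    DEFAULT_P_GRID,
    avg_germ_diff,
    comparison_table,
    error_histogram,
    per_image_diffs,
    sweep_checkpoints,
    sweep_threshold,
    underestimation_pct,
)
from strigacount.quantify import CountResult


def det(k, label, obj=0.9):
    # disjoint 10x10 boxes laid out on a row; NMS can never merge them
    x0 = 15.0 * k
    other = "radicle" if label == "seed" else "seed"
    return Detection(Box(x0, 5, x0 + 10, 15, label), obj,
                     {label: obj, other: 0.01})


def detection_set(n_seeds, n_radicles, fp_seed_scores=()):
    """True detections at objectness 0.9 plus planted seed false positives
    with the given (low) objectness scores, all on disjoint boxes."""
    dets = [det(k, "seed") for k in range(n_seeds)]
    dets += [det(100 + k, "radicle") for k in range(n_radicles)]
    dets += [det(200 + k, "seed", obj=s) for k, s in enumerate(fp_seed_scores)]
    return dets


class TestAvgGermDiff:
    def test_identical_predictions_give_zero(self):
        truth = [GroundTruthCount("a", 50, 20), GroundTruthCount("b", 40, 10)]
        pred = [CountResult("a", 50, 20), CountResult("b", 40, 10)]
        assert avg_germ_diff(pred, truth).value == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        truth = [GroundTruthCount("a", 100, 25), GroundTruthCount("b", 100, 13)]
        pred = [CountResult("a", 100, 20), CountResult("b", 100, 10)]
        assert avg_germ_diff(pred, truth).value == pytest.approx(4.0)

    def test_matches_independent_oracle_on_random_pairs(self, rng):
        truth, pred, oracle_diffs = [], [], []
        for i in range(50):
            ts, tr = int(rng.integers(10, 80)), int(rng.integers(0, 10))
            ps, pr = int(rng.integers(10, 80)), int(rng.integers(0, 10))
            truth.append(GroundTruthCount(f"s{i}", ts, tr))
            pred.append(CountResult(f"s{i}", ps, pr))
            oracle_diffs.append(abs(100 * pr / ps - 100 * tr / ts))
        expected = sum(oracle_diffs) / len(oracle_diffs)
        result = avg_germ_diff(pred, truth)
        assert result.value == pytest.approx(expected)
        assert result.n_images == 50

    def test_na_pairs_excluded_and_tallied(self):
        truth = [GroundTruthCount("a", 50, 20), GroundTruthCount("b", 0, 0)]
        pred = [CountResult("a", 50, 10), CountResult("b", 10, 5)]
        result = avg_germ_diff(pred, truth)
        assert result.value == pytest.approx(20.0)
        assert (result.n_images, result.n_excluded) == (1, 1)

    def test_order_invariant(self):
        truth = [GroundTruthCount("a", 50, 20), GroundTruthCount("b", 40, 10)]
        pred = [CountResult("a", 50, 15), CountResult("b", 40, 12)]
        assert (avg_germ_diff(pred, truth).value
                == avg_germ_diff(list(reversed(pred)), truth).value)

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            avg_germ_diff([CountResult("x", 5, 1)],
                          [GroundTruthCount("y", 5, 1)])


class TestUnderestimationPct:
    def test_seed_row(self):
        assert underestimation_pct(4848, 4486) == pytest.approx(7.467)

    def test_radicle_row(self):
        assert underestimation_pct(910, 851) == pytest.approx(6.484)

    def test_equal_totals(self):
        assert underestimation_pct(100, 100) == 0.0

    def test_overestimation_is_negative(self):
        assert underestimation_pct(100, 110) == pytest.approx(-10.0)

    def test_zero_hand_total_rejected(self):
        with pytest.raises(ValueError):
            underestimation_pct(0, 5)


class TestErrorHistogram:
    def test_all_small_errors_fill_first_bin(self):
        hist = error_histogram([1.0, 2.0, 4.9])
        assert hist.percentages[0] == pytest.approx(100.0)

    def test_hand_binning(self):
        hist = error_histogram([1.0, 2.0, 6.0, 11.0])
        assert hist.percentages[0] == pytest.approx(50.0)
        assert hist.percentages[1] == pytest.approx(25.0)
        assert hist.percentages[2] == pytest.approx(25.0)

    def test_matches_brute_force_binning(self, rng):
        diffs = rng.uniform(0, 40, size=200)
        hist = error_histogram(diffs)
        edges = list(np.arange(0, 35, 5))
        for i in range(len(edges) - 1):
            expected = np.mean((diffs >= edges[i]) & (diffs < edges[i + 1])) * 100
            assert hist.percentages[i] == pytest.approx(expected)
        overflow = np.mean(diffs >= 30) * 100
        assert hist.percentages[-1] == pytest.approx(overflow)

    def test_percentages_sum_to_100(self, rng):
        for _ in range(10):
            diffs = rng.uniform(0, 60, size=int(rng.integers(1, 50)))
            assert sum(error_histogram(diffs).percentages) == pytest.approx(
                100.0, abs=0.01
            )

    def test_empty_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            error_histogram([])
        with pytest.raises(ValueError):
            error_histogram([-1.0])

    def test_table_export(self):
        table = error_histogram([1.0, 7.0]).as_table()
        assert list(table.columns) == ["error_range_pct", "images_pct"]
        assert table["error_range_pct"].iloc[0] == "0-5"


class TestSweepThreshold:
    def test_planted_false_positives_select_optimum(self):
        """False positives graded just below P=0.06 make 0.06 the first grid
        point that recovers exact counts; exhaustive grid evaluation is the
        oracle."""
        truth = [GroundTruthCount("a", 10, 4), GroundTruthCount("b", 10, 4)]
        fp_scores = (0.015, 0.025, 0.035, 0.045, 0.055)
        score_sets = {
            "a": detection_set(10, 4, fp_scores),
            "b": detection_set(10, 4, fp_scores),
        }
        result = sweep_threshold(score_sets, truth)
        assert result.selected.setting == pytest.approx(0.06)
        assert result.selected.avg_germ_diff == pytest.approx(0.0)
        # oracle: metric computed per grid point by direct arithmetic
        for point in result.points:
            n_fp = sum(1 for s in fp_scores if s >= point.setting)
            expected = abs(100 * 4 / (10 + n_fp) - 40.0)
            assert point.avg_germ_diff == pytest.approx(expected)
        best = min(result.points, key=lambda p: (p.avg_germ_diff, p.setting))
        assert result.selected == best

    def test_ties_break_to_smallest_threshold(self):
        truth = [GroundTruthCount("a", 10, 4)]
        score_sets = {"a": detection_set(10, 4)}  # no FPs: all P identical
        result = sweep_threshold(score_sets, truth)
        assert result.selected.setting == pytest.approx(0.01)

    def test_single_point_grid(self):
        truth = [GroundTruthCount("a", 10, 4)]
        result = sweep_threshold({"a": detection_set(10, 4)}, truth, grid=[0.07])
        assert result.selected.setting == pytest.approx(0.07)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold({"a": []}, [GroundTruthCount("a", 1, 0)], grid=[])

    def test_selected_attains_grid_minimum(self):
        truth = [GroundTruthCount("a", 10, 4)]
        score_sets = {"a": detection_set(10, 4, (0.02, 0.04, 0.08))}
        result = sweep_threshold(score_sets, truth)
        assert all(result.selected.avg_germ_diff <= p.avg_germ_diff
                   for p in result.points)

    def test_default_grid_covers_001_to_010(self):
        assert DEFAULT_P_GRID[0] == 0.01 and DEFAULT_P_GRID[-1] == 0.10
        assert len(DEFAULT_P_GRID) == 10


class TestSweepCheckpoints:
    def make_checkpoint(self, miss_rate):
        # 40 seeds, 20 radicles hand-counted; checkpoint misses radicles
        n_rad = round(20 * (1 - miss_rate))
        return {"a": detection_set(40, n_rad)}

    def test_injected_miss_rates_select_middle(self):
        truth = [GroundTruthCount("a", 40, 20)]
        outputs = {
            3000: self.make_checkpoint(0.20),
            9000: self.make_checkpoint(0.05),
            15000: self.make_checkpoint(0.10),
        }
        result = sweep_checkpoints(outputs, truth, P=0.05)
        assert result.selected.setting == 9000
        # oracle: direct germination arithmetic per checkpoint
        for point in result.points:
            n_rad = round(20 * (1 - {3000: 0.2, 9000: 0.05, 15000: 0.1}[point.setting]))
            assert point.avg_germ_diff == pytest.approx(
                abs(100 * n_rad / 40 - 50.0)
            )

    def test_single_checkpoint_selected(self):
        truth = [GroundTruthCount("a", 40, 20)]
        result = sweep_checkpoints({9000: self.make_checkpoint(0.0)}, truth)
        assert result.selected.setting == 9000

    def test_all_identical_selects_earliest(self):
        truth = [GroundTruthCount("a", 40, 20)]
        outputs = {e: self.make_checkpoint(0.1) for e in (1000, 2000, 3000)}
        assert sweep_checkpoints(outputs, truth).selected.setting == 1000

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sweep_checkpoints({}, [GroundTruthCount("a", 1, 0)])


class TestComparisonTable:
    def test_reference_totals(self):
        table = comparison_table(
            (4848, 910, 21.42), (4486, 851, 20.03), [3.38] * 94
        )
        under = table.loc["underestimation_pct"]
        assert under["seeds"] == pytest.approx(7.467)
        assert under["radicles"] == pytest.approx(6.484)
        assert table.loc["hand_count", "avg_diff_per_image"] == pytest.approx(3.38)

    def test_identical_totals_give_zero_row(self):
        table = comparison_table((100, 40, 40.0), (100, 40, 40.0), [0.0])
        assert table.loc["underestimation_pct", "seeds"] == 0.0
        assert table.loc["underestimation_pct", "radicles"] == 0.0

    def test_overestimation_not_clamped(self):
        table = comparison_table((100, 40, 40.0), (110, 40, 36.4), [2.0])
        assert table.loc["underestimation_pct", "seeds"] == pytest.approx(-10.0)


class TestPerImageDiffs:
    def test_matches_metric_mean(self):
        truth = [GroundTruthCount("a", 50, 20), GroundTruthCount("b", 40, 10)]
        pred = [CountResult("a", 50, 15), CountResult("b", 40, 12)]
        diffs = per_image_diffs(pred, truth)
        assert np.mean(diffs) == pytest.approx(avg_germ_diff(pred, truth).value)
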