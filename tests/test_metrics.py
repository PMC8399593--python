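"""Confusion counts, the six metrics, undefined semantics, aggregation."""

import math

import numpy as np
import pytest

from neoseg.metrics import (
    UNDEFINED,
    ConfusionCounts,
    MetricsRecord,
    aggregate_report,
    compute_metrics,
    confusion,
    is_defined,
    patch_classify,
    round_half_up,
    segment_probabilities,
)
from neoseg.reference import load_reference_metrics, reference_records


def brute_force_confusion(pred, truth):
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


class TestSegmentDecision:
    def test_argmax_picks_larger_probability(self):
        probs = np.zeros((2, 1, 2))
        probs[:, 0, 0] = (0.9, 0.1)  # NotNeo wins
        probs[:, 0, 1] = (0.2, 0.8)  # Neo wins
        out = segment_probabilities(probs)
        assert out.tolist() == [[0, 255]]

    def test_exact_tie_goes_to_notneo(self):
        probs = np.full((2, 2, 2), 0.5)
        assert (segment_probabilities(probs) == 0).all()

    def test_output_matches_input_shape(self, rng):
        probs = rng.random((2, 5, 7))
        probs[1] = 1 - probs[0]
        assert segment_probabilities(probs).shape == (5, 7)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((6, 6)) > 0.5).astype(np.uint8) * 255
        c = confusion(truth, truth)
        assert c.fp == 0 and c.fn == 0
        assert c.tp + c.tn == 36

    def test_complement_prediction(self, rng):
        truth = (rng.random((6, 6)) > 0.5).astype(np.uint8) * 255
        c = confusion(255 - truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_toy_pair_matches_enumeration(self):
        pred = np.array([[255, 0], [255, 255], [0, 0]], dtype=np.uint8)
        truth = np.array([[255, 255], [0, 255], [0, 0]], dtype=np.uint8)
        c = confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 1, 1)
        assert c == brute_force_confusion(pred > 0, truth > 0)

    def test_counts_conserve_total(self, rng):
        pred = rng.random((9, 13)) > 0.4
        truth = rng.random((9, 13)) > 0.6
        assert confusion(pred, truth).total == 9 * 13

    def test_misaligned_masks_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestComputeMetrics:
    def test_published_row_identities(self):
        # printed per-image row: precision .7626, sensitivity .7330,
        # jaccard .5968 all imply the same printed dice .7475
        p, s, j = 0.7626, 0.7330, 0.5968
        assert 2 * p * s / (p + s) == pytest.approx(0.7475, abs=5e-5)
        assert 2 * j / (1 + j) == pytest.approx(0.7475, abs=5e-5)

    def test_all_negative_truth_with_false_positives(self):
        # tp = 0, fn = 0, fp > 0: sensitivity undefined; precision,
        # jaccard and dice are defined zeros
        m = compute_metrics(ConfusionCounts(tp=0, tn=990, fp=10, fn=0))
        assert not is_defined(m.sensitivity)
        assert m.precision == 0.0 and m.jaccard == 0.0 and m.dice == 0.0
        assert m.specificity == pytest.approx(0.99)

    def test_all_negative_perfect_image(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=100, fp=0, fn=0))
        assert m.accuracy == 1.0 and m.specificity == 1.0
        for name in ("sensitivity", "precision", "jaccard", "dice"):
            assert not is_defined(getattr(m, name))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_identities_on_random_counts(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            if is_defined(m.jaccard) and is_defined(m.dice):
                assert m.dice == pytest.approx(2 * m.jaccard / (1 + m.jaccard), rel=1e-12)
                assert m.jaccard <= m.dice <= 1.0
            if all(is_defined(v) for v in (m.precision, m.sensitivity, m.dice)) and (
                m.precision + m.sensitivity > 0
            ):
                assert m.dice == pytest.approx(
                    2 * m.precision * m.sensitivity / (m.precision + m.sensitivity),
                    rel=1e-12,
                )

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(250):
            pred = rng.random((16, 16)) > rng.random()
            truth = rng.random((16, 16)) > rng.random()
            fast = confusion(pred, truth)
            slow = brute_force_confusion(pred, truth)
            assert fast == slow
            m = compute_metrics(fast)
            assert m.accuracy == pytest.approx((slow.tp + slow.tn) / 256)


class TestPatchClassify:
    def test_study_tiling_eight_tiles(self):
        pred = np.zeros((400, 1184), dtype=np.uint8)
        truth = np.zeros((400, 1184), dtype=np.uint8)
        c = patch_classify(pred, truth)  # default 200 x 296 tiles
        assert c.total == 8
        assert c.tn == 8

    def test_single_neo_pixel_marks_one_tile(self):
        pred = np.zeros((400, 1184), dtype=np.uint8)
        truth = np.zeros((400, 1184), dtype=np.uint8)
        pred[10, 10] = truth[10, 10] = 255
        c = patch_classify(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 7, 0, 0)

    def test_disagreeing_tiles(self):
        pred = np.zeros((400, 592), dtype=np.uint8)
        truth = np.zeros((400, 592), dtype=np.uint8)
        pred[0, 0] = 255  # false-positive tile
        truth[399, 591] = 255  # false-negative tile
        c = patch_classify(pred, truth, 200, 296)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 2, 1, 1)

    def test_non_divisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            patch_classify(np.zeros((401, 1184)), np.zeros((401, 1184)))


class TestAggregation:
    def test_reference_table_averages(self):
        # the printed average row is reproducible only by excluding
        # undefined entries: 26 defined jaccard values average 0.7643,
        # 25 defined sensitivities average 0.8772
        report = aggregate_report(reference_records())
        avg = report.segmentation_average
        assert round_half_up(avg.jaccard) == pytest.approx(0.7643, abs=5e-5)
        assert round_half_up(avg.sensitivity) == pytest.approx(0.8772, abs=5e-5)
        assert round_half_up(avg.accuracy) == pytest.approx(0.9948, abs=5e-5)

    def test_reference_table_defined_counts(self):
        df = load_reference_metrics()
        assert len(df) == 50
        assert df["sensitivity"].notna().sum() == 25
        assert df["precision"].notna().sum() == 26
        assert df["jaccard"].notna().sum() == 26

    def test_single_record_average_is_itself(self):
        rec = compute_metrics(ConfusionCounts(5, 85, 5, 5))
        report = aggregate_report([rec])
        assert report.segmentation_average == rec

    def test_metric_undefined_everywhere_averages_undefined(self):
        recs = [compute_metrics(ConfusionCounts(0, 10, 0, 0)) for _ in range(3)]
        avg = aggregate_report(recs).segmentation_average
        assert not is_defined(avg.sensitivity)
        assert avg.accuracy == 1.0

    def test_csv_rendering_uses_dash_for_undefined(self):
        rec = compute_metrics(ConfusionCounts(0, 10, 0, 0))
        csv = aggregate_report([rec]).to_csv()
        assert "1,1.0000,-,1.0000,-,-,-" in csv

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.74745, 0.7475), (0.12344, 0.1234), (0.99995, 1.0), (0.5, 0.5)],
    )
    def test_half_up_to_four_decimals(self, value, expected):
        assert round_half_up(value) == pytest.approx(expected, abs=1e-12)
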