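"""Evaluation metrics against brute-force oracles and closed formulas."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import cohen_kappa_score

from pedbrain import (ConfusionCounts, aggregate_metrics, cohen_kappa,
                      diagnostic_metrics, dice_score, hausdorff95)
from pedbrain.metrics import _boundary, segmentation_metrics


def random_mask(rng, shape=(10, 10, 10), p=0.2):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


def brute_force_hd95(a, b, spacing):
    """All-pairs boundary-distance oracle (O(n^2))."""
    ca = np.argwhere(_boundary(a)) * np.asarray(spacing)
    cb = np.argwhere(_boundary(b)) * np.asarray(spacing)
    d = cdist(ca, cb)
    return max(np.percentile(d.min(axis=1), 95),
               np.percentile(d.min(axis=0), 95))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:3] = True
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0], b[4] = True, True
        assert dice_score(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |A| = 4, |B| = 6, |A∩B| = 3 -> 2*3/10
        a = np.zeros(12, dtype=bool)
        b = np.zeros(12, dtype=bool)
        a[:4] = True
        b[1:7] = True
        assert dice_score(a, b) == pytest.approx(0.6)

    def test_both_empty_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert dice_score(np.zeros(4, bool), np.zeros(4, bool)) == 1.0
        assert "convention" in caplog.text

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_score(np.zeros((3, 3), bool), np.zeros((4, 3), bool))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            assert dice_score(a, b) == pytest.approx(dice_score(b, a))


class TestHausdorff95:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True
        assert hausdorff95(m, m) == 0.0

    def test_single_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 2, 2], b[5, 2, 2] = True, True
        assert hausdorff95(a, b, (1, 1, 1)) == pytest.approx(3.0)

    def test_empty_mask_undefined(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = True
        assert hausdorff95(m, np.zeros_like(m)) is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b = random_mask(rng), random_mask(rng)
            got = hausdorff95(a, b, (1, 1, 1))
            assert got == pytest.approx(brute_force_hd95(a, b, (1, 1, 1)),
                                        abs=1e-10)

    def test_anisotropic_spacing_matches_oracle(self):
        rng = np.random.default_rng(7)
        spacing = (0.5, 1.0, 2.5)
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            got = hausdorff95(a, b, spacing)
            assert got == pytest.approx(brute_force_hd95(a, b, spacing),
                                        abs=1e-9)

    def test_symmetry_and_spacing_scale(self):
        rng = np.random.default_rng(3)
        a, b = random_mask(rng), random_mask(rng)
        assert hausdorff95(a, b) == pytest.approx(hausdorff95(b, a))
        assert hausdorff95(a, b, (2, 2, 2)) == pytest.approx(
            2 * hausdorff95(a, b, (1, 1, 1)))


class TestDiagnosticMetrics:
    def test_study_test_set_counts(self):
        # 18 tumors (16 found), 3 normals (all clean)
        m = diagnostic_metrics(ConfusionCounts(tp=16, fn=2, fp=0, tn=3))
        assert m["specificity"] == 1.0
        assert m["accuracy"] == pytest.approx(19 / 21)
        assert round(m["accuracy"], 2) == 0.90
        assert m["sensitivity"] == pytest.approx(16 / 18)

    def test_perfect_counts(self):
        m = diagnostic_metrics(ConfusionCounts(tp=1, fn=0, fp=0, tn=1))
        assert all(v == 1.0 for v in m.values())

    def test_all_wrong(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fn=1, fp=1, tn=0))
        assert m["sensitivity"] == 0.0 and m["specificity"] == 0.0

    def test_class_swap_symmetry(self):
        c = ConfusionCounts(tp=7, fn=2, fp=3, tn=11)
        swapped = ConfusionCounts(tp=c.tn, fn=c.fp, fp=c.fn, tn=c.tp)
        m, s = diagnostic_metrics(c), diagnostic_metrics(swapped)
        assert m["sensitivity"] == s["specificity"]
        assert m["ppv"] == s["npv"]

    def test_undefined_denominator_flagged_as_none(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=3))
        assert m["sensitivity"] is None


class TestCohenKappa:
    def test_perfect_agreement(self):
        pairs = [("a", "a"), ("b", "b"), ("a", "a"), ("c", "c")]
        assert cohen_kappa(pairs) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # table (20,5 / 10,15): p_o = 0.7, p_e = 0.5 -> kappa 0.4
        pairs = ([("x", "x")] * 20 + [("x", "y")] * 5
                 + [("y", "x")] * 10 + [("y", "y")] * 15)
        assert cohen_kappa(pairs) == pytest.approx(0.4)

    def test_chance_agreement_limit(self):
        rng = np.random.default_rng(0)
        pairs = list(zip(rng.integers(0, 2, 5000), rng.integers(0, 2, 5000)))
        assert abs(cohen_kappa(pairs)) < 0.05

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 4, 60)
            assert cohen_kappa(list(zip(a, b))) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_label_renaming_invariance(self):
        pairs = [(0, 0), (0, 1), (1, 1), (1, 0), (1, 1), (0, 0)]
        renamed = [({0: "u", 1: "v"}[a], {0: "u", 1: "v"}[b]) for a, b in pairs]
        assert cohen_kappa(pairs) == pytest.approx(cohen_kappa(renamed))

    def test_degenerate_marginals_flagged(self):
        assert cohen_kappa([("a", "a"), ("a", "a")]) is None

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            cohen_kappa([("a", "a")])


class TestAggregate:
    def test_single_case(self):
        agg = aggregate_metrics([0.8])
        assert agg["mean"] == 0.8 and agg["sd"] == 0.0

    def test_simple_mean(self):
        assert aggregate_metrics([0.5, 0.7, 0.9])["mean"] == pytest.approx(0.7)

    def test_quartiles_match_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.random(17).tolist()
        agg = aggregate_metrics(values)
        s = np.sort(values)

        def linear_pct(q):
            pos = q / 100 * (len(s) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            return s[lo] + frac * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert agg["q25"] == pytest.approx(linear_pct(25), abs=1e-12)
        assert agg["q75"] == pytest.approx(linear_pct(75), abs=1e-12)

    def test_undefined_values_excluded_and_counted(self):
        agg = aggregate_metrics([0.5, None, 0.7])
        assert agg["n_undefined"] == 1 and agg["mean"] == pytest.approx(0.6)


def test_segmentation_metrics_layout(tumor_case):
    res = segmentation_metrics(tumor_case.tumor, tumor_case.tumor,
                               tumor_case.study.spacing)
    for comp in ("WT", "ET", "NET"):
        assert res[comp]["dice"] == 1.0
        assert res[comp]["hd95"] == 0.0
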