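"""Metric correctness against brute-force oracles; parameter extraction."""

import numpy as np
import pytest
from sklearn.metrics import r2_score

from tmwsnet.geometry_io import LabeledCloud
from tmwsnet.metrics import (compute_metrics, confusion, crown_diameter,
                             dbh_estimate, extract_params, params_report,
                             r_squared, tree_height)
from tmwsnet.synthetic import PlotSpec, TreeSpec, sample_plot, true_params


def brute_force_metrics(pred, truth, n_classes):
    """Direct-from-labels oracle, independent of the counts pathway."""
    ious, precs, recs, f1s = [], [], [], []
    for i in range(n_classes):
        tp = np.sum((pred == i) & (truth == i))
        fp = np.sum((pred == i) & (truth != i))
        fn = np.sum((pred != i) & (truth == i))
        if tp + fp + fn > 0:
            ious.append(tp / (tp + fp + fn))
        if tp + fp > 0:
            precs.append(tp / (tp + fp))
        if tp + fn > 0:
            recs.append(tp / (tp + fn))
        if tp + fp > 0 and tp + fn > 0:
            p, r = tp / (tp + fp), tp / (tp + fn)
            f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    return (100 * np.mean(ious), 100 * np.mean(pred == truth),
            100 * np.mean(precs), 100 * np.mean(recs), 100 * np.mean(f1s))


class TestConfusion:
    def test_perfect_prediction_no_errors(self, rng):
        y = rng.integers(0, 3, 50)
        c = confusion(y, y, 3)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)

    def test_hand_counts(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 0], 2)
        assert (c.tp[1], c.fp[1], c.fn[1]) == (1, 1, 0)
        assert (c.tp[0], c.fp[0], c.fn[0]) == (2, 0, 1)

    def test_counts_sum_to_total_per_class(self, rng):
        pred = rng.integers(0, 4, 200)
        truth = rng.integers(0, 4, 200)
        c = confusion(pred, truth, 4)
        assert np.all(c.tp + c.fp + c.fn + c.tn == 200)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 2)


class TestComputeMetrics:
    def test_perfect_prediction_all_hundred(self, rng):
        y = rng.integers(0, 2, 100)
        rep = compute_metrics(confusion(y, y, 2), truth_values=[1.0, 2.0],
                              pred_values=[1.0, 2.0])
        for v in (rep.miou, rep.macc, rep.mprec, rep.mrec, rep.mf1):
            assert v == pytest.approx(100.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_hand_example_seven_twelfths(self):
        rep = compute_metrics(confusion([1, 1, 0, 0], [1, 0, 0, 0], 2))
        assert rep.miou == pytest.approx(100 * 7 / 12)

    def test_matches_brute_force_on_random_cases(self, rng):
        for _ in range(100):
            n_classes = int(rng.integers(2, 4))
            n = int(rng.integers(5, 60))
            pred = rng.integers(0, n_classes, n)
            truth = rng.integers(0, n_classes, n)
            if len(np.unique(truth)) < n_classes or len(np.unique(pred)) < n_classes:
                continue  # oracle means only defined with all classes present
            rep = compute_metrics(confusion(pred, truth, n_classes))
            miou, macc, mprec, mrec, mf1 = brute_force_metrics(pred, truth, n_classes)
            assert rep.miou == pytest.approx(miou)
            assert rep.macc == pytest.approx(macc)
            assert rep.mprec == pytest.approx(mprec)
            assert rep.mrec == pytest.approx(mrec)
            assert rep.mf1 == pytest.approx(mf1)

    def test_metrics_hundred_iff_equal(self, rng):
        pred = rng.integers(0, 2, 50)
        truth = pred.copy()
        truth[0] = 1 - truth[0]
        rep = compute_metrics(confusion(pred, truth, 2))
        assert rep.miou < 100 and rep.macc < 100


class TestRSquared:
    def test_mean_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_matches_sklearn(self, rng):
        y = rng.standard_normal(30)
        yh = y + rng.standard_normal(30) * 0.3
        assert r_squared(y, yh) == pytest.approx(r2_score(y, yh))


def _noise_free_plot(spec=None, seed=0, n_tree=6000):
    spec = spec or TreeSpec(trunk_height=5.0, trunk_radius=0.15,
                            crown_semi_axes=(2.0, 2.0, 3.0), crown_base_height=5.0)
    return spec, sample_plot(PlotSpec(tree=spec, n_tree_points=n_tree,
                                      n_ground_points=1000, n_neighbor_points=0,
                                      ground_roughness=0.0, jitter_sd=0.0,
                                      seed=seed))


class TestTreeHeight:
    def test_recovers_generator_truth(self):
        spec, cloud = _noise_free_plot()
        # the top-percentile estimator under-reads by ~1% at this density;
        # truth recovered within the 2% band the extractor is designed for
        assert tree_height(cloud) == pytest.approx(11.0, abs=0.02 * 11.0)

    def test_other_canopy_noise_above_does_not_inflate(self):
        spec, cloud = _noise_free_plot()
        noise = np.tile([0.0, 0.0, 30.0], (50, 1))
        cloud2 = LabeledCloud(np.vstack([cloud.coords, noise]),
                              labels=np.concatenate([cloud.labels, np.zeros(50, int)]))
        assert tree_height(cloud2) == pytest.approx(tree_height(cloud), abs=0.05)

    def test_unlabeled_cloud_rejected(self, rng):
        with pytest.raises(ValueError):
            tree_height(LabeledCloud(rng.random((10, 3))))


class TestDBH:
    def test_recovers_cylinder_diameter(self):
        spec, cloud = _noise_free_plot()
        assert dbh_estimate(cloud) == pytest.approx(0.30, abs=0.01)

    def test_insufficient_slice_points(self):
        spec = TreeSpec(trunk_height=5.0, crown_base_height=5.0)
        cloud = sample_plot(PlotSpec(tree=spec, n_tree_points=10,
                                     n_ground_points=0, n_neighbor_points=0,
                                     jitter_sd=0.0, seed=1))
        with pytest.raises(ValueError, match="insufficient"):
            dbh_estimate(cloud)

    def test_circle_fit_matches_kasa_oracle(self, rng):
        theta = rng.random(100) * 2 * np.pi
        cx, cy, r = 1.3, -0.4, 0.17
        xy = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        from tmwsnet.metrics import _fit_circle
        fx, fy, fr = _fit_circle(xy)
        # independent algebraic oracle on exact circle points
        A = np.column_stack([xy, np.ones(100)])
        b = (xy ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        ox, oy = sol[0] / 2, sol[1] / 2
        orad = np.sqrt(sol[2] + ox ** 2 + oy ** 2)
        assert (fx, fy, fr) == pytest.approx((ox, oy, orad), abs=1e-9)


class TestCrownDiameter:
    def test_symmetric_crown(self):
        spec, cloud = _noise_free_plot()
        assert crown_diameter(cloud) == pytest.approx(4.0, abs=0.2)

    def test_elongated_crown_mean_of_extents(self):
        spec = TreeSpec(trunk_height=5.0, crown_semi_axes=(1.0, 3.0, 3.0),
                        crown_base_height=5.0)
        _, cloud = _noise_free_plot(spec)
        assert crown_diameter(cloud) == pytest.approx(4.0, abs=0.25)

    def test_rotation_invariance_about_z(self):
        spec, cloud = _noise_free_plot()
        a = np.deg2rad(37.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                        [0, 0, 1.0]])
        cloud2 = LabeledCloud(cloud.coords @ rot.T, labels=cloud.labels)
        d1, d2 = crown_diameter(cloud), crown_diameter(cloud2)
        assert abs(d1 - d2) / d1 < 0.02


class TestParamsReport:
    def test_perfect_predictions_r2_one(self):
        truth = [(10.0, 0.3, 4.0), (12.0, 0.35, 4.5), (9.0, 0.25, 3.5)]
        _, r2 = params_report(truth, truth)
        assert all(v == pytest.approx(1.0) for v in r2.values())

    def test_mean_prediction_r2_zero(self):
        truth = np.array([(10.0, 0.3, 4.0), (12.0, 0.4, 5.0), (8.0, 0.2, 3.0)])
        pred = np.tile(truth.mean(axis=0), (3, 1))
        _, r2 = params_report(pred, truth)
        assert all(v == pytest.approx(0.0) for v in r2.values())

    def test_direct_sum_of_squares_on_five_pairs(self, rng):
        truth = rng.random((5, 3)) + 1
        pred = truth + rng.standard_normal((5, 3)) * 0.05
        _, r2 = params_report(pred, truth)
        for i, name in enumerate(["height", "dbh", "crown_diameter"]):
            expect = 1 - np.sum((truth[:, i] - pred[:, i]) ** 2) / \
                np.sum((truth[:, i] - truth[:, i].mean()) ** 2)
            assert r2[name] == pytest.approx(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            params_report([(1.0, 1.0, 1.0)], [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0)])


class TestRecoverySuite:
    def test_noise_free_parameter_recovery(self):
        """Height within 2%, DBH within 10%, crown within 5% of truth."""
        rng = np.random.default_rng(0)
        for i in range(5):
            spec = TreeSpec(trunk_height=float(rng.uniform(4.5, 7.0)),
                            trunk_radius=float(rng.uniform(0.12, 0.2)),
                            crown_semi_axes=tuple(rng.uniform(1.8, 3.0, 3)),
                            crown_base_height=None or float(rng.uniform(3.0, 4.4)))
            _, cloud = _noise_free_plot(spec, seed=i)
            h, dbh, cd = true_params(spec)
            p = extract_params(cloud)
            assert abs(p.height - h) / h < 0.02
            assert abs(p.dbh - dbh) / dbh < 0.10
            assert abs(p.crown_diameter - cd) / cd < 0.05
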