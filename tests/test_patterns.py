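import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lifespan_ec.io import Parcellation
from lifespan_ec.patterns import (
    TrajectoryMatrix,
    cluster_trajectories,
    early_late_sd,
    pca_gradient,
    select_k,
    trajectory_correlation,
)
from lifespan_ec.synth import transform_age

GRID_T = np.linspace(0.0, np.log2(101.0), 128)


def _prototype_curves():
    """Five well-separated lifespan shapes: inverted-U early peak,
    late-peak rise, monotone decline, flat-then-decline, dip-then-rise."""
    t = GRID_T
    tmax = t.max()
    return {
        "inverted_u_early": 1.2 * np.exp(-0.5 * ((t - 2.2) / 0.9) ** 2),
        "late_peak_rise": 1.5 / (1.0 + np.exp(-3.0 * (t - 4.8))),
        "monotone_decline": 1.0 - 1.6 * t / tmax,
        "flat_then_decline": 0.6 - 1.4 / (1.0 + np.exp(-4.0 * (t - 5.2))),
        "dip_then_rise": 0.8 - 1.1 * np.exp(-0.5 * ((t - 1.0) / 0.7) ** 2) + 0.5 * t / tmax,
    }


def _prototype_tm(n_copies=20, noise=0.08, seed=0):
    rng = np.random.default_rng(seed)
    protos = list(_prototype_curves().values())
    curves, labels = [], []
    for ci, proto in enumerate(protos):
        for _ in range(n_copies):
            curves.append(proto + rng.normal(0, noise, len(GRID_T)))
            labels.append(ci)
    region_ids = tuple(f"R{i:03d}" for i in range(len(curves)))
    return TrajectoryMatrix(np.array(curves), region_ids, GRID_T), np.array(labels)


class TestClustering:
    def test_planted_prototypes_recovered(self):
        tm, truth = _prototype_tm()
        res = cluster_trajectories(tm, k=5, seed=1)
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_determinism_and_label_convention(self):
        tm, _ = _prototype_tm()
        r1 = cluster_trajectories(tm, k=5, seed=7)
        r2 = cluster_trajectories(tm, k=5, seed=7)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        finals = [r1.centroids[c - 1][-1] for c in range(1, 6)]
        assert finals == sorted(finals, reverse=True)

    def test_region_order_invariance(self):
        tm, _ = _prototype_tm()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(tm.region_ids))
        tm_p = TrajectoryMatrix(tm.values[perm],
                                tuple(tm.region_ids[i] for i in perm), GRID_T)
        r = cluster_trajectories(tm, k=5, seed=2)
        r_p = cluster_trajectories(tm_p, k=5, seed=2)
        np.testing.assert_array_equal(r.labels[perm], r_p.labels)

    def test_identical_curves_single_cluster_zero_inertia(self):
        values = np.tile(np.sin(GRID_T), (6, 1))
        tm = TrajectoryMatrix(values, tuple(f"R{i}" for i in range(6)), GRID_T)
        res = cluster_trajectories(tm, k=1, n_init=1, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-20)
        assert set(res.labels) == {1}

    def test_composition_rows_sum_to_100(self):
        tm, _ = _prototype_tm(n_copies=4)
        ids = tm.region_ids
        nets = {r: ("X" if i < 10 else "Y") for i, r in enumerate(ids)}
        parc = Parcellation(ids, nets, ("X", "Y"))
        res = cluster_trajectories(tm, k=3, seed=0, parcellation=parc)
        np.testing.assert_allclose(res.composition.sum(axis=1), 100.0)


class TestSelectK:
    def test_silhouette_maximized_at_five_prototypes(self):
        tm, _ = _prototype_tm()
        diag = select_k(tm, range(2, 11))
        best = diag.loc[diag["silhouette"].idxmax(), "k"]
        assert best == 5

    def test_row_count_matches_range(self):
        tm, _ = _prototype_tm(n_copies=3)
        assert len(select_k(tm, range(2, 11))) == 9

    def test_noise_silhouette_low_flat(self):
        rng = np.random.default_rng(5)
        tm = TrajectoryMatrix(rng.normal(size=(40, len(GRID_T))),
                              tuple(f"R{i}" for i in range(40)), GRID_T)
        diag = select_k(tm, range(2, 8))
        assert diag["silhouette"].max() < 0.2


class TestCorrelation:
    def test_identities(self):
        tm, _ = _prototype_tm(n_copies=2)
        corr, _ = trajectory_correlation(tm)
        values = corr.to_numpy()
        np.testing.assert_allclose(np.diag(values), 1.0, atol=1e-12)
        np.testing.assert_allclose(values, values.T, atol=1e-12)
        assert np.nanmax(values) <= 1.0 + 1e-12
        assert np.nanmin(values) >= -1.0 - 1e-12

    def test_negated_curve_anticorrelated(self):
        base = np.sin(GRID_T)
        tm = TrajectoryMatrix(np.array([base, -base]), ("a", "b"), GRID_T)
        corr, _ = trajectory_correlation(tm)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_within_cluster_blocks_exceed_between(self):
        tm, truth = _prototype_tm(n_copies=10, noise=0.05)
        ids = tm.region_ids
        nets = {r: f"C{truth[i]}" for i, r in enumerate(ids)}
        parc = Parcellation(ids, nets, tuple(sorted(set(nets.values()))))
        _, blocks = trajectory_correlation(tm, parc)
        diag_mean = np.mean([blocks.loc[n, n] for n in parc.networks])
        off = [blocks.loc[a, b] for a in parc.networks for b in parc.networks if a != b]
        assert diag_mean > np.mean(off)

    def test_zero_variance_curve_missing(self):
        tm = TrajectoryMatrix(
            np.array([np.sin(GRID_T), np.zeros_like(GRID_T), np.cos(GRID_T)]),
            ("a", "flat", "c"), GRID_T,
        )
        corr, _ = trajectory_correlation(tm)
        assert corr.loc["flat"].isna().all()
        assert not np.isnan(corr.loc["a", "c"])


class TestEarlyLateSd:
    def test_constant_curve_zero_both(self):
        tm = TrajectoryMatrix(np.full((2, len(GRID_T)), 3.0), ("a", "b"), GRID_T)
        sd = early_late_sd(tm)
        assert (sd == 0).all().all()

    def test_early_only_variation(self):
        ages = tm_ages = np.exp2(GRID_T) - 1.0
        curve = np.where(ages < 12.0, np.sin(GRID_T * 4), 0.5)
        tm = TrajectoryMatrix(curve[None, :], ("a",), GRID_T)
        sd = early_late_sd(tm)
        assert sd.loc["a", "sd_early"] > 0.1
        assert sd.loc["a", "sd_late"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_rejected(self):
        short_grid = np.linspace(transform_age(30.0), transform_age(80.0), 32)
        tm = TrajectoryMatrix(np.ones((1, 32)), ("a",), short_grid)
        with pytest.raises(ValueError):
            early_late_sd(tm)


class TestGradient:
    def test_antiphase_groups_split_by_sign(self):
        rng = np.random.default_rng(6)
        base = np.sin(GRID_T)
        curves = [base + rng.normal(0, 0.01, len(GRID_T)) for _ in range(10)]
        curves += [-base + rng.normal(0, 0.01, len(GRID_T)) for _ in range(10)]
        tm = TrajectoryMatrix(np.array(curves),
                              tuple(f"R{i}" for i in range(20)), GRID_T)
        grad = pca_gradient(tm)
        signs = np.sign(grad.loadings)
        assert len(set(signs[:10])) == 1
        assert len(set(signs[10:])) == 1
        assert signs[0] != signs[10]

    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 40))
        tm = TrajectoryMatrix(X, tuple(f"R{i}" for i in range(15)),
                              np.linspace(0, 6, 40))
        grad = pca_gradient(tm)
        Xc = X - X.mean(axis=0, keepdims=True)
        cov = Xc @ Xc.T
        lam, vec = np.linalg.eigh(cov)
        lead = vec[:, -1]
        if np.sign(lead[np.argmax(np.abs(lead))]) != np.sign(
            grad.loadings[np.argmax(np.abs(grad.loadings))]
        ):
            lead = -lead
        np.testing.assert_allclose(np.abs(grad.loadings), np.abs(lead), atol=1e-10)
        assert grad.explained_variance_ratio == pytest.approx(
            lam[-1] / lam.sum(), abs=1e-12
        )

    def test_identical_curves_error(self):
        tm = TrajectoryMatrix(np.tile(np.sin(GRID_T), (5, 1)),
                              tuple(f"R{i}" for i in range(5)), GRID_T)
        with pytest.raises(ValueError, match="variance"):
            pca_gradient(tm)

    def test_vis_positive_convention(self):
        rng = np.random.default_rng(8)
        curves = np.vstack([
            np.tile(np.sin(GRID_T), (5, 1)) + rng.normal(0, 0.01, (5, len(GRID_T))),
            np.tile(-np.sin(GRID_T), (5, 1)) + rng.normal(0, 0.01, (5, len(GRID_T))),
        ])
        ids = tuple([f"VIS_{i}" for i in range(5)] + [f"DMN_{i}" for i in range(5)])
        nets = {r: ("VIS" if r.startswith("VIS") else "DMN") for r in ids}
        parc = Parcellation(ids, nets, ("VIS", "DMN"))
        grad = pca_gradient(TrajectoryMatrix(curves, ids, GRID_T), parc)
        assert grad.loadings[:5].mean() > 0
        assert grad.network_summary.loc["VIS", "mean"] > 0

    def test_explained_variance_in_unit_interval(self):
        rng = np.random.default_rng(9)
        tm = TrajectoryMatrix(rng.normal(size=(8, 30)),
                              tuple(f"R{i}" for i in range(8)),
                              np.linspace(0, 5, 30))
        grad = pca_gradient(tm)
        assert 0.0 <= grad.explained_variance_ratio <= 1.0
        assert np.linalg.norm(grad.loadings) == pytest.approx(1.0)
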