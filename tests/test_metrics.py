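import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lifespan_ec.io import ECMatrix, Parcellation
from lifespan_ec.metrics import (
    global_means,
    network_ec,
    nodal_strengths,
    normalize_nii,
    scan_metrics,
    segregation_integration,
)


def _ec(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or tuple(f"R{i}" for i in range(values.shape[0]))
    return ECMatrix(values=values, region_ids=tuple(ids))


class TestGlobalMeans:
    def test_hand_example_two_by_two(self):
        ec = _ec([[0.0, 0.4], [-0.2, 0.0]])
        out = global_means(ec)
        assert out["overall"] == pytest.approx(0.1)
        assert out["exc"] == pytest.approx(0.4)
        assert out["inh"] == pytest.approx(-0.2)

    def test_all_zero_flagged(self):
        out = global_means(_ec(np.zeros((3, 3))))
        assert out == {"overall": 0.0, "exc": 0.0, "inh": 0.0,
                       "exc_empty": True, "inh_empty": True}

    def test_negation_swaps_components(self, random_ec):
        ec = random_ec()
        pos = global_means(ec)
        neg = global_means(_ec(-ec.values))
        assert neg["exc"] == pytest.approx(-pos["inh"])
        assert neg["inh"] == pytest.approx(-pos["exc"])

    def test_diagonal_policy(self):
        ec = _ec([[5.0, 1.0], [1.0, 5.0]])
        assert global_means(ec)["overall"] == pytest.approx(1.0)
        assert global_means(ec, include_diagonal=True)["overall"] == pytest.approx(3.0)


class TestNetworkEc:
    def test_constant_blocks(self, toy_parcellation):
        w, b = 0.3, 0.1
        values = np.full((4, 4), b)
        values[:2, :2] = w
        values[2:, 2:] = w
        np.fill_diagonal(values, 0.0)
        table = network_ec(_ec(values, toy_parcellation.region_ids), toy_parcellation)
        for net in ("NA", "NB"):
            assert table.loc[net, "within"] == pytest.approx(w)
            assert table.loc[net, "between"] == pytest.approx(b)

    def test_incoming_outgoing_decomposition(self, toy_parcellation):
        b_in, b_out = 0.4, 0.1
        values = np.zeros((4, 4))
        values[:2, 2:] = b_in    # into NA from NB
        values[2:, :2] = b_out   # out of NA into NB
        table = network_ec(_ec(values, toy_parcellation.region_ids), toy_parcellation)
        assert table.loc["NA", "incoming"] == pytest.approx(b_in)
        assert table.loc["NA", "outgoing"] == pytest.approx(b_out)
        assert table.loc["NA", "between"] == pytest.approx((b_in + b_out) / 2)

    def test_between_is_pair_weighted_mean_of_directions(self, random_ec, toy_parcellation):
        ec = random_ec(4)
        ec = _ec(ec.values, toy_parcellation.region_ids)
        table = network_ec(ec, toy_parcellation)
        for net in ("NA", "NB"):
            combined = 0.5 * (table.loc[net, "incoming"] + table.loc[net, "outgoing"])
            assert table.loc[net, "between"] == pytest.approx(combined)

    def test_permutation_equivariance(self, random_ec):
        rng = np.random.default_rng(0)
        ids = tuple(f"R{i}" for i in range(8))
        nets = {r: ("X" if i % 2 else "Y") for i, r in enumerate(ids)}
        parc = Parcellation(ids, nets, ("Y", "X"))
        ec = random_ec(8)
        ec = _ec(ec.values, ids)
        base = network_ec(ec, parc)
        perm = rng.permutation(8)
        ids_p = tuple(ids[i] for i in perm)
        parc_p = Parcellation(ids_p, nets, ("Y", "X"))
        ec_p = _ec(ec.values[np.ix_(perm, perm)], ids_p)
        permuted = network_ec(ec_p, parc_p)
        pd.testing.assert_frame_equal(base, permuted, check_exact=False, atol=1e-12)

    def test_single_region_network_flagged(self):
        ids = ("A", "B", "C")
        parc = Parcellation(ids, {"A": "X", "B": "Y", "C": "Y"}, ("X", "Y"))
        table = network_ec(_ec(np.ones((3, 3)), ids), parc)
        assert table.loc["X", "within_flagged"]
        assert np.isnan(table.loc["X", "within"])


class TestSegregationIntegration:
    def _table(self, within, between, b_exc=0.0, b_inh=0.0):
        return pd.DataFrame(
            {"within": [within], "between": [between],
             "between_exc": [b_exc], "between_inh": [b_inh]},
            index=pd.Index(["N"], name="network"),
        )

    def test_nsi_hand_value(self):
        out = segregation_integration(self._table(0.20, 0.05))
        assert out.loc["N", "nsi"] == pytest.approx(0.75)

    def test_zero_between_fully_segregated(self):
        out = segregation_integration(self._table(0.3, 0.0))
        assert out.loc["N", "nsi"] == pytest.approx(1.0)

    def test_zero_within_reported_missing(self):
        out = segregation_integration(self._table(0.0, 0.1))
        assert np.isnan(out.loc["N", "nsi"])

    def test_raw_nii_absolute_sum(self):
        out = segregation_integration(self._table(0.2, 0.1, b_exc=0.03, b_inh=-0.02))
        assert out.loc["N", "nii_raw"] == pytest.approx(0.05)

    def test_nii_normalization_by_max(self):
        scaled = normalize_nii(np.array([0.05, 0.02, 0.01]))
        np.testing.assert_allclose(scaled, [1.0, 0.4, 0.2])

    def test_mean_nsi_uses_mean_components(self):
        table = pd.DataFrame(
            {"within": [0.4, 0.2], "between": [0.1, 0.1],
             "between_exc": [0.1, 0.1], "between_inh": [0.0, 0.0]},
            index=pd.Index(["N1", "N2"], name="network"),
        )
        out = segregation_integration(table)
        expected = (0.3 - 0.1) / 0.3  # mean within 0.3, mean between 0.1
        assert out.attrs["mean_nsi"] == pytest.approx(expected)


class TestNodalStrengths:
    def test_hand_row_sums(self):
        values = np.array([
            [0.0, 0.2, -0.1, 0.3],
            [0.0, 0.0, 0.0, 0.0],
            [0.1, 0.1, 0.0, 0.1],
            [-0.2, 0.0, 0.0, 0.0],
        ])
        df = nodal_strengths(_ec(values))
        assert df.loc["R0", "ecs"] == pytest.approx(0.4)
        assert df.loc["R0", "ecs_exc"] == pytest.approx(0.5)
        assert df.loc["R0", "ecs_inh"] == pytest.approx(-0.1)

    def test_zero_matrix(self):
        df = nodal_strengths(_ec(np.zeros((3, 3))))
        assert (df[["ecs", "ecs_exc", "ecs_inh"]] == 0).all().all()

    def test_decomposition_identity_random(self, random_ec):
        for seed in range(25):
            ec = random_ec(6, seed=seed)
            df = nodal_strengths(ec)
            np.testing.assert_allclose(
                df["ecs"], df["ecs_exc"] + df["ecs_inh"], atol=1e-12
            )

    def test_network_ecs_mean_of_members(self, toy_parcellation, random_ec):
        ec = random_ec(4)
        ec = _ec(ec.values, toy_parcellation.region_ids)
        df = nodal_strengths(ec, toy_parcellation)
        net = df.attrs["network_ecs"]
        manual = df.iloc[:2]["ecs"].mean()
        assert net.loc["NA", "ecs"] == pytest.approx(manual)


class TestMetricProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(arrays(np.float64, (5, 5), elements=st.floats(-2.0, 2.0, allow_nan=False)))
    def test_ecs_sign_decomposition_any_matrix(self, values):
        ec = _ec(values)
        df = nodal_strengths(ec)
        np.testing.assert_allclose(df["ecs"], df["ecs_exc"] + df["ecs_inh"], atol=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(arrays(np.float64, (4, 4), elements=st.floats(-1.0, 1.0, allow_nan=False)))
    def test_global_mean_is_count_weighted_sign_combination(self, values):
        ec = _ec(values)
        out = global_means(ec)
        off = ~np.eye(4, dtype=bool)
        n_pos = int((values[off] > 0).sum())
        n_neg = int((values[off] < 0).sum())
        recombined = (n_pos * out["exc"] + n_neg * out["inh"]) / off.sum()
        assert out["overall"] == pytest.approx(recombined, abs=1e-12)


class TestScanMetricsBundle:
    def test_long_rows_cover_all_levels(self, toy_parcellation, random_ec):
        ec = random_ec(4)
        ec = _ec(ec.values, toy_parcellation.region_ids)
        sm = scan_metrics(ec, toy_parcellation, subject_id="s", age=9.0, sex=1, site="X")
        rows = pd.DataFrame(sm.long_rows())
        assert {"global_ec", "mean_nsi", "network_ecs", "nsi"} <= set(rows["metric"])
        global_row = rows[rows["metric"] == "global_ec"]["value"].iloc[0]
        assert global_row == pytest.approx(global_means(ec)["overall"])

    def test_nsi_bounded_for_positive_components(self):
        rng = np.random.default_rng(1)
        ids = tuple(f"R{i}" for i in range(6))
        parc = Parcellation(ids, {r: ("X" if i < 3 else "Y") for i, r in enumerate(ids)},
                            ("X", "Y"))
        for _ in range(20):
            values = np.abs(rng.normal(0.2, 0.1, (6, 6)))
            values[:3, :3] += 0.5   # strong within-X block keeps EC_W > EC_B
            table = network_ec(_ec(values, ids), parc)
            out = segregation_integration(table)
            assert out.loc["X", "nsi"] <= 1.0
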