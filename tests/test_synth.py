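import numpy as np
import pytest

from lifespan_ec.io import reference_parcellation
from lifespan_ec.rdcm import build_frequency_glm, canonical_hrf
from lifespan_ec.synth import (
    CohortTruth,
    EdgeTrajectorySpec,
    SimulationSpec,
    default_truth,
    exact_discrete_dataset,
    generate_cohort,
    hierarchical_network,
    inverse_transform_age,
    make_lifespan_ec,
    simulate_bold,
    simulate_metric_cohort,
    transform_age,
)


DENSE_AGES = inverse_transform_age(np.linspace(0.0, np.log2(101.0), 20001))


class TestEdgeCurves:
    def test_zero_amplitude_constant(self):
        spec = EdgeTrajectorySpec(baseline=0.37, amplitude=0.0)
        values = spec.curve(np.array([0.0, 1.0, 9.0, 50.0]))
        np.testing.assert_allclose(values, 0.37, rtol=1e-12)

    @pytest.mark.parametrize("peak_age,rise,fall", [
        (9.0, 2.0, 2.0), (9.0, 2.5, 1.5), (3.0, 4.0, 0.6), (40.0, 1.0, 2.0),
    ])
    def test_planted_peak_brute_force_argmax(self, peak_age, rise, fall):
        spec = EdgeTrajectorySpec(
            baseline=0.0, amplitude=1.0, peak_age=peak_age,
            rise_rate=rise, fall_rate=fall,
        )
        curve = spec.curve(DENSE_AGES)
        argmax_age = DENSE_AGES[np.argmax(curve)]
        grid_step = np.max(np.diff(DENSE_AGES[DENSE_AGES < peak_age + 2]))
        assert abs(argmax_age - peak_age) <= 2 * grid_step + 1e-9

    def test_symmetric_parameters_symmetric_values(self):
        spec = EdgeTrajectorySpec(baseline=0.0, amplitude=1.0, peak_age=9.0,
                                  rise_rate=2.0, fall_rate=2.0)
        tp = transform_age(9.0)
        for dt in (0.3, 0.8, 1.5):
            lo = float(spec.curve(inverse_transform_age(tp - dt)))
            hi = float(spec.curve(inverse_transform_age(tp + dt)))
            assert lo == pytest.approx(hi, abs=1e-10)

    def test_inhibitory_edge_sign_fixed(self):
        spec = EdgeTrajectorySpec(baseline=0.2, amplitude=0.15, sign=-1)
        values = spec.curve(DENSE_AGES[::100])
        assert np.all(values < 0)


class TestGeneratingMatrices:
    def test_all_emitted_matrices_stable(self, toy_parcellation):
        rng = np.random.default_rng(3)
        truth = default_truth(toy_parcellation, rng)
        for age in (0.1, 2.0, 9.0, 40.0, 95.0):
            A, _ = make_lifespan_ec(age, 1, "BCP", 0.01, truth, 4)
            assert np.max(np.linalg.eigvals(A).real) < 0

    def test_diagonal_negative(self, toy_parcellation):
        rng = np.random.default_rng(3)
        truth = default_truth(toy_parcellation, rng)
        A, _ = make_lifespan_ec(9.0, -1, "BCP", 0.0, truth, 4)
        assert np.all(np.diag(A) < 0)

    def test_hierarchical_network_stable_and_signed(self):
        A = hierarchical_network(seed=0)
        assert np.max(np.linalg.eigvals(A).real) < 0
        off = A[~np.eye(10, dtype=bool)]
        assert (off > 0).sum() >= 18  # chain edges
        assert (off < 0).sum() == 5   # planted inhibition


class TestSimulateBold:
    def test_same_seed_identical(self):
        A = hierarchical_network(n_regions=4, n_inhibitory=2, seed=1)
        spec = SimulationSpec(n_regions=4, tr=0.8, n_timepoints=80, snr=3.0)
        r1 = simulate_bold(A, spec, seed=9)
        r2 = simulate_bold(A, spec, seed=9)
        np.testing.assert_array_equal(r1.series, r2.series)

    def test_unstable_matrix_rejected(self):
        A = np.array([[0.1, 0.0], [0.0, -1.0]])
        spec = SimulationSpec(n_regions=2, n_timepoints=80)
        with pytest.raises(ValueError, match="spectral abscissa"):
            simulate_bold(A, spec, seed=0)

    def test_noise_free_decay_matches_closed_form(self):
        # A = -I, no driving noise, nonzero initial state: the neuronal
        # state is x0 * exp(-t) and BOLD is its HRF convolution.
        spec = SimulationSpec(
            n_regions=2, tr=0.5, n_timepoints=64, snr=np.inf,
            driving_noise_sd=0.0, burnin_volumes=0,
        )
        x0 = np.array([2.0, -1.5])
        run = simulate_bold(-np.eye(2), spec, seed=0, initial_state=x0)

        dt = spec.neuronal_dt
        oversample = int(round(spec.tr / dt))
        n_steps = spec.n_timepoints * oversample
        # independent discrete reference: exact Euler recursion + convolution
        tgrid = dt * np.arange(1, n_steps + 1)
        decay = (1.0 - dt) ** np.arange(1, n_steps + 1)  # Euler decay factor
        kernel = canonical_hrf(tr=dt, duration=spec.hrf_duration).samples
        for j in range(2):
            x = x0[j] * decay
            bold = np.convolve(x, kernel)[:n_steps]
            expected = bold[oversample - 1 :: oversample]
            np.testing.assert_allclose(run.series[:, j], expected, rtol=1e-10)

    def test_directed_coupling_shows_in_lagged_crosscorrelation(self):
        A = np.array([[-1.0, 0.0], [0.9, -1.0]])  # 1 -> 2 only
        spec = SimulationSpec(n_regions=2, tr=0.72, n_timepoints=500, snr=10.0)
        run = simulate_bold(A, spec, seed=4)
        x, y = run.series[:, 0], run.series[:, 1]
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        lag = 2
        fwd = np.mean(x[:-lag] * y[lag:])   # region 1 leads region 2
        rev = np.mean(y[:-lag] * x[lag:])
        assert fwd > rev


class TestExactDiscreteData:
    def test_zero_residual_at_generating_parameters(self):
        rng = np.random.default_rng(8)
        r, n, tr = 4, 128, 0.72
        A = hierarchical_network(n_regions=r, n_inhibitory=2, seed=8)
        C = rng.normal(0, 1, (r, 1))
        u = rng.normal(0, 10, (1, n))
        hrf = canonical_hrf(tr)
        series = exact_discrete_dataset(A, C, u, tr, hrf)
        from lifespan_ec.io import BoldRun

        run = BoldRun("s", 20.0, 1, "SIM", tr, series, tuple(f"R{i}" for i in range(r)))
        design = build_frequency_glm(run, hrf=hrf, inputs=u)
        theta = np.hstack([A, C])
        resid = design.Y - design.X @ theta.T
        scale = np.abs(design.Y).max()
        assert np.abs(resid).max() < 1e-9 * scale


class TestCohorts:
    def test_reproducible_and_balanced(self, tmp_path):
        parc = reference_parcellation({"NA": 3, "NB": 3})
        spec = SimulationSpec(n_regions=6, tr=0.8, n_timepoints=64,
                              snr=3.0, parcellation=parc)
        m1, t1 = generate_cohort(10, spec, seed=5, out_dir=tmp_path / "a")
        m2, t2 = generate_cohort(10, spec, seed=5, out_dir=tmp_path / "b")
        assert len(m1.table) >= 10
        sexes = m1.table.drop_duplicates("subject_id")["sex"]
        assert abs(int(sexes.sum())) <= 1
        # byte-identical outputs under the same seed
        for name in ["manifest.tsv", "truth.json"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        s1 = sorted((tmp_path / "a" / "series").iterdir())
        s2 = sorted((tmp_path / "b" / "series").iterdir())
        assert [p.name for p in s1] == [p.name for p in s2]
        for p1, p2 in zip(s1, s2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_zero_sex_effect_balances_generated_ec(self, toy_parcellation):
        rng = np.random.default_rng(10)
        truth = default_truth(toy_parcellation, rng, sex_effect_sd=0.0)
        A_m, _ = make_lifespan_ec(9.0, 1, "BCP", 0.0, truth, 4)
        A_f, _ = make_lifespan_ec(9.0, -1, "BCP", 0.0, truth, 4)
        np.testing.assert_allclose(A_m, A_f, atol=1e-12)

    def test_metric_cohort_size_and_columns(self):
        df, spec = simulate_metric_cohort(n_scans=150, seed=3)
        assert len(df) == 150
        assert set(df.columns) == {"subject_id", "age", "t", "sex", "site", "value"}
        assert df["age"].min() >= 0
        assert set(df["sex"]) == {1, -1}


class TestAgeTransform:
    @pytest.mark.parametrize("age,t", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_log_transform_values(self, age, t):
        assert transform_age(age) == pytest.approx(t)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            transform_age(-0.5)
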