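"""The decomposition core: trapezoids, pseudoinverse steps, kernels, costs."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import laminarpa as lp
from laminarpa.containers import ProbeGeometry, RateMatrix, RecordingMatrix, SignalKind
from laminarpa.core import KernelParams, PopulationModel, TrapezoidProfile


def _mat(values, kind=SignalKind.MUA, dt=1.0):
    return RecordingMatrix(values, dt=dt, kind=kind)


class TestTrapezoid:
    @pytest.mark.parametrize(
        "depth, expected",
        [(0.0, 1.0), (75.0, 0.5), (200.0, 0.0), (-50.0, 1.0), (-100.0, 0.0)],
    )
    def test_pointwise_values(self, depth, expected):
        profile = TrapezoidProfile(z=0.0, a=100.0, b=50.0)
        assert lp.trapezoid_eval(profile, depth) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(
        z=st.floats(-500, 500),
        a=st.floats(0, 300),
        b=st.floats(1, 200),
        depth=st.floats(-1200, 1200),
    )
    def test_weight_bounded_and_supported(self, z, a, b, depth):
        profile = TrapezoidProfile(z=z, a=a, b=b)
        w = lp.trapezoid_eval(profile, depth)
        assert 0.0 <= w <= 1.0
        lo, hi = profile.support
        if depth < lo - 1e-6 or depth > hi + 1e-6:
            assert w == 0.0
        if abs(depth - z) <= a / 2.0:
            assert w == pytest.approx(1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TrapezoidProfile(z=0, a=-1.0, b=10.0)
        with pytest.raises(ValueError):
            TrapezoidProfile(z=0, a=10.0, b=0.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PopulationModel(
                (TrapezoidProfile(0, 100, 20), TrapezoidProfile(100, 100, 20))
            )


class TestSpatialMatrix:
    def test_disjoint_supports_disjoint_columns(self):
        geom = ProbeGeometry(depths_um=np.arange(6) * 50.0)
        model = PopulationModel(
            (TrapezoidProfile(50, 80, 10), TrapezoidProfile(200, 80, 10))
        )
        m = lp.build_spatial_matrix(model, geom)
        assert np.all((m > 0).sum(axis=0) <= 1)

    def test_uncovered_population_warns(self):
        geom = ProbeGeometry(depths_um=np.array([0.0, 400.0]))
        model = PopulationModel((TrapezoidProfile(200, 20, 10),))
        with pytest.warns(UserWarning, match="no channel"):
            lp.build_spatial_matrix(model, geom)

    def test_against_direct_evaluation(self, truth):
        # direct per-channel evaluation oracle on the 5-layer fixture
        m = lp.build_spatial_matrix(truth.populations, truth.geometry)
        for n, profile in enumerate(truth.populations.profiles):
            for i, depth in enumerate(truth.geometry.depths_um):
                lo, hi = profile.support
                d = abs(depth - profile.z)
                if d <= profile.a / 2:
                    expected = 1.0
                elif depth < lo or depth > hi:
                    expected = 0.0
                else:
                    expected = (profile.a / 2 + profile.b - d) / profile.b
                assert m[n, i] == pytest.approx(expected)


class TestInferRates:
    def test_identity_spatial_matrix(self, rng):
        phi = _mat(rng.standard_normal((3, 40)))
        rates = lp.infer_rates(np.eye(3), phi)
        assert np.allclose(rates.values, phi.values)

    def test_exact_recovery(self, rng):
        m = np.array([[1.0, 0.5, 0.0, 0.0], [0.0, 0.0, 0.8, 1.0]])
        r0 = rng.standard_normal((2, 30))
        rates = lp.infer_rates(m, _mat(m.T @ r0))
        assert np.allclose(rates.values, r0, atol=1e-12)

    def test_matches_normal_equations(self, rng):
        # independent dense least-squares oracle on a noisy toy problem
        m = np.array([[1.0, 0.6, 0.1], [0.0, 0.4, 1.0]])
        phi = m.T @ rng.standard_normal((2, 25)) + 0.1 * rng.standard_normal((3, 25))
        rates = lp.infer_rates(m, _mat(phi))
        oracle = np.linalg.solve(m @ m.T, m @ phi)
        assert np.allclose(rates.values, oracle, atol=1e-10)

    def test_rank_deficient_rejected(self):
        m = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="rank deficient"):
            lp.infer_rates(m, _mat(np.ones((2, 5)) + np.arange(5)))


class TestReconstruct:
    def test_flat_profile_constant_rate(self):
        out = lp.reconstruct(np.ones((1, 4)), np.ones((1, 10)))
        assert np.allclose(out, 1.0)

    def test_equals_naive_double_loop(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((4, 7))
        r = rng.standard_normal((4, 9))
        out = lp.reconstruct(m, r)
        oracle = np.zeros((7, 9))
        for n in range(4):
            for i in range(7):
                for j in range(9):
                    oracle[i, j] += m[n, i] * r[n, j]
        assert np.allclose(out, oracle)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="align"):
            lp.reconstruct(np.ones((3, 4)), np.ones((5, 10)))


class TestRelativeMse:
    def test_limits(self, rng):
        x = rng.standard_normal((4, 6))
        assert lp.relative_mse(x, x) == 0.0
        assert lp.relative_mse(x, np.zeros_like(x)) == pytest.approx(1.0)
        assert lp.relative_mse(x, 2 * x) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            lp.relative_mse(np.zeros((2, 2)), np.ones((2, 2)))


class TestExpKernel:
    def test_causality(self):
        h = lp.exp_kernel(tau_ms=7.0, delay_ms=12.0, dt=1.0, n_bins=100)
        assert np.all(h[:12] == 0.0)
        assert h[12] > 0.0

    def test_unit_mass(self):
        # Riemann mass converges to 1 from above (bias ~ dt / 2 tau)
        h = lp.exp_kernel(tau_ms=10.0, delay_ms=0.0, dt=0.25, n_bins=4000)
        assert h.sum() * 0.25 == pytest.approx(1.0, rel=0.05)
        coarse = lp.exp_kernel(tau_ms=10.0, delay_ms=0.0, dt=1.0, n_bins=1000)
        assert coarse.sum() * 1.0 > h.sum() * 0.25

    def test_closed_form_values(self):
        h = lp.exp_kernel(tau_ms=5.0, delay_ms=3.0, dt=1.0, n_bins=20)
        assert h[3] == pytest.approx(0.2)
        assert h[8] == pytest.approx(0.2 * np.exp(-1.0))

    def test_invalid_tau(self):
        with pytest.raises(ValueError, match="tau"):
            lp.exp_kernel(tau_ms=0.0, delay_ms=0.0, dt=1.0, n_bins=10)


class TestPostsynapticProfiles:
    def test_impulse_yields_shifted_kernel(self):
        b = 200
        r = np.zeros((1, b))
        k = 40
        r[0, k] = 1.0 / 1.0  # unit impulse of rate over one 1-ms bin
        rates = RateMatrix(r, dt=1.0)
        kern = KernelParams([6.0], [5.0])
        out = lp.postsynaptic_profiles(rates, kern)
        h = lp.exp_kernel(6.0, 5.0, 1.0, b)
        assert np.allclose(out[0, k:], h[: b - k], atol=1e-12)
        assert np.allclose(out[0, :k], 0.0, atol=1e-12)

    def test_steady_state_passes_constant(self):
        rates = RateMatrix(np.full((1, 600), 4.0), dt=1.0)
        out = lp.postsynaptic_profiles(rates, KernelParams([8.0], [2.0]))
        # steady state = rate times the (Riemann) kernel mass, which itself
        # approaches 1; both identities hold
        mass = lp.exp_kernel(8.0, 2.0, 1.0, 600).sum() * 1.0
        assert np.allclose(out[0, 200:], 4.0 * mass, rtol=1e-9)
        assert np.allclose(out[0, 200:], 4.0, rtol=0.1)

    def test_matches_naive_convolution(self):
        rng = np.random.default_rng(5)
        b = 120
        rates = RateMatrix(rng.standard_normal((2, b)), dt=0.5)
        kern = KernelParams([4.0, 9.0], [1.0, 3.0])
        out = lp.postsynaptic_profiles(rates, kern)
        for n in range(2):
            h = lp.exp_kernel(kern.tau_ms[n], kern.delay_ms[n], 0.5, b)
            oracle = np.zeros(b)
            for j in range(b):
                for k in range(j + 1):
                    oracle[j] += rates.values[n, k] * h[j - k] * 0.5
            assert np.allclose(out[n], oracle, atol=1e-10)

    def test_causality_with_silent_prelude(self):
        # zero rate before onset -> zero postsynaptic profile before onset+delay
        b = 100
        r = np.zeros((1, b))
        r[0, 30:] = 2.0
        out = lp.postsynaptic_profiles(RateMatrix(r, dt=1.0), KernelParams([5.0], [10.0]))
        assert np.allclose(out[0, :40], 0.0, atol=1e-12)
        assert out[0, 40] > 0.0


class TestInferSpatialField:
    def test_recovers_planted_field(self, rng):
        r = rng.standard_normal((3, 80))
        l0 = rng.standard_normal((10, 3))
        field = _mat(l0 @ r, kind=SignalKind.CSD)
        l_est = lp.infer_spatial_field(field, r)
        assert np.allclose(l_est, l0, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        r = rng.standard_normal((2, 40))
        field = _mat(rng.standard_normal((3, 40)), kind=SignalKind.CSD)
        l_est = lp.infer_spatial_field(field, r)
        oracle = field.values @ r.T @ np.linalg.inv(r @ r.T)
        assert np.allclose(l_est, oracle, atol=1e-10)

    def test_collinear_rates_warn_with_pair(self, rng):
        base = rng.standard_normal(60)
        r = np.vstack([base, base, rng.standard_normal(60)])
        field = _mat(rng.standard_normal((5, 60)), kind=SignalKind.CSD)
        with pytest.warns(UserWarning, match="near-collinear"):
            lp.infer_spatial_field(field, r, labels=("a", "b", "c"))


class TestCsdCost:
    def test_lambda_zero_reduces_to_relative_mse(self, rng):
        c = rng.standard_normal((6, 30))
        est = rng.standard_normal((6, 30))
        assert lp.csd_cost(c, est, 0.0) == lp.relative_mse(c, est)

    def test_balanced_estimate_unpenalized(self, rng):
        c = rng.standard_normal((4, 20))
        est = np.vstack([np.ones((2, 20)), -np.ones((2, 20))])
        assert lp.csd_cost(c, est, 5.0) == pytest.approx(lp.relative_mse(c, est))

    def test_affine_in_lambda(self, rng):
        c = rng.standard_normal((4, 20))
        est = rng.standard_normal((4, 20))
        costs = [lp.csd_cost(c, est, lam) for lam in (0.0, 1.0, 2.0)]
        assert costs[2] - costs[1] == pytest.approx(costs[1] - costs[0])
        assert costs[1] > costs[0]


class TestRateBookkeeping:
    def _rates(self, values, dt=1.0, labels=None, external=None):
        return RateMatrix(values, dt=dt, labels=labels or (), external=external or ())

    def test_append_external(self, rng):
        internal = self._rates(rng.standard_normal((4, 30)), labels=("a", "b", "c", "d"))
        external = RateMatrix(
            rng.standard_normal((3, 30)), dt=1.0,
            labels=("x", "y", "z"), external=(True,) * 3,
        )
        out = lp.append_external_rates(internal, external)
        assert out.n_populations == 7
        assert out.labels == ("a", "b", "c", "d", "x", "y", "z")
        assert out.external == (False,) * 4 + (True,) * 3

    def test_append_empty_identity(self, rng):
        internal = self._rates(rng.standard_normal((2, 30)))
        empty = RateMatrix(np.zeros((0, 30)), dt=1.0)
        assert lp.append_external_rates(internal, empty) is internal

    def test_append_time_base_mismatch(self, rng):
        internal = self._rates(rng.standard_normal((2, 30)))
        external = RateMatrix(rng.standard_normal((1, 30)), dt=2.0, external=(True,))
        with pytest.raises(ValueError, match="time base"):
            lp.append_external_rates(internal, external)

    def test_merge_groups_sum(self, rng):
        values = rng.standard_normal((4, 20))
        rates = self._rates(values, labels=("L2/3", "L4", "L5", "L6"))
        merged = lp.merge_populations(
            rates, {"upper": ("L2/3", "L4"), "deep": ("L5", "L6")}
        )
        assert merged.labels == ("upper", "deep")
        assert np.allclose(merged.values[0], values[0] + values[1])

    def test_merge_singletons_identity(self, rng):
        values = rng.standard_normal((2, 20))
        rates = self._rates(values, labels=("a", "b"))
        merged = lp.merge_populations(rates, {"a": ("a",), "b": ("b",)})
        assert np.allclose(merged.values, values)

    def test_merge_equal_rows_mean_unchanged(self):
        row = np.linspace(0, 1, 20)
        rates = self._rates(np.vstack([row, row]), labels=("a", "b"))
        merged = lp.merge_populations(
            rates, {"ab": ("a", "b")}, cell_counts={"a": 10, "b": 30}
        )
        assert np.allclose(merged.values[0], row)

    def test_merge_requires_partition(self, rng):
        rates = self._rates(rng.standard_normal((2, 20)), labels=("a", "b"))
        with pytest.raises(ValueError, match="partition"):
            lp.merge_populations(rates, {"g": ("a",)})


class TestFitMua:
    def test_single_population_flat_mua(self):
        geom = ProbeGeometry(depths_um=40.0 * np.arange(8))
        mua = _mat(np.full((8, 60), 2.0) + 0.1 * np.sin(np.arange(60))[None, :])
        cfg = lp.AnalysisConfig(n_populations=1, rng_seed=0, de_maxiter=60)
        fit = lp.fit_mua(mua, geom, cfg)
        assert fit.error < 1e-6
        weights = lp.build_spatial_matrix(fit.model, geom)
        assert np.all(weights > 0.999)  # trapezoid plateau spans the probe

    def test_seed_invariance_of_error(self, rng):
        geom = ProbeGeometry(depths_um=50.0 * np.arange(8))
        m = np.vstack([
            lp.trapezoid_eval(TrapezoidProfile(75, 100, 25), geom.depths_um),
            lp.trapezoid_eval(TrapezoidProfile(275, 100, 25), geom.depths_um),
        ])
        mua = _mat(m.T @ np.abs(rng.standard_normal((2, 80))) + 1.0)
        errors = []
        for seed in (0, 1):
            cfg = lp.AnalysisConfig(n_populations=2, rng_seed=seed, de_maxiter=150)
            errors.append(lp.fit_mua(mua, geom, cfg).error)
        assert abs(errors[0] - errors[1]) < 1e-3

    def test_rescaled_data_rescales_rates_not_profiles(self, truth, recordings, mua_fit):
        # unit trapezoid height pins the spatial scale; amplitude lives in rates
        cfg = lp.AnalysisConfig(n_populations=5, rng_seed=1)
        scaled = recordings.mua.with_values(recordings.mua.values * 3.0)
        fit2 = lp.fit_mua(scaled, truth.geometry, cfg)
        assert np.allclose(fit2.spatial, mua_fit.spatial, atol=1e-6)
        assert np.allclose(fit2.rates.values, 3.0 * mua_fit.rates.values, rtol=1e-5)

    def test_infeasible_population_count(self):
        geom = ProbeGeometry(depths_um=np.array([0.0, 40.0, 80.0]))
        mua = _mat(np.ones((3, 10)) + np.arange(10))
        with pytest.raises(ValueError, match="cannot place"):
            lp.fit_mua(mua, geom, lp.AnalysisConfig(n_populations=4))


class TestDecompositionInvariants:
    def test_contributions_sum_exactly(self, csd_fit):
        assert np.array_equal(
            csd_fit.contributions.sum(axis=0), csd_fit.reconstruction
        )

    def test_lambda_zero_error_is_relative_mse(self, csd_fit, recordings):
        assert csd_fit.lambda_penalty == 0.0
        assert csd_fit.error == pytest.approx(
            lp.relative_mse(recordings.csd.values, csd_fit.reconstruction), abs=1e-12
        )

    def test_determinism_same_seed(self, recordings, truth):
        cfg = lp.AnalysisConfig(rng_seed=3, de_maxiter=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = lp.fit_csd(recordings.csd, truth.rates_all, cfg)
            b = lp.fit_csd(recordings.csd, truth.rates_all, cfg)
        assert np.array_equal(a.kernels.tau_ms, b.kernels.tau_ms)
        assert np.array_equal(a.contributions, b.contributions)


class TestLayerClassification:
    def test_population_layer_by_maximal_overlap(self, geometry):
        model = PopulationModel(
            (TrapezoidProfile(60, 80, 20), TrapezoidProfile(200, 100, 30))
        )
        labels = lp.population_layer_labels(model, geometry)
        assert labels == ("L1", "L2/3")

    def test_true_layers_partition_channels(self, geometry):
        layers = lp.true_channel_layers(geometry)
        assert len(layers) == geometry.n_channels
        assert set(layers) == set(geometry.layer_names)

    def test_uncovered_channel_assigned_to_nearest(self, geometry):
        model = PopulationModel(
            (TrapezoidProfile(60, 80, 20), TrapezoidProfile(900, 200, 30))
        )
        predicted = lp.classify_channels(model, geometry)
        assert len(predicted) == geometry.n_channels
        # mid-probe channels fall to whichever support edge is closest
        assert predicted[3] == "L1"
        assert predicted[-1] == "L6"
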