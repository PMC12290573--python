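import numpy as np
import pandas as pd
import pytest

from trend.forward import (
    BOLDTimeSeries,
    DivergenceError,
    add_measurement_noise,
    bold_observation,
    hemo_drift,
    integrate,
    neuronal_drift,
    oxygen_extraction,
)
from trend.graph import NetworkGraph
from trend.params import (
    ConnectivityParams,
    HemoParams,
    NeuronalParams,
    pack_theta,
    unpack_theta,
)
from trend.stimulus import StimulusDesign


class TestOxygenExtraction:
    def test_rest_identity(self):
        assert oxygen_extraction(1.0, 0.4) == pytest.approx(0.4)

    def test_closed_form(self):
        # E(2) = 1 - 0.6^0.5
        assert oxygen_extraction(2.0, 0.4) == pytest.approx(1 - 0.6**0.5, abs=1e-12)

    def test_limits_and_monotonicity(self):
        f = np.linspace(0.05, 50, 200)
        e = oxygen_extraction(f, 0.4)
        assert np.all(np.diff(e) < 0)  # extraction falls as flow rises
        assert oxygen_extraction(1e4, 0.4) < 1e-3
        assert oxygen_extraction(1e-3, 0.4) > 0.999

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            oxygen_extraction(0.0, 0.4)
        with pytest.raises(ValueError):
            oxygen_extraction(1.0, 1.5)


class TestNeuronalDrift:
    def test_resting_fixed_point(self):
        n = NeuronalParams.default(2)
        c = ConnectivityParams(np.zeros((2, 2)), [], np.zeros((2, 1)))
        d_e, d_i = neuronal_drift(np.zeros(2), np.zeros(2), np.zeros(1), n, c)
        np.testing.assert_array_equal(d_e, 0)
        np.testing.assert_array_equal(d_i, 0)

    def test_inhibitory_equilibrium_line(self):
        n = NeuronalParams(np.full(2, 0.5), np.full(2, 0.7), np.full(2, 1.0))
        c = ConnectivityParams(np.zeros((2, 2)), [], np.zeros((2, 1)))
        x = np.array([1.3, -0.4])
        _, d_i = neuronal_drift(x, x.copy(), np.zeros(1), n, c)
        np.testing.assert_allclose(d_i, 0)

    def test_single_edge_arithmetic(self):
        # S=2, A_21=0.5, x_E=(1,0), sigma=mu=0 (tiny positive to satisfy
        # positivity), no input: drift is (~0, 0.5)
        eps = 1e-12
        n = NeuronalParams(np.full(2, eps), np.full(2, 0.2), np.full(2, eps))
        A = np.array([[0.0, 0.0], [0.5, 0.0]])
        c = ConnectivityParams(A, [], np.zeros((2, 1)))
        d_e, _ = neuronal_drift(np.array([1.0, 0.0]), np.zeros(2), np.zeros(1), n, c)
        np.testing.assert_allclose(d_e, [0.0, 0.5], atol=1e-10)

    def test_nonfinite_rejected(self):
        n = NeuronalParams.default(1)
        c = ConnectivityParams(np.zeros((1, 1)), [], np.zeros((1, 1)))
        with pytest.raises(FloatingPointError):
            neuronal_drift(np.array([np.nan]), np.zeros(1), np.zeros(1), n, c)


class TestHemoDrift:
    def rest(self, S=1):
        return {"s": np.zeros(S), "f": np.ones(S), "v": np.ones(S), "q": np.ones(S)}

    @pytest.mark.parametrize("variant", ["pdcm", "sdcm"])
    def test_rest_is_fixed_point(self, variant):
        d = hemo_drift(self.rest(), np.zeros(1), HemoParams(), variant)
        for key, val in d.items():
            np.testing.assert_allclose(val, 0, err_msg=key)

    def test_inflow_outflow_balance(self):
        hp = HemoParams()
        state = self.rest()
        state["v"] = np.array([1.2])
        state["f"] = state["v"] ** (1 / hp.alpha)
        d = hemo_drift(state, np.zeros(1), hp, "pdcm")
        np.testing.assert_allclose(d["v"], 0, atol=1e-14)

    def test_hand_evaluated_pdcm_drifts(self):
        # independent scalar evaluation of the closed forms
        hp = HemoParams(phi=0.6, tau_mtt=2.0, tau_visc=4.0, alpha=0.32, e0=0.4)
        f, v, q = 1.4, 1.1, 1.0
        state = {"s": np.array([0.2]), "f": np.array([f]),
                 "v": np.array([v]), "q": np.array([q])}
        x_e = np.array([0.5])
        d = hemo_drift(state, x_e, hp, "pdcm")
        w = v ** (1 / 0.32)
        dv = (f - w) / 6.0
        e_f = 1 - 0.6 ** (1 / f)
        dq = (f * e_f / 0.4 - (w + 4.0 * dv) * q / v) / 2.0
        assert d["s"][0] == pytest.approx(0.5 - 0.6 * 0.2)
        assert d["f"][0] == pytest.approx(0.6 * (0.2 - 0.4))
        assert d["v"][0] == pytest.approx(dv)
        assert d["q"][0] == pytest.approx(dq)

    def test_nonpositive_volume_rejected(self):
        state = self.rest()
        state["v"] = np.array([-0.1])
        with pytest.raises(DivergenceError):
            hemo_drift(state, np.zeros(1), HemoParams(), "pdcm")


class TestBoldObservation:
    def test_baseline_zero(self):
        assert bold_observation(1.0, 1.0, HemoParams()) == pytest.approx(0.0)

    def test_middle_term_cancels_when_q_equals_v(self):
        hp = HemoParams(v0=4, k1=4.92, k2=0.57, k3=0.46)
        x = 1.17
        expected = 4 * (4.92 * (1 - x) + 0.46 * (1 - x))
        assert bold_observation(x, x, hp) == pytest.approx(expected)

    def test_hand_substitution(self):
        hp = HemoParams(v0=4, k1=4.92, k2=0.57, k3=0.46)
        v, q = 1.05, 0.9
        expected = 4 * (4.92 * 0.1 + 0.57 * (1 - 0.9 / 1.05) + 0.46 * (-0.05))
        assert bold_observation(v, q, hp) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            bold_observation(0.0, 1.0, HemoParams())


class TestIntegrate:
    @pytest.mark.parametrize("variant", ["pdcm", "sdcm"])
    def test_zero_stimulus_gives_exact_zero(self, variant, single_region_setup):
        graph, neuronal, conn, _ = single_region_setup
        quiet = StimulusDesign(1, ["driving"], [[]], 60.0, 0.01)
        ts = integrate(graph, neuronal, conn, quiet, 1.0, variant=variant)
        assert np.all(ts.Y == 0.0)

    def test_sample_count(self, single_region_setup):
        graph, neuronal, conn, design = single_region_setup
        ts = integrate(graph, neuronal, conn, design, 1.5)
        assert ts.n_samples == int(np.floor(design.total_duration / 1.5))

    def test_grid_refinement(self, three_region):
        """Halving dt ten-fold changes no sample by more than 0.1% of peak."""
        sc = three_region
        coarse = integrate(sc.graph, sc.neuronal, sc.conn, sc.design, sc.tr,
                           dt_sim=0.01)
        fine = integrate(sc.graph, sc.neuronal, sc.conn, sc.design, sc.tr,
                         dt_sim=0.001)
        peak = np.abs(fine.Y).max()
        assert np.abs(coarse.Y - fine.Y).max() <= 1e-3 * peak

    def test_runge_kutta_oracle(self, two_region):
        """Euler at 10 ms agrees with an adaptive RK45 solution of the same
        vector field (independent integration route)."""
        from scipy.integrate import solve_ivp

        graph, neuronal, conn, design = two_region
        hp = HemoParams()
        U = design.on_grid(0.01)

        def rhs(t, z):
            S = 2
            x_e, x_i, s, f, v, q = z.reshape(6, S)
            i = min(int(t / 0.01), U.shape[0] - 1)
            u = U[i]
            d_e, d_i = neuronal_drift(x_e, x_i, u, neuronal, conn, design)
            hd = hemo_drift({"s": s, "f": f, "v": v, "q": q}, x_e, hp, "pdcm")
            return np.concatenate([d_e, d_i, hd["s"], hd["f"], hd["v"], hd["q"]])

        z0 = np.concatenate([np.zeros(6), np.ones(6)])
        t_eval = np.arange(120) * 1.0
        sol = solve_ivp(rhs, (0, 119.0), z0, t_eval=t_eval, max_step=0.25,
                        rtol=1e-8, atol=1e-10)
        v = sol.y[4 * 2 : 5 * 2].T
        q = sol.y[5 * 2 : 6 * 2].T
        y_rk = bold_observation(v, q, hp)
        y_euler = integrate(graph, neuronal, conn, design, 1.0, dt_sim=0.01).Y
        peak = np.abs(y_rk).max()
        assert np.abs(y_euler - y_rk).max() <= 2e-3 * peak

    def test_divergence_reported_with_time(self, two_region, single_region_design):
        # mutually excitatory pair with coupling far above the self-decay:
        # neuronal activity grows without bound and the trajectory is
        # rejected with the failure time attached
        a_mask = np.array([[0, 1], [1, 0]], dtype=np.int8)
        graph = NetworkGraph(2, a_mask, c_mask=np.array([[1], [0]], dtype=np.int8))
        neuronal = NeuronalParams.default(2)
        A = np.array([[0.0, 5.0], [5.0, 0.0]])
        conn = ConnectivityParams(A, [], graph.c_mask.astype(float))
        design = single_region_design
        with pytest.raises(DivergenceError) as exc:
            integrate(graph, neuronal, conn, design, 1.0)
        assert exc.value.t_fail > 0

    def test_sensitivities_match_finite_differences(self, two_region):
        graph, neuronal, conn, design = two_region
        ts, dY = integrate(graph, neuronal, conn, design, 1.0,
                           return_sensitivities=True)
        theta0 = pack_theta(neuronal, conn, graph)
        eps = 1e-5
        for p in range(theta0.size):
            up, dn = theta0.copy(), theta0.copy()
            up[p] += eps
            dn[p] -= eps
            yp = integrate(graph, *unpack_theta(up, graph), design, 1.0).Y
            ym = integrate(graph, *unpack_theta(dn, graph), design, 1.0).Y
            fd = (yp - ym) / (2 * eps)
            scale = max(np.abs(fd).max(), 1e-8)
            assert np.abs(dY[:, :, p] - fd).max() / scale < 1e-3


class TestTransients:
    def test_pdcm_poststimulus_undershoot(self, single_region_setup):
        graph, neuronal, conn, design = single_region_setup
        y = integrate(graph, neuronal, conn, design, 1.0).Y[:, 0]
        offset = 50  # stimulus ends at t=50 s
        post = y[offset:]
        assert y[:offset].max() > 0
        assert post.min() < -0.05 * y.max()  # sustained negative excursion
        below = post < 0
        # undershoot lasts several consecutive seconds
        runs = np.diff(np.where(np.concatenate(([0], below, [0])))[0])
        assert below.sum() >= 5
        assert abs(y[-1]) < 1e-3 * y.max()  # returns to baseline

    def test_sdcm_response_differs(self, single_region_setup):
        graph, neuronal, conn, design = single_region_setup
        y_p = integrate(graph, neuronal, conn, design, 1.0).Y[:, 0]
        y_s = integrate(graph, neuronal, conn, design, 1.0, variant="sdcm").Y[:, 0]
        # S-DCM lacks the deep viscoelastic undershoot of P-DCM
        assert y_s[50:].min() > y_p[50:].min() + 0.5
        assert np.abs(y_p - y_s).max() > 1.0

    def test_golden_traces_regression(self, single_region_setup, datadir=None):
        import pathlib

        graph, neuronal, conn, design = single_region_setup
        golden = pd.read_csv(
            pathlib.Path(__file__).parent / "data" / "golden_single_region_block.csv"
        )
        for variant in ("pdcm", "sdcm"):
            y = integrate(graph, neuronal, conn, design, 1.0, variant=variant).Y[:, 0]
            np.testing.assert_allclose(y, golden[variant].to_numpy(),
                                       rtol=1e-6, atol=1e-9)


class TestMeasurementNoise:
    def test_noiseless_passthrough(self, three_region_obs):
        out = add_measurement_noise(three_region_obs, np.inf, seed=0)
        np.testing.assert_array_equal(out.Y, three_region_obs.Y)

    def test_seed_determinism(self, three_region_obs):
        a = add_measurement_noise(three_region_obs, 10, seed=7)
        b = add_measurement_noise(three_region_obs, 10, seed=7)
        np.testing.assert_array_equal(a.Y, b.Y)
        c = add_measurement_noise(three_region_obs, 10, seed=8)
        assert not np.array_equal(a.Y, c.Y)

    def test_cnr_construction(self):
        rng = np.random.default_rng(0)
        base = BOLDTimeSeries(np.cumsum(rng.standard_normal((10_000, 2)), 0), 1.0)
        noisy = add_measurement_noise(base, 10, seed=1)
        ratio = base.Y.std(axis=0) / (noisy.Y - base.Y).std(axis=0)
        assert np.all((ratio > 9.5) & (ratio < 10.5))

    def test_constant_region_rejected(self):
        flat = BOLDTimeSeries(np.zeros((50, 1)) + 3.0, 1.0)
        with pytest.raises(ValueError):
            add_measurement_noise(flat, 10, seed=0)
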