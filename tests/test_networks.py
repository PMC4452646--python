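"""Adaptation motifs: means, linear-noise variances, SDE validation."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

from modnoise import (
    Motif,
    NetworkParams,
    ReceptorParams,
    Scheme,
    build_lna,
    iffl_variance_closed_form,
    lna_variance_numeric,
    mean_trajectories,
    ramp_linearization,
    simulate_sde,
    step_response,
)


@pytest.fixture(scope="module")
def iffl():
    return NetworkParams(motif=Motif.IFFL, k_x=10.0, k_y=5.0, b=1e-6)


@pytest.fixture(scope="module")
def ifl():
    return NetworkParams(motif=Motif.IFL, k_x=10.0, k_y=5.0, b=1.0)


@pytest.fixture(scope="module")
def ramp_lin_cm(ramp_params):
    return ramp_linearization(ramp_params, Scheme.CM)


class TestMeans:
    def test_iffl_flat_stimulus_output_is_one(self, iffl):
        p = ReceptorParams(k_plus=1.0, c0=1e6, k_minus=1e6, alpha=1e6, gamma=1.0)
        lin = ramp_linearization(p, Scheme.CM)
        mean_x, mean_y = mean_trajectories(iffl, lin)
        assert float(mean_x(123.0)) == pytest.approx(1.0)
        assert float(mean_y(0.0)) == pytest.approx(lin.u0 / iffl.k_y)

    def test_iffl_ramp_output_value(self):
        # b = 0.1 time, u1 = 2/time^2, k_y = 10/time -> x-mean = e^{0.02}
        net = NetworkParams(motif=Motif.IFFL, k_x=50.0, k_y=10.0, b=0.1)
        p = ReceptorParams(k_plus=1.0, c0=100.0, c1=2.42, k_minus=1e4, alpha=1e4, gamma=1.0)
        lin = ramp_linearization(p, Scheme.CM)
        lin.u1 = 2.0  # pin the ramp slope for the hand-evaluated value
        mean_x, _ = mean_trajectories(net, lin)
        assert float(mean_x(0.0)) == pytest.approx(np.exp(0.02))

    def test_ifl_precise_adaptation_mean(self, ifl):
        for c0 in (1e5, 1e6, 4e6):
            p = ReceptorParams(k_plus=1.0, c0=c0, k_minus=1e6, alpha=1e6, gamma=1.0)
            lin = ramp_linearization(p, Scheme.CM)
            mean_x, _ = mean_trajectories(ifl, lin)
            assert float(mean_x(10.0)) == pytest.approx(1.0)

    def test_ifl_ramp_mean_y_solves_balance(self, ifl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.CM)
        mean_x, mean_y = mean_trajectories(ifl, lin)
        # u(t) e^{-b y(t)} = k_x <x> at first order
        t = 2.0
        lhs = lin.mean_u(t) * np.exp(-ifl.b * float(mean_y(t)))
        assert lhs == pytest.approx(ifl.k_x * float(mean_x(t)), rel=1e-3)


class TestLNAVariance:
    def test_zero_intensity_means_zero_covariance(self, iffl):
        p = ReceptorParams(k_plus=1.0, c0=1e6, k_minus=1e6, alpha=1e6, gamma=1.0)
        lin = ramp_linearization(p, Scheme.CM)
        lin.intensity = lambda t: 0.0
        res = lna_variance_numeric(iffl, lin, np.linspace(0.1, 2.0, 5))
        assert np.allclose(res.var_x, 0.0, atol=1e-15)
        assert np.allclose(res.var_y, 0.0, atol=1e-15)

    @pytest.mark.parametrize("motif", [Motif.IFFL, Motif.IFL])
    def test_stationary_limit_matches_lyapunov(self, motif, ramp_params):
        """With no ramp the covariance settles on the algebraic Lyapunov
        solution M C + C M^T = q W W^T (independent oracle)."""
        net = NetworkParams(motif=motif, k_x=10.0, k_y=5.0, b=1e-6 if motif is Motif.IFFL else 1.0)
        p = ramp_params.with_(c1=0.0)
        lin = ramp_linearization(p, Scheme.BM)
        sys_ = build_lna(net, lin)
        c_oracle = solve_continuous_lyapunov(
            sys_.drift,
            lin.intensity(0.0) * np.outer(sys_.noise_coupling, sys_.noise_coupling),
        )
        res = lna_variance_numeric(net, lin, np.array([5.0]))
        assert res.var_x[-1] == pytest.approx(c_oracle[0, 0], rel=1e-6)
        assert res.var_y[-1] == pytest.approx(c_oracle[1, 1], rel=1e-6)

    def test_unstable_drift_rejected(self, iffl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.CM)
        sys_ = build_lna(iffl, lin)
        sys_.drift[0, 0] = -100.0
        with pytest.raises(ValueError, match="unstable"):
            sys_.__post_init__()

    @pytest.mark.filterwarnings("ignore:k_x <= k_y")
    def test_bm_beats_cm_in_fast_unbinding_ramp(self, ramp_params):
        """Fast-unbinding ordering: with k+c0 < k- the BM output variance lies
        below the CM one across the ramp window (slow-inhibitor operating
        point, which trips the timescale-separation warning by design)."""
        net = NetworkParams(motif=Motif.IFFL, k_x=5.0, k_y=10.0, b=1e-7)
        t = np.linspace(0.1, 5.0, 8)
        var = {}
        for scheme in Scheme:
            lin = ramp_linearization(ramp_params, scheme)
            var[scheme] = lna_variance_numeric(net, lin, t).var_x
        assert np.all(var[Scheme.BM] < var[Scheme.CM])

    def test_regime_flip_with_ratio(self):
        """The CM/BM ordering of the output variance flips as k+c0/k- crosses 1."""
        net = NetworkParams(motif=Motif.IFFL, k_x=10.0, k_y=5.0, b=1e-7)
        diffs = []
        for r in (0.5, 0.9, 1.1, 2.0):
            p = ReceptorParams(
                k_plus=1.0, c0=1e6, c1=1e4, k_minus=1e6 / r, alpha=1e6 / r, gamma=1.0
            )
            out = {}
            for scheme in Scheme:
                lin = ramp_linearization(p, scheme)
                out[scheme] = lna_variance_numeric(net, lin, np.array([2.0])).var_x[0]
            diffs.append(out[Scheme.CM] - out[Scheme.BM])
        assert diffs[0] > 0 and diffs[1] > 0      # r < 1: BM more accurate
        assert diffs[2] < 0 and diffs[3] < 0      # r > 1: CM more accurate


class TestClosedForm:
    @pytest.mark.filterwarnings("ignore:k_x <= k_y")
    @pytest.mark.parametrize("scheme", [Scheme.CM, Scheme.BM])
    def test_matches_numeric_lna(self, scheme, ramp_params):
        net = NetworkParams(motif=Motif.IFFL, k_x=5.0, k_y=10.0, b=1e-7)
        lin = ramp_linearization(ramp_params, scheme)
        t = np.linspace(0.005, 1.0, 12) * 0.05 * lin.u0 / lin.u1
        numeric = lna_variance_numeric(net, lin, t)
        closed = iffl_variance_closed_form(net, lin, scheme, t)
        assert np.max(np.abs(closed.var_x / numeric.var_x - 1.0)) < 0.01

    def test_zeroth_order_ratio(self, ramp_params):
        """With u1 = 0 the CM/BM variance ratio is 2/g*_BM, approaching 2 as
        k+c0/k- -> 0."""
        net = NetworkParams(motif=Motif.IFFL, k_x=10.0, k_y=5.0, b=1e-7)
        p0 = ramp_params.with_(c1=0.0)
        out = {}
        for scheme in Scheme:
            lin = ramp_linearization(p0, scheme)
            out[scheme] = iffl_variance_closed_form(net, lin, scheme, np.array([0.0]))
        lin = ramp_linearization(p0, Scheme.BM)
        assert out[Scheme.CM].var_x[0] / out[Scheme.BM].var_x[0] == pytest.approx(
            2.0 / lin.g_star_bm
        )
        # far in the fast-unbinding limit the ratio approaches the factor 2
        tiny = p0.with_(c0=1e3)
        ratio = (
            iffl_variance_closed_form(
                net, ramp_linearization(tiny, Scheme.CM), Scheme.CM, np.array([0.0])
            ).var_x[0]
            / iffl_variance_closed_form(
                net, ramp_linearization(tiny, Scheme.BM), Scheme.BM, np.array([0.0])
            ).var_x[0]
        )
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_ifl_not_supported(self, ifl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.CM)
        with pytest.raises(ValueError, match="IFFL"):
            iffl_variance_closed_form(ifl, lin, Scheme.CM, np.array([0.1]))


class TestSDE:
    def test_noiseless_follows_deterministic_means(self, iffl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.CM)
        lin.intensity = lambda t: 0.0
        ens = simulate_sde(iffl, lin, t_end=2.0, n_runs=3, seed=1, stationary_init=False)
        mean_x, mean_y = mean_trajectories(iffl, lin)
        assert np.allclose(ens.mean_x, np.asarray(mean_x(ens.t)), rtol=1e-3)
        assert np.allclose(ens.mean_y, np.asarray(mean_y(ens.t)), rtol=1e-3)
        assert np.allclose(ens.var_x, 0.0, atol=1e-20)

    def test_seed_reproducibility(self, iffl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.BM)
        a = simulate_sde(iffl, lin, t_end=0.5, n_runs=8, seed=42)
        b = simulate_sde(iffl, lin, t_end=0.5, n_runs=8, seed=42)
        assert np.array_equal(a.var_x, b.var_x)

    def test_dt_stability_guard(self, iffl, ramp_params):
        lin = ramp_linearization(ramp_params, Scheme.CM)
        with pytest.raises(ValueError, match="dt"):
            simulate_sde(iffl, lin, t_end=1.0, n_runs=2, seed=1, dt=1.0)


class TestAdaptation:
    @pytest.mark.parametrize(
        "motif,b", [(Motif.IFFL, 1e-6), (Motif.IFL, 1.0)]
    )
    @pytest.mark.parametrize("step", [(1e5, 3e5), (2e5, 5e4)])
    def test_step_returns_to_setpoint(self, motif, b, step):
        net = NetworkParams(motif=motif, k_x=10.0, k_y=5.0, b=b)
        u_before, u_after = step
        t, x, y = step_response(net, u_before, u_after, t_end=10.0)
        assert x[0] == pytest.approx(1.0, abs=1e-9)
        assert x[-1] == pytest.approx(1.0, abs=1e-6)  # independent of the step

    def test_transient_actually_moves(self):
        net = NetworkParams(motif=Motif.IFL, k_x=10.0, k_y=1.0, b=1.0)
        _, x, _ = step_response(net, 1e5, 3e5, t_end=10.0)
        assert np.max(np.abs(x - 1.0)) > 0.1  # the step is seen before adapting
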