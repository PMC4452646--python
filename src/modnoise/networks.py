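"""Ramp sensing through two adaptation motifs, with linear-noise variances.

Incoherent feedforward loop (IFFL) — the signal u drives both the output x and
its inhibitor y::

    dx/dt = k_x (f(u) g(y) - x),   f(u) = exp(b u),  g(y) = exp(-b k_y y)
    dy/dt = u - k_y y

(the inhibition carries the negative sign: with it the ramp solution
``<x> = exp(b u1/k_y)`` holds and a step in u is perfectly adapted away).

Integral feedback loop (IFL) — u drives x, x drives the integrator y, and y
feeds back on x::

    dx/dt = u f(y) - k_x x,        f(y) = exp(-b y)
    dy/dt = k_y (x - 1)

whose fixed point pins ``<x> = 1`` for any constant input (precise adaptation).

Writing u = u0 + u1 t + du with white noise du of intensity q(t) and
linearizing around the slowly moving means gives dX/dt + M X = (w du, z du)
for X = (dx, dy).  The covariance then solves the time-dependent Lyapunov
equation dC/dt = -M C - C M^T + q(t) W W^T, integrated numerically from the
stationary pre-ramp covariance; for the IFFL the first-order closed form of
var_x is also available and is checked against the numeric route.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov

from .receptor import Scheme, SignalLinearization

logger = logging.getLogger("modnoise")

__all__ = [
    "Motif",
    "NetworkParams",
    "LNASystem",
    "VarianceResult",
    "SDEEnsemble",
    "mean_trajectories",
    "build_lna",
    "lna_variance_numeric",
    "iffl_variance_closed_form",
    "simulate_sde",
    "step_response",
]


class Motif(str, Enum):
    IFFL = "iffl"
    IFL = "ifl"

    @classmethod
    def coerce(cls, value: "Motif | str") -> "Motif":
        if isinstance(value, Motif):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class NetworkParams:
    """Rate constants of an adaptation motif.

    ``b`` sets the strength of the exponential nonlinearity: it has units of
    time for the IFFL (it multiplies the rate u) and is dimensionless for the
    IFL (it multiplies the copy-number-like y).  Adaptation on the motifs'
    own timescale argument requires ``k_x > k_y`` (fast output, slow
    inhibitor); a violation is flagged with a warning only, since the
    linear-noise machinery is indifferent to it.
    """

    motif: Motif
    k_x: float
    k_y: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", Motif.coerce(self.motif))
        for name in ("k_x", "k_y", "b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.k_x <= self.k_y:
            warnings.warn(
                "k_x <= k_y: the output is not faster than the inhibitor, so "
                "adaptation transients are not timescale-separated",
                stacklevel=2,
            )


def mean_trajectories(
    net: NetworkParams, lin: SignalLinearization
) -> tuple[Callable, Callable]:
    """First-order mean trajectories (<x>(t), <y>(t)) for the ramp input.

    IFFL: ``<x> = exp(b u1/k_y)`` (time independent) and
    ``<y> = u0/k_y - u1/k_y^2 + u1 t/k_y``.
    IFL: ``<x> = 1`` (to zeroth order in the ramp) and ``<y>`` solves
    ``u(t) exp(-b y) = k_x`` at first order in ``u1 t``.
    """
    u0, u1 = lin.u0, lin.u1
    k_x, k_y, b = net.k_x, net.k_y, net.b
    if net.motif is Motif.IFFL:
        x_const = float(np.exp(b * u1 / k_y))

        def mean_x(t):
            return x_const * np.ones_like(np.asarray(t, dtype=float))

        def mean_y(t):
            return u0 / k_y - u1 / k_y**2 + u1 * np.asarray(t, dtype=float) / k_y

    else:
        if u0 <= 0:
            raise ValueError("IFL means require u0 > 0")
        x_const = 1.0 + u1 / (b * u0 * k_y)
        y0 = np.log(u0 / k_x) / b

        def mean_x(t):
            return x_const * np.ones_like(np.asarray(t, dtype=float))

        def mean_y(t):
            return y0 + u1 * np.asarray(t, dtype=float) / (b * u0) - (x_const - 1.0) / b

    return mean_x, mean_y


@dataclass
class LNASystem:
    """Linearized two-species system dX/dt + M X = W du around the means."""

    net: NetworkParams
    lin: SignalLinearization
    mean_x: Callable
    mean_y: Callable
    drift: np.ndarray           # M, 2x2
    noise_coupling: np.ndarray  # W = (w, z)
    intensity: Callable         # t -> q(t)

    def __post_init__(self) -> None:
        eig = np.linalg.eigvals(self.drift)
        if np.any(eig.real <= 0):
            raise ValueError(f"linearized system unstable: eigenvalues of M = {eig}")

    def stationary_covariance(self, q: float | None = None) -> np.ndarray:
        """Stationary covariance for constant intensity (Lyapunov solve)."""
        if q is None:
            q = self.intensity(0.0)
        w = self.noise_coupling.reshape(2, 1)
        return solve_continuous_lyapunov(self.drift, q * (w @ w.T))


def build_lna(net: NetworkParams, lin: SignalLinearization) -> LNASystem:
    """Assemble drift matrix and noise couplings for either motif."""
    mean_x, mean_y = mean_trajectories(net, lin)
    k_x, k_y, b = net.k_x, net.k_y, net.b
    if net.motif is Motif.IFFL:
        xbar = float(mean_x(0.0))
        drift = np.array([[k_x, k_x * b * k_y * xbar], [0.0, k_y]])
        coupling = np.array([k_x * b * xbar, 1.0])
    else:
        if lin.u0 <= 0:
            raise ValueError("IFL linearization requires u0 > 0")
        drift = np.array([[k_x, b * k_x], [-k_y, 0.0]])
        coupling = np.array([k_x / lin.u0, 0.0])
    return LNASystem(
        net=net,
        lin=lin,
        mean_x=mean_x,
        mean_y=mean_y,
        drift=drift,
        noise_coupling=coupling,
        intensity=lin.intensity,
    )


@dataclass
class VarianceResult:
    """Copy-number variances of the motif output along the ramp."""

    t: np.ndarray
    var_x: np.ndarray
    var_y: np.ndarray | None
    cov_xy: np.ndarray | None
    method: str
    delta_prefactor: float | None = None

    def rel_var_x(self, mean_x) -> np.ndarray:
        m = np.asarray(mean_x(self.t), dtype=float)
        return self.var_x / m**2


def lna_variance_numeric(
    net: NetworkParams,
    lin: SignalLinearization,
    t_grid: np.ndarray,
    rtol: float = 1e-9,
) -> VarianceResult:
    """Covariance along the ramp from the time-dependent Lyapunov equation.

    Integrates ``dC/dt = -M C - C M^T + q(t) W W^T`` (the differential form of
    the matrix-exponential-weighted integral) starting from the stationary
    covariance of the pre-ramp constant stimulus.
    """
    sys_ = build_lna(net, lin)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be strictly increasing and non-negative")
    m = sys_.drift
    w = sys_.noise_coupling.reshape(2, 1)
    ww = w @ w.T
    c0 = sys_.stationary_covariance(q=lin.intensity(0.0))

    def rhs(t, y):
        c = y.reshape(2, 2)
        dc = -m @ c - c @ m.T + lin.intensity(t) * ww
        return dc.ravel()

    t0, t1 = 0.0, float(t_grid[-1])
    if t1 == 0.0:
        cs = np.array([c0])
    else:
        sol = solve_ivp(
            rhs,
            (t0, t1),
            c0.ravel(),
            t_eval=t_grid,
            rtol=rtol,
            atol=rtol * max(float(np.abs(c0).max()), 1e-30),
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"covariance integration failed: {sol.message}")
        cs = sol.y.T.reshape(-1, 2, 2)
    var_x = cs[:, 0, 0].copy()
    var_y = cs[:, 1, 1].copy()
    cov = cs[:, 0, 1].copy()
    if np.any(var_x < -1e-12 * np.abs(var_x).max()):
        raise RuntimeError("negative variance from covariance integration")
    return VarianceResult(
        t=t_grid, var_x=var_x, var_y=var_y, cov_xy=cov, method="numeric_lna"
    )


def iffl_variance_closed_form(
    net: NetworkParams,
    lin: SignalLinearization,
    scheme: Scheme | str,
    t: np.ndarray,
) -> VarianceResult:
    """First-order closed form of the IFFL output variance along the ramp.

    ``var_x(t) = Delta * [g0 u0 + beta u1 (t - 1/(k_x + k_y))]`` with
    ``Delta = b^2 k_x^2 exp(2 b u1/k_y) / (2 (k_x + k_y) (1 + r)^2)``,
    ``r = k_plus c0/k_minus``, ``g0`` the scheme's noise prefactor at the ramp
    foot, and ``beta`` the first-order growth rate of the intensity:
    ``beta = 2(1 - 2r)`` for CM and ``1 - 2r + 3r^2`` for BM.  The y variance
    has no transcribed closed form here and is computed numerically only.
    """
    if net.motif is not Motif.IFFL:
        raise ValueError("closed-form variance is available for the IFFL only")
    scheme = Scheme.coerce(scheme)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lin._check_window(t)
    r = lin.ratio
    u0, u1 = lin.u0, lin.u1
    k_x, k_y, b = net.k_x, net.k_y, net.b
    delta = (
        b**2 * k_x**2 * np.exp(2.0 * b * u1 / k_y)
        / (2.0 * (k_x + k_y) * (1.0 + r) ** 2)
    )
    if scheme is Scheme.CM:
        g0 = 2.0
        beta = 2.0 * (1.0 - 2.0 * r)
    else:
        g0 = 1.0 + r**2
        beta = 1.0 - 2.0 * r + 3.0 * r**2
    var_x = delta * (g0 * u0 + beta * u1 * (t - 1.0 / (k_x + k_y)))
    return VarianceResult(
        t=t,
        var_x=var_x,
        var_y=None,
        cov_xy=None,
        method="closed_form",
        delta_prefactor=float(delta),
    )


# ---------------------------------------------------------------------------
# stochastic simulation (Euler-Maruyama) of the full nonlinear equations


@dataclass
class SDEEnsemble:
    """Ensemble summary of Euler-Maruyama runs of the nonlinear motif SDEs."""

    t: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    var_x: np.ndarray
    var_y: np.ndarray
    se_var_x: np.ndarray
    se_var_y: np.ndarray
    n_runs: int
    dt: float


def _drift_nonlinear(net: NetworkParams, x, y, u):
    k_x, k_y, b = net.k_x, net.k_y, net.b
    if net.motif is Motif.IFFL:
        dx = k_x * (np.exp(b * u - b * k_y * y) - x)
        dy = u - k_y * y
    else:
        dx = u * np.exp(-b * y) - k_x * x
        dy = k_y * (x - 1.0)
    return dx, dy


def simulate_sde(
    net: NetworkParams,
    lin: SignalLinearization,
    t_end: float,
    n_runs: int,
    seed: int,
    dt: float | None = None,
    n_record: int = 50,
    stationary_init: bool = True,
) -> SDEEnsemble:
    """Euler-Maruyama ensemble of the nonlinear motif equations.

    The signaling noise enters as ``u = u0 + u1 t + sqrt(q(t)/dt) * N(0,1)``
    per step.  By default the initial fluctuations are drawn from the
    stationary pre-ramp covariance so ensemble variances are directly
    comparable with the linear-noise prediction at every recorded time.
    """
    if dt is None:
        dt = 0.01 / max(net.k_x, net.k_y)
    if dt * max(net.k_x, net.k_y) > 0.1:
        raise ValueError("dt too large for stable explicit integration")
    n_steps = int(round(t_end / dt))
    if n_steps < n_record:
        raise ValueError("t_end/dt must exceed the number of recorded times")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2**20]))
    sys_ = build_lna(net, lin)
    x = np.full(n_runs, float(sys_.mean_x(0.0)))
    y = np.full(n_runs, float(sys_.mean_y(0.0)))
    if stationary_init:
        c0 = sys_.stationary_covariance()
        pert = rng.multivariate_normal(np.zeros(2), c0, size=n_runs, method="cholesky")
        x = x + pert[:, 0]
        y = y + pert[:, 1]

    record_every = max(1, n_steps // n_record)
    ts, mxs, mys, vxs, vys = [], [], [], [], []
    t = 0.0
    for step in range(n_steps):
        q = lin.intensity(t)
        du = np.sqrt(q / dt) * rng.standard_normal(n_runs)
        u = lin.u0 + lin.u1 * t + du
        dx, dy = _drift_nonlinear(net, x, y, u)
        x = x + dx * dt
        y = y + dy * dt
        t += dt
        if (step + 1) % record_every == 0:
            ts.append(t)
            mxs.append(x.mean())
            mys.append(y.mean())
            vxs.append(x.var(ddof=1))
            vys.append(y.var(ddof=1))
    var_x = np.array(vxs)
    var_y = np.array(vys)
    se_fac = np.sqrt(2.0 / (n_runs - 1))
    return SDEEnsemble(
        t=np.array(ts),
        mean_x=np.array(mxs),
        mean_y=np.array(mys),
        var_x=var_x,
        var_y=var_y,
        se_var_x=var_x * se_fac,
        se_var_y=var_y * se_fac,
        n_runs=n_runs,
        dt=dt,
    )


def step_response(
    net: NetworkParams,
    u_before: float,
    u_after: float,
    t_end: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic response of the motif to a step u_before -> u_after.

    Starts from the fixed point at ``u_before`` and integrates the noiseless
    nonlinear equations; precise adaptation means x(t_end) returns to its
    pre-step value (1 for both motifs with a constant stimulus) for any step
    size.
    """
    if net.motif is Motif.IFFL:
        y0 = u_before / net.k_y
        x0 = float(np.exp(net.b * u_before - net.b * net.k_y * y0))  # = 1
    else:
        if u_before <= 0 or u_after <= 0:
            raise ValueError("IFL requires positive stimulus")
        x0 = 1.0
        y0 = np.log(u_before / net.k_x) / net.b

    def rhs(t, state):
        dx, dy = _drift_nonlinear(net, state[0], state[1], u_after)
        return [dx, dy]

    sol = solve_ivp(
        rhs, (0.0, t_end), [x0, y0], rtol=1e-10, atol=1e-12, dense_output=True,
        t_eval=np.linspace(0.0, t_end, 200),
    )
    if not sol.success:
        raise RuntimeError(f"step-response integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]
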