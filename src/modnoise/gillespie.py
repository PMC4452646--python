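"""Event-driven stochastic simulation of single-receptor CM and BM dynamics.

Direct-method SSA over the joint state (receptor on/off, protein count n).
Active reactions and rates:

* on state:  unbind (k_minus), degrade (gamma*n), and for CM produce (alpha);
* off state: bind (k_plus*c0), degrade (gamma*n).

For BM the binding event atomically adds ``zeta`` proteins.  Waiting times are
exponential with the total active rate; the normalized-probability phrasing of
next-reaction choice (e.g. ``k_minus/(k_minus + gamma*n)``) is equivalent to
this standard direct method.

The inner loop is compiled with numba; a pure-Python fallback with identical
semantics is kept for environments where compilation fails.  Seeding is
counter-based: a master seed plus run index feeds ``numpy.random.SeedSequence``
and the derived 32-bit seed is recorded on the trajectory, so identical seeds
reproduce trajectories exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .master_equation import MomentSummary
from .receptor import ReceptorParams, Scheme

__all__ = [
    "Trajectory",
    "EmpiricalMoments",
    "WindowStats",
    "simulate",
    "empirical_moments",
    "signal_window_statistics",
    "resample_to_grid",
]


def _ssa_core(is_bm, k_on, k_off, alpha, gamma, zeta, t_end, seed):  # pragma: no cover - numba path
    np.random.seed(seed)
    cap = 4096
    times = np.empty(cap, dtype=np.float64)
    states = np.empty(cap, dtype=np.int8)
    counts = np.empty(cap, dtype=np.int64)
    t = 0.0
    s = 0  # off
    n = 0
    m = 0
    times[0] = 0.0
    states[0] = 0
    counts[0] = 0
    m = 1
    while True:
        if s == 1:
            r_sw = k_off
            r_prod = 0.0 if is_bm else alpha
        else:
            r_sw = k_on
            r_prod = 0.0
        r_deg = gamma * n
        total = r_sw + r_prod + r_deg
        t += -math.log(np.random.random()) / total
        if t >= t_end:
            break
        u = np.random.random() * total
        if u < r_sw:
            s = 1 - s
            if is_bm and s == 1:
                n += zeta
        elif u < r_sw + r_prod:
            n += 1
        else:
            n -= 1
        if m == cap:
            cap *= 2
            new_t = np.empty(cap, dtype=np.float64)
            new_s = np.empty(cap, dtype=np.int8)
            new_n = np.empty(cap, dtype=np.int64)
            new_t[:m] = times
            new_s[:m] = states
            new_n[:m] = counts
            times, states, counts = new_t, new_s, new_n
        times[m] = t
        states[m] = s
        counts[m] = n
        m += 1
    return times[:m], states[:m], counts[:m]


try:  # compile the hot loop; fall back to the identical Python implementation
    from numba import njit

    _ssa = njit(cache=False)(_ssa_core)
except Exception:  # pragma: no cover
    _ssa = _ssa_core


@dataclass
class Trajectory:
    """Event record of one SSA run (state and count *after* each event)."""

    params: ReceptorParams
    scheme: Scheme
    t_end: float
    seed: int
    times: np.ndarray
    states: np.ndarray
    counts: np.ndarray

    @property
    def binding_times(self) -> np.ndarray:
        """Times of off->on switching events."""
        toggled = np.zeros(len(self.times), dtype=bool)
        toggled[1:] = self.states[1:] != self.states[:-1]
        return self.times[toggled & (self.states == 1)]

    def occupancy(self, t_start: float = 0.0) -> float:
        """Fraction of time spent bound over [t_start, t_end]."""
        t, s = _with_terminal(self)[:2]
        dt = np.diff(t)  # len(dt) == len(s): value i holds over [t_i, t_{i+1})
        mask = t[:-1] >= t_start
        span = dt[mask].sum()
        return float((dt[mask] * s[mask]).sum() / span)


def simulate(
    params: ReceptorParams,
    scheme: Scheme | str,
    t_end: float,
    seed: int,
    run_index: int = 0,
) -> Trajectory:
    """Run one statistically exact SSA trajectory from (off, n=0) to ``t_end``."""
    scheme = Scheme.coerce(scheme)
    if not (t_end > 0 and np.isfinite(t_end)):
        raise ValueError("t_end must be positive and finite")
    for v in (params.k_on, params.k_minus, params.alpha, params.gamma):
        if not np.isfinite(v):
            raise ValueError("rates must be finite")
    child = np.random.SeedSequence([int(seed), int(run_index)])
    raw = int(child.generate_state(1, dtype=np.uint32)[0])
    times, states, counts = _ssa(
        scheme is Scheme.BM,
        params.k_on,
        params.k_minus,
        params.alpha,
        params.gamma,
        params.zeta,
        float(t_end),
        raw,
    )
    return Trajectory(
        params=params,
        scheme=scheme,
        t_end=float(t_end),
        seed=raw,
        times=times,
        states=states,
        counts=counts,
    )


def _with_terminal(traj: Trajectory):
    """Event times padded with the trajectory end time.

    The returned times have one more entry than states/counts: value ``i``
    holds over the segment ``[t[i], t[i+1])``.
    """
    t = np.append(traj.times, traj.t_end)
    s = traj.states.astype(np.float64)
    n = traj.counts.astype(np.float64)
    return t, s, n


def default_burn_in(params: ReceptorParams) -> float:
    """Default equilibration span: max(10/gamma, 100 receptor correlation times)."""
    return max(10.0 / params.gamma, 100.0 / (params.k_on + params.k_minus))


@dataclass(frozen=True)
class EmpiricalMoments:
    """Time-weighted stationary moments with batch-means standard errors."""

    mean: float
    variance: float
    third_central: float
    skewness_std: float
    se_mean: float
    se_variance: float
    n_batches: int
    span: float

    def summary(self) -> MomentSummary:
        m1 = self.mean
        var = self.variance
        m3 = self.third_central + 3.0 * m1 * var + m1**3
        return MomentSummary.from_raw(m1, m1**2 + var, m3)


def empirical_moments(
    traj: Trajectory, burn_in: float | None = None, n_batches: int = 20
) -> EmpiricalMoments:
    """Time-weighted copy-number moments over the post-burn-in span.

    Standard errors come from batch means: the span is cut into ``n_batches``
    equal time slices and the spread of per-batch means/variances estimates
    the Monte-Carlo error of the pooled values.
    """
    p = traj.params
    if burn_in is None:
        burn_in = min(default_burn_in(p), 0.2 * traj.t_end)
    span = traj.t_end - burn_in
    tau_corr = 1.0 / (p.k_on + p.k_minus)
    if span < 100.0 * tau_corr:
        raise ValueError(
            f"post-burn-in span {span:.3g} covers fewer than 100 receptor "
            f"correlation times ({tau_corr:.3g})"
        )
    t, _, n = _with_terminal(traj)
    # clip segments to [burn_in, t_end]
    left = np.clip(t[:-1], burn_in, traj.t_end)
    right = np.clip(t[1:], burn_in, traj.t_end)
    dt = right - left
    keep = dt > 0
    dt, vals, left = dt[keep], n[keep], left[keep]

    w = dt / dt.sum()
    m1 = float(w @ vals)
    var = float(w @ (vals - m1) ** 2)
    c3 = float(w @ (vals - m1) ** 3)
    skew = c3 / var**1.5 if var > 0 else 0.0

    edges = burn_in + span * np.arange(1, n_batches) / n_batches
    batch_idx = np.searchsorted(edges, left, side="right")
    bmeans = np.empty(n_batches)
    bvars = np.empty(n_batches)
    for b in range(n_batches):
        sel = batch_idx == b
        wb = dt[sel]
        tot = wb.sum()
        mb = (wb @ vals[sel]) / tot
        bmeans[b] = mb
        bvars[b] = (wb @ (vals[sel] - mb) ** 2) / tot
    se_mean = float(bmeans.std(ddof=1) / np.sqrt(n_batches))
    se_var = float(bvars.std(ddof=1) / np.sqrt(n_batches))
    return EmpiricalMoments(
        mean=m1,
        variance=var,
        third_central=c3,
        skewness_std=skew,
        se_mean=se_mean,
        se_variance=se_var,
        n_batches=n_batches,
        span=span,
    )


@dataclass(frozen=True)
class WindowStats:
    """Integrated signaling per window and the implied noise intensity."""

    window: float
    signals: np.ndarray        # integrated signal per window
    mean_per_window: float
    var_per_window: float
    intensity: float           # var/window -> q of the small-noise description
    se_intensity: float

    @property
    def n_windows(self) -> int:
        return int(self.signals.size)


def signal_window_statistics(
    traj: Trajectory, window: float, t_start: float | None = None
) -> WindowStats:
    """Mean/variance of the integrated signaling rate over equal time windows.

    CM: the window integral of ``alpha * r(t)`` (alpha times bound time).
    BM: ``zeta`` times the number of binding events in the window.  As the
    window grows beyond the receptor correlation time, variance/window
    converges to the delta-correlated intensity q of the linearized signal.
    """
    if traj.times.size < 2:
        raise ValueError("trajectory too short for windowed statistics")
    p = traj.params
    tau_min = max(1.0 / p.k_minus, 1.0 / p.k_on)
    if window < 10.0 * tau_min:
        raise ValueError(
            f"window {window:.3g} must exceed 10x the slower receptor "
            f"timescale ({tau_min:.3g})"
        )
    if t_start is None:
        t_start = min(window, 0.05 * traj.t_end)
    n_win = int((traj.t_end - t_start) / window)
    if n_win < 20:
        raise ValueError(f"only {n_win} windows available; need at least 20")
    edges = t_start + window * np.arange(n_win + 1)

    if traj.scheme is Scheme.CM:
        t, s, _ = _with_terminal(traj)
        bound_cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * s)])
        cum_at = np.interp(edges, t, bound_cum)
        signals = p.alpha * np.diff(cum_at)
    else:
        counts, _ = np.histogram(traj.binding_times, bins=edges)
        signals = p.zeta * counts.astype(float)

    mean_w = float(signals.mean())
    var_w = float(signals.var(ddof=1))
    dev2 = (signals - mean_w) ** 2
    m4 = float(dev2.var(ddof=1))  # sample variance of squared deviations
    se_var = math.sqrt(m4 / n_win)
    return WindowStats(
        window=window,
        signals=signals,
        mean_per_window=mean_w,
        var_per_window=var_w,
        intensity=var_w / window,
        se_intensity=se_var / window,
    )


def resample_to_grid(traj: Trajectory, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant resampling of (state, count) onto a uniform grid."""
    grid = np.arange(0.0, traj.t_end, dt)
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    return grid, traj.states[idx], traj.counts[idx]
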