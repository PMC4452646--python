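"""Exact stationary solutions of the CM and BM master equations.

The joint state is (receptor state s in {on, off}, protein copy number n).
CM reactions: production at rate ``alpha`` in the on state, degradation
``gamma*n`` in both states, switching ``k_plus*c0`` (off->on) and ``k_minus``
(on->off).  BM reactions: the same telegraph switching and degradation, but no
continuous production — instead ``zeta`` proteins appear atomically at each
off->on switch.

Two independent routes to the stationary moments are provided:

* :func:`stationary_distribution` — sparse null-space solve of the truncated
  generator (the full distribution; supports modality analysis);
* :func:`analytic_moments` — the stationary conditional-moment closure.  All
  transition rates are linear in ``n``, so the equations for
  ``E[n^k 1_s]``, k = 1..3, close exactly; this is the same object the
  generating-function treatment of the two-state birth-death system encodes,
  and it applies verbatim to the burst scheme (the burst enters through
  binomial moments of ``n + zeta``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .receptor import ReceptorParams, Scheme

__all__ = [
    "CountDistribution",
    "MomentSummary",
    "stationary_distribution",
    "analytic_moments",
    "cm_moments_gf",
    "moments_of",
    "modality",
]


@dataclass(frozen=True)
class MomentSummary:
    """First three stationary moments of the protein copy number."""

    mean: float
    variance: float
    third_raw: float      # <n^3>
    third_central: float  # <(n - <n>)^3>
    skewness_std: float   # third_central / variance**1.5 (0 if variance is 0)

    @classmethod
    def from_raw(cls, m1: float, m2: float, m3: float) -> "MomentSummary":
        var = m2 - m1**2
        central3 = m3 - 3.0 * m1 * var - m1**3
        skew = central3 / var**1.5 if var > 0 else 0.0
        return cls(
            mean=m1,
            variance=var,
            third_raw=m3,
            third_central=central3,
            skewness_std=skew,
        )


@dataclass
class CountDistribution:
    """Stationary joint distribution over (receptor state, copy number 0..n_max)."""

    n_max: int
    p_on: np.ndarray
    p_off: np.ndarray

    def __post_init__(self) -> None:
        self.p_on = np.asarray(self.p_on, dtype=float)
        self.p_off = np.asarray(self.p_off, dtype=float)
        if self.p_on.shape != (self.n_max + 1,) or self.p_off.shape != (self.n_max + 1,):
            raise ValueError("p_on/p_off must have length n_max + 1")
        total = self.p_on.sum() + self.p_off.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"distribution not normalized: total = {total!r}")

    @property
    def marginal(self) -> np.ndarray:
        """Marginal copy-number distribution p(n) = p_on(n) + p_off(n)."""
        return self.p_on + self.p_off

    @property
    def p_bound(self) -> float:
        """Marginal probability of the on state."""
        return float(self.p_on.sum())


class TruncationError(RuntimeError):
    """Stationary tail mass stayed above tolerance after the allowed doublings."""


def _build_generator(
    params: ReceptorParams, scheme: Scheme, n_max: int
) -> sp.csc_matrix:
    """Sparse generator Q (Q[i, j] = rate j -> i) over 2*(n_max+1) states.

    Index layout: off-block 0..n_max, on-block n_max+1..2*n_max+1.
    Rates are rescaled to O(1) internally by the caller via the time unit.
    """
    size = n_max + 1
    n = np.arange(size, dtype=float)
    k_on = params.k_on
    k_off = params.k_minus
    gamma = params.gamma

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    off = np.arange(size)
    on = off + size

    # degradation n -> n-1 in both blocks
    add(off[:-1], off[1:], gamma * n[1:])
    add(on[:-1], on[1:], gamma * n[1:])

    if scheme is Scheme.CM:
        # production in the on state (truncated at the boundary)
        add(on[1:], on[:-1], np.full(size - 1, params.alpha))
        # switching without copy-number change
        add(on, off, np.full(size, k_on))
        add(off, on, np.full(size, k_off))
    else:
        zeta = params.zeta
        # off,n -> on,min(n+zeta, n_max) with the burst applied atomically;
        # the clip only matters when the tail tolerance is already violated
        target = np.minimum(off + zeta, n_max)
        add(on[target], off, np.full(size, k_on))
        add(off, on, np.full(size, k_off))

    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    vals_a = np.concatenate(vals)
    q = sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(2 * size, 2 * size)).tocsc()
    # diagonal: minus the column sums (outflow)
    outflow = np.asarray(q.sum(axis=0)).ravel()
    q = q - sp.diags(outflow)
    return q.tocsc()


def _solve_stationary(params: ReceptorParams, scheme: Scheme, n_max: int) -> CountDistribution:
    # condition the solve by working in time units of the largest rate
    scale = max(params.k_on, params.k_minus, params.alpha, params.gamma)
    scaled = ReceptorParams(
        k_plus=params.k_plus / scale,
        c0=params.c0,
        k_minus=params.k_minus / scale,
        alpha=params.alpha / scale,
        gamma=params.gamma / scale,
        c1=0.0,
        zeta=params.zeta,
    )
    q = _build_generator(scaled, scheme, n_max)
    size = 2 * (n_max + 1)
    # replace one balance equation with the normalization row
    a = q.tolil()
    a[size - 1, :] = 1.0
    b = np.zeros(size)
    b[-1] = 1.0
    lu = splu(a.tocsc())
    p = lu.solve(b)
    p = np.where(np.abs(p) < 1e-300, 0.0, p)
    # clip tiny negative round-off and renormalize
    neg = p[p < 0]
    if neg.size and neg.min() < -1e-9:
        raise RuntimeError(f"stationary solve produced negative mass {neg.min():.3g}")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return CountDistribution(n_max=n_max, p_off=p[: n_max + 1], p_on=p[n_max + 1 :])


def stationary_distribution(
    params: ReceptorParams,
    scheme: Scheme | str,
    n_max: int | None = None,
    tail_tol: float = 1e-12,
    max_doublings: int = 8,
) -> CountDistribution:
    """Stationary joint distribution by direct solve of the truncated generator.

    The truncation ``n_max`` starts (in auto mode) at
    ``ceil(mean + 10*sqrt(mean+1) + 5*zeta + 10)`` with ``mean`` the exact
    stationary mean, and doubles until the tail mass ``p(n_max)`` (and the last
    five support points together) drops below ``tail_tol``.
    """
    scheme = Scheme.coerce(scheme)
    mean = analytic_moments(params, scheme).mean
    auto = n_max is None
    if auto:
        n_max = int(np.ceil(mean + 10.0 * np.sqrt(mean + 1.0) + 5.0 * params.zeta + 10.0))
    attempts = max_doublings if auto else 1
    last_tail = np.inf
    for _ in range(attempts):
        dist = _solve_stationary(params, scheme, n_max)
        marg = dist.marginal
        last_tail = float(marg[-1] + marg[-5:].sum())
        if last_tail < 6.0 * tail_tol:
            return dist
        n_max *= 2
    if not auto:
        return dist
    raise TruncationError(
        f"tail mass {last_tail:.3g} above tolerance {tail_tol:.3g} at n_max={n_max // 2}"
    )


def analytic_moments(params: ReceptorParams, scheme: Scheme | str = Scheme.CM) -> MomentSummary:
    """Exact stationary moments from the conditional-moment closure.

    Writes the stationary balance for ``E[n^k 1_s]`` (k = 0..3, s = on/off) and
    solves the resulting pair of 2x2 linear systems sequentially.  Exact for
    both schemes because every transition rate is linear in ``n``.
    """
    scheme = Scheme.coerce(scheme)
    k_on = params.k_on     # off -> on
    k_off = params.k_minus  # on -> off
    g = params.gamma
    if scheme is Scheme.CM:
        alpha, zeta = params.alpha, 0
    else:
        alpha, zeta = 0.0, params.zeta

    p_on = k_on / (k_on + k_off)
    p_off = 1.0 - p_on

    def solve_pair(a11, a12, b1, a21, a22, b2):
        det = a11 * a22 - a12 * a21
        return (b1 * a22 - a12 * b2) / det, (a11 * b2 - b1 * a21) / det

    # first moments: m1_s = E[n 1_s]
    # on:  -(gamma + k_off) m1_on + k_on m1_off + alpha p_on + k_on zeta p_off = 0
    # off: k_off m1_on - (gamma + k_on) m1_off = 0
    m1_on, m1_off = solve_pair(
        -(g + k_off), k_on, -(alpha * p_on + k_on * zeta * p_off),
        k_off, -(g + k_on), 0.0,
    )

    # second moments
    # on:  gamma(-2 m2_on + m1_on) + alpha(2 m1_on + p_on)
    #      + k_on(m2_off + 2 zeta m1_off + zeta^2 p_off) - k_off m2_on = 0
    # off: gamma(-2 m2_off + m1_off) + k_off m2_on - k_on m2_off = 0
    m2_on, m2_off = solve_pair(
        -(2.0 * g + k_off), k_on,
        -(g * m1_on + alpha * (2.0 * m1_on + p_on)
          + k_on * (2.0 * zeta * m1_off + zeta**2 * p_off)),
        k_off, -(2.0 * g + k_on), -g * m1_off,
    )

    # third moments
    # on:  gamma(-3 m3_on + 3 m2_on - m1_on) + alpha(3 m2_on + 3 m1_on + p_on)
    #      + k_on(m3_off + 3 zeta m2_off + 3 zeta^2 m1_off + zeta^3 p_off)
    #      - k_off m3_on = 0
    m3_on, m3_off = solve_pair(
        -(3.0 * g + k_off), k_on,
        -(g * (3.0 * m2_on - m1_on) + alpha * (3.0 * m2_on + 3.0 * m1_on + p_on)
          + k_on * (3.0 * zeta * m2_off + 3.0 * zeta**2 * m1_off + zeta**3 * p_off)),
        k_off, -(3.0 * g + k_on), -g * (3.0 * m2_off - m1_off),
    )

    return MomentSummary.from_raw(m1_on + m1_off, m2_on + m2_off, m3_on + m3_off)


def cm_moments_gf(params: ReceptorParams) -> MomentSummary:
    """Stationary CM moments (generating-function route; see module docstring)."""
    return analytic_moments(params, Scheme.CM)


def moments_of(dist: CountDistribution) -> MomentSummary:
    """Moments by direct summation over the truncated support."""
    n = np.arange(dist.n_max + 1, dtype=float)
    p = dist.marginal
    m1 = float(n @ p)
    m2 = float((n**2) @ p)
    m3 = float((n**3) @ p)
    return MomentSummary.from_raw(m1, m2, m3)


def modality(dist: CountDistribution, floor_rel: float = 1e-9) -> int:
    """Number of strict local maxima of the marginal copy-number distribution.

    Plateaus (runs of equal probability within relative round-off) are merged
    before counting, and probabilities below ``floor_rel`` times the largest
    probability are zeroed so that solver round-off in the far tail cannot
    create spurious modes.  Endpoint maxima (e.g. a peak at n = 0) count.
    """
    p = dist.marginal.copy()
    if p.size == 0:
        return 0
    p[p < floor_rel * p.max()] = 0.0
    # merge plateaus: keep one representative of each run of ~equal values
    keep = np.ones(p.size, dtype=bool)
    keep[1:] = ~np.isclose(p[1:], p[:-1], rtol=1e-12, atol=0.0)
    compressed = p[keep]
    if compressed.size == 1:
        return 1 if compressed[0] > 0 else 0
    padded = np.concatenate([[-np.inf], compressed, [-np.inf]])
    is_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
    is_max &= compressed > 0
    return int(is_max.sum())
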