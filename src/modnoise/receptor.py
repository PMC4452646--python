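"""Single receptor/ion-channel model and small-noise statistics of its signaling rate.

A receptor switches between *bound* (on) and *unbound* (off) states with rates
``k_plus * c`` (binding, set by the ligand concentration ``c``) and ``k_minus``
(unbinding) — a telegraph process.  Two schemes turn receptor occupancy into a
downstream signaling rate ``u(t)``:

* **CM** (continuous modulation): the bound receptor signals at constant rate
  ``alpha``, so ``u = alpha * r(t)``.
* **BM** (bursty modulation): a burst of ``zeta`` molecules is released at the
  instant of each binding event, ``u = zeta * sum_i delta(t - t_i^+)``.

With the matched-mean choice ``zeta = alpha / k_minus`` both schemes deliver
the same mean output, which is the basis for comparing their noise.  Averaging
over times long compared with the binding/unbinding intervals, the signaling
rate is ``<u> = k_plus*c / (1 + k_plus*c/k_minus)`` with delta-correlated
fluctuations of intensity ``q = g * k_plus*c / (1 + k_plus*c/k_minus)^3``; only
the dimensionless prefactor ``g`` distinguishes the schemes (g = 2 for CM,
g = 1 + (k_plus*c/k_minus)^2 for BM).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger("modnoise")

#: default bound on the relative ramp excursion u1*t/u0 within which the
#: first-order (linear-in-time) description of a ramp is trusted
DEFAULT_RAMP_VALIDITY = 0.1


class Scheme(str, Enum):
    """Signal-encoding scheme of a single receptor."""

    CM = "cm"  # continuous modulation: rate alpha while bound
    BM = "bm"  # bursty modulation: burst of zeta molecules per binding

    @classmethod
    def coerce(cls, value: "Scheme | str") -> "Scheme":
        if isinstance(value, Scheme):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class ReceptorParams:
    """Rate constants of a single two-state receptor and its output pathway.

    Parameters
    ----------
    k_plus
        Binding rate constant, 1/(concentration * time).
    c0
        Baseline ligand concentration.
    k_minus
        Unbinding rate, 1/time.
    alpha
        CM production rate while bound, 1/time.
    gamma
        Output protein degradation rate, 1/time.
    c1
        Ramp slope of the concentration, concentration/time (>= 0).
    zeta
        BM burst size (positive integer).  ``None`` selects the matched-mean
        value ``round(alpha / k_minus)`` so that CM and BM have equal mean
        output; a non-integer ratio is rounded (and the induced mean mismatch
        logged).
    """

    k_plus: float
    c0: float
    k_minus: float
    alpha: float
    gamma: float
    c1: float = 0.0
    zeta: int | None = None

    def __post_init__(self) -> None:
        for name in ("k_plus", "c0", "k_minus", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.alpha < 0 or not np.isfinite(self.alpha):
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        if self.c1 < 0 or not np.isfinite(self.c1):
            raise ValueError(f"c1 must be >= 0, got {self.c1!r}")
        if 0 < self.alpha < self.k_minus:
            warnings.warn(
                "alpha < k_minus: molecules are not generally produced during "
                "a bound interval and the matched burst size rounds to 1",
                stacklevel=2,
            )
        if self.zeta is None:
            matched = max(1, round(self.alpha / self.k_minus))
            mismatch = abs(matched - self.alpha / self.k_minus)
            if mismatch > 1e-9:
                logger.info(
                    "matched burst size alpha/k_minus = %.6g rounded to %d "
                    "(relative mean mismatch %.3g)",
                    self.alpha / self.k_minus,
                    matched,
                    mismatch / matched,
                )
            object.__setattr__(self, "zeta", matched)
        else:
            z = self.zeta
            if z != int(z) or z < 1:
                raise ValueError(f"zeta must be a positive integer, got {z!r}")
            object.__setattr__(self, "zeta", int(z))

    # -- derived quantities -------------------------------------------------
    @property
    def ratio(self) -> float:
        """Occupancy ratio k_plus*c0/k_minus = <tau_b>/<tau_u>."""
        return self.k_plus * self.c0 / self.k_minus

    @property
    def k_on(self) -> float:
        """Binding propensity k_plus*c0 at the baseline concentration."""
        return self.k_plus * self.c0

    @property
    def p_b(self) -> float:
        """Stationary bound-state probability."""
        return self.k_on / (self.k_on + self.k_minus)

    @property
    def f_bind(self) -> float:
        """Frequency of binding events, k_on/(1 + k_on/k_minus)."""
        return self.k_on / (1.0 + self.ratio)

    def is_mean_matched(self, tol: float = 1e-9) -> bool:
        """Whether zeta equals alpha/k_minus (the fair-comparison constraint)."""
        return abs(self.zeta - self.alpha / self.k_minus) <= tol * self.zeta

    def with_(self, **changes) -> "ReceptorParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class IntervalStats:
    """Statistics of the exponential bound/unbound dwell intervals."""

    mean_tau_b: float
    var_tau_b: float
    mean_tau_u: float
    var_tau_u: float
    p_b: float
    f_bind: float


def interval_stats(params: ReceptorParams) -> IntervalStats:
    """Dwell-interval statistics of the two-state receptor at concentration c0.

    Bound and unbound intervals are exponential, so ``var = mean**2`` exactly.
    """
    mtb = 1.0 / params.k_minus
    mtu = 1.0 / params.k_on
    return IntervalStats(
        mean_tau_b=mtb,
        var_tau_b=mtb**2,
        mean_tau_u=mtu,
        var_tau_u=mtu**2,
        p_b=params.p_b,
        f_bind=params.f_bind,
    )


# ---------------------------------------------------------------------------
# signaling-rate statistics


def signaling_mean(params: ReceptorParams, c) -> float | np.ndarray:
    """Mean signaling rate ``k_plus*c / (1 + k_plus*c/k_minus)``.

    Monotone increasing in ``c`` and saturating at ``k_minus`` (one burst-worth
    of signaling per mean bound interval).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kc = params.k_plus * c
    out = kc / (1.0 + kc / params.k_minus)
    return float(out) if out.ndim == 0 else out


def g_factor(scheme: Scheme | str, ratio) -> float | np.ndarray:
    """Dimensionless noise prefactor g of the signaling intensity.

    ``g = 1 + var(tau_b)/<tau_b>^2 = 2`` for CM (bound-interval variability);
    ``g = 1 + var(tau_b)/var(tau_u) = 1 + ratio^2`` for BM, with
    ``ratio = k_plus*c/k_minus``.
    """
    scheme = Scheme.coerce(scheme)
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("ratio must be non-negative")
    if scheme is Scheme.CM:
        out = np.full_like(ratio, 2.0)
    else:
        out = 1.0 + ratio**2
    return float(out) if out.ndim == 0 else out


def noise_intensity(params: ReceptorParams, scheme: Scheme | str, c) -> float | np.ndarray:
    """Delta-correlated signaling-noise intensity ``g * k+c/(1 + k+c/k-)^3``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kc = params.k_plus * c
    ratio = kc / params.k_minus
    g = g_factor(scheme, ratio)
    out = g * kc / (1.0 + ratio) ** 3
    return float(out) if out.ndim == 0 else out


@dataclass
class SignalLinearization:
    """First-order (in the ramp) description of the signaling rate.

    ``u(t) = u0 + u1*t + du`` with ``<du(t)du(t')> = q(t) delta(t-t')``.
    Valid while ``u1*t/u0`` stays below ``validity`` (requests beyond the
    window log a warning and set :attr:`window_exceeded`).
    """

    params: ReceptorParams
    scheme: Scheme
    u0: float
    u1: float
    g: float            # noise prefactor at t=0 (2 for CM, g*_BM for BM)
    g_star_bm: float    # zeroth-order BM prefactor 1 + (k+c0/k-)^2
    validity: float = DEFAULT_RAMP_VALIDITY
    window_exceeded: bool = field(default=False, init=False)

    @property
    def ratio(self) -> float:
        return self.params.ratio

    @property
    def t_valid(self) -> float:
        """Largest t with u1*t/u0 <= validity (inf for a constant stimulus)."""
        if self.u1 == 0:
            return math.inf
        return self.validity * self.u0 / self.u1

    def _check_window(self, t) -> None:
        tmax = float(np.max(t)) if np.ndim(t) else float(t)
        if tmax > self.t_valid * (1 + 1e-12):
            self.window_exceeded = True
            logger.warning(
                "ramp linearization evaluated at t=%.4g beyond validity "
                "window t<=%.4g (u1*t/u0 > %g)",
                tmax,
                self.t_valid,
                self.validity,
            )

    def mean_u(self, t) -> float | np.ndarray:
        """First-order mean signaling rate u0 + u1*t."""
        self._check_window(t)
        out = self.u0 + self.u1 * np.asarray(t, dtype=float)
        return float(out) if out.ndim == 0 else out

    def g_of_t(self, t) -> float | np.ndarray:
        """Time-dependent noise prefactor, first order in the ramp.

        For BM this is ``g*_BM + 2 k+^2 c0 c1 t / k-^2``; for CM it is 2.
        """
        self._check_window(t)
        t = np.asarray(t, dtype=float)
        if self.scheme is Scheme.CM:
            out = np.full_like(t, 2.0)
        else:
            p = self.params
            out = self.g_star_bm + 2.0 * p.k_plus**2 * p.c0 * p.c1 * t / p.k_minus**2
        return float(out) if out.ndim == 0 else out

    def intensity(self, t) -> float | np.ndarray:
        """Noise intensity q(t) along the ramp, q = g * k+c(t)/(1+k+c(t)/k-)^3."""
        self._check_window(t)
        t = np.asarray(t, dtype=float)
        c_t = self.params.c0 + self.params.c1 * t
        out = noise_intensity(self.params, self.scheme, c_t)
        return float(out) if np.ndim(out) == 0 else out


def ramp_linearization(
    params: ReceptorParams,
    scheme: Scheme | str,
    validity: float = DEFAULT_RAMP_VALIDITY,
) -> SignalLinearization:
    """Linearize the signaling rate around the baseline of a slow ramp.

    ``u0`` is the mean rate at ``c0``; ``u1 = k_plus*c1/(1 + k_plus*c0/k_minus)^2``
    is the first-order Taylor coefficient of the mean rate in ``c`` times the
    ramp slope ``c1``.
    """
    scheme = Scheme.coerce(scheme)
    if params.c0 <= 0:
        raise ValueError("ramp linearization requires c0 > 0 (u0 > 0)")
    r = params.ratio
    u0 = signaling_mean(params, params.c0)
    u1 = params.k_plus * params.c1 / (1.0 + r) ** 2
    g_star = 1.0 + r**2
    g0 = 2.0 if scheme is Scheme.CM else g_star
    return SignalLinearization(
        params=params,
        scheme=scheme,
        u0=u0,
        u1=u1,
        g=g0,
        g_star_bm=g_star,
        validity=validity,
    )


def mle_concentration_estimate(
    unbound_intervals: Sequence[float] | np.ndarray, params: ReceptorParams
) -> float:
    """Maximum-likelihood concentration estimate from unbound dwell times.

    The unbound intervals are exponential with rate ``k_plus*c``, so the MLE is
    ``c = 1/(k_plus * mean(tau_u))``; bound intervals carry no information
    about ``c`` and are discarded.
    """
    tau = np.asarray(unbound_intervals, dtype=float)
    if tau.size == 0:
        raise ValueError("need at least one unbound interval")
    if np.any(tau <= 0):
        raise ValueError("unbound intervals must be positive")
    return 1.0 / (params.k_plus * float(tau.mean()))
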