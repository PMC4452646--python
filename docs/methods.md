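# Methods

## Model

A single receptor (or ion channel) is a two-state telegraph process: it binds
ligand at rate `k₊c` and unbinds at rate `k₋`; both dwell times are
exponential, so `var(τ) = ⟨τ⟩²` in each state.  Continuous modulation (CM)
produces downstream molecules at rate `α` while bound; bursty modulation (BM)
releases `ζ` molecules instantaneously at each binding event.  The
matched-mean constraint `ζ = α/k₋` makes the two schemes emit the same average
flux, which is the basis of every comparison in this package.  When `α/k₋` is
not an integer, `ζ` is rounded to the nearest integer ≥ 1 and the induced mean
mismatch is logged; comparisons that rely on exactly equal means should choose
rates with integer `α/k₋`.

The downstream species degrades at rate `γ` per molecule.  The joint process
(receptor state, copy number `n`) is a Markov jump process whose stationary
law we compute two independent ways:

1. **Truncated generator solve** (`stationary_distribution`).  The generator
   over states `(s, n)`, `n = 0..n_max`, is assembled sparsely; one balance
   equation is replaced by the normalization row and the system is solved by
   sparse LU.  Rates are rescaled so the largest is 1, keeping the matrix
   well conditioned.  `n_max` starts at
   `ceil(mean + 10·sqrt(mean+1) + 5ζ + 10)` (with the exact stationary mean
   from the moment closure) and doubles until the tail mass at the boundary
   falls below `1e−12`.  The BM burst that would overshoot the truncation is
   clipped to `n_max`; by the time the tail tolerance is met this carries no
   measurable probability.
2. **Conditional-moment closure** (`analytic_moments`).  Because every
   transition rate is linear in `n`, the stationary balance equations for
   `E[nᵏ·1_s]`, `k = 1..3`, close exactly: each order is a 2×2 linear system
   fed by the lower orders (bursts enter through the binomial expansion of
   `(n+ζ)ᵏ`).  This is the same object the generating-function solution of
   the two-state birth–death system encodes, evaluated without symbolic
   algebra, and it is exact for both CM and BM.  The two routes agree to
   better than six significant digits in the tests, and the Gillespie
   estimator provides a third, sampling-based route.

Skewness is reported as the standardized third central moment
(`⟨δn³⟩/⟨δn²⟩^{3/2}`); the raw third moment `⟨n³⟩` is exposed alongside it,
since the two are easily conflated when only "third moment" is quoted.

**Modality.**  Mode counting merges plateaus (runs equal to round-off) and
zeroes probabilities below `1e−9` of the maximum before counting strict local
maxima, so solver noise in a `1e−15` tail cannot manufacture modes.  Endpoint
maxima count: the low mode of the slow-switching bimodal distribution sits at
`n = 0`.

## Stochastic simulation

The Gillespie engine is the standard direct method: the waiting time is
exponential in the total active rate and the reaction is chosen in proportion
to its rate.  (Phrasing next-reaction choice through normalized probabilities
such as `k₋/(k₋ + γn)` is algebraically the same thing.)  Reactions are:
production `α` (CM, on state only), degradation `γn`, and switching, with the
BM burst applied atomically at the off→on switch.  Trajectories start in
(off, `n = 0`); the default burn-in is `max(10/γ, 100/(k₊c₀ + k₋))`.

The inner loop is numba-compiled (a pure-Python fallback with identical
semantics is retained).  Seeding is counter-based — a master seed plus run
index through `numpy.random.SeedSequence`, recorded on the trajectory — so a
given (seed, parameters) pair reproduces its event list exactly.

Stationary moments are time-weighted over the post-burn-in span, with
batch-means standard errors (20–25 equal time slices by default).  The span
must cover at least 100 receptor correlation times `1/(k₊c₀ + k₋)`.

**Windowed signal statistics.**  The integrated signaling per window is
`α ×` (bound time) for CM — computed exactly from the event list via the
cumulative occupancy — and `ζ ×` (binding events) for BM.  As the window
grows past the receptor timescales, variance/window converges to the
white-noise intensity `q`; windows shorter than 10× the slower receptor
timescale are refused, and at least 20 windows are required.  The remaining
finite-window bias is O(1/(f·T_window)) and is kept near 1% at the default
problem sizes.

## Small-noise (linearized) description

Averaged over times long compared with both dwell times, the signaling rate
is `⟨u⟩ = k₊c/(1 + k₊c/k₋)` with delta-correlated fluctuations of intensity
`q = g·k₊c/(1 + k₊c/k₋)³`.  The dimensionless factor `g` encodes the interval
statistics: `g = 1 + var(τ_b)/⟨τ_b⟩² = 2` for CM and
`g = 1 + var(τ_b)/var(τ_u) = 1 + (k₊c/k₋)²` for BM.  Hence BM is quieter than
CM exactly when `k₊c < k₋` (bound intervals shorter than unbound ones, where
BM approaches the maximum-likelihood estimate `c = 1/(k₊⟨τ_u⟩)`), and its
advantage is bounded by the factor 2 reached as `k₊c/k₋ → 0`.

For a slow ramp `c(t) = c₀ + c₁t` the rate linearizes to `u ≃ u₀ + u₁t + δu`
with `u₀ = ⟨u⟩(c₀)` and `u₁ = k₊c₁/(1 + k₊c₀/k₋)²`, the chain rule applied
to `⟨u⟩`.  The first-order BM prefactor is
`g_BM(t) = 1 + (k₊c₀/k₋)² + 2k₊²c₀c₁t/k₋²`; the intensity function evaluates
the full `g(c(t))` along the ramp, which agrees with the first-order form to
second order in the ramp.  The linearization is trusted while
`u₁t/u₀ ≤ 0.1` (configurable); evaluations beyond the window log a warning
and set a flag rather than fail, since the expansion degrades gracefully.
A ramp out of `c₀ = 0` is refused (no relative-variance baseline).

## Adaptation motifs

Incoherent feedforward loop (IFFL): `dx/dt = k_x(f(u)g(y) − x)`,
`dy/dt = u − k_y y` with `f(u) = e^{bu}`, `g(y) = e^{−b k_y y}` (`b` in time
units).  The inhibition must carry the negative sign: only then does the
ramp solution `⟨x⟩ = e^{bu₁/k_y}` hold and a stimulus step adapt away.
Integral feedback loop (IFL): `dx/dt = u f(y) − k_x x`, `dy/dt = k_y(x − 1)`
with `f(y) = e^{−by}` (`b` dimensionless); its fixed point pins `⟨x⟩ = 1`
for any constant stimulus.  Timescale-separated adaptation wants `k_x > k_y`;
several standard operating points in the field use `k_x < k_y`, so a
violation warns instead of failing, and those operating points are
reproduced as given.

Linearizing around the slowly moving means gives `dX/dt + MX = W·δu` for
`X = (δx, δy)`, with

* IFFL: `M = [[k_x, k_x b k_y x̄], [0, k_y]]`, `W = (k_x b x̄, 1)`;
* IFL:  `M = [[k_x, b k_x], [−k_y, 0]]`, `W = (k_x/u₀, 0)`.

Stability (`Re λ(M) > 0`) is asserted at construction.  The covariance along
the ramp solves the time-dependent Lyapunov equation
`dC/dt = −MC − CM^T + q(t)·WW^T` — the differential form of the
matrix-exponential-weighted integral — integrated by RK45 at `rtol 1e−9`
(absolute tolerance scaled to the initial covariance magnitude) from the
stationary pre-ramp covariance `MC₀ + C₀M^T = q(0)WW^T`.

**Closed form (IFFL, var x).**  Carrying the first-order intensity
`q(t) ≈ (1+r)^{-2}[g₀u₀ + β u₁ t]`, `r = k₊c₀/k₋`, through the linear filter
gives

    var_x(t) = Δ·[g₀u₀ + β u₁ (t − 1/(k_x+k_y))],
    Δ = b²k_x² e^{2bu₁/k_y} / [2(k_x+k_y)(1+r)²],

with `g₀ = 2`, `β = 2(1−2r)` for CM and `g₀ = 1+r²`, `β = 1−2r+3r²` for BM.
Printed versions of this formula circulate with typographically ambiguous
grouping of the `u₁` terms and of the `Δ` denominator; the form above is the
package's own derivation and is asserted against the numeric Lyapunov route
(agreement < 0.1% over `u₁t/u₀ ≤ 0.05` at the standard operating points) —
the numeric integral is the ground truth, the closed form a convenience.
At zeroth order the CM/BM variance ratio is `2/g*_BM`, reproducing the
factor-2 limit.  Closed forms for `var_y` and for the IFL are not
transcribed; those quantities are numeric-LNA only.

**SDE validation.**  `simulate_sde` integrates the *nonlinear* motif
equations by Euler–Maruyama with `δu` drawn as `sqrt(q(t)/dt)·N(0,1)` per
step, `dt = 0.01/max(k_x, k_y)` by default (a guard rejects
`dt·max-rate > 0.1`).  White noise inside `e^{bu}` is only meaningful while
`b·sqrt(q/dt) ≪ 1` — the spurious exponential-mean correction is
`e^{b²q/2dt}`, about `3×10⁻⁴` at the default operating point — so the
nonlinearity scale is kept small.  `b` is not pinned by the standard
operating points (output variances scale as `b²` in the linear regime and
the published comparisons are shape-based); the default `b = 10⁻⁶ s` makes
`b·u₀ = O(0.1)`, keeping the small-noise linearization honest while leaving
the motif genuinely nonlinear for step responses.  Initial fluctuations are
drawn from the stationary pre-ramp covariance, so ensemble variances are
comparable with the LNA at every recorded time, not only after a transient.

## Receptor arrays

For `N` unsynchronized receptors means and intensities both add
(`mean → N·mean₁`, `q → N·q₁`), so the relative variance `q/mean²` falls as
`1/N`; for `N` synchronized receptors the fluctuations add coherently
(`q → N²·q₁`) and the relative variance is `N`-independent.  A mixed array
with synchronized block `⌊ρN⌋` and the rest independent composes as
`(⌊ρN⌋² + (N−⌊ρN⌋))·q₁`; this perfect-correlation/independence reading is
cross-validated in the tests by summing independent Gillespie signal streams
(variance ~`N`) and duplicating one stream (variance `N²` exactly).  The
floor rule means relative variance is monotone in `N` along exact block
sizes; at fractional `ρN` the floored block can locally break monotonicity
by design.

`minimal_n_for_am_advantage` scans `N` for strict `g_CM/N < g_BM`.  At
`ratio → 0` the comparison ties exactly at `N = 2` (`2/2 = 1 = g_BM`), so
the boundary is reported as a flag: two receptors suffice for AM to match
FM's best case, three to beat it strictly; for any `ratio > 0` the scan
returns 2 (or 1 once `g_BM > 2`).

## Synthetic data and scope

All inputs are parameter sets; there is no external data.  The generator of
record is the Gillespie engine itself, and the default operating points are
the standard ones used throughout the field's figure conventions: fast
switching (`k₊c₀ = 20/s, k₋ = 100/s, γ = 0.1/s, α = 100/s`), slow switching
(`k₊c₀ = 0.01/s, k₋ = 0.05/s, γ = 1/s, α = 25/s, ζ = 500`), the two ramp
operating points (`k₊c₀ = 10⁷/s` with `k₋ = 6.7×10⁷/s` or `6.7×10⁶/s`,
`k₊c₁ = 10⁵/s²`, `k_x = 5/s`, `k_y = 10/s`) and the SDE-validation point
(`k₊c₀ = 10⁶/s, k₋ = 6.7×10⁵/s, k₊c₁ = 10⁴/s², k_x = 10/s, k_y = 50/s`).
What the model deliberately omits: finite burst duration (real nuclear
bursts last minutes; delta pulses make the BM marginal unimodal where finite
pulses would be bimodal), non-exponential dwell times (irreversible cycles
can push `g` below 2), time-varying concentration inside the Gillespie
engine (ramps are handled at the linearized level), diffusion-limited
rebinding, and downstream transcriptional bursting.  Passing tests therefore
certify the idealized Markov model, not those mechanisms.

## Problem sizes

The test suite runs the Gillespie comparisons at `t_end = 2×10⁴/γ...2×10⁵`
time units (0.8–1.6 million events per trajectory), SDE ensembles at 600
runs × 5000 steps, and master-equation solves up to a few thousand copy
numbers; the acceptance script simulates `8×10⁵` time units per scheme
(~16,000 windows total).  At these sizes the Monte-Carlo standard errors are
a few percent or less, and all stochastic assertions are phrased in units of
the estimators' own standard errors (3–4 SE), not absolute tolerances.
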