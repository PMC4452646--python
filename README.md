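# modnoise

How accurately can a cell sense its environment when receptor occupancy is
relayed downstream **continuously** versus in **bursts**?  Cell-surface
receptors and ion channels switch between bound (*on*) and unbound (*off*)
states with rates `k₊c` (set by the ligand concentration `c`) and `k₋`.  Two
encoding schemes turn that telegraph signal into a production rate `u(t)` for
an intracellular species:

* **CM** (continuous modulation): the bound receptor signals at constant rate
  `α`, so `u_CM = α·r(t)`;
* **BM** (bursty modulation): a burst of `ζ` molecules is released at the
  instant of each binding, `u_BM = ζ·Σᵢ δ(t − tᵢ⁺)`.

With the matched-mean constraint `ζ = α/k₋` both deliver the same average
output, so their *noise* decides which encodes more information.  Their
multi-receptor analogues are amplitude modulation (AM: many unsynchronized CM
receptors) and frequency modulation (FM: synchronized BM receptors), the two
signaling modes observed for pulsatile transcription factors such as Msn2 and
Crz1.

`modnoise` implements the full comparison pipeline:

* **Exact master equations** for the joint (receptor state, copy number)
  distribution of both schemes — sparse truncated solves for the full
  distribution (modality, tails) and an exact conditional-moment closure for
  the first three moments.
* **Gillespie simulation** (numba-accelerated direct method) with
  time-weighted moment estimation and windowed-signal statistics.
* **Small-noise theory**: `⟨u⟩ = k₊c/(1 + k₊c/k₋)` with white-noise intensity
  `q = g·k₊c/(1 + k₊c/k₋)³`, where the factor `g` is 2 for CM and
  `1 + (k₊c/k₋)²` for BM — so BM beats CM only below unit occupancy ratio,
  and by at most a factor of 2.
* **Adaptation motifs** for ramp sensing: linear-noise (LNA) variances of the
  incoherent feedforward loop (`dx/dt = k_x(e^{bu}e^{−bk_y y} − x)`,
  `dy/dt = u − k_y y`) and the integral feedback loop
  (`dx/dt = u e^{−by} − k_x x`, `dy/dt = k_y(x − 1)`), via the time-dependent
  Lyapunov equation, a first-order closed form, and Euler–Maruyama ensembles.
* **Receptor arrays**: the `N`- and `N²`-scaling of unsynchronized vs
  synchronized arrays, mixed synchronization, and the minimal receptor count
  for AM to beat FM.

## Worked example

```python
import modnoise as mn

params = mn.ReceptorParams(k_plus=1.0, c0=20.0, k_minus=100.0,
                           alpha=100.0, gamma=0.1)
print("occupancy ratio r =", params.ratio, " matched burst size zeta =", params.zeta)
for scheme in ("cm", "bm"):
    ms = mn.analytic_moments(params, scheme)
    print(f"{scheme.upper()}: mean = {ms.mean:.2f}  variance = {ms.variance:.2f}")

traj = mn.simulate(params, "cm", t_end=2e4, seed=1)
em = mn.empirical_moments(traj)
print(f"Gillespie CM: mean = {em.mean:.2f} ± {em.se_mean:.2f}  "
      f"variance = {em.variance:.1f} ± {em.se_variance:.1f}")
print("minimal N for AM advantage at r = 0.5:",
      mn.minimal_n_for_am_advantage(0.5).n)
```

prints

```
occupancy ratio r = 0.2  matched burst size zeta = 1
CM: mean = 166.67  variance = 282.31
BM: mean = 166.67  variance = 143.54
Gillespie CM: mean = 166.45 ± 0.52  variance = 287.7 ± 9.9
minimal N for AM advantage at r = 0.5: 2
```

Both schemes share the mean `α·p_b/γ = 166.67` by construction; at occupancy
ratio `r = 0.2` (fast unbinding) the bursty scheme carries roughly half the
variance of the continuous one, in line with the small-noise ratio
`2/(1 + r²) ≈ 1.92`, and the stochastic simulation agrees with the exact
moments within its quoted standard errors.  Two receptors already suffice for
an unsynchronized CM array to beat a synchronized BM array.

## Command line

```bash
modnoise --show-defaults
modnoise moments  --scheme cm --config params.cfg --out moments.csv
modnoise simulate --scheme bm --config params.cfg --t-end 1e4 --seed 1 --out traj.csv
modnoise network  --motif iffl --scheme bm --config params.cfg --t-max 2 --out net.csv
modnoise array    --n 8 --rho 0.5 --scheme cm --config params.cfg --out array.json
modnoise sweep    --regime fast_unbinding --out sweep.csv
modnoise report   --name fig4
```

Configs are flat `key = value` files (`k_plus, c0, c1, k_minus, alpha, gamma,
zeta, scheme, k_x, k_y, b`); flags override file values, and every run writes
a `*.manifest.json` with the resolved config, seed and package version.

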