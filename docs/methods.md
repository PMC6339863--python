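# Methods

## Model

The simulator implements the classic three-variable Chay model of a
bursting excitable cell. Four conductance pathways shape the membrane
potential: a voltage-gated mixed Na⁺–Ca²⁺ channel with instantaneous
activation `m∞(V)` and inactivation `h∞(V)`; a delayed-rectifier-style K⁺
channel gated by the relaxing variable `n`; a Ca²⁺-activated K⁺ channel
whose conductance scales with `C/(1+C)`; and an ohmic leak. The slow
accumulation and efflux of the Ca²⁺ variable `C` modulates the
Ca²⁺-activated K⁺ conductance and is what terminates each burst, producing
the alternation between spiking and quiescence.

The gating rates are Hodgkin–Huxley-type exponential/logistic closed
forms. Two of them, `α_m` and `α_n`, have removable 0/0 singularities (at
V = −25 mV and V = −20 mV). They are evaluated as `a·u/(1 − e^{−b·u})`
via `expm1`, and within `|b·u| < 1e−7` of the singular point by the
analytic limit `a/b` plus its first-order series — this avoids
catastrophic cancellation while keeping the functions continuous to
better than 1e−4 across the singular points (tested).

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| V_i, V_c | mixed-channel / Ca²⁺ reversal potential | 100 | mV |
| V_k | K⁺ reversal potential | −75 | mV |
| V_l | leak reversal potential | −40 | mV |
| g_i, g_kv, g_kc, g_l | maximum conductances | 1800, 1700, 11.5, 7 | model units |
| λ_n | K⁺-gate rate scale | 230 | 1/s |
| ρ | Ca²⁺ balance proportionality | 0.27 | – |
| k_C | Ca²⁺ efflux rate constant | 3.3/18 | – |

The kinetic constants λ_n, ρ, k_C are the standard values of the original
model formulation; together with the conductance profile above they give
perfectly periodic bursting — 5 spikes per burst, intra-burst interspike
intervals growing from 0.39 to 0.74 s, inter-burst gaps of 3.47 s, V in
[−48.2, −19.5] mV.

On units: the model is treated as nominally unitless with V in mV and t in
s; conductances are used exactly as printed and currents reported as
`g·(V − V_rev)` in nominal nA. A strict dimensional reading (nS·mV = pA)
would disagree with this by 10³; the nominal reading is the only one under
which the conductances, current magnitudes, nW power axes and nJ/30 s
energy totals are mutually consistent, and is adopted throughout. The
membrane equation carries no explicit capacitance (implicit unit
capacitance), as in the standard formulation.

## Integration

Classic fixed-step 4th-order Runge–Kutta, default `dt = 1e−5 s`, recording
every 10th step (1e−4 s output grid). A spike upstroke lasts ~10 ms, so
the default resolves it with ~10³ integration points; halving `dt` changes
the 30 s energy total only in the 7th digit (the self-convergence test
bounds the change at 0.5%, the measured change is far smaller). A fixed
step keeps quadrature and landmark timing bit-for-bit reproducible. The
integration aborts with a diagnostic if |V| exceeds 500 mV.

Stimulus protocols are piecewise constant (none / single rectangular pulse
on `[t_on, t_off)` / intermittent train on the first `pulse_len` seconds
of every `period`, anchored at t = 0). The stimulus is evaluated at the
RK4 sub-step times; steps are not aligned to switch instants, an O(dt)
smearing that is negligible at sub-millisecond steps.

### Initial conditions

All headline runs start from `standard_initial_state`: integrate 30 s
without stimulus from the fixed seed (V = −40 mV, n = n∞(−40), C = 0.5)
and take the final state, so t = 0 lies in steady bursting. The package
contains no randomness anywhere; the warm-up is cached per parameter set
and bit-identical across calls. Because 30 s is not an integer multiple of
the 5.57 s burst period, the energy accumulated in a 30 s window depends
slightly (±2%) on the phase at which the window opens; the fixed warm-up
convention pins that phase deterministically.

## Energy accounting

`P = (|I_kv V_k| + |I_kc V_k| + |I_l V_l| − |I_i V_i|)·10⁻³` nW. The sign
convention follows the circuit picture: outward K⁺ and leak currents drain
their concentration-gradient batteries into transmembrane electrical
potential energy (absorption, positive), the inward mixed current drains
the Na⁺/Ca²⁺ batteries (release, negative). The ×10⁻³ rescaling maps
nominal nA·mV onto the nW scale of the headline results and can be
disabled (`rescale=False`) for unit-agnostic work.

A caveat inherent to this net-power accounting: charge carried by
simultaneously cancelling inward and outward currents costs the pump ATP
that `P` cannot see, so energy totals derived from `P` are a lower bound
on true pump consumption.

Energy integrals use trapezoidal quadrature of `P_positive = max(P, 0)`
and `P_negative_mag = max(−P, 0)` on the recorded grid. At 1e−4 s output
resolution the quadrature error against a closed-form test integrand
(∫|sin 2πt|) is below 1e−6, orders of magnitude below any tolerance used.
`E_total = E_absorb + E_release` holds exactly by construction, as does
additivity over abutting windows on a shared grid.

## Phase analysis

Spikes are local V maxima above −30 mV separated by ≥5 ms (detected with a
standard peak finder). Bursts group consecutive spikes with inter-peak
gaps below 1.5 s — chosen between the largest intra-burst interval
(0.74 s) and the inter-burst gap (3.47 s) of the default dynamics.
Landmarks per spike:

* **B** — last upward crossing of −45 mV before the peak (the mixed
  channel's effective opening threshold);
* **C** — the V maximum (grid argmax; no sub-sample interpolation, for
  determinism);
* **D** — maximum of P between C and the next inter-spike V minimum;
* **E** — first sample after D with `P ≤ ε_P`.

`ε_P` defaults to 2 nW, just above the resting-plateau power level
(0.9–1.4 nW at the defaults): during late repolarization P settles onto
that small positive plateau rather than to exactly zero, so a
near-machine-zero threshold would never fire within the DE segment.
Hyperpolarization is flagged for a burst when V after its final spike
dips more than 1 mV below the pre-burst plateau (median V over the 100 ms
preceding the burst's first B); at the defaults the dip is ~2.7 mV after
final spikes and within 0.3 mV of the plateau between intra-burst spikes,
so the flag cleanly separates the two. All thresholds are keyword
arguments.

At a spike peak the four currents cancel almost exactly (dV/dt = 0), so
whether the sampled imbalance is marginally inward or outward depends on
which side of the true maximum the grid point falls. Peak-current
analyses therefore run on trajectories recorded on the integration grid
(`record_stride=1`), where the argmax lands within 5 µs of the true peak;
on the default 1e−4 s output grid the sampled imbalance at the peak can
take either sign.

## What the simulations do and do not show

All experiments here are pure simulation of a single deterministic model
neuron; there is no external data. The stimulus experiments emulate
current-clamp protocols (1 s pulse, 5 s pulse, 1 s-per-5 s train at
−50..150 nA). What they do not emulate: channel noise, temperature
effects, multi-compartment geometry, synaptic conductance inputs, or any
ATP-molecule bookkeeping — results are energies in nJ only. Agreement of
the test suite therefore validates the numerics and the accounting method,
not the biophysical fidelity of the Chay model to any particular cell
type.

Problem sizes used by the packaged experiment drivers: 30 s production
runs at dt = 1e−5 s (3×10⁶ steps, 3×10⁵ recorded samples), a 10-cell
stimulus grid, and 21-point amplitude sweeps per protocol family; the
right-hand side is compiled (numba), making each 30 s run ~1 s.

## Known limitations

* The amplitude–energy curves carry few-nJ wiggles from the start-phase
  sensitivity noted above; they are trends, not smooth functions, and
  fine-grained orderings between nearby amplitudes (e.g. a −30 nA 1 s
  pulse vs no stimulus, ~0.3 nJ apart) are not stable features.
* The intermittent train delivers 6 s of total on-time in 30 s versus 5 s
  for the long pulse; under this scheme its energy totals consistently
  exceed the 5 s-pulse totals at matched amplitude by ~7%.
* Burst-segmentation and landmark defaults are calibrated to the default
  parameter profile; strongly different conductance sets may need the
  thresholds adjusted via the exposed keywords.
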