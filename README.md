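# chay-energy

Simulator and energy-accounting toolkit for a bursting neuron described by
the Chay model, aimed at computational neuroscientists studying the
metabolic cost of sub-threshold firing patterns.

Bursting — clusters of spikes separated by quiescent intervals — is
ubiquitous in electrophysiology, and its energetic cost bears on theories
of energy-efficient neural coding. This package simulates the
three-variable Chay model and quantifies, instant by instant, how much
electrical potential energy the membrane's ionic batteries (the reversal
potentials maintained by the Na/K-ATPase pump) absorb or release.

## The model

State `(V, n, C)`: membrane potential (mV), K⁺-gate opening probability,
and an intracellular Ca²⁺ variable. Dynamics:

```
dV/dt = g_i m∞³ h∞ (V_i − V) + g_kv n⁴ (V_k − V) + g_kc C/(1+C) (V_k − V) + g_l (V_l − V) + I
dn/dt = (n∞ − n) / τ_n,            τ_n = 1 / (λ_n (α_n + β_n))
dC/dt = ρ (m∞³ h∞ (V_c − V) − k_C C)
```

with Hodgkin–Huxley-style rate functions for `m∞`, `h∞`, `n∞` and the
default parameter profile `V_i = V_c = 100`, `V_k = −75`, `V_l = −40` mV,
`g_i = 1800`, `g_kv = 1700`, `g_kc = 11.5`, `g_l = 7`, `λ_n = 230 s⁻¹`,
`ρ = 0.27`, `k_C = 3.3/18`, which produces second-scale bursts of spikes
with `V` confined to roughly [−55, −15] mV.

## The energy statistic

Treating the reversal potentials as voltage sources in the membrane's
equivalent circuit, the instantaneous power of transmembrane
electrical-potential-energy change is

```
P = |I_kv V_k| + |I_kc V_k| + |I_l V_l| − |I_i V_i|      (nA·mV → nW, ×10⁻³)
```

Negative `P` means net release of stored gradient energy (dominant inward
mixed Na⁺–Ca²⁺ current, i.e. spike upstrokes); positive `P` means net
absorption (dominant outward K⁺/leak currents, repolarization and rest).
The total energy over a window,

```
E = ∫ P_positive dt + ∫ |P_negative| dt  =  ∫ |P| dt        (nJ)
```

is a proxy for the ATP consumed by the Na/K-ATPase pump to rebuild the
gradients. The library also segments trajectories into bursts, locates the
per-spike landmarks B (depolarization onset, −45 mV upward crossing),
C (V maximum), D (P maximum) and E (P back at the resting plateau), and
detects the hyperpolarization that follows only the final spike of each
burst.

## Worked example

```python
from chayenergy import (fig1_defaults, standard_initial_state, simulate,
                        total_energy, detect_spikes, annotate_phases,
                        first_spike_of_steady_burst, peak_to_power_zero_delay)

params = fig1_defaults()
init = standard_initial_state(params)       # warm onto the bursting attractor
traj = simulate(params, duration=30.0, init=init)

rep = total_energy(traj)
print(f"E_absorb={rep.E_absorb:.1f} nJ  E_release={rep.E_release:.1f} nJ  "
      f"E_total={rep.E_total:.1f} nJ")

peaks = detect_spikes(traj)
ann = annotate_phases(traj)
s = first_spike_of_steady_burst(ann)
print(f"{peaks.size} spikes in {len(ann.bursts)} bursts; "
      f"peak-to-power-zero delay {peak_to_power_zero_delay(traj, peaks, s)*1e3:.1f} ms")
```

prints

```
E_absorb=117.5 nJ  E_release=89.4 nJ  E_total=206.9 nJ
26 spikes in 6 bursts; peak-to-power-zero delay 6.9 ms
```

i.e. 30 s of spontaneous bursting costs ~207 nJ of electrical potential
energy (absorption and release contributions separated), the run contains
6 bursts of 5 spikes, and after a spike's voltage peak the power needs
~7 ms to climb back to zero — the membrane is still releasing gradient
energy at the very top of the spike.

The same computations are available from the shell:

```
chay-energy energy --duration 30 --out out/                    # E report
chay-energy phases --duration 6 --out out/                     # landmark CSVs
chay-energy table2 --out out/                                  # stimulus grid
chay-energy sweep --family pulse_5s --out out/                 # amplitude sweep
chay-energy simulate --stim pulse --amp -30 --off 1 --plot --out out/
```

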