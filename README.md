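# larvanet

Analysis toolkit for larval *Drosophila* chemotaxis behavior and the
circuits behind it. It re-implements, as a tested reusable library, the
bespoke computations of a connectome-and-behavior workflow:

* **Trajectory metrics** from 11-point midline ("spine") tracks: track
  quality filtering, the spine-based turn angle, turn and head-sweep
  detection, the navigation index, orientation-conditioned turn rates with
  Welch Z contrasts, and onset/offset statistics for pulsed-light screens.
* **Reverse correlation** of turn initiation under flickering light, as a
  linear–nonlinear–Poisson (LNP) model: turn-triggered averages, a
  third-order impulse-response kernel scaled to unit filtered-signal
  variance, the histogram turn-rate estimator
  r(x_f) = N_turn/N_all · 1/Δt, and the ratio-of-Gaussians closed form
  r_ROG(x) = r̄ · [e^(−(x−μ)²/2σ²)/σ] / e^(−x²/2).
* **Connectome post-processing** over hemilateral neuron pairs:
  strong-connection filtering (≥ 3 synapses from each presynaptic homolog,
  ≥ 10 total), the pⁿ false-positive model for a per-contact error rate of
  0.0167, binary connectivity matrices, matches/(matches+mismatches)
  similarity with hierarchical clustering, input fractions, convergence-
  neuron (CN) classification, and valence prediction from MBON input
  composition at a 5% input threshold.
* **Calcium response scoring**: ratiometric normalization against a
  structural channel, ΔF/F₀ with a 5 s pre-stimulus baseline, 3 s ON / 8 s
  OFF scores, response amplitudes, paired Wilcoxon tests, and an
  inter- vs intra-individual variance decomposition (one-way ANOVA).
* **Synthetic data** for all of the above — LNP-driven larvae on a Brownian
  light stimulus, gradient klinotaxis cohorts, paired connectomes with
  controlled false-positive contacts, and calcium traces with nested
  variance components — so every stage is testable end-to-end, including
  full simulate-then-recover round trips.

## Worked example: recover an LNP model from simulated behavior

```python
import numpy as np
from larvanet import simulate as sim
from larvanet.revcorr import TurnLNP

# 10 min of Brownian red-light flicker at 112 Hz, shared by all larvae
stim = sim.simulate_stimulus(600.0, seed=11)

# 50 larvae whose turn initiation follows a known kernel + ratio-of-
# Gaussians nonlinearity (defaults: rbar=0.067 turns/s, mu=-0.5, sigma2=0.64)
tracks, truth = sim.simulate_larvae_lnp(stim, n_larvae=50, seed=12)

res = TurnLNP.from_simulation(stim, truth).fit()
print(res.summary())
```

This prints:

```
LNP turn-initiation model
============================================
n turns used (TTA)              1803
n turns used (ROG)              1845
total run time T (s)         28564.4
kernel gain                   -32.95
kernel tau (s)                0.5296
kernel scale                0.001079
Var(x_f)                    1.000000
rbar (turns/s)                0.0646  (se 0.0015)
mu                            0.4788  (se 0.0196)
sigma                         0.8398  (se 0.0138)
conservation |err|         0.000e+00
```

Reading the output: 1,845 turns were observed over 28,564 s of run time,
giving a mean turn rate r̄ = 0.065 turns/s against a simulated 0.067. The
kernel timescale τ = 0.53 s recovers the simulated 0.5 s, and the filtered
signal has unit variance as the scaling contract requires. The fitted
(kernel, μ) pair is the sign-flipped gauge of the simulated one — reverse
correlation identifies them only up to a joint flip, so μ = +0.479 here
corresponds to the simulated −0.5, and the kernel-shape correlation with
truth is |r| = 0.997. `res.block_standard_errors()` gives Monte-Carlo SEs
that account for all larvae sharing one stimulus; `res.rate_table` and
`res.rog.rate(x)` give the empirical and closed-form rate functions, and
`res.plot()` draws both.

A command-line interface mirrors the library
(`larvanet simulate-stimulus`, `simulate-tracks`, `simulate-connectome`,
`simulate-calcium`, `analyze-tracks`, `revcorr`, `connectome`, `calcium`);
every simulation command takes `--seed` and writes a YAML provenance log.

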