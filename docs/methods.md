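# Methods

## Model overview

`goalseq` couples three processes: (1) a CA3 spiking continuous-attractor
network whose "bump" state represents a position in a familiar
environment; (2) reward-gated Hebbian learning at context→DG synapses that
stores context-specific goal locations; (3) a simulated Home/Away foraging
task in which 400 ms sequence episodes are generated at each trial-phase
onset and their endpoints set the rat's navigation target.

Assumptions inherited from the modelled system: context coding (Home vs
Away task phase) is hard-wired and noise-free apart from Poisson spiking;
CA3 recurrent weights are fixed, symmetric Gaussians of place-field
distance (no sequence learning in CA3); recurrent transmission is gated
off during movement; one place field per cell on a rigid lattice; a single
sequence per trial phase directly determines behavior.

## Neuron, synapse and integration

Leaky integrate-and-fire dynamics, exact integration at dt = 0.2 ms. All
equations are linear, so each step applies the closed-form solution for a
membrane with exponentially decaying synaptic currents and constant
external drive; with zero noise the update matches the analytic solution
to < 1e-9 mV (tested). Spikes reset u to E_L and open an absolute
refractory period (3 ms exc, 4 ms inh); delayed spikes are delivered at
the first integration step at or after emission time + delay.

The spike threshold is not part of the published parameter set; we use
V_theta = -50.4 mV, the standard-neuron threshold of the parameter family
the membrane constants come from, for every population (configurable).

The CA3 background-noise amplitude is specified as "2 mV/ms". Its
per-step interpretation is a config option: `sqrt_dt` (Wiener scaling,
sd·sqrt(dt) per step) or `dt` (sd·dt per step). The default is `dt`: with
the Wiener reading the pre-learning bump wanders measurably within one
episode (~15–19 cm over 350 ms at reduced scale), while the `dt` reading
keeps it stationary, which is the documented pre-learning behavior of the
model; both remain available.

## Connectivity and the calibrated gains

Topologies, Gaussian widths (σ_DG−CA3 = σ_CA3 = 50 cm, DG→CA3 cutoff
50 cm), time constants, delays, the one-to-one context→DG mapping and the
[0, 0.3] nA random weight initialization follow the source architecture.

The published peak weights for the CA3-internal projections, read as
per-spike current increments under the stated membrane equation, do not
produce a working attractor: summed recurrent drive at saturation
(~0.82 nA × Σ exp(−d²/σ²) ≈ 234 nA per cell) exceeds the maximum
inhibition 259 interneurons can deliver (≈2.4 nA at the refractory-limited
rate) by two orders of magnitude, making whole-network saturation the only
stable state; simulation confirms this at both full and reduced scale.
We therefore keep the printed exc→inh (9.75 pA) and inh→exc (18.45 pA)
values and recalibrate the remaining three gains by mean-field balance and
grid search against the model's documented behaviors (bump persistence and
stationarity before learning, goal capture after learning, ripple-band
oscillation):

| parameter | value (80×80 equivalent) | role |
|---|---|---|
| CA3 recurrent peak | 0.02 nA | bump self-excitation; above ~0.023 the bump delocalizes, below ~0.015 it dies |
| DG→CA3 peak | 0.2 nA | goal bias; sets the strength of mossy-fiber recruitment |
| inh→inh | 0.05 nA | interneuron synchronization (ripple period with the 2.5 ms delay) |

In this regime CA3 cells fire ~10–20 Hz during sequences in a bump of
roughly σ_CA3 extent, with strongly oscillatory population rates
(100–250 Hz band).

## Scale reduction

The canonical lattice is 80 × 80; the package's reduced scale is 40 × 40
over the same environment (spacing 10.5 cm instead of 5.25 cm). Two
rescaling rules keep dynamics comparable:

* density scaling (∝ spacing²) for the mean-drive projections (CA3
  recurrent; exc→inh by sender count), preserving each cell's summed
  input;
* fluctuation scaling (∝ spacing) for DG→CA3, because the goal bias acts
  through threshold recruitment driven by shot-noise fluctuations of the
  mossy-fiber input (sd ∝ w·sqrt(density)); preserving the mean instead
  leaves the bias ineffective at full scale or overdriven at reduced
  scale (checked empirically at both scales).

The interneuron count stays at 259 at every scale.

## Task and plasticity bookkeeping

The task follows the alternating Home/Random structure: 36 wells on a
6 × 6 grid (33.3 cm pitch), reward radius 5 cm, movement in 100 ms steps
at 15 cm/s with Gaussian step noise (0.5 cm² per component), rat starting
in a random arena corner and continuing from each reward site. After each
sequence the rat walks to the endpoint, probes the nearest well (a failed
probe triggers R = −1 once), visits the four endpoint-nearest wells, then
probes the remaining wells in uniformly random order, each exactly once.
The uniform order was chosen over a nearest-first heuristic because the
latter searches too efficiently to reproduce the documented Home/Away
latency contrast (≈15 s vs ≈75 s); nearest-first remains a config option.

Eligibility traces decay with τ_trace = 100 ms, so reward-driven weight
updates depend only on spikes from the last few hundred ms. Movement is
therefore advanced kinematically, and context + DG spiking is simulated
only inside windows from 6 τ_trace before each reward event to 100 ms
after it (truncation error < 0.3% of a trace); traces decay in closed form
across the gaps. During the 100 ms reward window the rat consumes at the
reward site (place current at that location); during an omission window it
keeps searching. Weight updates integrate with the 0.2 ms neural step
(Euler on the gated rule), and only the active context's projection is
plastic.

## Decoding

Tuning curves for the Bayesian decoder are, by default, isotropic
Gaussians per unit with peak and width fitted to movement-state firing
measured in a short calibration simulation (recurrents off, rat parked at
increasing distances from a probe cell's field center). Movement-state
rates saturate near the refractory limit at the field center, so the
fitted width (~80–90 cm) is broader than σ_PF; the decoder only needs
relative shape, and posterior centers of mass are unbiased on
model-matched synthetic bumps to within one bin (tested). A binned
rate-map mode ("simulated", from a random-walk traversal) exists for
cross-checking at small scale.

Decoding frames are 5 ms windows advanced by 2 ms, in log space, with a
rate floor of 1e-4 Hz. The population is partitioned into random disjoint
subsets (full scale: 40 × 160 cells, bin 2.625 cm); the pooled track is
the center of mass of the across-subset mean of individually normalized
posteriors. Inside the parameter sweep, decoding uses 4 subsets of 160
cells and 5.25 cm bins — the pooled track is already stable at that size,
and this keeps the 450-event sweep tractable on one CPU.

## Sequence classification and sweep

Max-jump: an event is jump-like if any consecutive-frame displacement of
the pooled decoded track strictly exceeds 40 cm. Cluster count: mean-shift
mode seeking (Gaussian kernel, bandwidth 52.5 cm, tolerance 0.1 cm, max
500 iterations, modes merged within bandwidth/2, iterates seeded from
occupied bandwidth/2 grid cells) on the spiking cells' field centers per
frame, weighted by spike counts; two or more modes in any frame flags the
event. The first 50 ms (bump initialization) are excluded everywhere.

The transition distance scans candidate thresholds at midpoints of the
pooled sorted start-to-end distances and returns the d* minimizing
α(d) = max(P[jump ≤ d], P[smooth ≥ d]), ties toward smaller d.

The sweep runs a 3 × 3 grid over (σ_DG−CA3, σ_CA3) at ×0.5, ×0.75, ×1.0
of the 50 cm defaults (the original grid's σ values are not printed), with
peak weights rescaled by (σ0/σ)² to hold the 2-D weight integral constant
(a linear option exists). Inputs are (weight vector, start position)
snapshots stored at post-learning phase onsets of the behavioral runs;
each configuration replays 50 such episodes.

Observed behavior at reduced scale: transition distances 105–148 cm with
broader profiles giving larger d*, overlap α ≤ 0.15 (cluster criterion),
and bump speed increasing with start-to-end distance in every
configuration. Unlike the original report, the jump-like *proportion* is
nearly flat across the grid (~12–14%) rather than falling from ~40%
(narrowest) to 0% (broadest): in the calibrated regime, secondary-bump
ignition is governed mostly by the trial's start-to-goal distance, and
area-preserving σ rescaling barely moves the ignition distance. This is a
known, documented divergence; we did not adjust parameters to force the
published proportions.

## Problem sizes

Tests and the acceptance script run the behavioral study at the 40 × 40
scale with 10 networks × 8 trial pairs (counterbalanced Home wells), the
sweep with 50 events per configuration, and a single full-scale (80 × 80)
sequence for the spectral analysis. Sequence episodes cost ~0.4 s
(reduced) / ~1.2 s (full) of wall time each.

## What the synthetic fixtures do and do not show

The fixture generators produce Poisson spikes from ideal Gaussian tuning
(stationary or linearly translating bumps), bimodal spatial frames, and
smooth goal-centered weight profiles. They validate the decoding and
classification machinery under the decoder's own model assumptions —
independence, known tuning, stationarity within frames. Passing those
tests does not certify performance on real recordings, where tuning is
estimated, firing is correlated within ripple cycles, and bump shapes are
irregular; the network-generated events exercise those harder conditions
qualitatively but with simulated, not biological, variability.

## Known limitations

* The published CA3-internal weight magnitudes are replaced by calibrated
  values (see above); conclusions that depend on absolute synaptic
  strengths should not be drawn from this implementation.
* The jump-proportion phase diagram is compressed relative to the original
  (flat ~12–14% across the σ grid).
* Reward latencies depend on the exhaustive-search order; the uniform
  no-repeat order reproduces the documented means, but any such order is
  an assumption.
* At reduced scale, lattice granularity adds COM quantization (~one
  10.5 cm spacing) to bump-drift estimates, and single DG spikes carry
  larger kicks than at full scale.
* Degenerate episodes (bump death) are flagged, not repaired; they are
  rare at default parameters (< 1%).
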