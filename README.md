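# goalseq

Goal-directed hippocampal place-cell sequences from a spiking
continuous-attractor network.

During awake pauses, hippocampal place cells emit time-compressed
"sequences" that often sweep from the animal's current position toward a
known goal, and these sequences predict where the animal goes next.
`goalseq` implements a mechanistic account of how such goal-anticipating
sequences can arise and guide behavior: a cortical context signal, filtered
through reward-modulated synapses onto dentate gyrus (DG), biases the bump
state of a CA3 spiking continuous-attractor network, so that recall
activity travels from the current location toward the remembered,
context-appropriate goal. The package contains the full loop — spiking
simulation, goal learning, a Home/Away foraging task driven by sequence
endpoints, Bayesian population decoding, and smooth-vs-jump sequence
classification — and is aimed at computational neuroscientists studying
replay, planning and continuous-attractor dynamics.

## Model

DG and CA3 cells are leaky integrate-and-fire neurons with current-based
synapses (instantaneous rise, exponential decay), advanced by exact
integration at dt = 0.2 ms:

    C du/dt = -g_L (u - E_L) + I_exc - I_inh + I_ext + C ξ
    τ_s dI_s/dt = -I_s,   I_s ← I_s + w  on each presynaptic spike

with C = 300 pF, g_L = 30 nS, E_L = -70.6 mV, τ_exc = 6 ms, τ_inh = 2 ms,
and a Gaussian background noise ξ on CA3 cells. 6,400 DG and 6,400 CA3
cells tile a 4.2 m × 4.2 m virtual environment as an 80 × 80 lattice of
place-field centers (the visitable arena is the central 2 m × 2 m). CA3
recurrent weights fall off as a Gaussian of field-center distance
(σ_CA3 = 50 cm); DG→CA3 projections are local Gaussians (σ = 50 cm, cut
off at 50 cm); 259 interneurons provide delayed (2.5 ms) global inhibition,
which makes population activity oscillate in the 100–250 Hz ripple band
during recall.

Goal memory lives in one-to-one context→DG synapses, learned with a
reward-gated Hebbian rule on eligibility traces x̄ (pre) and ȳ (post),
τ_trace = 100 ms:

    dw/dt =  α_L [x̄ ȳ - w]+   while R = +1   (saturating potentiation)
    dw/dt = -α_L  x̄ ȳ         while R = -1   (depression)

The saturating form makes goal learning one-shot and immune to occupancy
bias. During movement, place-specific currents I_ext = I_max
exp(-|x-x_j|²/σ_PF²) (I_max = 10 nA, σ_PF = 25 cm) drive place-field
activity; during 400 ms sequence episodes the place current initializes a
bump at the rat's position (50 ms), then the active context population
steps from 10 Hz to 200 Hz and the learned DG bias steers the bump for
350 ms. The bump's final center of mass is the rat's next navigation goal
in a 36-well Home/Away foraging task.

Analysis follows the experimental playbook: memoryless Bayesian decoding
of 5 ms spike-count frames under independent-Poisson tuning curves
(decoded on random 160-cell subsets, pooled by averaging posteriors),
population-vector cross-checks, max-jump (40 cm) and mean-shift
cluster-count (bandwidth 52.5 cm) classification of events as smooth or
jump-like, and the transition distance d* that best separates the two
classes' start-to-end distance distributions.

## Worked example

Simulate two networks for four Home/Away trial pairs at reduced scale
(40 × 40 lattice; same environment, density-rescaled weights):

```bash
cat > cfg.yaml <<EOF
seed: 7
n_networks: 2
n_pairs: 4
EOF
goalseq simulate --config cfg.yaml --out runs/demo
```

which prints

```
mean latency: home 27.7 s, away 82.0 s (16 phases) -> runs/demo/trials.csv
```

Per-trial Home latencies from `trials.csv` show the one-shot learning
signature — the first Home trial is found by random search, all later ones
by a direct, sequence-guided run:

```
home latency by trial: {1: 93.6, 2: 3.4, 3: 7.4, 4: 6.4}
home endpoint error t>=2: 5.3 cm
```

i.e. after a single rewarded visit the sequence endpoint lands ~5 cm from
the Home well, and reward latency collapses from ~94 s to ~5 s. The
archive `runs/demo/blocks.h5` holds every sequence event (spikes, bump
track) and the learned weight snapshots; `goalseq analyze` classifies the
stored events and `goalseq sweep --snapshots runs/demo/blocks.h5` replays
them across a 3 × 3 grid of Gaussian profile widths.

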