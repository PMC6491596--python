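# Methods

## Model

A network of `n` neurons evolves on a discrete grid of `dt = 2 ms` steps
(one step ≈ an absolute refractory period).  Neuron `i'` is simultaneously
(a) a generative *process*: at step `t` it emits a spike drawn from a
Bernoulli with its instantaneous firing expectation, which becomes the
observation `o_{t+1}^{i'}` of every efferent target; and (b) a generative
*model*: it explains its `k` afferent observations as caused by one binary
hidden state, "the network is silent / firing".  Treating many presynaptic
neurons as a single hidden cause is a mean-field assumption; each neuron
therefore estimates the average propensity of its network to fire, not any
particular peer.

### Likelihood and precision

Each synapse carries an unnormalised 2×2 base table `A` (rows:
observation, columns: hidden state) and a precision `ζ ≥ 0`:

    P(o | s=h, ζ) = A[o,h]^ζ / Σ_l A[l,h]^ζ  =  Ā(ζ)[o,h].

`ζ` is the single coupling knob: at 0 the synapse is uninformative, and
the likelihood sharpens monotonically with `ζ`.  All synapses share one
base table (exposed in the configuration).

### Semi-Markov transition

The transition prior is a deterministic function of the neuron's own
thresholded firing history restricted to the window
`𝒯(τ) = {τ−t_max, …, τ−t_min}`: if no firing occurred in the window the
next state is "firing" with probability 1, otherwise "silent".  Both
columns of either matrix are equal, so the forward message
`ln(B s_{τ−1})` does not depend on the previous belief.  A neuron counts
as having fired when its firing expectation exceeds 0.5 strictly; ties are
silent.  History before the first step is padded with silence plus one
synthetic pre-burst whose placement sets the neuron's initial phase.

### Belief updating

The somatic potential follows a gradient flow on the step free energy,

    ε = ln σ(υ) − m,    υ ← υ − 0.25 ε   (up to 16 iterations per step,
                                          stop at max|ε| < 1e−6),

where `m` sums the likelihood messages `ζ^i ln Ā^i[o^i, :]` over active
synapses and the forward transition message.  `ε` is reported mean-centred
so it vanishes exactly at the fixed point `σ(m)` (log messages are defined
up to an additive constant on the simplex).  The backward (postdictive)
message is omitted throughout: without a model of future policies it
carries no information here.  The step free energy is recorded as
`F = s·(ln s − m)`, which upper-bounds the negative log evidence of the
step's observations and is tight at the exact posterior.

### Short-term plasticity

Precisions carry unit-shape gamma priors with rate `β = 1/ζ₀` and gamma
posteriors with rate `𝛃` (expected precision `1/𝛃`).  Each step the
outcome prediction error

    g = Σ_j ln A[:,j] · (onehot(o) − Ā[:,j]) s_j

(the ζ-derivative of the expected log likelihood; verified against finite
differences to 1e−4 relative error) is accumulated; every `p = 25` steps
the posterior rate moves a fraction `η` towards the variational solution:
`𝛃 ← 𝛃 + η (β − Σg − 𝛃)`.  With no evidence the posterior relaxes to the
prior.  The expected precision is clamped to `(0, 0.95]` — a stand-in for
synaptic homoeostasis, which is not modelled.

### Pruning (Bayesian model reduction)

Removing a synapse is modelled as replacing its precision prior by a much
tighter gamma prior `Γ(1, β̃)` concentrated near zero.  For unit-shape
gammas the log evidence change is available in closed form from the full
model's posterior alone:

    ΔF = ln β̃ − ln β + ln 𝛃 − ln(𝛃 − β + β̃),   valid for 𝛃 − β + β̃ > 0,

verified against numerical quadrature (1e−6) and satisfying the two sanity
identities ΔF = 0 when β̃ = β and when 𝛃 = β.  A synapse is pruned,
irreversibly, when ΔF strictly exceeds 2.5 (≈ 12-fold evidence for the
reduced model).

**Which posterior enters ΔF.**  The damped short-term posterior cannot be
used: its rate is bounded by the self-consistency condition
`𝛃* = β − G(1/𝛃*)`, and because the normalised likelihood flattens as `ζ`
falls, the per-step evidence `g` vanishes near `ζ ≈ 0.2`, capping `𝛃*` near
5 and hence ΔF ≤ ln(𝛃*/β) ≈ 1 — below any useful threshold, for every
choice of β̃.  The engine therefore evaluates the reduction on the
*epoch-evidence posterior* `𝛃_eval = 𝛃 − Σ_epoch g`, i.e. the undamped
closed-form update applied to the evidence accumulated over the epoch
(`e = 50` steps).  This is the same update equation that drives plasticity,
without the learning-rate damping, and is the only reading under which
threshold-2.5 pruning is reachable at all.  Strong positive evidence can
push `𝛃_eval` to its floor, giving a very negative ΔF (synapse clearly
retained).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_neurons` | 16 | – | stock network size |
| `dt_ms` | 2 | ms | one step ≈ refractory period |
| `t_min` | 5 | steps | bursts extend up to 10 ms |
| `t_max` | per-neuron U{15..25} | steps | onset-to-onset interval `t_max+t_min` ∈ 40–60 ms |
| `initial_zeta` | 0.5 | – | initial synaptic gain (gamma prior rate 2) |
| `base_table` | ((0.70, 0.25), (0.30, 0.75)) | – | calibrated; see below |
| `transition_floor` | 0.1 | – | pseudo-probability for B's zero entries; see below |
| `belief_step`, `belief_iters`, `belief_tol` | 0.25, 16, 1e−6 | – | converges well inside one step |
| `plasticity_period` | 25 | steps | ≈ one intrinsic cycle |
| `plasticity_rate` | 0.01 | per period | per-step ζ increments of order 1e−3 |
| `zeta_max` | 0.95 | – | precision ceiling (homoeostasis stand-in) |
| `epoch_length` | 50 | steps | pruning evaluation cadence |
| `pruning_threshold` | 2.5 | nats | log Bayes factor for removal |
| `reduced_rate` | 400 | – | reduced prior ≈ delta at zero (E[ζ]=0.0025) |
| `fe_window` | 15 (perturbation) / 35 (structure) | steps | sliding free-energy window |

### Calibration of the unpublished constants

The base table, the transition floor and the plasticity rate are not
derivable from first principles; they were fixed once, by a coarse grid
search over candidate values scored against the behaviours the model is
meant to exhibit, and then frozen before the test suite was written:

* **Transition floor** (0.1).  The zero entries of the deterministic `B`
  enter the somatic potential through a logarithm; flooring them at the
  generic numerical floor (1e−16) makes the intrinsic rhythm contribute
  ±37 to the potential, which no biologically sensible number of synapses
  can override — the network reduces to independent clocks, coupled in
  name only, and uncoupled beliefs are perfectly precise rather than
  near-chance.  The floor is therefore a *model* parameter — the precision
  of the intrinsic rhythm relative to synaptic evidence (±2.2 at 0.1) —
  not a numerical detail.
* **Base table** (asymmetric).  A symmetric high-contrast table makes
  ensemble silence exactly as strong evidence as ensemble firing; mean-field
  analysis of the message balance (15 synapses at ζ = 0.5 against the ±2.2
  transition message) then yields either mutual suppression deadlock or a
  self-sustained all-firing state.  With spikes strongly informative
  (column ratio 0.75/0.30) and silence weakly informative (0.70/0.25 →
  flat under ζ = 0.5), ensemble silence can delay early firers, a few
  noise spikes can ignite a coherent avalanche, and the stochastic firing
  map collapses after each burst — the regime in which synchronisation,
  desynchronisation and recovery all occur.
* **Plasticity rate** (0.01/period).  Chosen so that in the synchronised
  perturbation run the mean precision grows from 0.5 to ≈ 0.7 over the
  250-step experiment, with per-step ζ increments of order 1e−3.

## Stock experiments

* **Synchrony** (500 steps): free-running network, initial phases spread
  over a full cycle; the coupled condition uses ζ₀ = 0.5, the uncoupled
  one ζ₀ = 0 (precisions switched off).  Plasticity off to keep the
  comparison clean.
* **Perturbation** (250 steps): network starts near-synchronised (phase
  spread 2 steps); two 3-step pulses force every observation of neurons
  0–7 to 1 at steps 50–52 and 75–77; plasticity on.  Reported measures:
  the burst-phase order parameter `R` (baseline = mean over steps 25–50),
  resynchronisation time (first `t` after pulse offset with `R ≥ 0.9 ×`
  baseline sustained for 25 steps ≈ one cycle), the sliding free-energy
  ratio of the post-recovery window (steps 85–115) to baseline, and the
  final mean precision over active synapses.
* **Structure** (1200 steps = 24 epochs): pools {0–7} and {8–15} receive
  sustained antiphase square-wave drive (period 50, half-duty) from the
  start of epoch 3 to the end of epoch 20; plasticity and pruning on.

**Stimulation semantics.**  Pulses are delivered by overwriting the target's
observation vector with 1s (spoofed EPSPs).  The sustained structured input
is instead delivered as an injected current: an additive ±gain/2 push on the
potential during belief updating, alternating depolarising/hyperpolarising
half-cycles, while the real observations stay visible.  The distinction
matters: overwriting observations forces even between-pool synapses to
*agree* with the driven belief during every forced phase, which caps the
between-pool reduction evidence below any useful threshold, so segregation
could never emerge.  Injected drive leaves the between-pool disagreement
(pool A confidently firing while pool B's afferents are silent, and vice
versa) in the data, which is what the pruning statistics consume.  The
injected message is excluded from the recorded free energy, so stimulation
appears as the expected free-energy elevation.

## Metrics

Bursts are detected on the thresholded-belief train (the model's own
definition of having fired), merging spike runs separated by ≤ 2 silent
steps; using the stochastic raster instead would contaminate isolated-neuron
statistics with Bernoulli false positives.  Inter-burst intervals are
onset-to-onset differences in ms.  Synchrony is summarised by `R`: each
neuron's phase interpolates linearly between bracketing burst onsets and
`R = |mean_j exp(i φ_j)|`.  `R` is this package's operationalisation of
raster-level synchrony; the underlying model never references it.

## Numerical choices and degenerate inputs

* Logarithms of probabilities are floored at 1e−16 except for the
  transition message (see above).
* The window definition makes `t_max + t_min` the onset-to-onset interval:
  the burst itself occupies the `t_min` refractory-gap steps after onset.
  `t_max` is therefore drawn from {15..25} so the printed 40–60 ms
  inter-burst range holds under the onset-difference definition used by the
  metrics.
* A neuron whose afferents are all pruned runs on its transition prior
  alone (an autonomous oscillator).
* Pruning evaluations with a non-positive gamma-expectation denominator are
  treated as "not evaluable, retain"; `𝛃_eval` is floored at 0.05.
* Partial trailing plasticity periods / pruning epochs are skipped.
* Dual seeding: one seed stream for structure (windows, phases), one for
  action sampling, each keyed by neuron id, so architecture can be held
  fixed across stochastic replicates and an uncoupled network is
  bit-identical to the matching set of isolated single-neuron runs.

## What the simulations do and do not show

The simulated conditions are idealised: fully connected initial topology,
shared base table, one-step delays, no inhibition, no conduction
heterogeneity, and stimulation modelled as clean observation/current
manipulation.  Passing tests demonstrate that the three phenomena emerge
from free-energy minimisation under these conditions; they do not calibrate
the model against any recorded neural data.  Within-pool precision
saturates at the ceiling in the structure run — an explicit consequence of
clamping rather than modelling homoeostasis.  Emergence is sensitive to the
balance between intrinsic-rhythm precision and total synaptic gain (network
size × ζ); the defaults encode one working point of that balance, and
substantially different network sizes would require re-balancing `ζ₀` or
the base table.
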