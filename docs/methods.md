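# Model and methods

## The model

`ca1sim` simulates a firing-rate network modeled on the hippocampal CA1
circuit and its dopaminergic novelty loop. Its purpose is to study
catastrophic interference: how learning new stimuli degrades the memory of
old ones, and how two biological mechanisms — novelty-gated dopamine and
homeostatic plasticity of lateral inhibition — protect against it.

**Architecture.** An input layer of N pixels (default 40×40 = 1600) projects
all-to-all onto a layer of N pyramidal cells arranged on a square toroidal
map (opposite edges adjacent, so there are no edge effects). A coarser grid
of interneurons (default 13×13 = 169, the ~9:1 CA1 ratio) is embedded
uniformly in the same extent. Pyramidal cells excite each other through a
narrow distance-dependent Gaussian kernel and excite the interneurons the
same way; interneurons inhibit pyramidal cells through a difference-of-
Gaussians ("Mexican hat") kernel that is zero at distance 0 and peaks on a
ring. Every stochastic weight is (kernel value × uniform draw), and each
neuron's converging weight vector is L2-normalized. Input→pyramidal weights
start as normalized uniform noise. Downstream, a subiculum layer copies the
pyramidal layer one-to-one (weight 1) through a high threshold θ⁺; any
subiculum activity drives a single accumbens/pallidum unit, which inhibits
(weight −1) a single dopaminergic VTA unit. Dopamine DA = 1 therefore means
"nothing on the map is familiar".

**Dynamics.** Potentials are leaky integrators advanced by forward Euler
(dt = 1 step, τ = 10 steps; interneurons use 1.5τ):

    τ·Δu = −u + SI + LE + LI + Noise

with SI the afferent drive, LE the lateral excitation, LI the lateral
inhibition (weights stored non-positive so the sum is subtractive) and
Noise = λ·U[0,1)·İ, where İ is the summed absolute per-step change of the
neuron's input synaptic potentials — noise exists only while the input is in
flux. Activations come from the gain f(u) = 0 for u ≤ 0, else
min(1, sinh(u)·h + 0.008). The sinh makes the map's response strongly
expansive: small advantages in drive become large advantages in activation,
which is what lets a winning population separate from the bulk.

**Plasticity.** Two plastic pathways, both multiplied by DA (novelty is a
hard prerequisite for any weight change) and by two gates: LT (postsynaptic
activation strictly above θ⁻) and SA (activation rising relative to its
exponential moving average, window δ₁·τ, by more than δ₂, while the input
synaptic flux is below 0.012 — learning happens only on a stable, still
improving response, never during the onset transient).

* Excitatory (input→pyramidal), an Oja-flavored Hebbian rule:
  Δw = lr·DA·a_post·(a_pre − w). The (a_pre − w) factor makes w converge to
  the stimulus vector and bounds growth without renormalization.
* Inhibitory (interneuron→pyramidal), homeostatic:
  Δw = −(L/τ)·DA·a_post·(a_i + 0.3·w), additionally gated by ELL (mean
  |a_pre − w| over input synapses above 0.004, i.e. the neuron is still
  learning). Equilibrium w* = −a_i/0.3: sustained interneuron activity deepens
  inhibition of winners while they learn, preventing them from dominating
  future stimuli.

A **learning episode** presents one image: the network settles (it is never
reset between images), then dynamics and plasticity iterate until dopamine
switches off (familiar) or a forced-advance budget (300 steps) expires.
Neurons whose input weights change are labeled with the image's task
(last-write-wins; per-task update mass is also kept so a dominant-label map
can be drawn).

## The two protocols

**Catastrophic forgetting.** 10 tasks × 4 images are learned one after
another, each image seen once; then every image is re-presented with
plasticity off and scored by whether the most active neuron carries the
right task label (an unlabeled winner is a miss). With 4 images per task the
per-task score is quantized to {0, 25, 50, 75, 100}%. The run is repeated
over seeded permutations of the task order and reported as mean ± sd per
*learning position*, the axis on which forgetting-over-time is read.

**Lifelong two-corridor learning.** An agent alternates between two
corridors of 20 images, repeating each corridor until a full pass produces
no learning episode (an epoch), then switching. The run ends when two
consecutive epochs need zero episodes. Reported: episodes per epoch, the
per-epoch peak-neuron map, the number of distinct winners over all images,
and how many corridor-1 winners are unchanged when the agent first returns
to it. A presentation counts as a learning episode iff weights changed or
the image never became familiar within the budget; a presentation where
dopamine switches off without a single weight update is recognition, not
learning.

**Lesions.** `no-da` pins DA to 1 (novelty never stops learning; episodes
always run the full budget and epochs are single forced passes); `no-inh`
freezes the inhibitory weights; `both` combines them; `no-learning` pins DA
to 0. These reproduce the evaluation conditions of the catastrophic-
forgetting and lifelong experiments.

## Parameters

The printed constants of the learning rule are kept verbatim: the 0.012
flux ceiling of the SA gate, the 0.004 floor of the ELL gate, the 0.3
equilibrium factor of the inhibitory rule, and the 0.008 offset of the gain.
The remaining constants are tunable configuration; the defaults below were
chosen so the model operates in its intended regime — a novel stimulus
settles well below θ⁺, learning drives its winners across θ⁺ within one or
few episodes, and re-presentation is recognized without further learning.

| parameter | default | meaning |
|---|---|---|
| τ | 10 steps | pyramidal time constant (interneurons 1.5τ) |
| h | 0.13 | sinh gain slope |
| θ⁺ | 0.95 | subiculum familiarity threshold, just below the ceiling of 1 |
| θ⁻ | 0.2 | learning threshold |
| δ₁, δ₂ | 5, 0.005 | SA moving-average window factor and deviation threshold |
| lr | 0.03 | excitatory step scale (absent from the printed rule; needed for Euler stability) |
| L | 1.5 / 10 / 6 | inhibitory constant (default / task-sequence preset / corridor preset) |
| onset/stall replay | 2; 45/3 | input-onset replay steps at episode start; stall interval/burst (off in the task-sequence preset) |
| λ | 1.0 / 0.1 / 1.0 | noise level |
| s1_pp | 1.0 / 0.5 / 1.0 | lateral-excitation kernel decay |
| s1_pi | 0.2 | pyramidal→interneuron kernel decay |
| s1_ip, s2_ip | 0.05–0.1, 0.5 | Mexican-hat decays (s1 < s2 required) |
| t_max | 300 steps | forced-advance episode budget |

Two presets, `cf_protocol_params()` and `lifelong_protocol_params()`,
package the operating points used by the two experiments — the task-sequence
experiment wants narrow excitation and strong homeostatic inhibition so
consecutive tasks carve out separate populations; the corridor experiment
wants shorter-range inhibition and an intermediate L so revisits converge to
a stable novelty-free map. Using different parameter tables per experiment
mirrors how the two image datasets require different brightness/contrast
accommodation.

**Stimulus operating point.** The familiarity detector compares the drive a
stimulus produces through random initial weights (∝ cos between the
stimulus and a dense positive random vector) with the drive through trained
weights (∝ the stimulus norm). The expansive gain makes the usable window
about ±0.4 in potential, so generators and loaders scale every stimulus to
a common L2 norm (`target_norm` = 3.2; values clipped to [0,1]). This
per-image normalization stands in for the luminance adaptation of the eye
and early visual areas, which the model deliberately omits. Dense bright
images are intrinsically near-parallel to the dense random weights
(cos ≈ 0.9) and would be born familiar; stimuli must be sparse-ish
(cos ≈ 0.3–0.5) for novelty detection to operate.

**Onset/stall replay.** When a settled state is still novel, the input
onset is replayed for 2 steps (and again in 3-step bursts if no update
occurs for 45 steps), re-arming the activity-dependent noise. This is an
attention/refixation analogue added by this implementation: without it, a
previously learned population can weakly dominate a new stimulus in a
static state below θ⁺ where nothing rises, and the SA gate never unlocks —
a permanent novelty deadlock. The replay only perturbs states in which
nothing is being learned.

## Synthetic data

The generators are first-class, seeded, pure functions:

* `gen_digit_like` — per class, a random blurred-stroke prototype
  (rejection-sampled so class prototypes stay below cos 0.45 of each
  other); variants apply small shifts/rotations plus pixel noise. This
  reproduces the structure the digit experiments rely on: intra-class
  cosine ≈ 0.8, inter-class ≈ 0.3, and a nearest-prototype baseline
  classifies held-out variants far above chance.
* `gen_corridor` / `gen_corridor_pair` — crops from a long 1/f-noise
  panorama, high-pass filtered (detail-rich, no dominant blob shared
  between distant crops), with per-corridor luminance/contrast; consecutive
  crops overlap, so adjacent images correlate more than distant ones.

What they do not emulate: the visual statistics of real handwriting or
photographs (oriented strokes, objects, perspective), MNIST's class
structure beyond "similar variants of a prototype", and the actual
brightness profile of the photographic corridors. Passing tests therefore
show that the mechanisms (novelty gating, homeostatic protection,
winner-take-all mapping) behave as described on stimuli with the stated
similarity structure — not that the exact published percentages on MNIST or
the photographic corridors are reproduced, which would require those
datasets and the original tuned parameter tables.

## Problem sizes and numerics

Protocol-level tests and the acceptance script run a 20×20 pyramidal map
with 7×7 interneurons and 20×20 stimuli (ratio ≈ 8:1), 10×4 digit-like
tasks with 2–3 task-order permutations, and 8-image corridors; these sizes
preserve every qualitative contrast while keeping runs to seconds or a few
minutes. The full-size 40×40/13×13 network is exercised by construction
and in the structural tests.

Numerical choices: forward Euler with dt = 1; settling stops when the
largest per-step activation change falls below 1e-4 or after 15τ steps
(non-convergence is reported, not raised); sinh argument clipped at 500
(far above any attainable potential, below overflow); peak-neuron ties
break to the lowest row-major index; inhibitory weights are clipped at 0
from above after updates; every random stream is a named child of one
top-level seed (weights and noise are independently reproducible).

## Known limitations

* Absolute recognition percentages on synthetic data (intact ≈ 20–40%
  overall at the scaled size) sit well below the published MNIST figures;
  the lesion contrasts (intact ≫ lesioned on early tasks; distinct and
  stable maps vs. degenerate ones) are the reproduced findings.
* The no-DA lesion makes every episode run its full budget, so lesioned
  runs dominate wall-clock time.
* Map capacity at the scaled size is limited: 10 tasks on 400 neurons leave
  mid-sequence tasks under-represented.
* Dopamine is binary and interneurons are a single generic class, as in the
  modeled circuit; spiking dynamics and graded dopamine are out of scope.
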