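"""Dopamine-gated synaptic plasticity and the per-image learning episode.

Two plastic pathways:

* Excitatory (input -> pyramidal): an Oja-like Hebbian rule
  ``dw = lr * DA * a_post * (a_pre - w)`` applied only where two gates hold —
  LT, the learning threshold (a_post strictly above theta_minus), and SA, the
  stable-activation gate (activation rising relative to its moving average by
  more than delta2 while the input synaptic flux is below 0.012).  The
  (a_pre - w) term makes w converge to the presynaptic pattern and bounds
  growth without renormalization.

* Inhibitory (interneuron -> pyramidal): a homeostatic rule
  ``dw = -(L/tau) * DA * a_post * (a_i + 0.3 * w)`` under the same LT and SA
  gates plus ELL, the excitatory-learning-level gate (mean |a_pre - w_inp|
  above 0.004): inhibition onto a neuron strengthens only while that neuron's
  excitatory weights are still far from the stimulus, i.e. while it is still
  learning.  With weights stored non-positive the equilibrium is
  w* = -a_i/0.3: sustained interneuron activity deepens inhibition of the
  winning neurons, preventing them from dominating future stimuli.

Dopamine multiplies both rules, so novelty (DA = 1) is a hard prerequisite
for any weight change.  A "learning episode" presents one image: the network
settles, then dynamics and plasticity run together until dopamine switches
off (the image has become familiar) or a forced-advance step budget expires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetworkState, network_step, settle
from .geometry import WeightState
from .params import LesionConfig, ModelParams, PlasticityParams

__all__ = [
    "gate_LT",
    "gate_SA",
    "gate_ELL",
    "update_excitatory",
    "update_inhibitory",
    "LearningTrace",
    "EpisodeResult",
    "learn_image",
]


def gate_LT(a_post, theta_minus: float):
    """Learning-threshold gate: postsynaptic activation strictly above
    theta_minus.  Elementwise on arrays."""
    return np.asarray(a_post) > theta_minus


def gate_SA(
    a_post: np.ndarray,
    ema_a: np.ndarray,
    flux: np.ndarray,
    steps: int,
    params: PlasticityParams,
    tau: float,
):
    """Stable-activation gate.

    True where the activation's deviation from its moving average (window
    delta1*tau steps) exceeds delta2 AND the input synaptic flux is below
    sa_flux_max.  With fewer than delta1*tau steps of history the state is
    treated as transient and the gate is closed everywhere.
    """
    if steps < params.delta1 * tau:
        return np.zeros(np.shape(a_post), dtype=bool)
    dev = np.asarray(a_post) - np.asarray(ema_a)
    if params.sa_absolute:
        dev = np.abs(dev)
    return (dev > params.delta2) & (np.asarray(flux) < params.sa_flux_max)


def gate_ELL(w_inp: np.ndarray, a_inp: np.ndarray, ell_min: float = 0.004):
    """Excitatory-learning-level gate: mean |a_pre - w| over the input
    synapses strictly above ell_min.  Accepts one row or a (n_post, n_pre)
    matrix; returns a flag per row."""
    w = np.atleast_2d(w_inp)
    if w.shape[1] != np.shape(a_inp)[0]:
        raise ValueError("weight row length must match the input vector")
    mean_dev = np.abs(a_inp[None, :] - w).mean(axis=1)
    out = mean_dev > ell_min
    return bool(out[0]) if np.ndim(w_inp) == 1 else out


def update_excitatory(
    w_inp: np.ndarray,
    a_inp: np.ndarray,
    a_p: np.ndarray,
    da: int,
    gates: np.ndarray,
    lr_exc: float,
) -> np.ndarray:
    """Delta for the input->pyramidal block; nonzero only on gated rows."""
    delta = np.zeros_like(w_inp)
    if da == 0 or not gates.any():
        return delta
    rows = np.flatnonzero(gates)
    delta[rows] = lr_exc * da * a_p[rows, None] * (a_inp[None, :] - w_inp[rows])
    return delta


def update_inhibitory(
    w_ip: np.ndarray,
    a_i: np.ndarray,
    a_p: np.ndarray,
    da: int,
    gates: np.ndarray,
    L: float,
    tau: float,
) -> np.ndarray:
    """Delta for the interneuron->pyramidal block; nonzero only on gated
    rows.  ``gates`` must already include the ELL factor."""
    delta = np.zeros_like(w_ip)
    if da == 0 or not gates.any():
        return delta
    rows = np.flatnonzero(gates)
    delta[rows] = -(L / tau) * da * a_p[rows, None] * (a_i[None, :] + 0.3 * w_ip[rows])
    return delta


@dataclass
class LearningTrace:
    """Per-neuron labeling bookkeeping for the recognition protocols.

    ``labels[i]`` is the task id of the last image whose learning modified
    neuron i's input weights (-1 = never updated); ``update_mass`` accumulates
    the total |dw| per neuron; ``mass_by_label`` retains the same mass split
    per task id so a dominant-label map can be drawn.  ``episode_log`` is one
    dict per learning episode.
    """

    n_neurons: int
    labels: np.ndarray = field(init=False)
    update_mass: np.ndarray = field(init=False)
    mass_by_label: dict = field(default_factory=dict)
    episode_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.full(self.n_neurons, -1, dtype=int)
        self.update_mass = np.zeros(self.n_neurons)

    def record_update(self, rows: np.ndarray, mass: np.ndarray, task_id: int) -> None:
        self.labels[rows] = task_id
        self.update_mass[rows] += mass
        per_label = self.mass_by_label.setdefault(task_id, np.zeros(self.n_neurons))
        per_label[rows] += mass

    def write_episode_log(self, path) -> None:
        """Append the episode log as JSON lines (one object per episode)."""
        import json
        from pathlib import Path

        with Path(path).open("a") as fh:
            for entry in self.episode_log:
                fh.write(json.dumps(entry) + "\n")

    def dominant_labels(self) -> np.ndarray:
        """Label per neuron by the task with the largest cumulative update
        mass (-1 where the neuron never learned)."""
        if not self.mass_by_label:
            return np.full(self.n_neurons, -1, dtype=int)
        tasks = sorted(self.mass_by_label)
        stack = np.stack([self.mass_by_label[t] for t in tasks])
        out = np.array(tasks, dtype=int)[np.argmax(stack, axis=0)]
        out[stack.sum(axis=0) == 0] = -1
        return out


@dataclass(frozen=True)
class EpisodeResult:
    """One learning episode: whether the image ended familiar (DA = 0),
    the steps spent, which neurons were updated, and whether the
    presentation engaged learning at all (``da_at_presentation`` is 0 only
    for an image recognized without a single weight update)."""

    learned: bool
    steps: int
    updated_neurons: np.ndarray
    da_at_presentation: int
    da_end: int

    @property
    def n_updated(self) -> int:
        return int(self.updated_neurons.size)

    @property
    def is_learning_episode(self) -> bool:
        """An episode counts if any weights changed, or the image never
        became familiar (forced advance with dopamine still on).  A
        presentation where dopamine switches off without a single weight
        update is recognition, not learning."""
        return self.n_updated > 0 or self.da_end == 1


def _effective_da(da: int, lesions: LesionConfig) -> int:
    if lesions.no_learning:
        return 0
    if lesions.no_da_modulation:
        return 1
    return da


def learn_image(
    state: NetworkState,
    weights: WeightState,
    stimulus: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    trace: LearningTrace | None = None,
    *,
    task_id: int = 0,
    image_id: str = "",
    lesions: LesionConfig = LesionConfig(),
) -> EpisodeResult:
    """Present one image with plasticity on.

    The network first settles on the stimulus (no reset), then dynamics and
    plasticity iterate until dopamine switches off (the image has become
    familiar) or the ``t_max_episode`` forced-advance budget expires.  If the
    settled state is still novel, the input-onset transient is replayed once
    so the activity-dependent noise can perturb the landscape — without it a
    previously learned population can weakly dominate the new stimulus in a
    static state that the rising-activation gate would never unlock.

    Every neuron whose input weights receive a nonzero update is labeled
    with ``task_id`` (last-write-wins).  Under the no-DA-modulation lesion
    dopamine never switches off and the episode always runs the full budget;
    under no-learning dopamine is pinned to 0 and no weights change.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    pl = params.plasticity
    dyn = params.dynamics
    tau = dyn.tau

    report = settle(state, weights, stimulus, params, rng)
    da_presentation = _effective_da(report.da, lesions)

    updated = np.zeros(weights.w_inp.shape[0], dtype=bool)
    steps = 0
    da_eff = da_presentation
    stalled_steps = 0
    burst_remaining = pl.onset_replay_steps
    while da_eff == 1 and steps < pl.t_max_episode:
        if burst_remaining > 0 and state.syn_pot_prev is not None:
            # replay the input onset so the activity-dependent noise
            # perturbs the landscape: a short kick at episode start, and a
            # burst whenever a still-novel state has been static for a
            # while — without this a previously learned population can
            # weakly dominate the new stimulus in a frozen state that the
            # rising-activation gate would never unlock
            state.syn_pot_prev = np.zeros_like(state.syn_pot_prev)
            burst_remaining -= 1
        network_step(state, weights, stimulus, params, rng)
        steps += 1
        da_eff = _effective_da(state.da, lesions)
        if da_eff == 0:
            break
        lt = gate_LT(state.a_p, pl.theta_minus)
        sa = gate_SA(state.a_p, state.ema_a, state.flux, state.steps, pl, tau)
        gates = lt & sa
        did_update = False
        if gates.any():
            d_exc = update_excitatory(
                weights.w_inp, stimulus, state.a_p, da_eff, gates, pl.lr_exc
            )
            rows = np.flatnonzero(np.abs(d_exc).sum(axis=1) > 0)
            if rows.size:
                weights.w_inp += d_exc
                weights.version += 1
                updated[rows] = True
                did_update = True
                if trace is not None:
                    trace.record_update(rows, np.abs(d_exc[rows]).sum(axis=1), task_id)
            if not lesions.no_inhibitory_plasticity:
                ell = gate_ELL(weights.w_inp, stimulus, pl.ell_min)
                d_inh = update_inhibitory(
                    weights.w_ip, state.a_i, state.a_p, da_eff, gates & ell, pl.L, tau
                )
                if np.any(d_inh):
                    np.minimum(weights.w_ip + d_inh, 0.0, out=weights.w_ip)
                    weights.version += 1
                    did_update = True
        stalled_steps = 0 if did_update else stalled_steps + 1
        if stalled_steps >= pl.stall_replay_interval > 0:
            burst_remaining = max(burst_remaining, pl.stall_replay_burst)
            stalled_steps = 0

    updated_idx = np.flatnonzero(updated)
    result = EpisodeResult(
        learned=(da_eff == 0),
        steps=steps,
        updated_neurons=updated_idx,
        da_at_presentation=da_presentation,
        da_end=da_eff,
    )
    if trace is not None:
        trace.episode_log.append(
            {
                "image_id": image_id,
                "task_id": task_id,
                "steps": steps,
                "n_updated": result.n_updated,
                "da_end": da_eff,
                "lesions": {
                    "no_da_modulation": lesions.no_da_modulation,
                    "no_inhibitory_plasticity": lesions.no_inhibitory_plasticity,
                    "no_learning": lesions.no_learning,
                },
            }
        )
    return result
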