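"""Rate dynamics of the CA1 network and the novelty-detection circuit.

Pyramidal cells and interneurons are leaky integrators advanced by forward
Euler.  A pyramidal cell's potential u integrates sensory input (SI),
lateral excitation (LE), lateral inhibition (LI, weights stored negative)
and an activity-dependent noise term:

    tau * du = -u + SI + LE + LI + Noise

Interneurons integrate the pyramidal drive with time constant 1.5*tau.
Activations come from a sinh gain, zero for non-positive potentials and
clamped at 1.  The noise is lambda * U[0,1) * flux, where flux is the sum of
absolute per-step changes of a neuron's input synaptic potentials (w * a per
input synapse), so noise fires on input transients and dies out once the
input signal stabilizes.

Novelty is read out by a three-stage circuit: the subiculum thresholds the
pyramidal activations (binary, threshold theta_plus); a single
accumbens/pallidum unit fires if any subiculum neuron fires; the VTA dopamine
unit fires exactly when the accumbens/pallidum unit is silent.  Dopamine = 1
therefore means "nothing is familiar yet": novelty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import WeightState
from .params import DynamicsParams, ModelParams

__all__ = [
    "gain",
    "NetworkState",
    "compute_flux",
    "step_pyramidal",
    "step_interneuron",
    "novelty_circuit",
    "settle",
    "SettleReport",
]

# sinh argument clip; well below overflow, far above any clamped activation
_SINH_CLIP = 500.0


def gain(x, h: float):
    """Neuronal gain: 0 for x <= 0, else min(1, sinh(x)*h + 0.008).

    Works elementwise on arrays; returns a scalar for scalar input.
    """
    x = np.asarray(x, dtype=float)
    pos = np.minimum(1.0, np.sinh(np.minimum(x, _SINH_CLIP)) * h + 0.008)
    out = np.where(x <= 0, 0.0, pos)
    return float(out) if out.ndim == 0 else out


@dataclass
class NetworkState:
    """Mutable simulation state.

    Potentials/activations of the pyramidal (u_p, a_p) and interneuron
    (u_i, a_i) layers; binary subiculum (a_s) and accumbens/pallidum (a_ap)
    outputs; the dopamine flag; the previous-step input synaptic-potential
    matrix (for the flux), the per-neuron flux itself; the exponential moving
    average of pyramidal activation (for the stable-activation gate); and the
    global step counter.  All potentials start at zero.
    """

    u_p: np.ndarray
    a_p: np.ndarray
    u_i: np.ndarray
    a_i: np.ndarray
    a_s: np.ndarray
    a_ap: int = 0
    da: int = 1
    syn_pot_prev: np.ndarray | None = None
    flux: np.ndarray = field(default=None)  # type: ignore[assignment]
    ema_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    steps: int = 0

    @classmethod
    def zeros(cls, params: ModelParams) -> "NetworkState":
        n_p = params.geometry.n_pyramidal
        n_i = params.geometry.n_interneuron
        return cls(
            u_p=np.zeros(n_p),
            a_p=np.zeros(n_p),
            u_i=np.zeros(n_i),
            a_i=np.zeros(n_i),
            a_s=np.zeros(n_p, dtype=np.int8),
            flux=np.zeros(n_p),
            ema_a=np.zeros(n_p),
        )


def compute_flux(syn_pot_now: np.ndarray, syn_pot_prev: np.ndarray) -> np.ndarray:
    """Per-neuron sum of |per-step change| of the input synaptic potentials.

    Both arguments are (n_post, n_pre) matrices of w * a values.
    """
    if syn_pot_now.shape != syn_pot_prev.shape:
        raise ValueError("synaptic-potential matrices must have equal shapes")
    return np.abs(syn_pot_now - syn_pot_prev).sum(axis=1)


def step_pyramidal(
    state: NetworkState,
    weights: WeightState,
    input_act: np.ndarray,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> NetworkState:
    """One Euler step of the pyramidal layer (in place; returns state).

    Uses the interneuron activations from the current state (synchronous
    update at the caller's level).  Also refreshes the flux and the moving
    average of activation.
    """
    input_act = np.asarray(input_act, dtype=float)
    if input_act.shape[0] != weights.w_inp.shape[1]:
        raise ValueError(
            f"stimulus length {input_act.shape[0]} != input layer size {weights.w_inp.shape[1]}"
        )
    syn_pot = weights.w_inp * input_act[None, :]
    if state.syn_pot_prev is None or state.syn_pot_prev.shape != syn_pot.shape:
        state.flux = np.zeros(syn_pot.shape[0])
    else:
        state.flux = compute_flux(syn_pot, state.syn_pot_prev)
    state.syn_pot_prev = syn_pot

    si = syn_pot.sum(axis=1)  # = w_inp @ input_act
    le = weights.w_pp @ state.a_p
    li = weights.w_ip @ state.a_i  # w_ip <= 0: inhibitory
    if params.lambda_noise > 0.0:
        noise = params.lambda_noise * rng.random(si.shape[0]) * state.flux
    else:
        noise = 0.0
    state.u_p = state.u_p + (params.dt / params.tau) * (-state.u_p + si + le + li + noise)
    state.a_p = gain(state.u_p, params.h)
    # moving average with effective window delta1*tau is updated by the
    # caller that knows the plasticity params; dynamics only counts steps
    state.steps += 1
    return state


def step_interneuron(
    state: NetworkState, weights: WeightState, params: DynamicsParams
) -> NetworkState:
    """One Euler step of the interneuron layer, time constant 1.5*tau."""
    drive = weights.w_pi @ state.a_p
    state.u_i = state.u_i + (params.dt / (1.5 * params.tau)) * (-state.u_i + drive)
    state.a_i = gain(state.u_i, params.h)
    return state


def novelty_circuit(a_p: np.ndarray, theta_plus: float) -> tuple[np.ndarray, int, int]:
    """Subiculum -> accumbens/pallidum -> VTA chain.

    Returns (a_s, a_ap, da): a_s[i] = 1 iff a_p[i] >= theta_plus; a_ap = 1
    iff any subiculum unit fires; da = 1 iff a_ap = 0.  Dopamine is thus a
    pure function of the pyramidal activation vector.
    """
    a_s = (np.asarray(a_p) >= theta_plus).astype(np.int8)
    a_ap = int(a_s.any())
    da = 1 - a_ap
    return a_s, a_ap, da


@dataclass(frozen=True)
class SettleReport:
    """Outcome of settling on a stimulus."""

    peak_neuron: int
    peak_activation: float
    da: int
    steps: int
    converged: bool

    def to_json(self) -> dict:
        return {
            "peak_neuron": self.peak_neuron,
            "peak_activation": self.peak_activation,
            "da": self.da,
            "steps": self.steps,
            "converged": self.converged,
        }


def _ema_update(state: NetworkState, window: float) -> None:
    alpha = 1.0 / max(window, 1.0)
    state.ema_a += alpha * (state.a_p - state.ema_a)


def network_step(
    state: NetworkState,
    weights: WeightState,
    stimulus: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> NetworkState:
    """One synchronous step of the full network: pyramidal and interneuron
    layers advance from the same pre-step activations, then the novelty
    circuit reads out the new pyramidal activations."""
    a_p_old = state.a_p
    step_pyramidal(state, weights, stimulus, params.dynamics, rng)  # reads old a_i
    a_p_new = state.a_p
    state.a_p = a_p_old
    step_interneuron(state, weights, params.dynamics)  # reads old a_p
    state.a_p = a_p_new
    _ema_update(state, params.plasticity.delta1 * params.dynamics.tau)
    state.a_s, state.a_ap, state.da = novelty_circuit(state.a_p, params.dynamics.theta_plus)
    return state


def settle(
    state: NetworkState,
    weights: WeightState,
    stimulus: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    trace: list | None = None,
) -> SettleReport:
    """Run the dynamics on a stimulus until the pyramidal activations stop
    changing (max per-step change below settle_eps) or the step budget runs
    out.  The network state is NOT reset beforehand: settling always starts
    from whatever the previous stimulus left behind.

    Ties for the peak neuron break to the lowest row-major index.
    Optionally appends (step, peak activation, da) tuples to ``trace``.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    dyn = params.dynamics
    converged = False
    steps = 0
    for _ in range(dyn.t_settle_max):
        prev = state.a_p.copy()
        network_step(state, weights, stimulus, params, rng)
        steps += 1
        if trace is not None:
            trace.append((state.steps, float(state.a_p.max()), state.da))
        if np.max(np.abs(state.a_p - prev)) < dyn.settle_eps:
            converged = True
            break
    peak = int(np.argmax(state.a_p))
    return SettleReport(
        peak_neuron=peak,
        peak_activation=float(state.a_p[peak]),
        da=state.da,
        steps=steps,
        converged=converged,
    )
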