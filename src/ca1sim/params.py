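"""Model parameter records.

All scalar constants of the network live here, grouped the way the model is
built: layer geometry, connectivity kernels, rate dynamics, and plasticity.
Every record validates its invariants on construction and round-trips through
plain dicts (and hence YAML/JSON), so a simulation is reproducible from its
config file alone.

The gate constants 0.012 (synaptic-flux ceiling for the stable-activation
gate) and 0.004 (floor of the excitatory-learning-level gate) are part of the
learning rule itself; everything else is tunable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "GeometryParams",
    "KernelParams",
    "DynamicsParams",
    "PlasticityParams",
    "LesionConfig",
    "ModelParams",
]


@dataclass(frozen=True)
class GeometryParams:
    """Layer sizes. Pyramidal cells sit on a square toroidal grid; the
    interneuron grid is embedded uniformly in the same extent.

    Defaults give 1600 pyramidal cells and 169 interneurons, the ~9:1
    pyramidal:interneuron ratio of CA1, with a 40x40 input layer matching
    the stimulus resolution.
    """

    p_rows: int = 40
    p_cols: int = 40
    i_rows: int = 13
    i_cols: int = 13
    input_rows: int = 40
    input_cols: int = 40

    def __post_init__(self) -> None:
        for name in ("p_rows", "p_cols", "i_rows", "i_cols", "input_rows", "input_cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_pyramidal(self) -> int:
        return self.p_rows * self.p_cols

    @property
    def n_interneuron(self) -> int:
        return self.i_rows * self.i_cols

    @property
    def n_input(self) -> int:
        return self.input_rows * self.input_cols


@dataclass(frozen=True)
class KernelParams:
    """Decay constants of the distance-dependent connectivity kernels.

    Lateral excitation (pyramidal->pyramidal) and the pyramidal->interneuron
    projection use a narrow Gaussian ``exp(-d^2 * s1)``.  Interneuron->
    pyramidal inhibition uses a difference of Gaussians
    ``0.5 * (exp(-d^2 * s1_ip) - exp(-d^2 * s2_ip))`` which is zero at
    distance 0 and peaks on a ring: the "large Mexican hat".  That requires
    ``s1_ip < s2_ip``.
    """

    s1_pp: float = 1.0
    s1_pi: float = 0.2
    s1_ip: float = 0.05
    s2_ip: float = 0.5

    def __post_init__(self) -> None:
        for name in ("s1_pp", "s1_pi", "s1_ip", "s2_ip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s1_ip >= self.s2_ip:
            raise ValueError(
                "s1_ip must be < s2_ip for a non-negative Mexican-hat kernel"
            )


@dataclass(frozen=True)
class DynamicsParams:
    """Rate-dynamics constants.

    tau is the pyramidal membrane time constant in integration steps
    (interneurons use 1.5*tau); h is the slope of the sinh gain; lambda_noise
    scales the activity-dependent noise (noise is proportional to the flux of
    the input synaptic potentials, so it vanishes once the input stabilizes);
    theta_plus is the subiculum familiarity threshold, a little below the
    activation ceiling of 1.
    """

    tau: float = 10.0
    dt: float = 1.0
    h: float = 0.13
    lambda_noise: float = 1.0
    theta_plus: float = 0.95
    settle_eps: float = 1e-4
    t_settle_max: int = 150

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 < self.theta_plus <= 1:
            raise ValueError("theta_plus must be in (0, 1]")
        if self.settle_eps <= 0:
            raise ValueError("settle_eps must be > 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.lambda_noise < 0:
            raise ValueError("lambda_noise must be >= 0")
        if self.t_settle_max < 1:
            raise ValueError("t_settle_max must be >= 1")


@dataclass(frozen=True)
class LesionConfig:
    """Switches reproducing the lesion conditions of the experiments.

    no_da_modulation pins dopamine to 1 (novelty never shuts learning off, so
    episodes run their full time budget); no_inhibitory_plasticity freezes the
    interneuron->pyramidal weights; no_learning pins dopamine to 0 (no
    plasticity at all).
    """

    no_da_modulation: bool = False
    no_inhibitory_plasticity: bool = False
    no_learning: bool = False

    def __post_init__(self) -> None:
        if self.no_learning and self.no_da_modulation:
            raise ValueError("no_learning (DA=0) contradicts no_da_modulation (DA=1)")

    @staticmethod
    def named(name: str) -> "LesionConfig":
        """Look up one of the canonical conditions by name:
        ``none``, ``no-da``, ``no-inh``, ``both``, ``no-learning``."""
        table = {
            "none": LesionConfig(),
            "no-da": LesionConfig(no_da_modulation=True),
            "no-inh": LesionConfig(no_inhibitory_plasticity=True),
            "both": LesionConfig(no_da_modulation=True, no_inhibitory_plasticity=True),
            "no-learning": LesionConfig(no_learning=True),
        }
        try:
            return table[name]
        except KeyError:
            raise ValueError(f"unknown lesion condition {name!r}; one of {sorted(table)}") from None


@dataclass(frozen=True)
class PlasticityParams:
    """Learning-rule constants.

    theta_minus: learning threshold on the postsynaptic activation (strict >).
    delta1: moving-average window factor; the stable-activation gate compares
        the activation's deviation from an exponential moving average with
        effective window delta1*tau steps against delta2.
    sa_flux_max = 0.012 and ell_min = 0.004 are the hand-tuned gate constants
        of the learning rule and should not normally be changed.
    lr_exc: overall step scale of the excitatory update (the Oja-like term
        bounds growth; the scale sets the Euler step).
    L: inhibitory learning constant; the inhibitory step is L/tau.
    t_max_episode: forced-advance budget, in steps, for one learning episode.
    onset_replay_steps: number of steps at the start of a still-novel episode
        during which the input onset is replayed, re-arming the
        activity-dependent noise (an attention analogue; 0 disables).
    stall_replay_interval / stall_replay_burst: if a still-novel episode
        produces no weight update for ``stall_replay_interval`` steps, the
        input onset is replayed for ``stall_replay_burst`` steps — a renewed
        fixation that perturbs a frozen map out of a dominated state
        (interval 0 disables).
    sa_absolute: use |deviation| instead of signed deviation in the
        stable-activation gate (alternate reading of the rule).
    """

    theta_minus: float = 0.2
    delta1: float = 5.0
    delta2: float = 0.005
    L: float = 1.5
    sa_flux_max: float = 0.012
    ell_min: float = 0.004
    lr_exc: float = 0.03
    t_max_episode: int = 300
    onset_replay_steps: int = 2
    stall_replay_interval: int = 45
    stall_replay_burst: int = 3
    sa_absolute: bool = False

    def __post_init__(self) -> None:
        for name in ("theta_minus", "delta1", "delta2", "L", "sa_flux_max", "ell_min", "lr_exc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_max_episode < 1:
            raise ValueError("t_max_episode must be >= 1")
        if self.onset_replay_steps < 0:
            raise ValueError("onset_replay_steps must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Everything needed to build and run the network, in one record."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {"geometry", "kernel", "dynamics", "plasticity"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            geometry=GeometryParams(**d.get("geometry", {})),
            kernel=KernelParams(**d.get("kernel", {})),
            dynamics=DynamicsParams(**d.get("dynamics", {})),
            plasticity=PlasticityParams(**d.get("plasticity", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def cf_protocol_params(geometry: GeometryParams | None = None) -> ModelParams:
    """Parameter set tuned for the task-sequence (catastrophic-forgetting)
    experiment: narrow lateral excitation with a strong homeostatic
    inhibitory constant, so consecutive tasks carve out separate
    populations.  The two experiments use different operating points, just
    as the two image datasets require different brightness/contrast
    accommodation.
    """
    return ModelParams(
        geometry=geometry or GeometryParams(),
        kernel=KernelParams(s1_pp=0.5, s1_pi=0.2, s1_ip=0.05, s2_ip=0.5),
        dynamics=DynamicsParams(h=0.13, lambda_noise=0.1),
        plasticity=PlasticityParams(theta_minus=0.2, L=10.0, lr_exc=0.03,
                                    delta2=0.005, stall_replay_interval=0),
    )


def lifelong_protocol_params(geometry: GeometryParams | None = None) -> ModelParams:
    """Parameter set tuned for the two-corridor lifelong experiment:
    shorter-range inhibition and a weak inhibitory constant, so repeated
    revisits converge to a stable novelty-free map, plus a stronger
    activity-dependent noise that lets dominated stimuli claim their own
    population.
    """
    return ModelParams(
        geometry=geometry or GeometryParams(),
        kernel=KernelParams(s1_pp=1.0, s1_pi=0.2, s1_ip=0.1, s2_ip=0.5),
        dynamics=DynamicsParams(h=0.13, lambda_noise=1.0),
        plasticity=PlasticityParams(theta_minus=0.2, L=6.0, lr_exc=0.03,
                                    delta2=0.005, onset_replay_steps=2,
                                    stall_replay_interval=45,
                                    stall_replay_burst=3),
    )


def scaled_params(side: int = 20, i_side: int = 7, **overrides) -> ModelParams:
    """A smaller network (side x side pyramidal grid, i_side x i_side
    interneurons, matching input resolution) for quick experiments.  The
    ratio i_side ~ side/3 keeps the pyramidal:interneuron ratio near 9:1.
    """
    geom = GeometryParams(
        p_rows=side, p_cols=side, i_rows=i_side, i_cols=i_side,
        input_rows=side, input_cols=side,
    )
    return ModelParams(geometry=geom, **overrides)
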