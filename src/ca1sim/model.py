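"""High-level facade bundling weights, state, trace and random streams."""

from __future__ import annotations

import numpy as np

from .dynamics import NetworkState, SettleReport, settle
from .geometry import WeightState, seed_streams
from .params import LesionConfig, ModelParams
from .plasticity import EpisodeResult, LearningTrace, learn_image

__all__ = ["CA1Model"]


class CA1Model:
    """A ready-to-run CA1 network.

    Builds all weight blocks from ``params`` and a top-level seed (one named
    random sub-stream per block, plus one for the dynamics noise), starts
    from zero potentials, and keeps the labeling trace used by the
    recognition protocols.  The network state is carried over between
    stimuli — it is never reset.
    """

    def __init__(self, params: ModelParams, seed: int = 0):
        self.params = params
        self.seed = int(seed)
        self.weights = WeightState.build(params, seed)
        self.state = NetworkState.zeros(params)
        self.trace = LearningTrace(params.geometry.n_pyramidal)
        self.rng = seed_streams(seed, ("noise",))["noise"]

    def settle(self, stimulus: np.ndarray) -> SettleReport:
        """Present a stimulus with plasticity off and let the network settle."""
        return settle(self.state, self.weights, stimulus, self.params, self.rng)

    def learn(
        self,
        stimulus: np.ndarray,
        task_id: int = 0,
        image_id: str = "",
        lesions: LesionConfig = LesionConfig(),
    ) -> EpisodeResult:
        """Run one learning episode on a stimulus."""
        return learn_image(
            self.state,
            self.weights,
            stimulus,
            self.params,
            self.rng,
            self.trace,
            task_id=task_id,
            image_id=image_id,
            lesions=lesions,
        )

    @property
    def peak_neuron(self) -> int:
        """Index of the currently most active pyramidal neuron (row-major,
        ties break to the lowest index)."""
        return int(np.argmax(self.state.a_p))
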