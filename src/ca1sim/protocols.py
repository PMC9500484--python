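"""The two continual-learning experiments and their metrics.

Catastrophic forgetting: the model learns 10 tasks of 4 images, each image
seen once, then all images are re-presented with plasticity off.  An image is
recognized if the most active neuron was labeled, during learning, with the
image's task.  With 4 images per task the per-task recognition is quantized
to {0, 25, 50, 75, 100}%.  The run is repeated over seeded permutations of
the task order and reported as mean +/- sd per task identity.

Lifelong learning: an agent alternates between two corridors of 20 images,
repeating each corridor until a full pass produces no novelty signal; each
corridor phase is an epoch, each plasticity-active image presentation a
learning episode.  The experiment ends when two consecutive epochs need zero
episodes.  Reported are episodes per epoch, the per-epoch peak-neuron map,
the number of distinct winners over all images, and the stability of corridor
1's winners between its first epoch and its first revisit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CA1Model
from .params import LesionConfig, ModelParams
from .plasticity import LearningTrace
from .stimuli import StimulusSet

__all__ = [
    "CFResult",
    "LifelongResult",
    "classify",
    "run_catastrophic_forgetting",
    "run_lifelong",
    "distinct_peak_count",
    "peak_stability",
]


def classify(peak_neuron: int, trace: LearningTrace, true_task: int) -> bool:
    """Recognition rule: the most active neuron must have been labeled,
    during learning, with the image's task.  An unlabeled winner counts as a
    misclassification."""
    label = int(trace.labels[peak_neuron])
    return label == int(true_task)


@dataclass
class CFResult:
    """Catastrophic-forgetting outcome over permutation runs.

    ``runs`` is (n_permutations, n_tasks) of per-task recognition
    percentages, indexed by learning position: column 0 is the task learned
    first in that permutation, column 9 the task learned last — the axis on
    which forgetting-over-time is read.  ``permutation_orders[r][pos]`` gives
    the task identity learned at each position of run ``r``.
    """

    runs: np.ndarray
    generalization_runs: np.ndarray | None = None
    permutation_orders: list = field(default_factory=list)

    @property
    def per_task_mean(self) -> np.ndarray:
        return self.runs.mean(axis=0)

    @property
    def per_task_sd(self) -> np.ndarray:
        return self.runs.std(axis=0)

    @property
    def generalization_mean(self) -> np.ndarray | None:
        if self.generalization_runs is None:
            return None
        return self.generalization_runs.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "learning_position": np.arange(1, self.runs.shape[1] + 1),
                "mean_recognition_pct": self.per_task_mean,
                "sd_recognition_pct": self.per_task_sd,
            }
        )
        if self.generalization_runs is not None:
            df["generalization_mean_pct"] = self.generalization_mean
            df["generalization_sd_pct"] = self.generalization_runs.std(axis=0)
        return df

    def save(self, out_dir: str | Path, name: str = "cf_result") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / f"{name}.csv", index=False)
        payload = {
            "runs": self.runs.tolist(),
            "permutation_orders": [list(map(int, p)) for p in self.permutation_orders],
        }
        if self.generalization_runs is not None:
            payload["generalization_runs"] = self.generalization_runs.tolist()
        (out_dir / f"{name}.json").write_text(json.dumps(payload, indent=2))


def _score_tasks(model: CA1Model, task_order, tasks) -> np.ndarray:
    """Present every image of every task, in the learning order, with
    plasticity off; return per-task recognition percentages indexed by
    learning position (position 0 = first-learned task)."""
    n_tasks = len(task_order)
    correct = np.zeros(n_tasks)
    counts = np.zeros(n_tasks)
    before = model.weights.checksum()
    for pos, t in enumerate(task_order):
        for stim in tasks[t]:
            report = model.settle(stim.values)
            correct[pos] += classify(report.peak_neuron, model.trace, t)
            counts[pos] += 1
    after = model.weights.checksum()
    if before != after:
        raise RuntimeError("plasticity was not off during the test phase")
    return 100.0 * correct / np.maximum(counts, 1)


def run_catastrophic_forgetting(
    params: ModelParams,
    train_set: StimulusSet,
    test_set: StimulusSet | None = None,
    permutations: int = 10,
    lesions: LesionConfig = LesionConfig(),
    seed: int = 0,
) -> CFResult:
    """Run the catastrophic-forgetting protocol.

    For each permutation a fresh model (weights reseeded from ``seed``)
    learns every task's images once, tasks in a permuted order, then all
    images are re-presented with plasticity off and scored.  If ``test_set``
    is given, held-out images are scored the same way (generalization).
    """
    tasks = train_set.tasks
    if any(len(t) == 0 for t in tasks):
        raise ValueError("every task needs at least one image")
    n_tasks = len(tasks)
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    model_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(permutations + 1)[1:]]

    runs = np.zeros((permutations, n_tasks))
    gen_runs = np.zeros((permutations, n_tasks)) if test_set is not None else None
    orders = []
    for r in range(permutations):
        order = order_rng.permutation(n_tasks)
        orders.append(order)
        model = CA1Model(params, seed=model_seeds[r])
        for t in order:
            for stim in tasks[t]:
                model.learn(stim.values, task_id=t, image_id=stim.id, lesions=lesions)
        runs[r] = _score_tasks(model, order, tasks)
        if test_set is not None:
            gen_runs[r] = _score_tasks(model, order, test_set.tasks)
    return CFResult(runs=runs, generalization_runs=gen_runs, permutation_orders=orders)


@dataclass
class LifelongResult:
    """Lifelong two-corridor outcome."""

    episodes_per_epoch: list
    corridor_per_epoch: list
    peak_maps: list  # one {image_id: peak_neuron} per epoch (epoch's corridor)
    terminal_novelty_free: bool
    final_peaks: dict  # last recorded peak for every image of both corridors

    @property
    def epochs_total(self) -> int:
        return len(self.episodes_per_epoch)

    @property
    def distinct_peaks(self) -> int:
        return distinct_peak_count(self.final_peaks)

    def stability_count(self) -> int | None:
        """Images of corridor 1 whose peak is unchanged between its first
        epoch and its first revisit (None if never revisited)."""
        first = revisit = None
        for e, c in enumerate(self.corridor_per_epoch):
            if c == 0 and first is None:
                first = e
            elif c == 0 and first is not None:
                revisit = e
                break
        if first is None or revisit is None:
            return None
        return peak_stability(self.peak_maps[first], self.peak_maps[revisit])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_total + 1),
                "corridor": self.corridor_per_epoch,
                "learning_episodes": self.episodes_per_epoch,
            }
        )

    def save(self, out_dir: str | Path, name: str = "lifelong_result") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / f"{name}.csv", index=False)
        payload = {
            "episodes_per_epoch": self.episodes_per_epoch,
            "corridor_per_epoch": self.corridor_per_epoch,
            "terminal_novelty_free": self.terminal_novelty_free,
            "distinct_peaks": self.distinct_peaks,
            "stability_count": self.stability_count(),
            "peak_maps": self.peak_maps,
        }
        (out_dir / f"{name}.json").write_text(json.dumps(payload, indent=2))

    def peak_table(self, geometry_cols: int) -> pd.DataFrame:
        """Final peak positions as (image_id, row, col) coordinates."""
        rows = []
        for image_id, peak in self.final_peaks.items():
            r, c = divmod(int(peak), geometry_cols)
            rows.append({"image_id": image_id, "row": r, "col": c})
        return pd.DataFrame(rows)


def distinct_peak_count(peak_map: dict) -> int:
    """Number of distinct winner neurons over a peak map."""
    return len(set(peak_map.values()))


def peak_stability(map_a: dict, map_b: dict) -> int:
    """Count of images whose winner neuron is identical in both maps."""
    if set(map_a) != set(map_b):
        raise ValueError("peak maps cover different image ids")
    return sum(map_a[k] == map_b[k] for k in map_a)


def run_lifelong(
    params: ModelParams,
    corridor_a,
    corridor_b,
    lesions: LesionConfig = LesionConfig(),
    max_epochs: int = 20,
    max_passes_per_epoch: int = 10,
    seed: int = 0,
    model: CA1Model | None = None,
) -> LifelongResult:
    """Run the lifelong two-corridor protocol.

    The current corridor is traversed repeatedly; an epoch ends when a full
    pass needs no learning episode (no novelty anywhere), then the agent
    switches corridor.  Under the no-DA-modulation lesion novelty never
    ceases, so an epoch is a single forced pass.  The experiment ends when
    two consecutive epochs have zero episodes, or at ``max_epochs``.
    """
    corridors = [list(corridor_a), list(corridor_b)]
    if not corridors[0] or not corridors[1]:
        raise ValueError("both corridors must be non-empty")
    if model is None:
        model = CA1Model(params, seed=seed)

    episodes_per_epoch: list[int] = []
    corridor_per_epoch: list[int] = []
    peak_maps: list[dict] = []
    final_peaks: dict = {}

    current = 0
    for _ in range(max_epochs):
        corridor = corridors[current]
        episodes = 0
        passes = 0
        peak_map: dict = {}
        while True:
            passes += 1
            pass_episodes = 0
            for stim in corridor:
                result = model.learn(stim.values, task_id=current, image_id=stim.id,
                                     lesions=lesions)
                pass_episodes += int(result.is_learning_episode)
                peak_map[stim.id] = model.peak_neuron
            episodes += pass_episodes
            if pass_episodes == 0 or lesions.no_da_modulation or passes >= max_passes_per_epoch:
                break
        episodes_per_epoch.append(episodes)
        corridor_per_epoch.append(current)
        peak_maps.append(peak_map)
        final_peaks.update(peak_map)
        if len(episodes_per_epoch) >= 2 and episodes_per_epoch[-1] == 0 and episodes_per_epoch[-2] == 0:
            break
        current = 1 - current

    terminal = (
        len(episodes_per_epoch) >= 2
        and episodes_per_epoch[-1] == 0
        and episodes_per_epoch[-2] == 0
    )
    return LifelongResult(
        episodes_per_epoch=episodes_per_epoch,
        corridor_per_epoch=corridor_per_epoch,
        peak_maps=peak_maps,
        terminal_novelty_free=terminal,
        final_peaks=final_peaks,
    )
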