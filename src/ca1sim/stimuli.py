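"""Stimulus loading, preprocessing and synthetic generation.

The network sees 40x40 grayscale images flattened to 1600 input activations
in [0, 1].  Real inputs come from MNIST IDX files or a directory of
PNG/JPEG photographs; synthetic stand-ins for both are generated here so
every experiment runs without downloads:

* digit-like sets: per class, a random stroke prototype; variants are small
  affine perturbations plus pixel noise, giving high intra-class and low
  inter-class similarity (the structure the digit experiments rely on);
* corridor sets: crops from a long 1/f-filtered noise panorama, so
  consecutive images overlap (a contiguous landscape) and each corridor has
  its own luminance and contrast, mimicking naturalistic photo sequences.

Each stimulus set carries a single brightness gain.  Because the model's
familiarity detection compares the drive of random-weight neurons with that
of trained neurons, the stimulus vector norm is the model's operating point;
real photographs span a huge brightness range that eyes and early visual
areas would compensate for, so set loaders/generators scale each set to a
common mean L2 norm (``target_norm``) by default.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageStimulus",
    "StimulusSet",
    "preprocess",
    "read_idx",
    "load_mnist_subsets",
    "gen_digit_like",
    "gen_corridor",
    "gen_corridor_pair",
]

#: Default L2 norm of a stimulus vector (the model's operating point).
DEFAULT_TARGET_NORM = 3.2


@dataclass
class ImageStimulus:
    """One flattened stimulus: values in [0,1], row-major square image."""

    values: np.ndarray
    id: str
    task_id: int
    position: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty stimulus")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("stimulus values must lie in [0, 1]")

    @property
    def side(self) -> int:
        return int(round(self.values.size ** 0.5))

    def as_image(self) -> np.ndarray:
        return self.values.reshape(self.side, self.side)


@dataclass
class StimulusSet:
    """Ordered tasks (subsets or corridors) of stimuli with set-level
    brightness gain/offset metadata."""

    tasks: list
    kind: str = "mnist-like"
    gain: float = 1.0
    offset: float = 0.0
    seed: int | None = None

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def all_stimuli(self):
        for task in self.tasks:
            yield from task

    def __iter__(self):
        return iter(self.tasks)

    def save_png_grid(self, out_dir: str | Path, name: str = "stimuli") -> Path:
        """Dump every stimulus as one PNG grid plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stimuli = list(self.all_stimuli())
        side = stimuli[0].side
        cols = max(len(t) for t in self.tasks)
        grid = np.zeros((self.n_tasks * side, cols * side))
        lo, hi = min(s.values.min() for s in stimuli), max(s.values.max() for s in stimuli)
        span = (hi - lo) or 1.0
        for s in stimuli:
            r, c = s.task_id, s.position
            grid[r * side:(r + 1) * side, c * side:(c + 1) * side] = (s.as_image() - lo) / span
        png = out_dir / f"{name}.png"
        Image.fromarray((grid * 255).astype(np.uint8), mode="L").save(png)
        manifest = {
            "kind": self.kind,
            "gain": self.gain,
            "offset": self.offset,
            "seed": self.seed,
            "tasks": [
                [{"id": s.id, "task_id": s.task_id, "position": s.position} for s in task]
                for task in self.tasks
            ],
        }
        (out_dir / f"{name}.json").write_text(json.dumps(manifest, indent=2))
        return png


def preprocess(
    raw_image: np.ndarray,
    target: tuple[int, int] = (40, 40),
    gain: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Resize a 2D array of gray levels (0-255) to ``target`` with bilinear
    resampling and map to activations ``clip((v/255)*gain + offset, 0, 1)``.

    Returns the flattened activation vector.  Resizing is skipped when the
    input already has the target shape, so preprocessing is idempotent on
    40x40 inputs.
    """
    raw = np.asarray(raw_image, dtype=float)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw image must be a non-empty 2D array")
    if raw.shape != tuple(target):
        img = Image.fromarray(raw)
        raw = np.asarray(img.resize((target[1], target[0]), Image.BILINEAR), dtype=float)
    act = np.clip((raw / 255.0) * gain + offset, 0.0, 1.0)
    return act.ravel()


def _apply_target_norm(arrays: list[np.ndarray], target_norm: float | None) -> float:
    """Scale each array in place so its L2 norm equals target_norm (a
    luminance/contrast adaptation step standing in for the eye and early
    visual areas, which the model does not include).  Returns the mean gain
    applied."""
    if target_norm is None:
        return 1.0
    gains = []
    for a in arrays:
        norm = float(np.linalg.norm(a))
        if norm > 0:
            a *= target_norm / norm
            gains.append(target_norm / norm)
            np.clip(a, 0.0, 1.0, out=a)  # keep the activation contract
    return float(np.mean(gains)) if gains else 1.0


# --------------------------------------------------------------------------
# MNIST IDX
# --------------------------------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX file (unsigned-byte images, magic 0x803, or labels,
    magic 0x801) into a numpy array."""
    data = Path(path).read_bytes()
    if len(data) < 8:
        raise ValueError(f"{path}: truncated IDX file")
    (magic,) = struct.unpack(">I", data[:4])
    if magic == _IDX_IMAGES_MAGIC:
        n, rows, cols = struct.unpack(">III", data[4:16])
        body = np.frombuffer(data, dtype=np.uint8, offset=16)
        if body.size != n * rows * cols:
            raise ValueError(f"{path}: IDX payload size mismatch")
        return body.reshape(n, rows, cols)
    if magic == _IDX_LABELS_MAGIC:
        (n,) = struct.unpack(">I", data[4:8])
        body = np.frombuffer(data, dtype=np.uint8, offset=8)
        if body.size != n:
            raise ValueError(f"{path}: IDX payload size mismatch")
        return body
    raise ValueError(f"{path}: unknown IDX magic 0x{magic:08x}")


def load_mnist_subsets(
    images_path: str | Path,
    labels_path: str | Path,
    per_class: int = 4,
    classes: tuple[int, ...] = tuple(range(10)),
    gain: float = 1.0,
    offset: float = 0.0,
    target_norm: float | None = DEFAULT_TARGET_NORM,
) -> tuple[StimulusSet, StimulusSet]:
    """Build the digit tasks from MNIST IDX files.

    Returns (train, test): for each digit class, the first ``per_class``
    images of that class form the training task and the next ``per_class``
    the disjoint test task, each image resized to 40x40.
    """
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("image/label counts differ")
    train_tasks, test_tasks = [], []
    for t, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2 * per_class:
            raise ValueError(f"class {cls}: need {2*per_class} images, found {idx.size}")
        def mk(rank_indices, ids_prefix):
            return [
                ImageStimulus(
                    preprocess(images[i], gain=gain, offset=offset),
                    id=f"{ids_prefix}{cls}.{k}", task_id=t, position=k,
                )
                for k, i in enumerate(rank_indices)
            ]
        train_tasks.append(mk(idx[:per_class], "mnist-"))
        test_tasks.append(mk(idx[per_class:2 * per_class], "mnist-test-"))
    train = StimulusSet(train_tasks, kind="mnist-like", gain=gain, offset=offset)
    test = StimulusSet(test_tasks, kind="mnist-like", gain=gain, offset=offset)
    for s in (train, test):
        arrays = [st.values for st in s.all_stimuli()]
        s.gain *= _apply_target_norm(arrays, target_norm)
    return train, test


# --------------------------------------------------------------------------
# Synthetic generators
# --------------------------------------------------------------------------


def _stroke_prototype(rng: np.random.Generator, size: int) -> np.ndarray:
    """A digit-like glyph: a few random strokes, blurred."""
    canvas = np.zeros((size, size))
    n_strokes = rng.integers(2, 5)
    margin = size // 6
    for _ in range(n_strokes):
        p0 = rng.uniform(margin, size - margin, 2)
        p1 = rng.uniform(margin, size - margin, 2)
        t = np.linspace(0, 1, 4 * size)[:, None]
        pts = p0 + t * (p1 - p0)
        # curve the stroke a little
        bend = rng.normal(0, size / 10, 2)
        pts = pts + np.sin(np.pi * t) * bend
        rr = np.clip(pts[:, 0].round().astype(int), 0, size - 1)
        cc = np.clip(pts[:, 1].round().astype(int), 0, size - 1)
        canvas[rr, cc] = 1.0
    canvas = ndimage.gaussian_filter(canvas, sigma=size / 28)
    peak = canvas.max()
    # headroom below 1 so norm equalization rarely clips
    return canvas * (0.75 / peak) if peak > 0 else canvas


def gen_digit_like(
    seed: int,
    classes: int = 10,
    per_class: int = 4,
    size: int = 40,
    jitter: float = 0.6,
    noise: float = 0.02,
    target_norm: float | None = DEFAULT_TARGET_NORM,
) -> StimulusSet:
    """Synthetic stand-in for the digit tasks.

    Each class gets a random stroke prototype; variants apply a small
    translation and rotation (scaled by ``jitter``) plus pixel noise, so
    intra-class correlation stays well above inter-class correlation.
    A pure function of its arguments.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tasks = []
    protos: list[np.ndarray] = []
    for cls in range(classes):
        # rejection-sample prototypes so classes stay distinguishable
        for _ in range(50):
            proto = _stroke_prototype(rng, size)
            v = proto.ravel()
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            if all(
                v @ q / (nv * np.linalg.norm(q)) < 0.45 for q in protos
            ):
                break
        protos.append(proto.ravel())
        task = []
        for k in range(per_class):
            img = ndimage.shift(proto, rng.uniform(-2 * jitter, 2 * jitter, 2), order=1)
            img = ndimage.rotate(img, rng.uniform(-8 * jitter, 8 * jitter),
                                 reshape=False, order=1)
            img = img + rng.normal(0, noise, img.shape)
            img = np.clip(img, 0, 1)
            task.append(ImageStimulus(img, id=f"digit-{cls}.{k}", task_id=cls, position=k))
        tasks.append(task)
    out = StimulusSet(tasks, kind="mnist-like", seed=seed)
    out.gain = _apply_target_norm([s.values for s in out.all_stimuli()], target_norm)
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], beta: float = 1.2) -> np.ndarray:
    """Spatially correlated noise with a 1/f^beta amplitude spectrum."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spectrum = (rng.normal(size=shape) + 1j * rng.normal(size=shape)) / f**beta
    spectrum[0, 0] = 0.0
    img = np.fft.ifft2(spectrum).real
    img = (img - img.mean()) / (img.std() or 1.0)
    return img


def gen_corridor(
    seed: int,
    n: int = 20,
    size: int = 40,
    luminance: float = -0.20,
    contrast: float = 0.40,
    overlap: float = 0.5,
    task_id: int = 0,
    target_norm: float | None = None,
) -> list[ImageStimulus]:
    """One corridor: ``n`` contiguous crops from a 1/f noise panorama.

    Consecutive crops share an ``overlap`` fraction of their width, so
    adjacent images correlate more than distant ones.  ``luminance`` sets the
    mean gray level and ``contrast`` the gray-level spread before clipping to
    [0, 1].  A pure function of its arguments.
    """
    if n < 1:
        raise ValueError("a corridor needs at least one image")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    step = max(1, int(round(size * (1.0 - overlap))))
    width = size + step * (n - 1)
    panorama = _pink_noise(rng, (size, width))
    # remove large-scale luminance gradients: keeps the images detail-rich
    # and stops distant crops from sharing one dominant blob
    panorama = panorama - ndimage.gaussian_filter(panorama, size / 5)
    panorama /= panorama.std() or 1.0
    task = []
    for k in range(n):
        crop = panorama[:, k * step:k * step + size]
        img = np.clip(luminance + contrast * crop, 0, 1)
        task.append(ImageStimulus(img, id=f"corridor{task_id}-{k}", task_id=task_id, position=k))
    if target_norm is not None:
        _apply_target_norm([s.values for s in task], target_norm)
    return task


def gen_corridor_pair(
    seed: int,
    n: int = 20,
    size: int = 40,
    luminances: tuple[float, float] = (-0.16, -0.24),
    contrasts: tuple[float, float] = (0.42, 0.38),
    overlap: float = 0.5,
    target_norm: float | None = DEFAULT_TARGET_NORM,
) -> StimulusSet:
    """The two-corridor set of the lifelong experiment: two sequences of
    ``n`` contiguous textured images, each corridor with its own brightness
    and contrast."""
    ss = np.random.SeedSequence(seed).spawn(2)
    tasks = [
        gen_corridor(int(ss[i].generate_state(1)[0] % 2**31), n=n, size=size,
                     luminance=luminances[i], contrast=contrasts[i],
                     overlap=overlap, task_id=i)
        for i in range(2)
    ]
    out = StimulusSet(tasks, kind="corridor-like", seed=seed)
    out.gain = _apply_target_norm([s.values for s in out.all_stimuli()], target_norm)
    return out


def load_image_dir(
    path: str | Path,
    n_tasks: int,
    per_task: int,
    gain: float = 1.0,
    offset: float = 0.0,
    target_norm: float | None = DEFAULT_TARGET_NORM,
    kind: str = "corridor-like",
) -> StimulusSet:
    """Load PNG/JPEG files (sorted by name) from a directory and split them
    into ``n_tasks`` consecutive tasks of ``per_task`` images each."""
    files = sorted(
        p for p in Path(path).iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    need = n_tasks * per_task
    if len(files) < need:
        raise ValueError(f"need {need} images in {path}, found {len(files)}")
    tasks = []
    for t in range(n_tasks):
        task = []
        for k in range(per_task):
            f = files[t * per_task + k]
            raw = np.asarray(Image.open(f).convert("L"), dtype=float)
            task.append(ImageStimulus(preprocess(raw, gain=gain, offset=offset),
                                      id=f.stem, task_id=t, position=k))
        tasks.append(task)
    out = StimulusSet(tasks, kind=kind, gain=gain, offset=offset)
    out.gain *= _apply_target_norm([s.values for s in out.all_stimuli()], target_norm)
    return out
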