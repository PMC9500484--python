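"""Toroidal layer geometry and distance-dependent connectivity.

The pyramidal cells sit on a square 2D grid treated as a torus (opposite
edges adjacent) to avoid edge effects; distances are Euclidean under minimal
wraparound, in units of the spacing between neighboring pyramidal cells.
Interneurons live on a coarser grid embedded uniformly in the same extent.

Connection weights are generated stochastically: a distance-dependent kernel
times a uniform [0,1) draw, then each neuron's converging weight vector is
L2-normalized.  Lateral excitation uses a narrow Gaussian kernel; lateral
inhibition uses a difference-of-Gaussians ("Mexican hat") kernel that is zero
at distance 0 and peaks on a ring.  Inhibitory weights are stored with a
negative sign so that the lateral-inhibition term of the dynamics is simply a
weighted sum, and strengthening inhibition means making weights more negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LayerGeometry",
    "torus_distance",
    "torus_distance_matrix",
    "place_interneurons",
    "init_input_weights",
    "build_lateral_excitatory",
    "build_inhibitory_weights",
    "WeightState",
]


@dataclass(frozen=True)
class LayerGeometry:
    """A rows x cols grid of neurons with unit spacing, optionally toroidal."""

    rows: int
    cols: int
    wrap: bool = True
    unit: float = 1.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates in row-major order."""
        r, c = np.divmod(np.arange(self.n), self.cols)
        return np.column_stack([r, c]).astype(float) * self.unit

    @property
    def extent(self) -> tuple[float, float]:
        """Periodic box size (row extent, col extent) in grid units."""
        return (self.rows * self.unit, self.cols * self.unit)


def torus_distance(p, q, geom: LayerGeometry) -> float:
    """Euclidean distance between two grid coordinates under minimal
    wraparound in each axis (if ``geom.wrap``)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    ext = np.array(geom.extent)
    if np.any(p < 0) or np.any(q < 0) or np.any(p >= ext) or np.any(q >= ext):
        raise ValueError(f"coordinate outside grid extent {ext}: {p}, {q}")
    d = np.abs(p - q)
    if geom.wrap:
        d = np.minimum(d, ext - d)
    return float(np.hypot(d[0], d[1]))


def torus_distance_matrix(
    post_xy: np.ndarray, pre_xy: np.ndarray, extent: tuple[float, float]
) -> np.ndarray:
    """(n_post, n_pre) matrix of wrapped Euclidean distances within one
    periodic box.  Both coordinate sets must live in the same extent."""
    ext = np.asarray(extent, dtype=float)
    diff = np.abs(post_xy[:, None, :] - pre_xy[None, :, :])
    diff = np.minimum(diff, ext - diff)
    return np.hypot(diff[..., 0], diff[..., 1])


def place_interneurons(geom_p: LayerGeometry, geom_i: LayerGeometry) -> np.ndarray:
    """Embed the interneuron grid uniformly in the pyramidal extent.

    Interneuron (0, 0) anchors at pyramidal coordinate (0, 0); neighbors are
    separated by rows_p/rows_i pyramidal units, so the coarse grid tiles the
    same torus.  Returns an (n_i, 2) coordinate array in pyramidal units.
    """
    sr = geom_p.rows * geom_p.unit / geom_i.rows
    sc = geom_p.cols * geom_p.unit / geom_i.cols
    r, c = np.divmod(np.arange(geom_i.n), geom_i.cols)
    return np.column_stack([r * sr, c * sc])


def _normalize_rows(w: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return w / norms


def init_input_weights(n_post: int, n_pre: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random afferent weights, each converging (row) vector
    L2-normalized."""
    if n_post < 1 or n_pre < 1:
        raise ValueError("counts must be >= 1")
    return _normalize_rows(rng.random((n_post, n_pre)))


def build_lateral_excitatory(
    geom: LayerGeometry,
    s1: float,
    rng: np.random.Generator,
    *,
    pre_xy: np.ndarray | None = None,
    post_xy: np.ndarray | None = None,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """Gaussian-kernel stochastic weights w = Normalize[exp(-d^2 s1) * U].

    With default coordinates this is the pyramidal->pyramidal block (no
    self-connections, diagonal forced to 0 before normalization).  Passing
    ``post_xy`` (e.g. interneuron positions) builds the pyramidal->interneuron
    block on the same torus.
    """
    pre = geom.coords() if pre_xy is None else pre_xy
    post = pre if post_xy is None else post_xy
    d = torus_distance_matrix(post, pre, geom.extent)
    w = np.exp(-(d**2) * s1) * rng.random(d.shape)
    if zero_diagonal and w.shape[0] == w.shape[1] and post is pre:
        np.fill_diagonal(w, 0.0)
    return _normalize_rows(w)


def mexican_hat_kernel(d: np.ndarray, s1: float, s2: float) -> np.ndarray:
    """Difference-of-Gaussians 0.5*(exp(-d^2 s1) - exp(-d^2 s2)); zero at
    d = 0 and non-negative everywhere when s1 < s2."""
    return 0.5 * (np.exp(-(d**2) * s1) - np.exp(-(d**2) * s2))


def build_inhibitory_weights(
    geom_p: LayerGeometry,
    i_xy: np.ndarray,
    s1: float,
    s2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Interneuron->pyramidal weights from the Mexican-hat kernel.

    Magnitudes are kernel * U, L2-normalized per converging (pyramidal) row,
    then stored with a negative sign (inhibition convention).
    Requires s1 < s2, otherwise the kernel would be non-positive.
    """
    if s1 >= s2:
        raise ValueError("inhibitory kernel requires s1 < s2")
    d = torus_distance_matrix(geom_p.coords(), i_xy, geom_p.extent)
    w = mexican_hat_kernel(d, s1, s2) * rng.random(d.shape)
    return -_normalize_rows(w)


@dataclass
class WeightState:
    """The four CA1 weight blocks plus the fixed downstream gains.

    w_inp : input->pyramidal, plastic, (n_p, n_input), non-negative.
    w_pp  : pyramidal->pyramidal, static, zero diagonal.
    w_pi  : pyramidal->interneuron, static, (n_i, n_p).
    w_ip  : interneuron->pyramidal, plastic, (n_p, n_i), entries <= 0.
    w_sub : CA1->subiculum one-to-one gain, always 1.
    w_ap_vta : accumbens/pallidum->VTA gain, always -1.
    ``version`` increments on every plastic update (cheap change detection).
    """

    w_inp: np.ndarray
    w_pp: np.ndarray
    w_pi: np.ndarray
    w_ip: np.ndarray
    w_sub: float = 1.0
    w_ap_vta: float = -1.0
    version: int = 0
    meta: dict = field(default_factory=dict)

    @classmethod
    def build(cls, params, seed: int) -> "WeightState":
        """Generate all blocks from ``ModelParams`` geometry/kernels.

        One named child random stream per block, derived from the top-level
        seed, so blocks are independently reproducible.
        """
        geom = params.geometry
        kern = params.kernel
        gp = LayerGeometry(geom.p_rows, geom.p_cols)
        gi = LayerGeometry(geom.i_rows, geom.i_cols)
        streams = seed_streams(seed, ("w_inp", "w_pp", "w_pi", "w_ip"))
        i_xy = place_interneurons(gp, gi)
        w_inp = init_input_weights(geom.n_pyramidal, geom.n_input, streams["w_inp"])
        w_pp = build_lateral_excitatory(gp, kern.s1_pp, streams["w_pp"])
        w_pi = build_lateral_excitatory(
            gp, kern.s1_pi, streams["w_pi"], post_xy=i_xy, zero_diagonal=False
        )
        w_ip = build_inhibitory_weights(gp, i_xy, kern.s1_ip, kern.s2_ip, streams["w_ip"])
        meta = {
            "seed": int(seed),
            "geometry": {"p": [geom.p_rows, geom.p_cols], "i": [geom.i_rows, geom.i_cols],
                         "input": [geom.input_rows, geom.input_cols]},
            "kernel": {"s1_pp": kern.s1_pp, "s1_pi": kern.s1_pi,
                       "s1_ip": kern.s1_ip, "s2_ip": kern.s2_ip},
        }
        return cls(w_inp=w_inp, w_pp=w_pp, w_pi=w_pi, w_ip=w_ip, meta=meta)

    def checksum(self) -> tuple[float, float]:
        """Cheap fingerprint of the plastic blocks (used to prove plasticity
        was off during test phases)."""
        return (float(self.w_inp.sum()), float(self.w_ip.sum()))

    def save(self, path: str | Path) -> None:
        """Write all blocks to an .npz container with a JSON sidecar
        recording seed, geometry and kernel parameters."""
        path = Path(path)
        np.savez_compressed(
            path, w_inp=self.w_inp, w_pp=self.w_pp, w_pi=self.w_pi, w_ip=self.w_ip
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WeightState":
        path = Path(path)
        with np.load(path) as z:
            blocks = {k: z[k] for k in ("w_inp", "w_pp", "w_pi", "w_ip")}
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(**blocks, meta=meta)


def seed_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Independent, named child generators derived from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}
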