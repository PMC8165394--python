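"""Recurrence-plot encoding: delay embedding, distance matrices, texture images.

A scalar series x of length N is embedded into m-dimensional states
s_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}), giving N' = N - (m-1)*tau
states. The un-thresholded recurrence matrix stores the Euclidean distance
between every pair of states (a 5 s, 1,000-sample segment with m=2, tau=1
yields a 999 x 999 matrix); the classical binary variant thresholds it at a
radius epsilon. Distance matrices are min-max normalized per matrix, passed
through a fixed 256-entry blue->cyan->green->yellow->red lookup table (low
distance = blue, high = red) and bilinearly resized to the classifier input
size, 299 x 299 x 3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import resize as _sk_resize


@dataclass(frozen=True)
class RPParams:
    """Embedding, thresholding and rendering parameters."""

    m: int = 2
    tau: int = 1
    norm: str = "euclidean"
    epsilon: Optional[float] = None
    out_size: int = 299
    colormap: str = "rp-bgyr"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.out_size < 8:
            raise ValueError("out_size must be >= 8")


@dataclass
class RecurrenceMatrix:
    """Square recurrence matrix, either raw distances or binary recurrences."""

    R: np.ndarray
    kind: str  # "distance" | "binary"

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if self.kind not in ("distance", "binary"):
            raise ValueError("kind must be 'distance' or 'binary'")

    @property
    def n_states(self) -> int:
        return self.R.shape[0]


@dataclass
class EncodedImage:
    """H x W x 3 float image in [0, 1] plus provenance."""

    pixels: np.ndarray
    source: dict

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")


def embed(x: np.ndarray, m: int = 2, tau: int = 1) -> np.ndarray:
    """Time-delay embedding: rows are states (x_i, x_{i+tau}, ...)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_states = n - (m - 1) * tau
    if n_states < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau}; "
            f"need at least {(m - 1) * tau + 1} samples")
    idx = np.arange(n_states)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def distance_matrix(trajectory: np.ndarray) -> RecurrenceMatrix:
    """Un-thresholded recurrence matrix: pairwise Euclidean state distances."""
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 1:
        raise ValueError("trajectory must contain at least one state")
    R = cdist(traj, traj, metric="euclidean")
    # enforce exact symmetry and zero diagonal against round-off
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 0.0)
    return RecurrenceMatrix(R=R, kind="distance")


def threshold_rp(R: RecurrenceMatrix, epsilon: float) -> RecurrenceMatrix:
    """Binary recurrence matrix: 1 where distance <= epsilon (Heaviside
    convention theta(0) = 1), else 0."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if R.kind != "distance":
        raise ValueError("threshold_rp expects a distance-kind matrix")
    return RecurrenceMatrix(R=(R.R <= epsilon).astype(float), kind="binary")


def _build_colormap() -> np.ndarray:
    """256 x 3 piecewise-linear blue->cyan->green->yellow->red table."""
    anchors = np.array([
        [0.0, 0.0, 1.0],   # blue
        [0.0, 1.0, 1.0],   # cyan
        [0.0, 1.0, 0.0],   # green
        [1.0, 1.0, 0.0],   # yellow
        [1.0, 0.0, 0.0],   # red
    ])
    pos = np.linspace(0.0, 1.0, len(anchors))
    grid = np.linspace(0.0, 1.0, 256)
    table = np.empty((256, 3))
    for c in range(3):
        table[:, c] = np.interp(grid, pos, anchors[:, c])
    return table


COLORMAP_BGYR = _build_colormap()


def colorize(values: np.ndarray) -> np.ndarray:
    """Map an array of values in [0, 1] through the package colormap."""
    idx = np.clip(np.round(np.asarray(values, dtype=float) * 255), 0,
                  255).astype(np.intp)
    return COLORMAP_BGYR[idx]


def normalize_matrix(R: np.ndarray) -> np.ndarray:
    """Per-matrix min-max normalization to [0, 1]; constant matrices map to 0
    (rendered at the blue endpoint)."""
    R = np.asarray(R, dtype=float)
    lo, hi = R.min(), R.max()
    if hi - lo == 0:
        return np.zeros_like(R)
    return (R - lo) / (hi - lo)


def _resize_rgb(rgb: np.ndarray, out_size: int) -> np.ndarray:
    if rgb.shape[0] == out_size and rgb.shape[1] == out_size:
        return rgb
    out = _sk_resize(rgb, (out_size, out_size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def rp_image(R: RecurrenceMatrix, params: RPParams = RPParams(),
             source: Optional[dict] = None) -> EncodedImage:
    """Render a recurrence matrix as a normalized color texture image."""
    norm = R.R if R.kind == "binary" else normalize_matrix(R.R)
    rgb = colorize(norm)
    rgb = _resize_rgb(rgb, params.out_size)
    src = dict(source or {})
    src.setdefault("encoder", "rp")
    return EncodedImage(pixels=rgb, source=src)


def encode_segment(samples: np.ndarray, params: RPParams = RPParams(),
                   source: Optional[dict] = None) -> EncodedImage:
    """Full pipeline for one segment: embed -> distance matrix [-> threshold]
    -> color image."""
    traj = embed(samples, m=params.m, tau=params.tau)
    R = distance_matrix(traj)
    if params.epsilon is not None:
        R = threshold_rp(R, params.epsilon)
    return rp_image(R, params, source=source)
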