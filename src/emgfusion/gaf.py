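"""Gramian Angular Field encoding of 1-D signal segments.

A segment is downsampled to a fixed length N by piecewise aggregate
approximation (PAA), min-max rescaled into [-1, 1],

    x~_i = ((x_i - max X) + (x_i - min X)) / (max X - min X),

mapped to polar angles phi_i = arccos(x~_i) in [0, pi] (with the timestamp
t_i/N kept as the radius), and expanded into the pairwise angular matrices

    GASF[i, j] = cos(phi_i + phi_j)      (symmetric)
    GADF[i, j] = sin(phi_i - phi_j)      (antisymmetric, zero diagonal)

Time runs from the top-left to the bottom-right corner of either matrix, so
the encoding preserves temporal ordering and — via the GASF diagonal
cos(2 phi_i) = 2 x~_i^2 - 1 — is invertible up to a global sign.

A ``[0, 1]`` rescaling compatibility mode is available; the default is the
standard ``[-1, 1]`` construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np

GAFKind = Literal["GASF", "GADF"]

#: Default image side length (the segment is PAA-resampled to this many points).
DEFAULT_IMAGE_SIZE = 64


@dataclass
class RescaledSeries:
    """Min-max rescaled series with its original range retained."""

    values: np.ndarray
    original_min: float
    original_max: float


@dataclass
class GAFImage:
    """An N x N Gramian Angular Field with its polar-angle provenance."""

    matrix: np.ndarray
    kind: GAFKind
    phi: np.ndarray
    radius_scale: float
    source_channel: str = ""

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def paa_resample(x: np.ndarray, N: int) -> np.ndarray:
    """Piecewise aggregate approximation to length ``N``.

    The input is partitioned into N near-equal-width frames (boundaries at
    round(i * len/N)) and each output value is the mean of its frame.
    """
    x = np.asarray(x, dtype=float)
    if N < 1 or x.size < 1:
        raise ValueError("need N >= 1 and a non-empty input")
    if N == x.size:
        return x.copy()
    edges = np.round(np.linspace(0, x.size, N + 1)).astype(int)
    return np.array([x[edges[i]: max(edges[i + 1], edges[i] + 1)].mean() for i in range(N)])


def rescale(x: np.ndarray, mode: str = "symmetric") -> RescaledSeries:
    """Min-max rescale into [-1, 1] (default) or [0, 1] (``mode="unit"``).

    A constant input has an undefined range; it is mapped to all zeros
    (angle pi/2) with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to rescale")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant input to rescale; mapping to zeros", stacklevel=2)
        return RescaledSeries(np.zeros_like(x), lo, hi)
    if mode == "symmetric":
        values = ((x - hi) + (x - lo)) / (hi - lo)
    elif mode == "unit":
        values = (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    return RescaledSeries(values, lo, hi)


def to_polar(xt: RescaledSeries) -> Tuple[np.ndarray, np.ndarray]:
    """Polar encoding: phi = arccos(x~), radius r_i = t_i / N (1-based t).

    Values outside [-1, 1] by more than 1e-9 raise; smaller excursions
    (floating-point residue of the rescale) are clipped.
    """
    v = np.asarray(xt.values, dtype=float)
    if np.any(np.abs(v) > 1 + 1e-9):
        raise ValueError("rescaled values outside [-1, 1]")
    phi = np.arccos(np.clip(v, -1.0, 1.0))
    r = np.arange(1, v.size + 1) / v.size
    return phi, r


def gasf(phi: np.ndarray, source_channel: str = "") -> GAFImage:
    """Gramian angular summation field: cos(phi_i + phi_j)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty angle vector")
    m = np.cos(phi[:, None] + phi[None, :])
    return GAFImage(m, "GASF", phi, radius_scale=float(phi.size), source_channel=source_channel)


def gadf(phi: np.ndarray, source_channel: str = "") -> GAFImage:
    """Gramian angular difference field: sin(phi_i - phi_j)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty angle vector")
    m = np.sin(phi[:, None] - phi[None, :])
    np.fill_diagonal(m, 0.0)
    return GAFImage(m, "GADF", phi, radius_scale=float(phi.size), source_channel=source_channel)


def encode_segment(
    x: np.ndarray,
    size: int = DEFAULT_IMAGE_SIZE,
    kind: GAFKind = "GASF",
    rescale_mode: str = "symmetric",
    source_channel: str = "",
) -> GAFImage:
    """PAA -> rescale -> polar -> GAF, in one call."""
    resampled = paa_resample(x, size)
    phi, _ = to_polar(rescale(resampled, rescale_mode))
    return (gasf if kind == "GASF" else gadf)(phi, source_channel)


def encode_stack(
    signal: np.ndarray,
    size: int = DEFAULT_IMAGE_SIZE,
    kind: GAFKind = "GASF",
    rescale_mode: str = "symmetric",
    channel_names: Optional[list] = None,
) -> np.ndarray:
    """Encode each channel of a (n_channels, n_samples) matrix.

    Returns a (n_channels, size, size) stack: one GAF plane per muscle,
    stacked as input planes for the convolutional branch.
    """
    names = channel_names or [""] * signal.shape[0]
    return np.stack(
        [encode_segment(ch, size, kind, rescale_mode, nm).matrix
         for ch, nm in zip(signal, names)]
    )


def to_uint8(img: GAFImage) -> np.ndarray:
    """Linear [-1, 1] -> [0, 255] map for PNG-style export/inspection."""
    return np.round((img.matrix + 1.0) * 127.5).astype(np.uint8)
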