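"""Time-domain, frequency-domain and VMD+Welch features for the LSTM branch.

Per analysis window and channel the feature vector is, in order::

    [MAV, RMS, WL, ZC, MDF, MPF, BP_1, ..., BP_K]

where MAV/RMS are mean-absolute and root-mean-square amplitude (uV), WL is
waveform length (sum of absolute first differences, uV), ZC the
zero-crossing count, MDF/MPF the median and mean power frequency of the
window's Welch spectrum (Hz), and BP_k the total Welch band power of the
k-th variational mode (uV^2). Channel blocks are concatenated in recording
channel order, so the full vector has length ``n_channels * (6 + K)``.

The variational mode decomposition (VMD) splits a signal into K narrow-band
modes by the standard frequency-domain ADMM: each mode spectrum is updated
by Wiener-like shrinkage around its center frequency with bandwidth penalty
``alpha``, each center frequency as the power-weighted mean frequency of
its mode, plus optional dual ascent with step ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .io_core import Recording
from .preprocess import ActiveSegment


# ---------------------------------------------------------------------------
# time-domain features

def td_features(
    x: np.ndarray, zc_deadband: Optional[float] = None
) -> Tuple[float, float, float, int]:
    """MAV, RMS, waveform length and zero-crossing count of one window.

    ``zc_deadband`` suppresses noise-inflated crossings: a sign change only
    counts when the step across zero exceeds the deadband. ``None`` uses
    0.01 * RMS; pass 0 for the strict textbook definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mav = float(np.mean(np.abs(x)))
    rms = float(np.sqrt(np.mean(x**2)))
    wl = float(np.sum(np.abs(np.diff(x))))
    eps = 0.01 * rms if zc_deadband is None else zc_deadband
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(np.diff(x)) > eps
    zc = int(np.count_nonzero(sign_change & big_enough))
    return mav, rms, wl, zc


# ---------------------------------------------------------------------------
# variational mode decomposition

@dataclass
class VMDResult:
    """K narrow-band modes plus their center frequencies (ascending)."""

    modes: np.ndarray          # (K, n_samples)
    center_freqs: np.ndarray   # (K,), Hz if fs given else cycles/sample
    K: int
    alpha: float
    tol: float
    converged: bool = True
    n_iter: int = 0


def vmd(
    x: np.ndarray,
    K: int = 4,
    alpha: float = 2000.0,
    tau: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    fs: Optional[float] = None,
) -> VMDResult:
    """Decompose ``x`` into K band-limited modes (frequency-domain ADMM).

    The signal is mirror-extended to suppress boundary effects, the mode
    spectra are iterated on the positive half-spectrum, and the returned
    modes are cropped back to the original support. Iteration stops when
    the summed relative change of the mode spectra drops below ``tol``;
    hitting ``max_iter`` first returns ``converged=False``.

    Modes are returned sorted by ascending center frequency.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if K < 1 or n < 2 * K:
        raise ValueError(f"need len(x) >= 2K, got n={n}, K={K}")

    # mirror extension: half the signal reflected on each side
    half = n // 2
    f = np.concatenate([x[:half][::-1], x, x[n - half:][::-1]])
    T = f.size
    freqs = np.arange(T) / T - 0.5 - 1.0 / T

    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0.0

    u_hat = np.zeros((K, T), dtype=complex)
    omega = 0.5 * np.arange(K) / K  # uniform initialisation over [0, 0.5)
    lam = np.zeros(T, dtype=complex)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_prev = u_hat.copy()
        for k in range(K):
            others = u_hat.sum(axis=0) - u_hat[k]
            u_hat[k] = (f_hat_plus - others - lam / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2
            )
            power = np.abs(u_hat[k, T // 2:]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float(freqs[T // 2:] @ power / denom)
        if tau != 0.0:
            lam = lam + tau * (u_hat.sum(axis=0) - f_hat_plus)
        diff = np.sum(np.abs(u_hat - u_prev) ** 2) / max(np.sum(np.abs(u_prev) ** 2), 1e-30)
        if diff < tol:
            converged = True
            break

    # back to time domain: hermitian-complete each mode spectrum
    modes = np.empty((K, n))
    for k in range(K):
        full = np.zeros(T, dtype=complex)
        full[T // 2:] = u_hat[k, T // 2:]
        full[1: T // 2 + 1] = np.conj(u_hat[k, T // 2:][::-1])
        m = np.real(np.fft.ifft(np.fft.ifftshift(full)))
        modes[k] = m[half: half + n]

    order = np.argsort(omega)
    cf = omega[order] * (fs if fs is not None else 1.0)
    return VMDResult(
        modes=modes[order], center_freqs=cf, K=K, alpha=alpha, tol=tol,
        converged=converged, n_iter=it,
    )


# ---------------------------------------------------------------------------
# spectral features

def welch_psd(
    x: np.ndarray,
    fs: float,
    nperseg: int = 256,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (uV^2/Hz)."""
    x = np.asarray(x, dtype=float)
    if nperseg > x.size:
        raise ValueError(f"nperseg={nperseg} > signal length {x.size}")
    return sps.welch(
        x, fs=fs, window=window, nperseg=nperseg,
        noverlap=int(overlap_frac * nperseg),
    )


def fd_features(freqs: np.ndarray, psd: np.ndarray) -> Tuple[float, float]:
    """Median frequency (MDF) and mean power frequency (MPF) of a PSD.

    MDF uses the grouped-data convention: the cumulative power is anchored
    at each bin's half mass (C_i = cumsum - psd_i/2) and the half-total
    crossing is located by linear interpolation. This places a single
    spectral line exactly at its own frequency and the median of two equal
    lines at their midpoint.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("psd must be non-negative")
    total = psd.sum()
    if total <= 0:
        raise ValueError("all-zero PSD: spectral features undefined")

    mpf = float(freqs @ psd / total)

    half = total / 2.0
    c = np.cumsum(psd) - psd / 2.0
    i = int(np.searchsorted(c, half))
    if i == 0:
        mdf = float(freqs[0])
    elif i >= freqs.size:
        mdf = float(freqs[-1])
    else:
        c0, c1 = c[i - 1], c[i]
        t = 0.0 if c1 == c0 else (half - c0) / (c1 - c0)
        mdf = float(freqs[i - 1] + t * (freqs[i] - freqs[i - 1]))
    return mdf, mpf


def band_power(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Total power: integral of the PSD over its frequency grid (uV^2)."""
    return float(np.trapezoid(psd, freqs))


# ---------------------------------------------------------------------------
# feature sequences

@dataclass
class VMDConfig:
    K: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500


@dataclass
class WelchConfig:
    nperseg: int = 256
    overlap_frac: float = 0.5
    window: str = "hann"


@dataclass
class FeatureSequence:
    """Ordered per-window feature vectors for one active segment."""

    vectors: np.ndarray  # (n_windows, n_features)
    window_len: float
    stride: float
    feature_names: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.vectors.shape[0]


def feature_names(channel_names, K: int) -> List[str]:
    base = ["mav", "rms", "wl", "zc", "mdf", "mpf"] + [f"bp{k+1}" for k in range(K)]
    return [f"{ch}.{b}" for ch in channel_names for b in base]


def window_features(
    window: np.ndarray,
    fs: float,
    vmd_cfg: VMDConfig,
    welch_cfg: WelchConfig,
) -> np.ndarray:
    """Feature block for one channel window (length 6 + K)."""
    nper = min(welch_cfg.nperseg, window.size)
    mav, rms, wl, zc = td_features(window)
    fgrid, psd = welch_psd(window, fs, nper, welch_cfg.overlap_frac, welch_cfg.window)
    if psd.sum() > 0:
        mdf, mpf = fd_features(fgrid, psd)
    else:
        mdf = mpf = 0.0
    res = vmd(window, vmd_cfg.K, vmd_cfg.alpha, vmd_cfg.tau, vmd_cfg.tol,
              vmd_cfg.max_iter, fs=fs)
    bps = [
        band_power(*welch_psd(m, fs, nper, welch_cfg.overlap_frac, welch_cfg.window))
        for m in res.modes
    ]
    return np.array([mav, rms, wl, zc, mdf, mpf] + bps)


def build_feature_sequence(
    rec: Recording,
    segment: ActiveSegment,
    window_len: float = 0.25,
    stride: float = 0.125,
    vmd_cfg: Optional[VMDConfig] = None,
    welch_cfg: Optional[WelchConfig] = None,
) -> FeatureSequence:
    """Sliding-window feature vectors over one active segment.

    Windows start at ``segment.start`` and advance by ``stride`` while they
    fit inside the segment; each window contributes one flattened
    all-channel feature vector.
    """
    vmd_cfg = vmd_cfg or VMDConfig()
    welch_cfg = welch_cfg or WelchConfig()
    win = int(round(window_len * rec.fs))
    hop = int(round(stride * rec.fs))
    if segment.n_samples < win:
        raise ValueError(
            f"segment ({segment.n_samples} samples) shorter than window ({win})"
        )
    starts = range(segment.start, segment.end - win + 1, max(hop, 1))
    rows = []
    for s in starts:
        blocks = [
            window_features(rec.signal[c, s: s + win], rec.fs, vmd_cfg, welch_cfg)
            for c in range(rec.n_channels)
        ]
        rows.append(np.concatenate(blocks))
    return FeatureSequence(
        vectors=np.asarray(rows),
        window_len=window_len,
        stride=stride,
        feature_names=feature_names(rec.channel_names, vmd_cfg.K),
    )
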