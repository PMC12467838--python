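"""Assist-effect evaluation: %MVC normalisation and the paired t-test.

Muscle load is quantified from the sliding-window RMS envelope of the
cleaned sEMG. Activation is normalised against the maximum voluntary
contraction (MVC) benchmark — the largest of three repetition RMS peaks —
as ``%MVC = action RMS / MVC RMS * 100``. The with/without-exoskeleton
comparison uses the paired t statistic

    t = dbar / (s_d / sqrt(n)),    df = n - 1,

with ``dbar`` the mean paired difference and ``s_d`` its sample standard
deviation (n-1 denominator); the p-value is two-sided by default. A
summary-mode entry point accepts (dbar, s_d, n) directly, e.g. the printed
per-study summary dbar = 40, s_d = 5, n = 8 gives t ≈ 22.627 with df = 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import Recording
from .preprocess import moving_average_series


@dataclass
class MVCRecord:
    """Per-muscle MVC benchmark: the maximum of 3 repetition RMS peaks (uV)."""

    mvc_rms: Dict[str, float]

    def __post_init__(self) -> None:
        bad = [m for m, v in self.mvc_rms.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive MVC RMS for {bad}")

    @classmethod
    def from_repetitions(cls, peaks: Dict[str, Sequence[float]]) -> "MVCRecord":
        """Take the max over each muscle's repetition peaks."""
        return cls({m: float(max(v)) for m, v in peaks.items()})


@dataclass
class TTestSummary:
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    sd_diff: float
    n: int


@dataclass
class AssistResult:
    """Per-muscle activation with/without assist plus the paired test."""

    percent_mvc_without: Dict[str, float]
    percent_mvc_with: Dict[str, float]
    peak_power_without: Dict[str, float]
    peak_power_with: Dict[str, float]
    ttest: Optional[TTestSummary]
    per_muscle_ttest: Dict[str, TTestSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.percent_mvc_without:
            rows.append({
                "muscle": m,
                "percent_mvc_without": self.percent_mvc_without[m],
                "percent_mvc_with": self.percent_mvc_with[m],
                "peak_power_without": self.peak_power_without[m],
                "peak_power_with": self.peak_power_with[m],
            })
        return pd.DataFrame(rows)


class DegenerateTestError(ValueError):
    """Paired differences with zero variance: t is undefined."""


def rms_envelope(x: np.ndarray, window: float, fs: float) -> np.ndarray:
    """Sliding-window RMS: moving average of the squared signal, rooted.

    Same trailing-window convention as the moving-average series used for
    segmentation; entries before the first full window are NaN.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(window * fs))
    if n < 1:
        raise ValueError("window shorter than one sample")
    if n > x.size:
        raise ValueError(f"window ({n} samples) longer than signal ({x.size})")
    mas = moving_average_series(x**2, n, source="squared")
    return np.sqrt(mas.values)


def percent_mvc(action_rms: float, mvc_rms: float) -> float:
    """Activation as a percentage of the MVC benchmark."""
    if mvc_rms <= 0:
        raise ValueError("MVC RMS must be positive")
    return action_rms / mvc_rms * 100.0


def paired_t(
    differences: np.ndarray, two_sided: bool = True
) -> Tuple[float, int, float]:
    """Paired t-test from a vector of paired differences.

    Returns (t, df, p). The sample SD uses the n-1 denominator. Matches
    :func:`paired_t_summary` evaluated at the sample moments.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateTestError(
            "paired differences have zero variance; t-statistic undefined")
    return paired_t_summary(float(np.mean(d)), sd, d.size, two_sided)


def paired_t_summary(
    mean_diff: float, sd_diff: float, n: int, two_sided: bool = True
) -> Tuple[float, int, float]:
    """Paired t-test from summary statistics (dbar, s_d, n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff <= 0:
        raise DegenerateTestError("sd of differences must be positive")
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    if two_sided:
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = stats.t.sf(t, df)
    return t, df, float(p)


def _centered_abs_envelope(rec: Recording, ch: int, window: float) -> np.ndarray:
    """Mean-centered absolute RMS envelope of one channel (power curve)."""
    env = rms_envelope(rec.signal[ch], window, rec.fs)
    env = env[~np.isnan(env)]
    return np.abs(env - env.mean())


def compare_assist(
    without: Sequence[Recording],
    with_exo: Sequence[Recording],
    mvc: MVCRecord,
    rms_window: float = 0.1,
    two_sided: bool = True,
) -> AssistResult:
    """Full with/without-exoskeleton comparison.

    ``without[i]`` and ``with_exo[i]`` must be the same subject's paired
    trials (same subject_id, standardized movement cycles). Per muscle the
    mean-centered absolute envelope gives a power curve; its peak is the
    peak power and its peak RMS feeds the %MVC normalisation. The paired
    t-test runs on per-subject %MVC differences pooled over muscles, and
    per muscle individually.
    """
    if len(without) != len(with_exo):
        raise ValueError("paired trial lists differ in length")
    for a, b in zip(without, with_exo):
        if a.subject_id != b.subject_id:
            raise ValueError(
                f"unpaired subjects: {a.subject_id!r} vs {b.subject_id!r}")
    if not without:
        raise ValueError("empty trial lists")

    muscles = list(without[0].channel_names)
    pm_wo: Dict[str, list] = {m: [] for m in muscles}
    pm_wi: Dict[str, list] = {m: [] for m in muscles}
    pk_wo: Dict[str, list] = {m: [] for m in muscles}
    pk_wi: Dict[str, list] = {m: [] for m in muscles}

    for rec_wo, rec_wi in zip(without, with_exo):
        for ci, m in enumerate(muscles):
            env_wo = _centered_abs_envelope(rec_wo, ci, rms_window)
            env_wi = _centered_abs_envelope(rec_wi, ci, rms_window)
            peak_wo = float(env_wo.max())
            peak_wi = float(env_wi.max())
            pk_wo[m].append(peak_wo)
            pk_wi[m].append(peak_wi)
            pm_wo[m].append(percent_mvc(peak_wo, mvc.mvc_rms[m]))
            pm_wi[m].append(percent_mvc(peak_wi, mvc.mvc_rms[m]))

    diffs = np.concatenate(
        [np.asarray(pm_wo[m]) - np.asarray(pm_wi[m]) for m in muscles])
    try:
        t, df, p = paired_t(diffs, two_sided)
        ttest = TTestSummary(t, df, p, float(diffs.mean()),
                             float(np.std(diffs, ddof=1)), diffs.size)
    except DegenerateTestError:
        ttest = None   # identical with/without: no-effect degenerate case

    per_muscle: Dict[str, TTestSummary] = {}
    for m in muscles:
        d = np.asarray(pm_wo[m]) - np.asarray(pm_wi[m])
        try:
            t, df, p = paired_t(d, two_sided)
            per_muscle[m] = TTestSummary(t, df, p, float(d.mean()),
                                         float(np.std(d, ddof=1)), d.size)
        except (DegenerateTestError, ValueError):
            continue

    mean = lambda v: float(np.mean(v))  # noqa: E731
    return AssistResult(
        percent_mvc_without={m: mean(pm_wo[m]) for m in muscles},
        percent_mvc_with={m: mean(pm_wi[m]) for m in muscles},
        peak_power_without={m: mean(pk_wo[m]) for m in muscles},
        peak_power_with={m: mean(pk_wi[m]) for m in muscles},
        ttest=ttest,
        per_muscle_ttest=per_muscle,
    )
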