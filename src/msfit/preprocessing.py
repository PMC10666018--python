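"""Low-pass filtering and resampling of per-joint time series.

The default smoothing path is a causal, single-pass, third-order Butterworth
filter with a 5 Hz cutoff (bilinear design), so the same code is realizable in
an online feedback loop. A zero-phase forward–backward variant is available
behind an explicit flag for post-hoc analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError
from .skeleton import Frame, SkeletonSequence

DEFAULT_FILTER_ORDER = 3
DEFAULT_CUTOFF_HZ = 5.0


@dataclass
class Series:
    """A uniformly sampled scalar time series."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("Series values must be 1-D")
        if self.fs <= 0:
            raise ParameterError("Series fs must be > 0")

    def __len__(self) -> int:
        return len(self.values)


def butter_coefficients(
    fs: float, order: int = DEFAULT_FILTER_ORDER, cutoff: float = DEFAULT_CUTOFF_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Design the low-pass Butterworth (bilinear transform) for a given rate."""
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2:g}) Hz, got {cutoff:g}"
        )
    return signal.butter(order, cutoff, btype="low", fs=fs)


def _filter_array(
    x: np.ndarray, fs: float, order: int, cutoff: float, zero_phase: bool
) -> np.ndarray:
    b, a = butter_coefficients(fs, order, cutoff)
    if zero_phase:
        return signal.filtfilt(b, a, x, axis=0)
    # Initial conditions at the first sample value shorten the start-up
    # transient (a step from zero would otherwise bleed into the exercise).
    zi = signal.lfilter_zi(b, a)
    if x.ndim == 1:
        y, _ = signal.lfilter(b, a, x, zi=zi * x[0])
        return y
    y = np.empty_like(x)
    flat = x.reshape(x.shape[0], -1)
    out = y.reshape(x.shape[0], -1)
    for k in range(flat.shape[1]):
        out[:, k], _ = signal.lfilter(b, a, flat[:, k], zi=zi * flat[0, k])
    return y


def butterworth_lowpass(
    series: Series,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    zero_phase: bool = False,
) -> Series:
    """Low-pass filter a series; output length equals input length.

    Raises
    ------
    ParameterError
        If ``cutoff >= fs/2``, ``order < 1``, or the series is shorter than
        ``3 * order`` samples.
    """
    if len(series) < 3 * order:
        raise ParameterError(
            f"series too short for order-{order} filtering: "
            f"need >= {3 * order} samples, got {len(series)}"
        )
    y = _filter_array(series.values, series.fs, order, cutoff, zero_phase)
    return Series(values=y, fs=series.fs)


def filter_positions(
    seq: SkeletonSequence,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    zero_phase: bool = False,
) -> SkeletonSequence:
    """Apply the low-pass filter to every joint coordinate of a sequence.

    Timestamps, nominal rate, and tracking flags are carried over unchanged.
    """
    n = len(seq)
    if n < 3 * order:
        raise ParameterError(
            f"sequence too short for order-{order} filtering: {n} frames"
        )
    fs = seq.nominal_fs
    filtered = _filter_array(seq.positions, fs, order, cutoff, zero_phase)
    frames = [
        Frame(timestamp=f.timestamp, positions=filtered[i], tracked=f.tracked)
        for i, f in enumerate(seq)
    ]
    return SkeletonSequence(frames=frames, nominal_fs=seq.nominal_fs)


def group_delay_frames(
    fs: float, order: int = DEFAULT_FILTER_ORDER, cutoff: float = DEFAULT_CUTOFF_HZ
) -> int:
    """Low-frequency group delay of the causal filter, rounded to whole frames.

    Used to shift event boundaries detected on causally filtered signals back
    onto the raw time base.
    """
    b, a = butter_coefficients(fs, order, cutoff)
    _, gd = signal.group_delay((b, a), w=[1e-4], fs=fs)
    return int(round(float(gd[0])))


def resample_uniform(series: Series, target_fs: float) -> Series:
    """Linearly interpolate onto a uniform grid spanning the original support."""
    if target_fs <= 0:
        raise ParameterError("target_fs must be > 0")
    n = len(series)
    if n < 2:
        raise ParameterError("resampling needs at least 2 samples")
    duration = (n - 1) / series.fs
    m = int(np.floor(duration * target_fs + 1e-9)) + 1
    t_old = np.arange(n) / series.fs
    t_new = np.arange(m) / target_fs
    return Series(values=np.interp(t_new, t_old, series.values), fs=target_fs)
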