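"""Waveform-shape features of averaged extracellular spikes.

Four features summarize an averaged waveform (an STA or a peak-aligned
mean spike):

- ``amplitude`` — signed value of the main negative peak (μV);
- ``half_width`` — duration of the main phase below 50% of the negative
  peak (μs), with sub-sample precision from linear interpolation at the
  50% crossings;
- ``trough_peak_width`` — time from the main negative peak to the first
  positive local maximum after it (μs); undefined (NaN) for purely
  monophasic waveforms;
- ``rstd`` — relative standard deviation: per-sample standard deviation
  across the contributing spike snippets after normalization by the mean
  waveform's peak-to-peak amplitude, reduced to a scalar by averaging
  over samples.  A shape-consistency / multi-unit-contamination index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "WaveformFeatures",
    "amplitude",
    "half_width",
    "trough_peak_width",
    "rstd",
    "compute_features",
]

#: Required prominence of the post-trough positive peak, as a fraction of
#: the trough depth; ignores noise ripples.
_PEAK_PROMINENCE_FRAC = 0.05


@dataclass(frozen=True)
class WaveformFeatures:
    """Shape features of one averaged waveform."""

    amplitude_uV: float  # signed, negative for valid spikes
    half_width_us: float
    trough_peak_width_us: float  # NaN when no post-trough positive peak
    rstd: float  # NaN when snippets were not supplied
    n_spikes: int


def amplitude(sta: np.ndarray) -> float:
    """Signed amplitude of the main negative peak (μV)."""
    sta = np.asarray(sta, dtype=float)
    m = float(sta.min())
    if m >= 0:
        raise ValueError("waveform has no negative peak")
    return m


def _interp_crossing(x0: float, x1: float, y0: float, y1: float, level: float) -> float:
    """x where the segment (x0,y0)-(x1,y1) crosses y = level."""
    return x0 + (level - y0) / (y1 - y0) * (x1 - x0)


def half_width(sta: np.ndarray, sample_period_us: float) -> float:
    """Duration (μs) of the contiguous main phase below 50% of the trough.

    The 50% level is ``0.5 * min(sta)`` (a negative number); crossing
    times on both flanks of the trough are located by linear
    interpolation between samples.
    """
    sta = np.asarray(sta, dtype=float)
    trough = int(np.argmin(sta))
    level = 0.5 * sta[trough]
    if level >= 0:
        raise ValueError("waveform has no negative peak")
    # walk left
    i = trough
    while i > 0 and sta[i - 1] < level:
        i -= 1
    if i == 0 and sta[0] < level:
        raise ValueError("half-width flank truncated by the window edge")
    left = _interp_crossing(i - 1, i, sta[i - 1], sta[i], level)
    # walk right
    j = trough
    n = sta.size
    while j < n - 1 and sta[j + 1] < level:
        j += 1
    if j == n - 1 and sta[n - 1] < level:
        raise ValueError("half-width flank truncated by the window edge")
    right = _interp_crossing(j, j + 1, sta[j], sta[j + 1], level)
    return float((right - left) * sample_period_us)


def trough_peak_width(sta: np.ndarray, sample_period_us: float) -> float:
    """Time (μs) from the main negative peak to the first positive peak
    after it.

    The first strictly positive local maximum after the trough with
    prominence of at least 5% of the trough depth is used.  Returns NaN
    when no such peak exists (monophasic waveform).
    """
    sta = np.asarray(sta, dtype=float)
    trough = int(np.argmin(sta))
    depth = -sta[trough]
    if depth <= 0:
        raise ValueError("waveform has no negative peak")
    tail = sta[trough:]
    peaks, _ = find_peaks(tail, height=0.0, prominence=_PEAK_PROMINENCE_FRAC * depth)
    if peaks.size == 0:
        return float("nan")
    return float(peaks[0] * sample_period_us)


def rstd(snippets: np.ndarray, mean_waveform: np.ndarray | None = None) -> float:
    """Relative standard deviation of spike snippets.

    Every snippet is normalized by the peak-to-peak amplitude of the
    mean waveform; the per-sample population standard deviation across
    snippets is then averaged over samples.
    """
    snippets = np.asarray(snippets, dtype=float)
    if snippets.ndim != 2 or snippets.shape[0] < 2:
        raise ValueError("need at least 2 snippets")
    if mean_waveform is None:
        mean_waveform = snippets.mean(axis=0)
    mean_waveform = np.asarray(mean_waveform, dtype=float)
    p2p = float(mean_waveform.max() - mean_waveform.min())
    if p2p <= 0:
        raise ValueError("mean waveform has zero peak-to-peak amplitude")
    sd = snippets.std(axis=0, ddof=0)
    return float(sd.mean() / p2p)


def compute_features(
    sta: np.ndarray,
    sample_period_us: float,
    snippets: np.ndarray | None = None,
    n_spikes: int | None = None,
) -> WaveformFeatures:
    """Bundle the four features for one averaged waveform."""
    amp = amplitude(sta)
    hw = half_width(sta, sample_period_us)
    tpw = trough_peak_width(sta, sample_period_us)
    if snippets is not None:
        r = rstd(snippets, sta if len(sta) == np.asarray(snippets).shape[1] else None)
        n = snippets.shape[0] if n_spikes is None else n_spikes
    else:
        r = float("nan")
        n = 0 if n_spikes is None else n_spikes
    return WaveformFeatures(amp, hw, tpw, r, int(n))
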