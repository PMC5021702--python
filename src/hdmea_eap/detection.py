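"""Threshold-crossing spike detection and activity maps.

Traces are band-pass filtered (500–3,000 Hz, zero-phase 2nd-order
Butterworth applied forward–backward so trough timing is preserved) and
events are detected where the filtered signal crosses below minus
``k`` times the background-noise standard deviation (default k = 5).
The noise SD is estimated robustly as ``median(|x|)/0.6745`` so spike
content does not inflate it.

After a threshold crossing the detector is blind to further crossings
for 0.8 ms; the event time is the deepest sample within that blanking
span (earliest sample on ties), and a fixed-length snippet (2.5 ms) is
extracted centered on the trough.  Events whose snippet would be
truncated by a recording edge are discarded.

The activity map assigns each electrode its firing rate over the whole
recording; electrodes are "active" when the rate strictly exceeds
0.2 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SpikeEvents",
    "bandpass",
    "estimate_noise_sd",
    "detect_events",
    "detect_all",
    "extract_snippets",
    "events_dataframe",
    "activity_map",
    "DEFAULT_BAND_HZ",
    "DEFAULT_THRESHOLD_K",
    "DEFAULT_BLANK_S",
    "DEFAULT_WINDOW_S",
    "DEFAULT_ACTIVITY_MIN_HZ",
]

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (500.0, 3000.0)
DEFAULT_THRESHOLD_K = 5.0
DEFAULT_BLANK_S = 0.8e-3
DEFAULT_WINDOW_S = 2.5e-3
DEFAULT_ACTIVITY_MIN_HZ = 0.2

_MAD_TO_SD = 0.6744897501960817  # Phi^-1(0.75)


@dataclass(frozen=True)
class SpikeEvents:
    """Threshold-crossing events of one electrode."""

    electrode_id: int
    times_s: np.ndarray  # trough times, ascending
    indices: np.ndarray  # trough sample indices
    snippets: np.ndarray  # (n_events, window_samples), trough at center
    threshold_uV: float  # positive number; events crossed below -threshold

    @property
    def n_events(self) -> int:
        return self.times_s.size


def bandpass(
    trace: np.ndarray,
    sampling_rate: float,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
) -> np.ndarray:
    """Zero-phase band-pass filter (2nd-order Butterworth, filtfilt)."""
    if not (0 < low < high < sampling_rate / 2):
        raise ValueError("need 0 < low < high < Nyquist")
    sos = butter(2, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD of a filtered trace: ``median(|x|)/0.6745``."""
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValueError("need at least 1,000 samples for a noise estimate")
    return float(np.median(np.abs(x)) / _MAD_TO_SD)


def detect_events(
    trace: np.ndarray,
    sampling_rate: float,
    k_threshold: float = DEFAULT_THRESHOLD_K,
    blank_s: float = DEFAULT_BLANK_S,
    window_s: float = DEFAULT_WINDOW_S,
    noise_sd: float | None = None,
    electrode_id: int = 0,
) -> SpikeEvents:
    """Detect negative threshold crossings on one filtered trace.

    Parameters
    ----------
    trace
        Band-pass filtered voltage trace (μV).
    noise_sd
        Background-noise SD; estimated from the trace when omitted.
    """
    x = np.asarray(trace, dtype=float)
    if k_threshold <= 0:
        raise ValueError("k_threshold must be positive")
    n_w = int(round(window_s * sampling_rate))
    if n_w > x.size:
        raise ValueError("snippet window larger than the trace")
    n_blank = max(int(round(blank_s * sampling_rate)), 1)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(x)
    thr = k_threshold * noise_sd

    below = x < -thr
    onsets = np.flatnonzero(below & ~np.r_[False, below[:-1]])
    troughs = []
    blank_until = -1
    for onset in onsets:
        if onset < blank_until:
            continue
        span_end = min(onset + n_blank, x.size)
        troughs.append(onset + int(np.argmin(x[onset:span_end])))
        blank_until = onset + n_blank
    # enforce the blanking distance between event (trough) times as well
    kept: list[int] = []
    for tr in troughs:
        if kept and tr - kept[-1] < n_blank:
            continue
        kept.append(tr)
    idx = np.asarray(kept, dtype=int)
    idx, snippets = extract_snippets(x, idx, n_w)
    return SpikeEvents(
        electrode_id=electrode_id,
        times_s=idx / sampling_rate,
        indices=idx,
        snippets=snippets,
        threshold_uV=float(thr),
    )


def extract_snippets(
    trace: np.ndarray, indices: np.ndarray, window_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-length snippets centered on ``indices``.

    Indices whose window would be truncated by a recording edge are
    dropped; returns the kept indices and the (n, window) snippet array.
    """
    x = np.asarray(trace)
    indices = np.asarray(indices, dtype=int)
    half = window_samples // 2
    start = indices - half
    ok = (start >= 0) & (start + window_samples <= x.size)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("dropped %d edge-truncated snippets", n_drop)
    kept = indices[ok]
    if kept.size == 0:
        return kept, np.empty((0, window_samples), dtype=x.dtype)
    offsets = np.arange(window_samples)
    return kept, x[(kept - half)[:, None] + offsets[None, :]]


def detect_all(
    traces: np.ndarray,
    sampling_rate: float,
    k_threshold: float = DEFAULT_THRESHOLD_K,
    blank_s: float = DEFAULT_BLANK_S,
    window_s: float = DEFAULT_WINDOW_S,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    prefiltered: bool = False,
) -> dict[int, SpikeEvents]:
    """Band-pass filter and detect events on every electrode."""
    out: dict[int, SpikeEvents] = {}
    for e in range(traces.shape[0]):
        x = traces[e] if prefiltered else bandpass(traces[e], sampling_rate, *band)
        out[e] = detect_events(
            x, sampling_rate, k_threshold, blank_s, window_s, electrode_id=e
        )
    return out


def events_dataframe(events: dict[int, SpikeEvents]) -> pd.DataFrame:
    """Flat per-event table: electrode_id, time_s, peak_uV."""
    rows = []
    for e, ev in events.items():
        if ev.n_events == 0:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "electrode_id": e,
                    "time_s": ev.times_s,
                    "peak_uV": ev.snippets.min(axis=1),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["electrode_id", "time_s", "peak_uV"])
    return pd.concat(rows, ignore_index=True)


def activity_map(
    events: dict[int, SpikeEvents] | dict[int, int],
    duration_s: float,
    min_rate_hz: float = DEFAULT_ACTIVITY_MIN_HZ,
) -> pd.DataFrame:
    """Firing rate per electrode over the whole recording.

    ``active`` is strict: the rate must exceed ``min_rate_hz``.
    Accepts either :class:`SpikeEvents` per electrode or raw counts.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rows = []
    for e, ev in events.items():
        count = ev.n_events if isinstance(ev, SpikeEvents) else int(ev)
        f = count / duration_s
        rows.append(
            {"electrode_id": e, "firing_rate_hz": f, "active": bool(f > min_rate_hz)}
        )
    return pd.DataFrame(rows, columns=["electrode_id", "firing_rate_hz", "active"])
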