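"""Spike-shape adaptation versus continuous firing rate.

During a burst the instantaneous firing rate rises and the spike shape
adapts: amplitudes shrink, widths stretch.  The degree of adaptation
differs between somatic and distal-axonal signal sources, which makes it
a classification cue.

The continuous firing rate (cFR) is an exponentially smoothed rate
updated at every spike::

    cFR(t) = d * cFR(t - dt) + (1 - d) / dt,      d = exp(-dt / tau)

with ``dt`` the time since the previous spike and ``tau = 100 ms`` by
default.  For a constant inter-spike interval the recursion has the
fixed point ``cFR = 1/dt``.

A three-parameter exponential is fitted to a shape feature ``y`` versus
the cFR ``x`` by least squares::

    g(x) = y_c * exp(b * x) + y_inf

and the adaptation rate is the percent change from the zero-rate
baseline ``g(0) = y_c + y_inf`` to the high-rate asymptote ``y_inf``::

    AR = (y_inf / (y_inf + y_c) - 1) * 100

Amplitude reduction during bursts gives negative AR; spike widening
gives positive AR (amplitude is fitted on its absolute value so the sign
convention holds).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu

__all__ = [
    "CFRSeries",
    "AdaptationResult",
    "continuous_firing_rate",
    "fit_adaptation",
    "adaptation_rate",
    "compare_groups",
    "boxplot_stats",
    "DEFAULT_TAU_S",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU_S = 0.1


@dataclass(frozen=True)
class CFRSeries:
    """Per-spike continuous firing rate."""

    spike_times: np.ndarray  # s, strictly increasing
    cfr: np.ndarray  # Hz, one value per spike
    tau: float  # s
    d: np.ndarray  # per-spike decay term exp(-dt/tau); NaN for the first spike


@dataclass(frozen=True)
class AdaptationResult:
    """Exponential feature-vs-cFR fit and the derived adaptation rate."""

    feature_name: str
    y_c: float
    b: float  # 1/Hz
    y_inf: float
    ar_percent: float  # NaN when |y_inf + y_c| ~ 0
    fit_rss: float
    n_spikes: int


def continuous_firing_rate(
    spike_times: np.ndarray, tau: float = DEFAULT_TAU_S
) -> CFRSeries:
    """Apply the cFR recursion to a spike train.

    The cFR at the first spike is initialized to 0 Hz (there is no
    preceding interval); callers fitting adaptation should exclude the
    first spike.
    """
    t = np.asarray(spike_times, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if t.size == 0:
        return CFRSeries(t, np.empty(0), tau, np.empty(0))
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("spike_times must be strictly increasing (no duplicates)")
    cfr = np.zeros(t.size)
    d = np.full(t.size, np.nan)
    d[1:] = np.exp(-dt / tau)
    for i in range(1, t.size):
        cfr[i] = d[i] * cfr[i - 1] + (1.0 - d[i]) / dt[i - 1]
    return CFRSeries(t, cfr, tau, d)


def adaptation_rate(y_c: float, y_inf: float) -> float:
    """AR in percent; NaN when the baseline ``y_inf + y_c`` is ~ 0."""
    denom = y_inf + y_c
    if abs(denom) < 1e-9:
        return float("nan")
    return (y_inf / denom - 1.0) * 100.0


def _exp_model(x, y_c, b, y_inf):
    # clip the exponent so wayward optimizer steps cannot overflow
    return y_c * np.exp(np.clip(b * x, -700.0, 700.0)) + y_inf


def fit_adaptation(
    feature_values: np.ndarray,
    cfr: np.ndarray,
    feature_name: str = "feature",
    n_starts: int = 5,
) -> AdaptationResult | None:
    """Least-squares fit of ``g(x) = y_c exp(b x) + y_inf`` to per-spike
    feature values versus cFR.

    Uses multi-start over the rate constant ``b`` (negative starts
    spanning the observed cFR range); returns ``None`` when no start
    converges.  NaN feature values (e.g. undefined trough–peak widths)
    are dropped before fitting.
    """
    y = np.asarray(feature_values, dtype=float)
    x = np.asarray(cfr, dtype=float)
    if y.shape != x.shape:
        raise ValueError("feature_values and cfr must have equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 10:
        raise ValueError("need at least 10 (cfr, feature) pairs")
    x_lo, x_hi = float(x.min()), float(x.max())
    if x_hi < 2.0 * max(x_lo, 1e-12):
        raise ValueError("cfr values must span at least a factor of 2")
    if np.ptp(y) == 0.0:
        # feature independent of rate: exact fit with a flat function
        return AdaptationResult(feature_name, 0.0, 0.0, float(y[0]), 0.0, 0.0, y.size)

    # initialization from the low/high-rate tails
    order = np.argsort(x)
    q = max(y.size // 4, 2)
    y_low = float(y[order[:q]].mean())
    y_high = float(y[order[-q:]].mean())
    y_inf0 = y_high
    y_c0 = y_low - y_high if y_low != y_high else float(np.ptp(y)) or 1.0

    scale = x_hi if x_hi > 0 else 1.0
    b_starts = -np.array([0.02, 0.1, 0.3, 0.6, 1.0])[:n_starts] / scale

    best = None
    for b0 in b_starts:
        try:
            popt, _ = curve_fit(
                _exp_model, x, y, p0=[y_c0, b0, y_inf0], maxfev=20_000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _exp_model(x, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        logger.warning("adaptation fit for %s did not converge", feature_name)
        return None
    (y_c, b, y_inf), rss = best

    # model selection against the flat (no-adaptation) model: near b = 0
    # the exponential is unidentifiable (only y_c + y_inf is constrained)
    # and least squares drifts along that valley, amplifying noise wiggles
    # into large spurious AR values.  Keep the exponential only when BIC
    # supports its two extra parameters; otherwise the feature does not
    # adapt and AR = 0 with y_inf at the feature mean.
    n = y.size
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    if rss <= 0 or (rss_flat > 0 and n * np.log(rss_flat / rss) <= 2.0 * np.log(n)):
        if rss > 0:
            return AdaptationResult(
                feature_name, 0.0, 0.0, float(y.mean()), 0.0, rss_flat, n
            )
    # identifiability guard: an exponential that is supported but whose
    # asymptote extrapolates far outside the observed feature range is
    # still unusable; flag it missing rather than report a wild AR
    span = float(np.ptp(y))
    if not (y.min() - span <= y_inf <= y.max() + span):
        logger.warning(
            "adaptation fit for %s non-identifiable (asymptote %.3g outside data)",
            feature_name,
            y_inf,
        )
        return None
    return AdaptationResult(
        feature_name,
        float(y_c),
        float(b),
        float(y_inf),
        adaptation_rate(float(y_c), float(y_inf)),
        rss,
        y.size,
    )


def boxplot_stats(values: np.ndarray) -> dict:
    """Median, quartiles and 1.5·IQR whiskers (Tukey convention)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()) if inside.size else float("nan"),
        "whisker_hi": float(inside.max()) if inside.size else float("nan"),
        "n": int(v.size),
        "n_outliers": int(v.size - inside.size),
    }


def compare_groups(groups: dict[str, np.ndarray], min_group_size: int = 3) -> list[dict]:
    """Pairwise two-tailed Mann–Whitney U tests between AR groups.

    Parameters
    ----------
    groups
        Mapping of group label (e.g. template type) to an array of AR
        values.  Groups with fewer than ``min_group_size`` finite values
        are skipped with a log message.

    Returns
    -------
    list of dict
        One row per pair: labels, sample sizes, U statistic, two-tailed
        p-value, and boxplot summaries for each side.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < min_group_size:
            logger.info("group %s skipped (%d values)", name, v.size)
            continue
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with enough values")
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(clean.items(), 2):
        u, p = mannwhitneyu(va, vb, alternative="two-sided")
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "n_a": int(va.size),
                "n_b": int(vb.size),
                "U": float(u),
                "p_two_tailed": float(p),
                "stats_a": boxplot_stats(va),
                "stats_b": boxplot_stats(vb),
            }
        )
    return rows
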