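"""Canonical EAP waveform types.

Four waveform classes are used throughout the pipeline, mirroring the
shapes typically recorded near somata and distal neurites:

- Type 1 — broad, essentially monophasic somatic spike (a deep negative
  peak; any positive deflection stays below 10% of the trough depth);
- Type 2 — broad biphasic somatic spike with a pronounced positive peak
  *after* the main negative peak;
- Type 3 — narrow triphasic neuritic spike whose *larger* positive peak
  precedes the main negative peak;
- Type 4 — narrow, symmetric triphasic neuritic spike (the classical
  distal-axon shape).

Each type is a parametric sum of Gaussian lobes: one negative lobe
(trough fixed at t = 0, relative depth −1) and 0–2 positive lobes.
Default lobe widths are calibrated so that the median shape features of
the two classes come out at the values reported for somatic and neuritic
averaged spikes: half-width 250 μs (somatic) / 130 μs (neuritic) and
trough–peak width 900 μs / 420 μs.  The analytic full width at half
maximum of a Gaussian of scale ``sigma`` is ``2*sigma*sqrt(2*ln 2)``,
which pins the negative-lobe sigmas; positive-lobe centers pin the
trough–peak widths.

A Tukey taper over the 2.5 ms support brings the waveform smoothly to
zero at the window edges so that rendered spikes do not introduce step
discontinuities into synthetic traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "SOURCE_KINDS",
    "SOMATIC_KINDS",
    "NEURITIC_KINDS",
    "GaussianLobe",
    "template_function",
    "template_lobes",
    "make_template_waveform",
    "DEFAULT_WINDOW_S",
]

#: Snippet / template support in seconds (2.5 ms).
DEFAULT_WINDOW_S = 2.5e-3

#: Fraction of the window tapered at each edge (Tukey alpha).
_TAPER_ALPHA = 0.15

# FWHM = 2 sigma sqrt(2 ln 2); invert for the class median half-widths.
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))
_SIGMA_SOMATIC_S = 250e-6 / _FWHM_FACTOR  # ≈ 106.2 μs
_SIGMA_NEURITIC_S = 130e-6 / _FWHM_FACTOR  # ≈ 55.2 μs

SOMATIC_KINDS = ("somatic_type1", "somatic_type2")
NEURITIC_KINDS = ("neuritic_type3", "neuritic_type4")
SOURCE_KINDS = SOMATIC_KINDS + NEURITIC_KINDS

#: source kind -> template type index (1–4)
KIND_TO_TYPE = {
    "somatic_type1": 1,
    "somatic_type2": 2,
    "neuritic_type3": 3,
    "neuritic_type4": 4,
}
TYPE_TO_KIND = {v: k for k, v in KIND_TO_TYPE.items()}


@dataclass(frozen=True)
class GaussianLobe:
    """One Gaussian lobe: ``amp * exp(-(t - center)^2 / (2 sigma^2))``."""

    amp: float  # relative amplitude (trough lobe is -1)
    center_s: float  # lobe center relative to the trough (s)
    sigma_s: float  # Gaussian scale (s)


_DEFAULT_LOBES: dict[str, tuple[GaussianLobe, ...]] = {
    # Broad monophasic: the small late positive hump stays below 10% of
    # the trough depth but is prominent enough to define a trough–peak
    # width at the somatic class median.
    "somatic_type1": (
        GaussianLobe(-1.0, 0.0, _SIGMA_SOMATIC_S),
        GaussianLobe(0.09, 900e-6, 300e-6),
    ),
    # Broad biphasic: pronounced positive peak after the trough.
    "somatic_type2": (
        GaussianLobe(-1.0, 0.0, _SIGMA_SOMATIC_S),
        GaussianLobe(0.45, 900e-6, 250e-6),
    ),
    # Narrow triphasic, larger positive peak before the trough.
    "neuritic_type3": (
        GaussianLobe(0.50, -380e-6, 110e-6),
        GaussianLobe(-1.0, 0.0, _SIGMA_NEURITIC_S),
        GaussianLobe(0.25, 420e-6, 110e-6),
    ),
    # Narrow symmetric triphasic.
    "neuritic_type4": (
        GaussianLobe(0.35, -420e-6, 120e-6),
        GaussianLobe(-1.0, 0.0, _SIGMA_NEURITIC_S),
        GaussianLobe(0.35, 420e-6, 120e-6),
    ),
}


def template_lobes(kind: str) -> tuple[GaussianLobe, ...]:
    """Return the default Gaussian-lobe parameters for ``kind``."""
    try:
        return _DEFAULT_LOBES[kind]
    except KeyError:
        raise ValueError(
            f"unknown source kind {kind!r}; expected one of {SOURCE_KINDS}"
        ) from None


def template_function(kind: str, lobes: tuple[GaussianLobe, ...] | None = None):
    """Return a vectorized callable ``f(t_s) -> relative amplitude``.

    ``t_s`` is time in seconds relative to the trough; the trough has
    relative amplitude −1 (plus negligible tails of positive lobes).
    The callable has infinite support; windowing and tapering are applied
    by :func:`make_template_waveform` and by the renderer.
    """
    if lobes is None:
        lobes = template_lobes(kind)
    amps = np.array([lb.amp for lb in lobes])
    centers = np.array([lb.center_s for lb in lobes])
    sigmas = np.array([lb.sigma_s for lb in lobes])

    def f(t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - centers) / sigmas
        return (amps * np.exp(-0.5 * z * z)).sum(axis=-1)

    return f


def window_taper(n_samples: int) -> np.ndarray:
    """Tukey taper applied over the template support."""
    return tukey(n_samples, alpha=_TAPER_ALPHA)


def make_template_waveform(
    kind: str,
    sampling_rate: float,
    window_s: float = DEFAULT_WINDOW_S,
    lobes: tuple[GaussianLobe, ...] | None = None,
    amplitude_uV: float = 1.0,
) -> np.ndarray:
    """Sample a canonical waveform on a regular grid.

    Parameters
    ----------
    kind
        One of ``somatic_type1``, ``somatic_type2``, ``neuritic_type3``,
        ``neuritic_type4``.
    sampling_rate
        Hz; at least 20 kHz so that the narrow neuritic trough is
        adequately sampled.
    window_s
        Total support (default 2.5 ms); the trough sits at the center
        sample.
    lobes
        Optional override of the lobe parameters.
    amplitude_uV
        Scale factor: the trough depth in μV (returned waveform has its
        minimum at ``-amplitude_uV`` up to positive-lobe tails).

    Returns
    -------
    numpy.ndarray
        Voltage vector of ``round(window_s * sampling_rate)`` samples.
    """
    if sampling_rate < 20_000:
        raise ValueError("sampling_rate must be at least 20 kHz")
    if window_s < DEFAULT_WINDOW_S - 1e-12:
        raise ValueError("window must cover at least 2.5 ms")
    f = template_function(kind, lobes)
    n = int(round(window_s * sampling_rate))
    t = (np.arange(n) - n // 2) / sampling_rate
    wf = f(t) * window_taper(n)
    return amplitude_uV * wf
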