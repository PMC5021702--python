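"""Screening, template matching and the soma-distance rule.

Averaged spikes are first screened by three constraints — negative peak
amplitude of at least 100 μV, RSTD below 1, and more than 100
contributing spikes — rejecting low-amplitude, sparse or multi-unit
recordings.  Each surviving average is assigned to one of four canonical
waveform types by maximum normalized cross-correlation against
amplitude-normalized templates (lags searched within ±0.25 ms); Types
1–2 count as somatic, Types 3–4 as neuritic.

Independently of waveform shape, a footprint can be labeled by geometry:
somatic when its representative electrode lies strictly within 50 μm of
the nearest soma, neuritic otherwise (also when no soma is known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hdmea_eap.features import WaveformFeatures
from hdmea_eap.templates import (
    DEFAULT_WINDOW_S,
    SOURCE_KINDS,
    make_template_waveform,
)

__all__ = [
    "TemplateSet",
    "ClassificationResult",
    "screen",
    "match_template",
    "distance_label",
    "population_summary",
    "SCREEN_MIN_AMPLITUDE_UV",
    "SCREEN_MAX_RSTD",
    "SCREEN_MIN_SPIKES",
    "SOMA_DISTANCE_UM",
    "DEFAULT_MAX_LAG_S",
]

logger = logging.getLogger(__name__)

SCREEN_MIN_AMPLITUDE_UV = 100.0
SCREEN_MAX_RSTD = 1.0
SCREEN_MIN_SPIKES = 100
SOMA_DISTANCE_UM = 50.0
DEFAULT_MAX_LAG_S = 0.25e-3

_SOMATIC_TYPES = (1, 2)


def _p2p_normalize(w: np.ndarray) -> np.ndarray:
    p2p = float(w.max() - w.min())
    if p2p <= 0:
        raise ValueError("flat waveform cannot be amplitude-normalized")
    return w / p2p


@dataclass(frozen=True)
class TemplateSet:
    """Four amplitude-normalized template waveforms on a common time base."""

    waveforms: dict[int, np.ndarray]  # type (1–4) -> peak-to-peak-normalized vector
    sampling_rate: float  # Hz

    def __post_init__(self):
        lengths = {w.size for w in self.waveforms.values()}
        if sorted(self.waveforms) != [1, 2, 3, 4] or len(lengths) != 1:
            raise ValueError("need templates 1–4 of equal length")

    @classmethod
    def defaults(
        cls, sampling_rate: float = 320_000.0, window_s: float = DEFAULT_WINDOW_S
    ) -> "TemplateSet":
        """The canonical synthetic waveform types, p2p-normalized."""
        waveforms = {
            i + 1: _p2p_normalize(make_template_waveform(kind, sampling_rate, window_s))
            for i, kind in enumerate(SOURCE_KINDS)
        }
        return cls(waveforms, float(sampling_rate))

    def to_csv(self, path) -> None:
        """4-column numeric CSV; the header carries the sample period."""
        df = pd.DataFrame({f"type_{k}": v for k, v in sorted(self.waveforms.items())})
        with open(path, "w") as fh:
            fh.write(f"# sample_period_us={1e6 / self.sampling_rate:.9g}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemplateSet":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# sample_period_us="):
                raise ValueError("template CSV must start with '# sample_period_us='")
            period_us = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        waveforms = {
            int(c.split("_")[1]): _p2p_normalize(df[c].to_numpy(float))
            for c in df.columns
        }
        return cls(waveforms, 1e6 / period_us)


@dataclass(frozen=True)
class ClassificationResult:
    """Template assignment of one averaged spike."""

    record_id: int
    assigned_type: int  # 1–4
    xcorr_scores: dict[int, float]  # per template, in [-1, 1]
    source_class: str  # 'somatic' (types 1–2) or 'neuritic' (types 3–4)
    distance_label: str = "unknown"  # geometry-based label when available


def screen(
    feats: WaveformFeatures,
    min_amplitude_uV: float = SCREEN_MIN_AMPLITUDE_UV,
    max_rstd: float = SCREEN_MAX_RSTD,
    min_spikes: int = SCREEN_MIN_SPIKES,
) -> bool:
    """Constraint screen for averaged spikes.

    Passes iff |amplitude| ≥ 100 μV, RSTD < 1 (strict) and the spike
    count strictly exceeds 100.
    """
    return bool(
        abs(feats.amplitude_uV) >= min_amplitude_uV
        and feats.rstd < max_rstd
        and feats.n_spikes > min_spikes
    )


def _lagged_cosine(w: np.ndarray, t: np.ndarray, lag: int) -> float:
    """Cosine similarity of ``w`` shifted by ``lag`` against ``t``
    (zero-padded shift; norms over the full vectors)."""
    n = w.size
    if lag >= 0:
        num = float(np.dot(w[: n - lag], t[lag:])) if lag < n else 0.0
    else:
        num = float(np.dot(w[-lag:], t[: n + lag])) if -lag < n else 0.0
    denom = float(np.linalg.norm(w) * np.linalg.norm(t))
    return num / denom if denom > 0 else 0.0


def match_template(
    waveform: np.ndarray,
    templates: TemplateSet,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    record_id: int = 0,
) -> ClassificationResult:
    """Assign a waveform to the template type with the highest
    normalized cross-correlation.

    The waveform is peak-to-peak normalized and its trough aligned to
    the template trough; the score per template is the maximum
    normalized cross-correlation over lags within ±0.25 ms.  Ties break
    toward the lower type index (logged).
    """
    w = _p2p_normalize(np.asarray(waveform, dtype=float))
    max_lag = int(round(max_lag_s * templates.sampling_rate))
    scores: dict[int, float] = {}
    for ttype, templ in sorted(templates.waveforms.items()):
        if templ.size != w.size:
            raise ValueError("waveform and templates must share the time base")
        base = int(np.argmin(templ)) - int(np.argmin(w))
        best = -1.0
        for lag in range(base - max_lag, base + max_lag + 1):
            best = max(best, _lagged_cosine(w, templ, lag))
        scores[ttype] = best
    top = max(scores.values())
    winners = [k for k, v in scores.items() if v == top]
    if len(winners) > 1:
        logger.warning(
            "template-match tie between types %s; taking type %d", winners, winners[0]
        )
    assigned = winners[0]
    source = "somatic" if assigned in _SOMATIC_TYPES else "neuritic"
    return ClassificationResult(record_id, assigned, scores, source)


def distance_label(
    position, soma_table, threshold_um: float = SOMA_DISTANCE_UM
) -> str:
    """Geometry label: 'somatic' iff the nearest soma is strictly within
    50 μm; 'neuritic' otherwise (including an empty soma table)."""
    soma = np.asarray(soma_table, dtype=float).reshape(-1, 2)
    if soma.size == 0:
        return "neuritic"
    d = np.hypot(*(soma - np.asarray(position, float)).T)
    return "somatic" if float(d.min()) < threshold_um else "neuritic"


def population_summary(
    results: list[ClassificationResult],
    groups: list | None = None,
) -> pd.DataFrame:
    """Per-type counts and fractions over screened records.

    ``groups`` optionally assigns each result to an experiment; per-group
    rows are emitted alongside a pooled row.  Fractions sum to 1.
    """
    if not results:
        raise ValueError("population_summary needs at least one result")
    if groups is None:
        groups = ["all"] * len(results)
    if len(groups) != len(results):
        raise ValueError("groups must match results")
    df = pd.DataFrame(
        {
            "group": groups,
            "type": [r.assigned_type for r in results],
            "source_class": [r.source_class for r in results],
        }
    )
    rows = []
    group_keys = list(dict.fromkeys(groups))
    pooled_keys = group_keys + (["pooled"] if len(group_keys) > 1 else [])
    for g in pooled_keys:
        sub = df if g == "pooled" else df[df["group"] == g]
        n = len(sub)
        row = {"group": g, "n_records": n}
        for t in (1, 2, 3, 4):
            c = int((sub["type"] == t).sum())
            row[f"count_type_{t}"] = c
            row[f"frac_type_{t}"] = c / n
        row["somatic_fraction"] = float((sub["source_class"] == "somatic").mean())
        row["neuritic_fraction"] = float((sub["source_class"] == "neuritic").mean())
        rows.append(row)
    return pd.DataFrame(rows)
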