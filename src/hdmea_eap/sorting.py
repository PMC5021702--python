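"""Spike sorting on three-electrode groups and STA footprints.

Sorting follows the overcluster-then-merge scheme: events detected on a
group of three neighboring electrodes are merged into multi-channel
events, aligned on the trough of the largest-amplitude channel, and the
concatenated three-channel snippets are projected onto principal
components and overclustered with K-means.  Miniclusters are then
aggregated with an interface-energy similarity metric (pairwise
similarity ``exp(-d_ij / sigma)`` summed between clusters and normalized
by the within-cluster similarities, with ``sigma`` the median
nearest-neighbor distance in PC space); pairs above the aggregation
criterion are merged iteratively, recomputing after each merge, until no
pair exceeds it.  Clusters are screened by their refractory-period
violation (RPV) fraction.

Footprints are spike-triggered averages across all electrodes of the
recording block, computed from wideband traces oversampled to 320 kHz
by band-limited (Fourier) interpolation.  The electrode whose STA has
the largest negative peak is the unit's representative electrode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from hdmea_eap.detection import SpikeEvents, extract_snippets

__all__ = [
    "SortedUnit",
    "Footprint",
    "align_and_stack",
    "cluster",
    "accept_units",
    "oversample",
    "footprint",
    "DEFAULT_N_PC",
    "DEFAULT_KMEANS_K",
    "DEFAULT_AGG_CRITERION",
    "DEFAULT_RPV_FLOOR_S",
    "DEFAULT_MERGE_WINDOW_S",
    "DEFAULT_OVERSAMPLE_RATE",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PC = 10
DEFAULT_KMEANS_K = 8
DEFAULT_AGG_CRITERION = 0.001
DEFAULT_RPV_FLOOR_S = 1.5e-3
DEFAULT_MERGE_WINDOW_S = 0.5e-3
DEFAULT_OVERSAMPLE_RATE = 320_000.0


@dataclass(frozen=True)
class SortedUnit:
    """One sorted unit: spike times and cluster-quality bookkeeping."""

    unit_id: int
    spike_times: np.ndarray  # s, strictly increasing
    member_event_ids: np.ndarray  # row indices into the stacked matrix
    rpv_fraction: float  # fraction of ISIs below the refractory floor


@dataclass(frozen=True)
class Footprint:
    """Spike-triggered-average waveforms of one unit on every electrode."""

    unit_id: int
    sta: np.ndarray  # (n_electrodes, n_samples) μV at sampling_rate
    sampling_rate: float  # Hz (oversampled)
    n_spikes: int
    representative_electrode: int  # electrode with the largest negative STA peak


def align_and_stack(
    events: list[SpikeEvents],
    traces: np.ndarray,
    sampling_rate: float,
    window_s: float = 2.5e-3,
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge events across three electrodes and stack aligned snippets.

    Events from different electrodes within 0.5 ms of each other are
    treated as one multi-channel event, aligned on the trough of the
    channel with the largest (deepest) amplitude.  Each output row is
    the three 2.5 ms snippets concatenated.

    Returns
    -------
    (matrix, align_indices)
        ``matrix`` has one row per multi-channel event and
        ``3 * window_samples`` columns; ``align_indices`` holds the
        alignment trough sample of each row.
    """
    if len(events) != 3:
        raise ValueError("spike sorting uses exactly 3 electrode event streams")
    if traces.shape[0] != 3:
        raise ValueError("need the 3 traces matching the event streams")
    n_w = int(round(window_s * sampling_rate))
    n_merge = int(round(merge_window_s * sampling_rate))

    pooled = []  # (trough_idx, channel, depth)
    for ch, ev in enumerate(events):
        for idx in ev.indices:
            pooled.append((int(idx), ch, float(traces[ch, idx])))
    if not pooled:
        return np.empty((0, 3 * n_w)), np.empty(0, dtype=int)
    pooled.sort()

    groups: list[list[tuple[int, int, float]]] = []
    for item in pooled:
        if groups and item[0] - groups[-1][-1][0] <= n_merge:
            groups[-1].append(item)
        else:
            groups.append([item])

    align_idx = []
    for grp in groups:
        deepest = min(grp, key=lambda it: it[2])  # most negative trace value
        align_idx.append(deepest[0])
    align_idx = np.asarray(sorted(set(align_idx)), dtype=int)

    rows = []
    kept_idx = []
    half = n_w // 2
    n_samples = traces.shape[1]
    for idx in align_idx:
        if idx - half < 0 or idx - half + n_w > n_samples:
            continue
        row = np.concatenate([traces[ch, idx - half : idx - half + n_w] for ch in range(3)])
        rows.append(row)
        kept_idx.append(idx)
    if not rows:
        return np.empty((0, 3 * n_w)), np.empty(0, dtype=int)
    return np.vstack(rows), np.asarray(kept_idx, dtype=int)


def _interface_connection(
    sim: np.ndarray, members: list[np.ndarray]
) -> np.ndarray:
    """Normalized interface-energy connection strength between clusters.

    ``sim`` is the full pairwise similarity matrix ``exp(-d/sigma)``.
    The between-cluster mean similarity is normalized by the geometric
    mean of the within-cluster mean similarities (diagonal excluded;
    singletons use self-similarity 1).
    """
    k = len(members)
    within = np.empty(k)
    for a in range(k):
        m = members[a]
        if m.size < 2:
            within[a] = 1.0
        else:
            block = sim[np.ix_(m, m)]
            within[a] = (block.sum() - m.size) / (m.size * (m.size - 1))
    conn = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            e_ab = sim[np.ix_(members[a], members[b])].mean()
            denom = np.sqrt(max(within[a] * within[b], 1e-300))
            conn[a, b] = conn[b, a] = e_ab / denom
    return conn


def cluster(
    stacked: np.ndarray,
    event_times_s: np.ndarray,
    n_pc: int = DEFAULT_N_PC,
    kmeans_k: int = DEFAULT_KMEANS_K,
    agg_criterion: float = DEFAULT_AGG_CRITERION,
    rpv_floor_s: float = DEFAULT_RPV_FLOOR_S,
    random_state: int = 0,
) -> list[SortedUnit]:
    """PCA → K-means overclustering → interface-energy aggregation.

    Miniclusters whose normalized interface energy exceeds
    ``agg_criterion`` are merged iteratively (recomputing after each
    merge) until no pair exceeds it.
    """
    X = np.asarray(stacked, dtype=float)
    t = np.asarray(event_times_s, dtype=float)
    if X.ndim != 2 or X.shape[0] != t.size:
        raise ValueError("stacked matrix rows and event times must match")
    n = X.shape[0]
    if n == 0:
        return []
    if n < kmeans_k:
        logger.warning("only %d events; reducing kmeans_k from %d", n, kmeans_k)
        kmeans_k = n
    n_pc_eff = min(n_pc, X.shape[1], n)
    pcs = PCA(n_components=n_pc_eff, random_state=random_state).fit_transform(X)
    labels = (
        KMeans(n_clusters=kmeans_k, n_init=10, random_state=random_state)
        .fit_predict(pcs)
        if kmeans_k > 1
        else np.zeros(n, dtype=int)
    )

    d = squareform(pdist(pcs))
    nn = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1) if n > 1 else np.array([1.0])
    sigma = float(np.median(nn))
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = 1.0
    # Gaussian similarity kernel: decays fast enough that clusters a few
    # noise widths apart stay below the 0.001 aggregation criterion,
    # while miniclusters tiling one unit stay far above it
    sim = np.exp(-0.5 * (d / sigma) ** 2)

    members = [np.flatnonzero(labels == c) for c in range(kmeans_k)]
    members = [m for m in members if m.size > 0]
    while len(members) > 1:
        conn = _interface_connection(sim, members)
        a, b = np.unravel_index(np.argmax(conn), conn.shape)
        if conn[a, b] <= agg_criterion:
            break
        merged = np.sort(np.concatenate([members[a], members[b]]))
        members = [m for i, m in enumerate(members) if i not in (a, b)] + [merged]

    units = []
    for uid, m in enumerate(sorted(members, key=lambda m: m[0])):
        st = np.sort(t[m])
        isi = np.diff(st)
        rpv = float((isi < rpv_floor_s).mean()) if isi.size else 0.0
        units.append(SortedUnit(uid, st, m, rpv))
    return units


def accept_units(
    units: list[SortedUnit], max_rpv: float = 0.01, min_spikes: int = 100
) -> list[SortedUnit]:
    """Automatic cluster-acceptance filter.

    Keeps well-isolated units: RPV fraction below ``max_rpv`` and at
    least ``min_spikes`` spikes.  (Codifies the conventionally manual
    cluster-evaluation step so runs are reproducible.)
    """
    kept = [
        u
        for u in units
        if u.rpv_fraction < max_rpv and u.spike_times.size >= min_spikes
    ]
    logger.info("accepted %d of %d sorted units", len(kept), len(units))
    return kept


def oversample(
    trace: np.ndarray,
    sampling_rate: float,
    target_rate: float = DEFAULT_OVERSAMPLE_RATE,
) -> np.ndarray:
    """Band-limited (Fourier) interpolation to an integer multiple rate.

    Original samples are reproduced exactly at their positions.
    """
    ratio = target_rate / sampling_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target_rate must be an integer multiple of sampling_rate")
    q = int(round(ratio))
    x = np.asarray(trace, dtype=float)
    if q == 1:
        return x.copy()
    return resample(x, x.size * q)


def footprint(
    unit: SortedUnit,
    wideband_traces: np.ndarray,
    sampling_rate: float,
    window_s: float = 2.5e-3,
    oversample_rate: float = DEFAULT_OVERSAMPLE_RATE,
    margin_s: float = 0.5e-3,
) -> Footprint:
    """Spike-triggered-average footprint of one unit.

    For every electrode, wideband snippets around the unit's spike times
    are averaged and the average is oversampled to ``oversample_rate``
    (averaging and band-limited interpolation commute, so this equals
    averaging oversampled snippets); a margin around the window absorbs
    interpolation edge effects before cropping.  Spike times that fall
    outside the traces are skipped with a logged count.
    """
    if unit.spike_times.size == 0:
        raise ValueError("unit has no spikes")
    n_w = int(round(window_s * sampling_rate))
    n_m = int(round(margin_s * sampling_rate))
    n_ext = n_w + 2 * n_m
    q = int(round(oversample_rate / sampling_rate))
    idx = np.round(unit.spike_times * sampling_rate).astype(int)

    n_el, n_samples = wideband_traces.shape
    half = n_ext // 2
    ok = (idx - half >= 0) & (idx - half + n_ext <= n_samples)
    if (~ok).any():
        logger.info("footprint: skipped %d spikes outside the traces", int((~ok).sum()))
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no spikes inside the traces")

    offsets = np.arange(n_ext)
    gather = (idx - half)[:, None] + offsets[None, :]
    stas = np.empty((n_el, n_w * q))
    for e in range(n_el):
        mean_ext = wideband_traces[e][gather].mean(axis=0)
        over = oversample(mean_ext, sampling_rate, oversample_rate)
        stas[e] = over[n_m * q : n_m * q + n_w * q]
    rep = int(np.argmax(-stas.min(axis=1)))
    return Footprint(
        unit_id=unit.unit_id,
        sta=stas,
        sampling_rate=float(oversample_rate),
        n_spikes=int(idx.size),
        representative_electrode=rep,
    )
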