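"""Synthetic ground-truth HDMEA recordings.

Emulates the statistical structure the analysis chain assumes:

- a hexagonally packed electrode layout (17.8 μm pitch by default);
- ground-truth units of four canonical waveform kinds, two somatic and
  two neuritic (:mod:`hdmea_eap.templates`);
- burst-structured spike trains with a 1 ms refractory floor;
- rate-dependent spike-shape adaptation: per spike, amplitude and width
  are modulated by an exponential function of the continuous firing
  rate, ``g(cFR) = y_c exp(b·cFR) + y_inf`` with ``g(0) = 1``;
- spatially decaying multi-electrode footprints — the waveform added at
  an electrode is scaled by ``exp(-distance/decay_constant)`` with a
  25 μm default decay constant, so signals vanish beyond ~100 μm;
- additive Gaussian noise band-limited to 25 Hz–3.5 kHz, emulating an
  on-chip recording filter.

All stochastic operations require an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from hdmea_eap.adaptation import continuous_firing_rate
from hdmea_eap.templates import (
    DEFAULT_WINDOW_S,
    KIND_TO_TYPE,
    NEURITIC_KINDS,
    SOMATIC_KINDS,
    SOURCE_KINDS,
    make_template_waveform,
    template_function,
    window_taper,
)

__all__ = [
    "ArrayLayout",
    "GroundTruthUnit",
    "SyntheticRecording",
    "make_layout",
    "make_spike_train",
    "render_recording",
    "make_population",
    "generate_population_recording",
    "DEFAULT_PITCH_UM",
    "DEFAULT_DECAY_UM",
    "DEFAULT_NOISE_SD_UV",
    "DEFAULT_ADAPTATION",
]

DEFAULT_PITCH_UM = 17.8
DEFAULT_DECAY_UM = 25.0
DEFAULT_NOISE_SD_UV = 10.0
#: on-chip analog band emulated for the noise floor (Hz)
CHIP_BAND_HZ = (25.0, 3500.0)
#: contributions below this are not rendered (μV at the electrode)
_RENDER_CUTOFF_UV = 0.25
#: physiological refractory floor for spike trains (s)
_REFRACTORY_S = 1e-3

#: default per-kind adaptation parameters, normalized so g(0) = 1.
#: Somatic spikes adapt strongly (amplitude AR −30%, width AR +10%),
#: the pre-trough-peak neuritic type mildly (−10%), and the narrow
#: symmetric neuritic type not at all — the distal-axon signature.
DEFAULT_ADAPTATION: dict[str, dict[str, tuple[float, float, float]]] = {
    "somatic_type1": {"amplitude": (0.3, -0.05, 0.7), "width": (-0.1, -0.05, 1.1)},
    "somatic_type2": {"amplitude": (0.3, -0.05, 0.7), "width": (-0.1, -0.05, 1.1)},
    "neuritic_type3": {"amplitude": (0.1, -0.05, 0.9), "width": (0.0, 0.0, 1.0)},
    "neuritic_type4": {"amplitude": (0.0, 0.0, 1.0), "width": (0.0, 0.0, 1.0)},
}


@dataclass(frozen=True)
class ArrayLayout:
    """Electrode ids and positions (μm) on a hexagonally packed grid."""

    electrode_id: np.ndarray  # (n,) contiguous ints from 0
    positions: np.ndarray  # (n, 2) x, y in μm
    pitch: float  # μm
    n_rows: int
    n_cols: int

    @property
    def n_electrodes(self) -> int:
        return self.electrode_id.size

    def distances_to(self, point) -> np.ndarray:
        """Euclidean distance (μm) from every electrode to ``point``."""
        return np.hypot(*(self.positions - np.asarray(point, float)).T)


@dataclass(frozen=True)
class GroundTruthUnit:
    """One signal source with known position, waveform and adaptation."""

    unit_id: int
    kind: str  # one of SOURCE_KINDS
    signal_origin: tuple[float, float]  # μm
    amplitude_uV: float  # trough depth at the origin, positive number
    soma_position: tuple[float, float] | None = None
    decay_constant_um: float = DEFAULT_DECAY_UM
    adaptation_params: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self):
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.amplitude_uV <= 0:
            raise ValueError("amplitude_uV must be positive (trough depth)")
        if self.kind in SOMATIC_KINDS:
            if self.soma_position is None:
                raise ValueError("somatic units need a soma_position")
            if _dist(self.signal_origin, self.soma_position) >= 50.0:
                raise ValueError("somatic signal origin must be within 50 μm of its soma")
        elif self.soma_position is not None:
            if _dist(self.signal_origin, self.soma_position) <= 50.0:
                raise ValueError("neuritic signal origin must be > 50 μm from any soma")

    @property
    def template_type(self) -> int:
        return KIND_TO_TYPE[self.kind]

    def base_waveform(self, sampling_rate: float) -> np.ndarray:
        """The unadapted waveform (μV) sampled at ``sampling_rate``."""
        return make_template_waveform(
            self.kind, sampling_rate, amplitude_uV=self.amplitude_uV
        )

    def adaptation_g(self, feature: str, cfr: np.ndarray) -> np.ndarray:
        """Per-spike modulation factor g(cFR)/g(0) for ``feature``."""
        params = (self.adaptation_params or DEFAULT_ADAPTATION[self.kind]).get(feature)
        if params is None:
            return np.ones_like(np.asarray(cfr, float))
        y_c, b, y_inf = params
        g0 = y_c + y_inf
        return (y_c * np.exp(b * np.asarray(cfr, float)) + y_inf) / g0


@dataclass
class SyntheticRecording:
    """Ground-truth container: traces plus everything used to make them."""

    layout: ArrayLayout
    sampling_rate: float  # Hz
    traces: np.ndarray  # (n_electrodes, n_samples) μV, float32
    units: list[GroundTruthUnit]
    true_spike_times: list[np.ndarray]  # per unit, sorted (s)
    soma_table: np.ndarray  # (n_somata, 2) μm
    noise_sd: float  # μV (before band-limiting)

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.sampling_rate


def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _filtfilt_noise_gain(sos, sampling_rate: float, n_freq: int = 4096) -> float:
    """SD ratio out/in for white noise through a zero-phase sos filter."""
    from scipy.signal import sosfreqz

    _, h = sosfreqz(sos, worN=n_freq, fs=sampling_rate)
    # forward-backward filtering squares the magnitude response
    power = np.mean(np.abs(h) ** 4)
    return float(np.sqrt(power))


def make_layout(
    n_rows: int, n_cols: int, pitch: float = DEFAULT_PITCH_UM
) -> ArrayLayout:
    """Hexagonally packed electrode grid.

    Rows are spaced ``pitch * sqrt(3)/2`` apart and alternate rows are
    offset by ``pitch / 2``, so every nearest-neighbor distance equals
    the pitch exactly.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be at least 1")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    x = (cols + 0.5 * (rows % 2)) * pitch
    y = rows * (pitch * np.sqrt(3.0) / 2.0)
    pos = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    ids = np.arange(pos.shape[0])
    return ArrayLayout(ids, pos, float(pitch), n_rows, n_cols)


def make_spike_train(
    duration_s: float,
    burst_rate_hz: float,
    intra_burst_rate_hz: float,
    burst_length: int,
    seed: int,
    dead_time_s: float = 2e-3,
) -> np.ndarray:
    """Burst-structured spike train.

    Burst onsets follow a Poisson process of rate ``burst_rate_hz``;
    each burst contains ``burst_length`` spikes whose inter-spike
    intervals are a refractory dead time plus an exponential of mean
    ``1/intra_burst_rate_hz`` (a dead-time-modified Poisson process —
    neurons do not fire at near-refractory intervals even inside
    bursts).  ``burst_length = 1`` gives a plain Poisson-like train.
    Spikes beyond ``duration_s`` are dropped and a global 1 ms
    refractory floor is enforced across overlapping bursts.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if burst_rate_hz <= 0 or intra_burst_rate_hz <= 0:
        raise ValueError("rates must be positive")
    if burst_length >= 2 and intra_burst_rate_hz <= burst_rate_hz:
        raise ValueError("intra-burst rate must exceed the burst rate")
    if dead_time_s < _REFRACTORY_S:
        raise ValueError("dead time cannot undercut the 1 ms refractory floor")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    times = []
    t = rng.exponential(1.0 / burst_rate_hz)
    while t < duration_s:
        isis = dead_time_s + rng.exponential(
            1.0 / intra_burst_rate_hz, size=burst_length - 1
        )
        spikes = t + np.concatenate([[0.0], np.cumsum(isis)])
        times.append(spikes)
        t += rng.exponential(1.0 / burst_rate_hz)
    if not times:
        return np.empty(0)
    all_t = np.sort(np.concatenate(times))
    all_t = all_t[all_t < duration_s]
    if all_t.size == 0:
        return all_t
    # global refractory floor (overlapping bursts)
    keep = np.ones(all_t.size, dtype=bool)
    last = all_t[0]
    for i in range(1, all_t.size):
        if all_t[i] - last < _REFRACTORY_S:
            keep[i] = False
        else:
            last = all_t[i]
    return all_t[keep]


def render_recording(
    layout: ArrayLayout,
    units: list[GroundTruthUnit],
    trains: list[np.ndarray],
    noise_sd: float,
    sampling_rate: float,
    seed: int,
    duration_s: float | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    tau_s: float = 0.1,
) -> SyntheticRecording:
    """Render units and spike trains into multichannel voltage traces.

    Every spike adds the unit's waveform to each electrode, scaled by
    ``exp(-distance/decay_constant)``; amplitude and width of the
    waveform are modulated per spike by the unit's adaptation parameters
    evaluated at the train's cFR.  Independent Gaussian noise, band
    limited to 25 Hz–3.5 kHz, is added per electrode.
    """
    if len(units) != len(trains):
        raise ValueError("need exactly one spike train per unit")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if duration_s is None:
        last = max((t[-1] for t in trains if len(t)), default=0.0)
        duration_s = last + window_s
    n_samples = int(round(duration_s * sampling_rate))
    n_w = int(round(window_s * sampling_rate))
    taper = window_taper(n_w)
    half = n_w // 2
    traces = np.zeros((layout.n_electrodes, n_samples), dtype=np.float32)

    for unit, train in zip(units, trains):
        train = np.asarray(train, float)
        if train.size == 0:
            continue
        if train.min() < 0 or train.max() >= duration_s:
            raise ValueError("every spike time must lie inside the recording")
        f = template_function(unit.kind)
        cfr = continuous_firing_rate(train, tau=tau_s).cfr
        amp_scale = unit.adaptation_g("amplitude", cfr)
        width_scale = unit.adaptation_g("width", cfr)
        dists = layout.distances_to(unit.signal_origin)
        weights = np.exp(-dists / unit.decay_constant_um)
        near = weights * unit.amplitude_uV >= _RENDER_CUTOFF_UV
        w_near = weights[near].astype(np.float32)
        idx_near = np.flatnonzero(near)
        for t_spike, a_s, w_s in zip(train, amp_scale, width_scale):
            i0 = int(round(t_spike * sampling_rate)) - half
            t_rel = (np.arange(i0, i0 + n_w) / sampling_rate) - t_spike
            wf = (unit.amplitude_uV * a_s) * f(t_rel / w_s) * taper
            lo = max(i0, 0)
            hi = min(i0 + n_w, n_samples)
            if hi <= lo:
                continue
            seg = wf[lo - i0 : hi - i0].astype(np.float32)
            traces[idx_near[:, None], np.arange(lo, hi)[None, :]] += (
                w_near[:, None] * seg[None, :]
            )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sos = butter(
            2,
            [CHIP_BAND_HZ[0], min(CHIP_BAND_HZ[1], 0.45 * sampling_rate)],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )
        # normalize the band-limiting power loss so the in-band noise
        # floor has sd exactly noise_sd (noise_sd is the noise seen in
        # the recording band, not of a hypothetical white process)
        gain = _filtfilt_noise_gain(sos, sampling_rate)
        for e in range(layout.n_electrodes):
            noise = rng.standard_normal(n_samples) * (noise_sd / gain)
            traces[e] += sosfiltfilt(sos, noise).astype(np.float32)

    soma_table = np.array(
        [u.soma_position for u in units if u.soma_position is not None], dtype=float
    ).reshape(-1, 2)
    return SyntheticRecording(
        layout=layout,
        sampling_rate=float(sampling_rate),
        traces=traces,
        units=list(units),
        true_spike_times=[np.asarray(t, float) for t in trains],
        soma_table=soma_table,
        noise_sd=float(noise_sd),
    )


def make_population(
    layout: ArrayLayout,
    n_somatic: int,
    n_neuritic: int,
    seed: int,
    somatic_amplitude_uV: tuple[float, float] = (150.0, 200.0),
    neuritic_amplitude_uV: tuple[float, float] = (110.0, 140.0),
    min_separation_um: float = 53.0,
    decay_constant_um: float = DEFAULT_DECAY_UM,
) -> list[GroundTruthUnit]:
    """Place a labeled unit population on the array.

    Signal origins sit on electrode positions (a unit is only countable
    by the per-electrode analysis if some electrode records it well), on
    a sparse site lattice (every ``ceil(min_separation/pitch)``-th
    column of every ``ceil(min_separation/row_spacing)``-th row) so that
    all units keep at least ``min_separation_um`` mutual distance and a
    unit's spikes stay subthreshold on other units' electrodes.
    Neuritic units occupy their own lattice rows, which puts every
    neuritic origin one full row spacing (> 55 μm here) from every
    somatic origin and therefore > 50 μm from every soma (somata sit
    within ~7 μm of their somatic origin).  Somatic units alternate
    Types 1/2, neuritic units Types 3/4.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    pos = layout.positions
    row_spacing = layout.pitch * np.sqrt(3.0) / 2.0
    row_step = int(np.ceil(min_separation_um / row_spacing))
    col_step = int(np.ceil(min_separation_um / layout.pitch))
    site_rows = list(range(0, layout.n_rows, row_step))
    site_cols = list(range(0, layout.n_cols, col_step))
    sites_per_row = len(site_cols)

    n_neuritic_rows = int(np.ceil(n_neuritic / sites_per_row)) if n_neuritic else 0
    if n_neuritic_rows + int(np.ceil(n_somatic / sites_per_row)) > len(site_rows):
        raise ValueError("could not place the requested population on this layout")
    neuritic_sites = [
        (r, c) for r in site_rows[:n_neuritic_rows] for c in site_cols
    ]
    somatic_sites = [
        (r, c) for r in site_rows[n_neuritic_rows:] for c in site_cols
    ]
    if len(somatic_sites) < n_somatic or len(neuritic_sites) < n_neuritic:
        raise ValueError("could not place the requested population on this layout")
    neuritic_at = [
        int(r * layout.n_cols + c)
        for r, c in (neuritic_sites[i] for i in rng.permutation(len(neuritic_sites))[:n_neuritic])
    ]
    somatic_at = [
        int(r * layout.n_cols + c)
        for r, c in (somatic_sites[i] for i in rng.permutation(len(somatic_sites))[:n_somatic])
    ]

    units: list[GroundTruthUnit] = []
    uid = 0
    for i, e in enumerate(somatic_at):
        kind = SOMATIC_KINDS[i % 2]
        origin = tuple(pos[e])
        offset = rng.uniform(-5.0, 5.0, size=2)
        soma = (origin[0] + offset[0], origin[1] + offset[1])
        amp = rng.uniform(*somatic_amplitude_uV)
        units.append(
            GroundTruthUnit(uid, kind, origin, amp, soma, decay_constant_um)
        )
        uid += 1
    for i, e in enumerate(neuritic_at):
        kind = NEURITIC_KINDS[i % 2]
        origin = tuple(pos[e])
        amp = rng.uniform(*neuritic_amplitude_uV)
        units.append(GroundTruthUnit(uid, kind, origin, amp, None, decay_constant_um))
        uid += 1
    return units


def generate_population_recording(
    layout: ArrayLayout,
    n_somatic: int,
    n_neuritic: int,
    duration_s: float,
    seed: int,
    burst_rate_hz: float = 0.7,
    intra_burst_rate_hz: float = 50.0,
    burst_length: int = 8,
    noise_sd: float = DEFAULT_NOISE_SD_UV,
    sampling_rate: float = 20_000.0,
) -> SyntheticRecording:
    """Population recording used by the end-to-end recovery studies."""
    rng = np.random.default_rng(seed)
    units = make_population(
        layout, n_somatic, n_neuritic, seed=int(rng.integers(2**31))
    )
    trains = [
        make_spike_train(
            duration_s - DEFAULT_WINDOW_S,
            burst_rate_hz,
            intra_burst_rate_hz,
            burst_length,
            seed=int(rng.integers(2**31)),
        )
        + DEFAULT_WINDOW_S / 2
        for _ in units
    ]
    return render_recording(
        layout,
        units,
        trains,
        noise_sd=noise_sd,
        sampling_rate=sampling_rate,
        seed=int(rng.integers(2**31)),
        duration_s=duration_s,
    )
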