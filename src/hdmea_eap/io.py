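"""Trace container, ground-truth tables and run configuration.

The trace container is an HDF5 file with a versioned logical schema:

- ``/traces``: float32 (n_electrodes, n_samples) voltage in μV;
- ``/layout/{electrode_id,x_um,y_um}``: the electrode table;
- root attributes: ``format_version``, ``sampling_rate_hz``,
  ``pitch_um``, ``n_rows``, ``n_cols``.

Round trips are bit-exact for float32 (hence for integer-quantized μV)
samples.  Ground truth is exported as plain CSVs (units.csv,
spikes.csv), and :class:`RunConfig` mirrors the analysis parameters
one-to-one in a YAML key-value file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from hdmea_eap.synthetic import ArrayLayout, SyntheticRecording

__all__ = [
    "FormatError",
    "RunConfig",
    "write_traces",
    "read_traces",
    "write_units_csv",
    "write_spikes_csv",
]

_FORMAT_VERSION = 1


class FormatError(Exception):
    """Malformed or truncated trace container."""


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the standard analysis values."""

    sampling_rate: float = 20_000.0  # Hz
    oversample_rate: float = 320_000.0  # Hz
    band_low_hz: float = 500.0
    band_high_hz: float = 3000.0
    threshold_k: float = 5.0  # detection threshold in noise SDs
    blank_s: float = 0.8e-3  # detector blanking
    window_s: float = 2.5e-3  # snippet window
    activity_min_hz: float = 0.2  # activity-map cut (strict)
    screen_min_amplitude_uV: float = 100.0
    screen_max_rstd: float = 1.0
    screen_min_spikes: int = 100
    soma_distance_um: float = 50.0
    tau_s: float = 0.1  # cFR decay constant
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def write_traces(
    path,
    traces: np.ndarray,
    layout: ArrayLayout,
    sampling_rate: float,
) -> None:
    """Write a recording to the HDF5 trace container."""
    traces = np.asarray(traces)
    if traces.ndim != 2 or traces.shape[0] != layout.n_electrodes:
        raise ValueError("traces must be (n_electrodes, n_samples)")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["sampling_rate_hz"] = float(sampling_rate)
        f.attrs["pitch_um"] = float(layout.pitch)
        f.attrs["n_rows"] = int(layout.n_rows)
        f.attrs["n_cols"] = int(layout.n_cols)
        f.create_dataset("traces", data=traces.astype(np.float32), chunks=True)
        g = f.create_group("layout")
        g.create_dataset("electrode_id", data=layout.electrode_id.astype(np.int64))
        g.create_dataset("x_um", data=layout.positions[:, 0])
        g.create_dataset("y_um", data=layout.positions[:, 1])


def read_traces(path) -> tuple[np.ndarray, ArrayLayout, float]:
    """Read a recording; raises :class:`FormatError` on malformed files."""
    try:
        with h5py.File(path, "r") as f:
            for attr in ("format_version", "sampling_rate_hz", "pitch_um", "n_rows", "n_cols"):
                if attr not in f.attrs:
                    raise FormatError(f"missing header attribute {attr!r}")
            if int(f.attrs["format_version"]) != _FORMAT_VERSION:
                raise FormatError(
                    f"unsupported format_version {f.attrs['format_version']}"
                )
            fs = float(f.attrs["sampling_rate_hz"])
            if fs <= 0:
                raise FormatError("sampling_rate_hz must be positive")
            if "traces" not in f or "layout" not in f:
                raise FormatError("missing 'traces' or 'layout'")
            traces = f["traces"][...]
            g = f["layout"]
            ids = g["electrode_id"][...]
            pos = np.column_stack([g["x_um"][...], g["y_um"][...]])
            if ids.size != traces.shape[0]:
                raise FormatError("layout size does not match trace count")
            layout = ArrayLayout(
                electrode_id=ids,
                positions=pos,
                pitch=float(f.attrs["pitch_um"]),
                n_rows=int(f.attrs["n_rows"]),
                n_cols=int(f.attrs["n_cols"]),
            )
    except OSError as exc:  # unreadable / truncated HDF5
        raise FormatError(f"not a readable trace container: {exc}") from exc
    return traces, layout, fs


def write_units_csv(path, recording: SyntheticRecording) -> None:
    """Ground-truth unit table: unit_id, kind, x, y, soma_x, soma_y."""
    rows = []
    for u in recording.units:
        rows.append(
            {
                "unit_id": u.unit_id,
                "kind": u.kind,
                "x_um": u.signal_origin[0],
                "y_um": u.signal_origin[1],
                "soma_x_um": u.soma_position[0] if u.soma_position else np.nan,
                "soma_y_um": u.soma_position[1] if u.soma_position else np.nan,
                "amplitude_uV": u.amplitude_uV,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def write_spikes_csv(path, recording: SyntheticRecording) -> None:
    """Ground-truth spike table: unit_id, time_s (≥ 9 significant digits)."""
    frames = [
        pd.DataFrame({"unit_id": u.unit_id, "time_s": t})
        for u, t in zip(recording.units, recording.true_spike_times)
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.9g"
    )
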