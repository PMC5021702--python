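#!/usr/bin/env python
"""Simulate a demo HDMEA recording with known ground truth.

Places 6 somatic (Types 1-2) and 2 neuritic (Types 3-4) units on a
12x12 hexagonal block (17.8 um pitch) and renders 25 s of bursty
activity with a 10 uV in-band noise floor at 20 kHz.  The traces go to
the scratch trace container (binary); the ground-truth unit and spike
tables go to results/ as CSVs.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hdmea_eap.io import write_spikes_csv, write_traces, write_units_csv  # noqa: E402
from hdmea_eap.synthetic import generate_population_recording, make_layout  # noqa: E402

SEED = 11


def main():
    layout = make_layout(12, 12)
    rec = generate_population_recording(
        layout, n_somatic=6, n_neuritic=2, duration_s=25.0, seed=SEED
    )
    scratch = ROOT / "scratch" / "demo"
    results = ROOT / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    write_traces(scratch / "recording.h5", rec.traces, layout, rec.sampling_rate)
    write_units_csv(results / "demo_units.csv", rec)
    write_spikes_csv(scratch / "demo_spikes.csv", rec)

    n_spikes = sum(t.size for t in rec.true_spike_times)
    print(f"rendered {layout.n_electrodes} electrodes x {rec.duration_s:.0f} s")
    print(f"{len(rec.units)} units ({len(rec.soma_table)} somatic), {n_spikes} spikes")
    print(f"traces -> {scratch / 'recording.h5'}")
    print(f"ground truth -> {results / 'demo_units.csv'}")


if __name__ == "__main__":
    main()
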