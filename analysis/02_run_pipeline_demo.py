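#!/usr/bin/env python
"""Run the full analysis pipeline on the simulated demo recording.

Reads the trace container written by 01_simulate_demo_recording.py,
runs detection -> activity map -> averaging -> screening -> template
matching -> distance labels -> adaptation -> sorting/footprint, and
copies the small summary tables into results/.  Large per-event tables
stay in scratch/.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hdmea_eap.io import RunConfig, read_traces  # noqa: E402
from hdmea_eap.pipeline import run_pipeline  # noqa: E402

SEED = 11


def main():
    scratch = ROOT / "scratch" / "demo"
    results = ROOT / "results"
    container = scratch / "recording.h5"
    if not container.exists():
        sys.exit("run analysis/01_simulate_demo_recording.py first")
    traces, layout, fs = read_traces(container)
    units = pd.read_csv(results / "demo_units.csv")
    soma = units.dropna(subset=["soma_x_um"])[["soma_x_um", "soma_y_um"]].to_numpy()

    outdir = scratch / "pipeline_run"
    report = run_pipeline(
        traces, layout, RunConfig(sampling_rate=fs, seed=SEED), outdir, soma_table=soma
    )

    for name in (
        "features.csv",
        "classification.csv",
        "population_summary.csv",
        "group_comparison.csv",
        "footprints.csv",
        "report.json",
    ):
        src = outdir / name
        if src.exists():
            shutil.copy(src, results / f"demo_{name}")

    print(f"events detected:      {report['n_events']}")
    print(f"active electrodes:    {report['n_active_electrodes']}")
    print(f"screened electrodes:  {report['n_screened_electrodes']}")
    print(f"somatic fraction:     {report.get('somatic_fraction', float('nan')):.2f}")
    print(f"footprint units:      {report['n_footprint_units']}")
    print(f"summaries -> {results}/demo_*.csv")


if __name__ == "__main__":
    main()
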