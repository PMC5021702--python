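"""Reproducible end-to-end studies on synthetic ground truth.

These drive the whole chain — generator → detection → averaging →
screening → template matching → adaptation — and compare the pipeline's
output against the generator's ground truth.  They are shared by the
test suite, the acceptance script and the numbered analysis drivers so
that all three report the same computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hdmea_eap.io import RunConfig
from hdmea_eap.pipeline import run_pipeline
from hdmea_eap.synthetic import generate_population_recording, make_layout

__all__ = ["RecoveryStudy", "ground_truth_recovery"]

# Study scale: a 28x14 hexagonal block (392 electrodes) holding 30 units
# with an 80/20 somatic/neuritic mix, recorded for 50 s.  Units sit on
# electrodes with >= 55 um mutual spacing so each is screened only at
# its own electrode; bursty trains (~0.7 bursts/s of 8 spikes at 50 Hz)
# give every unit a few hundred spikes spanning a wide cFR range.
DEFAULT_SCALE = dict(
    n_rows=14,
    n_cols=28,
    n_somatic=24,
    n_neuritic=6,
    duration_s=50.0,
)


@dataclass
class RecoveryStudy:
    """Ground-truth recovery results of one end-to-end run."""

    report: dict  # full pipeline report
    true_somatic_fraction: float
    recovered_somatic_fraction: float
    n_screened: int
    true_ar_percent: dict[str, float]  # generator amplitude-AR by kind
    ar_medians: dict[str, float]  # recovered per-type amplitude-AR medians
    somatic_vs_neuritic_p: float  # Mann-Whitney on amplitude AR


def ground_truth_recovery(
    seed: int,
    outdir,
    n_rows: int = DEFAULT_SCALE["n_rows"],
    n_cols: int = DEFAULT_SCALE["n_cols"],
    n_somatic: int = DEFAULT_SCALE["n_somatic"],
    n_neuritic: int = DEFAULT_SCALE["n_neuritic"],
    duration_s: float = DEFAULT_SCALE["duration_s"],
) -> RecoveryStudy:
    """Generate a labeled population, run the pipeline, compare."""
    layout = make_layout(n_rows, n_cols)
    rec = generate_population_recording(
        layout, n_somatic, n_neuritic, duration_s, seed=seed
    )
    config = RunConfig(seed=seed)
    report = run_pipeline(
        rec.traces,
        layout,
        config,
        outdir,
        soma_table=rec.soma_table,
    )
    true_frac = n_somatic / (n_somatic + n_neuritic)
    true_ar = {}
    for u in rec.units:
        g = u.adaptation_g("amplitude", np.array([1e9]))[0]  # asymptote
        true_ar[u.kind] = (g - 1.0) * 100.0
    p = float("nan")
    for row in report.get("group_comparisons", []):
        if {row["group_a"], row["group_b"]} == {"somatic", "neuritic"}:
            p = row["p_two_tailed"]
    return RecoveryStudy(
        report=report,
        true_somatic_fraction=true_frac,
        recovered_somatic_fraction=report.get("somatic_fraction", float("nan")),
        n_screened=report.get("n_screened_electrodes", 0),
        true_ar_percent=true_ar,
        ar_medians=report.get("amplitude_AR_medians", {}),
        somatic_vs_neuritic_p=p,
    )
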