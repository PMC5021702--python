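"""End-to-end analysis pipeline.

Stage order: detect → activity map → per-electrode averaged spikes →
features → screen → template match → distance label → adaptation →
group comparison → three-electrode sorting + STA footprint.  Every stage
writes a CSV into the output directory and appends itself to a MANIFEST
file, so a failed run retains all completed outputs; stage failures
abort with the stage name and cause.

Two classification paths coexist, mirroring how such recordings are
analyzed in practice:

- the *per-electrode* path needs no spike sorting: all spikes detected
  on an electrode are peak-aligned and averaged, the average is screened
  (≥ 100 μV, RSTD < 1, > 100 spikes) and template-matched — this path
  produces the population statistics (somatic/neuritic fractions) and
  the per-electrode adaptation rates;
- the *footprint* path sorts a three-electrode group around the most
  active electrode into units and builds their spike-triggered-average
  footprints across the whole block, labeling the representative
  electrode by the 50 μm soma-distance rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from hdmea_eap import classify as _classify
from hdmea_eap import detection as _detection
from hdmea_eap import features as _features
from hdmea_eap import sorting as _sorting
from hdmea_eap.adaptation import compare_groups, continuous_firing_rate, fit_adaptation
from hdmea_eap.io import RunConfig
from hdmea_eap.synthetic import ArrayLayout

__all__ = ["PipelineError", "ElectrodeRecord", "run_pipeline"]

logger = logging.getLogger(__name__)

_SNIPPET_MARGIN_SAMPLES = 10


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ElectrodeRecord:
    """Per-electrode averaging-path intermediate."""

    electrode_id: int
    spike_times_s: np.ndarray
    snippets: np.ndarray  # wideband, recording rate
    mean_spike: np.ndarray  # oversampled average
    feats: _features.WaveformFeatures


def _write_manifest(outdir, stages: list[str]) -> None:
    (outdir / "MANIFEST").write_text("\n".join(stages) + "\n")


def run_pipeline(
    traces: np.ndarray,
    layout: ArrayLayout,
    config: RunConfig,
    outdir,
    soma_table: np.ndarray | None = None,
    templates: _classify.TemplateSet | None = None,
) -> dict:
    """Run the full analysis on one recording block.

    Parameters
    ----------
    traces
        Wideband voltage traces, (n_electrodes, n_samples) in μV.
    layout
        Electrode geometry.
    config
        All analysis parameters (:class:`hdmea_eap.io.RunConfig`).
    outdir
        Output directory (created if missing) for stage CSVs, MANIFEST
        and report.json.
    soma_table
        Optional (n, 2) array of soma positions in μm for ground-truth
        distance labeling.
    templates
        Template set for matching; the canonical synthetic shapes when
        omitted.

    Returns
    -------
    dict
        The report: per-stage counts, the population summary, adaptation
        group comparisons and the footprint summary.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fs = config.sampling_rate
    duration_s = traces.shape[1] / fs
    completed: list[str] = []
    report: dict = {"duration_s": duration_s, "n_electrodes": int(traces.shape[0])}
    if templates is None:
        templates = _classify.TemplateSet.defaults(config.oversample_rate, config.window_s)

    def _finish_stage(name: str):
        completed.append(name)
        _write_manifest(outdir, completed)

    # --- detect ---------------------------------------------------------
    stage = "detect"
    try:
        filtered = np.empty_like(traces, dtype=np.float32)
        events: dict[int, _detection.SpikeEvents] = {}
        for e in range(traces.shape[0]):
            filtered[e] = _detection.bandpass(
                traces[e], fs, config.band_low_hz, config.band_high_hz
            )
            events[e] = _detection.detect_events(
                filtered[e],
                fs,
                k_threshold=config.threshold_k,
                blank_s=config.blank_s,
                window_s=config.window_s,
                electrode_id=e,
            )
        ev_df = _detection.events_dataframe(events)
        ev_df.to_csv(outdir / "events.csv", index=False, float_format="%.9g")
        report["n_events"] = int(len(ev_df))
        logger.info("detect: %d events on %d electrodes", len(ev_df), traces.shape[0])
        _finish_stage(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- activity map ---------------------------------------------------
    stage = "activity_map"
    try:
        amap = _detection.activity_map(events, duration_s, config.activity_min_hz)
        amap.to_csv(outdir / "activity_map.csv", index=False, float_format="%.9g")
        active_ids = amap.loc[amap["active"], "electrode_id"].to_numpy()
        report["n_active_electrodes"] = int(active_ids.size)
        logger.info("activity_map: %d active electrodes", active_ids.size)
        _finish_stage(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- per-electrode averaged spikes + features -----------------------
    stage = "features"
    try:
        n_w = int(round(config.window_s * fs))
        q = int(round(config.oversample_rate / fs))
        records: dict[int, ElectrodeRecord] = {}
        feat_rows = []
        for e in active_ids:
            ev = events[e]
            idx, wide = _detection.extract_snippets(
                traces[e], ev.indices, n_w + 2 * _SNIPPET_MARGIN_SAMPLES
            )
            if idx.size < 2:
                continue
            mean_ext = wide.mean(axis=0)
            over = _sorting.oversample(mean_ext, fs, config.oversample_rate)
            mean_spike = over[_SNIPPET_MARGIN_SAMPLES * q : (_SNIPPET_MARGIN_SAMPLES + n_w) * q]
            snips = wide[:, _SNIPPET_MARGIN_SAMPLES : _SNIPPET_MARGIN_SAMPLES + n_w]
            try:
                amp = _features.amplitude(mean_spike)
                hw = _features.half_width(mean_spike, 1e6 / config.oversample_rate)
                tpw = _features.trough_peak_width(mean_spike, 1e6 / config.oversample_rate)
            except ValueError:
                continue
            r = _features.rstd(snips)
            feats = _features.WaveformFeatures(amp, hw, tpw, r, idx.size)
            records[int(e)] = ElectrodeRecord(
                int(e), idx / fs, snips, mean_spike, feats
            )
            feat_rows.append(
                {
                    "electrode_id": int(e),
                    "amplitude_uV": amp,
                    "half_width_us": hw,
                    "trough_peak_width_us": tpw,
                    "rstd": r,
                    "n_spikes": idx.size,
                }
            )
        pd.DataFrame(
            feat_rows,
            columns=[
                "electrode_id",
                "amplitude_uV",
                "half_width_us",
                "trough_peak_width_us",
                "rstd",
                "n_spikes",
            ],
        ).to_csv(outdir / "features.csv", index=False, float_format="%.9g")
        report["n_averaged_electrodes"] = len(records)
        _finish_stage(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- screen + template match + distance label -----------------------
    stage = "classify"
    try:
        screened = {
            e: rec
            for e, rec in records.items()
            if _classify.screen(
                rec.feats,
                config.screen_min_amplitude_uV,
                config.screen_max_rstd,
                config.screen_min_spikes,
            )
        }
        report["n_screened_electrodes"] = len(screened)
        logger.info("screen: %d of %d electrodes pass", len(screened), len(records))
        results: dict[int, _classify.ClassificationResult] = {}
        cls_rows = []
        for e, rec in screened.items():
            res = _classify.match_template(rec.mean_spike, templates, record_id=e)
            if soma_table is not None:
                dl = _classify.distance_label(
                    layout.positions[e], soma_table, config.soma_distance_um
                )
                res = _classify.ClassificationResult(
                    res.record_id, res.assigned_type, res.xcorr_scores, res.source_class, dl
                )
            results[e] = res
            cls_rows.append(
                {
                    "electrode_id": e,
                    "assigned_type": res.assigned_type,
                    **{f"score_{k}": v for k, v in sorted(res.xcorr_scores.items())},
                    "source_class": res.source_class,
                    "distance_label": res.distance_label,
                }
            )
        pd.DataFrame(cls_rows).to_csv(
            outdir / "classification.csv", index=False, float_format="%.9g"
        )
        if results:
            summary = _classify.population_summary(list(results.values()))
            summary.to_csv(outdir / "population_summary.csv", index=False, float_format="%.9g")
            report["population_summary"] = summary.to_dict(orient="records")
            report["somatic_fraction"] = float(summary.iloc[-1]["somatic_fraction"])
        _finish_stage(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- adaptation ------------------------------------------------------
    stage = "adaptation"
    try:
        sp_us = 1e6 / fs
        adapt_rows = []
        ar_by_type: dict[str, list[float]] = {}
        ar_by_class: dict[str, list[float]] = {"somatic": [], "neuritic": []}
        for e, rec in screened.items():
            if rec.spike_times_s.size < 11:
                continue
            cfr = continuous_firing_rate(rec.spike_times_s, tau=config.tau_s).cfr
            # per-spike amplitude via matched-filter projection onto the
            # mean spike: linear in the data, so zero-mean noise cancels
            # instead of biasing a per-snippet minimum
            m = rec.snippets.mean(axis=0)
            scale = rec.snippets @ m / float(m @ m)
            per_spike = {
                "amplitude": np.abs(scale * m.min()),
                "half_width": np.array(
                    [_try_feature(_features.half_width, s, sp_us) for s in rec.snippets]
                ),
                "trough_peak_width": np.array(
                    [
                        _try_feature(_features.trough_peak_width, s, sp_us)
                        for s in rec.snippets
                    ]
                ),
            }
            for fname, vals in per_spike.items():
                try:
                    fit = fit_adaptation(vals[1:], cfr[1:], feature_name=fname)
                except ValueError:
                    fit = None
                if fit is None:
                    continue
                adapt_rows.append(
                    {
                        "electrode_id": e,
                        "feature": fname,
                        "y_c": fit.y_c,
                        "b_per_hz": fit.b,
                        "y_inf": fit.y_inf,
                        "AR_percent": fit.ar_percent,
                        "rss": fit.fit_rss,
                        "n_spikes": fit.n_spikes,
                        "assigned_type": results[e].assigned_type,
                    }
                )
                if fname == "amplitude" and np.isfinite(fit.ar_percent):
                    ar_by_type.setdefault(
                        f"type_{results[e].assigned_type}", []
                    ).append(fit.ar_percent)
                    ar_by_class[results[e].source_class].append(fit.ar_percent)
        adf = pd.DataFrame(
            adapt_rows,
            columns=[
                "electrode_id",
                "feature",
                "y_c",
                "b_per_hz",
                "y_inf",
                "AR_percent",
                "rss",
                "n_spikes",
                "assigned_type",
            ],
        )
        adf.to_csv(outdir / "adaptation.csv", index=False, float_format="%.9g")
        report["n_adaptation_fits"] = int(len(adf))
        comp_rows = []
        try:
            for row in compare_groups({k: np.array(v) for k, v in ar_by_class.items()}):
                comp_rows.append({"feature": "amplitude", **_flatten_comparison(row)})
            for row in compare_groups({k: np.array(v) for k, v in ar_by_type.items()}):
                comp_rows.append({"feature": "amplitude", **_flatten_comparison(row)})
        except ValueError:
            logger.info("group comparison skipped (not enough groups)")
        pd.DataFrame(comp_rows).to_csv(
            outdir / "group_comparison.csv", index=False, float_format="%.9g"
        )
        report["group_comparisons"] = comp_rows
        report["amplitude_AR_medians"] = {
            k: float(np.median(v)) for k, v in ar_by_type.items() if v
        }
        _finish_stage(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- sorting + footprint --------------------------------------------
    stage = "footprint"
    try:
        fp_rows = []
        if active_ids.size:
            rates = {e: events[e].n_events for e in active_ids}
            seed_el = max(rates, key=rates.get)
            d = layout.distances_to(layout.positions[seed_el])
            group = list(np.argsort(d)[:3])
            X, align_idx = _sorting.align_and_stack(
                [events[e] for e in group],
                filtered[group],
                fs,
                window_s=config.window_s,
            )
            if X.shape[0] >= 2:
                units = _sorting.cluster(
                    X, align_idx / fs, random_state=config.seed
                )
                kept = _sorting.accept_units(
                    units, min_spikes=config.screen_min_spikes
                )
                for u in kept:
                    fp = _sorting.footprint(
                        u,
                        traces,
                        fs,
                        window_s=config.window_s,
                        oversample_rate=config.oversample_rate,
                    )
                    rep = fp.representative_electrode
                    sta = fp.sta[rep]
                    try:
                        res = _classify.match_template(sta, templates, record_id=u.unit_id)
                        assigned = res.assigned_type
                    except ValueError:
                        assigned = -1
                    dl = (
                        _classify.distance_label(
                            layout.positions[rep], soma_table, config.soma_distance_um
                        )
                        if soma_table is not None
                        else "unknown"
                    )
                    fp_rows.append(
                        {
                            "unit_id": u.unit_id,
                            "n_spikes": fp.n_spikes,
                            "rpv_fraction": u.rpv_fraction,
                            "representative_electrode": rep,
                            "amplitude_uV": float(sta.min()),
                            "assigned_type": assigned,
                            "distance_label": dl,
                        }
                    )
        pd.DataFrame(
            fp_rows,
            columns=[
                "unit_id",
                "n_spikes",
                "rpv_fraction",
                "representative_electrode",
                "amplitude_uV",
                "assigned_type",
                "distance_label",
            ],
        ).to_csv(outdir / "footprints.csv", index=False, float_format="%.9g")
        report["n_footprint_units"] = len(fp_rows)
        report["footprints"] = fp_rows
        _finish_stage(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    _finish_stage("report")
    return report


def _try_feature(fn, snippet, sp_us) -> float:
    try:
        v = fn(snippet, sp_us)
        return v if v is not None else float("nan")
    except ValueError:
        return float("nan")


def _flatten_comparison(row: dict) -> dict:
    flat = {k: v for k, v in row.items() if not k.startswith("stats_")}
    for side in ("a", "b"):
        for key, val in row[f"stats_{side}"].items():
            flat[f"{key}_{side}"] = val
    return flat


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
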