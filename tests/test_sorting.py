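"""Sorting: event merging, clustering, oversampling, footprints."""

import numpy as np
import pytest

from hdmea_eap import sorting, synthetic, templates
from hdmea_eap.detection import SpikeEvents, detect_events
from hdmea_eap.synthetic import GroundTruthUnit, make_layout, render_recording

from conftest import aligned_train

FS = 20_000.0
N_W = 50


def _events(indices, trace, electrode_id=0):
    idx = np.asarray(indices, dtype=int)
    return SpikeEvents(
        electrode_id=electrode_id,
        times_s=idx / FS,
        indices=idx,
        snippets=np.zeros((idx.size, N_W)),
        threshold_uV=10.0,
    )


class TestAlignAndStack:
    def test_zero_events_empty_matrix(self):
        traces = np.zeros((3, 2000))
        X, idx = sorting.align_and_stack([_events([], traces[i], i) for i in range(3)], traces, FS)
        assert X.shape == (0, 3 * N_W) and idx.size == 0

    def test_one_spike_on_three_electrodes_merges(self):
        traces = np.zeros((3, 2000))
        wf = templates.make_template_waveform("somatic_type2", FS, amplitude_uV=100.0)
        tr = np.argmin(wf)
        for ch, (amp, jitter) in enumerate([(1.0, 0), (0.6, 1), (0.4, -1)]):
            traces[ch, 1000 + jitter - tr : 1000 + jitter - tr + wf.size] += amp * wf
        evs = [_events([1000 + j], traces[ch], ch) for ch, j in enumerate([0, 1, -1])]
        X, idx = sorting.align_and_stack(evs, traces, FS)
        assert X.shape == (1, 3 * N_W)
        assert idx[0] == 1000  # aligned on the deepest channel's trough

    def test_disjoint_units_keep_all_rows(self):
        traces = np.zeros((3, 20_000))
        wf = templates.make_template_waveform("neuritic_type4", FS, amplitude_uV=100.0)
        tr = np.argmin(wf)
        a_idx = np.arange(1000, 9000, 1000)
        b_idx = np.arange(1400, 9400, 1000)
        for i in a_idx:
            traces[0, i - tr : i - tr + wf.size] += wf
        for i in b_idx:
            traces[1, i - tr : i - tr + wf.size] += 0.7 * wf
        evs = [_events(a_idx, traces[0], 0), _events(b_idx, traces[1], 1), _events([], traces[2], 2)]
        X, idx = sorting.align_and_stack(evs, traces, FS)
        assert X.shape[0] == a_idx.size + b_idx.size

    def test_requires_three_streams(self):
        with pytest.raises(ValueError):
            sorting.align_and_stack([_events([], np.zeros(100))], np.zeros((1, 100)), FS)


def _two_cluster_data(rng, n=200, noise=5.0, sep_scale=1.0):
    ts20 = templates.make_template_waveform
    w1 = np.tile(ts20("somatic_type1", FS), 3) * 200 * sep_scale
    w2 = np.tile(ts20("neuritic_type4", FS), 3) * 90 * sep_scale
    X = np.vstack(
        [
            w1 + rng.normal(0, noise, (n, w1.size)),
            w2 + rng.normal(0, noise, (n, w2.size)),
        ]
    )
    times = np.concatenate(
        [np.sort(rng.uniform(0, 100, n)), np.sort(rng.uniform(0, 100, n))]
    )
    return X, times


class TestCluster:
    def test_two_separated_clusters_recovered(self, rng):
        X, times = _two_cluster_data(rng)
        units = sorting.cluster(X, times)
        assert len(units) == 2
        # zero misassignments vs brute-force nearest-centroid labels
        centroids = np.vstack([X[:200].mean(0), X[200:].mean(0)])
        brute = np.argmin(
            ((X[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        for u in units:
            assert len(set(brute[u.member_event_ids])) == 1
        assert sorted(u.member_event_ids.size for u in units) == [200, 200]

    def test_homogeneous_cluster_merges_to_one(self, rng):
        wf = np.tile(templates.make_template_waveform("somatic_type1", FS), 3) * 150
        X = wf + rng.normal(0, 5.0, (300, wf.size))
        units = sorting.cluster(X, np.sort(rng.uniform(0, 100, 300)), kmeans_k=8)
        assert len(units) == 1

    def test_identical_waveforms_merge_and_rpv_reflects_it(self, rng):
        wf = np.tile(templates.make_template_waveform("somatic_type1", FS), 3) * 150
        # two interleaved trains of the same waveform: indistinguishable
        t1 = np.arange(0.0, 2.0, 0.01)
        t2 = t1 + 0.0005  # 0.5 ms later -> constant refractory violations
        times = np.sort(np.concatenate([t1, t2]))
        X = wf + rng.normal(0, 5.0, (times.size, wf.size))
        units = sorting.cluster(X, times)
        assert len(units) == 1
        assert units[0].rpv_fraction > 0.4

    def test_scaling_invariance(self, rng):
        X, times = _two_cluster_data(rng)
        u1 = sorting.cluster(X, times)
        u2 = sorting.cluster(3.0 * X, times)
        assert len(u1) == len(u2)
        m1 = sorted(tuple(u.member_event_ids) for u in u1)
        m2 = sorted(tuple(u.member_event_ids) for u in u2)
        assert m1 == m2

    def test_fewer_rows_than_k(self, rng):
        X, times = _two_cluster_data(rng, n=3)
        units = sorting.cluster(X, times, kmeans_k=8)
        assert sum(u.member_event_ids.size for u in units) == 6

    def test_unit_count_recovery_over_seeds(self):
        # amplitude ratio >= 2 and distinct shapes: the 2-unit block is
        # recovered in >= 95% of seeded runs
        ok = 0
        n_runs = 50
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            X, times = _two_cluster_data(rng, n=150)
            ok += len(sorting.cluster(X, times, random_state=s)) == 2
        assert ok / n_runs >= 0.95


class TestOversample:
    def test_sinusoid_matches_analytic(self):
        t = np.arange(400) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        y = sorting.oversample(x, FS, 320_000.0)
        t16 = np.arange(y.size) / 320_000.0
        mid = slice(800, y.size - 800)  # away from edge effects
        assert np.abs(y[mid] - np.sin(2 * np.pi * 1000.0 * t16[mid])).max() < 0.01

    def test_constant_preserved(self):
        y = sorting.oversample(np.full(64, 3.5), FS, 320_000.0)
        assert np.allclose(y, 3.5, atol=1e-9)

    def test_length_and_exactness_at_original_samples(self, rng):
        x = rng.normal(size=50)
        y = sorting.oversample(x, FS, 320_000.0)
        assert y.size == 800
        assert np.abs(y[::16] - x).max() < 1e-9

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            sorting.oversample(np.zeros(50), FS, 50_000.0)


def _noise_free_recording(layout, n_spikes=20):
    u = GroundTruthUnit(
        0,
        "somatic_type2",
        tuple(layout.positions[20]),
        150.0,
        soma_position=tuple(layout.positions[20]),
        adaptation_params={"amplitude": (0.0, 0.0, 1.0), "width": (0.0, 0.0, 1.0)},
    )
    train = aligned_train(0.05, n_spikes, 0.05, FS)
    rec = render_recording(layout, [u], [train], 0.0, FS, seed=1)
    return rec, u, train


class TestFootprint:
    def test_sta_equals_rendered_waveform(self, small_layout):
        rec, u, train = _noise_free_recording(small_layout)
        unit = sorting.SortedUnit(0, train, np.arange(train.size), 0.0)
        fp = sorting.footprint(unit, rec.traces, FS)
        # original 20 kHz samples are preserved at every 16th position
        sta20 = fp.sta[fp.representative_electrode][::16]
        expected = u.base_waveform(FS)
        assert np.abs(sta20 - expected).max() < 1e-3

    def test_representative_electrode_is_origin(self, small_layout):
        rec, u, train = _noise_free_recording(small_layout)
        unit = sorting.SortedUnit(0, train, np.arange(train.size), 0.0)
        fp = sorting.footprint(unit, rec.traces, FS)
        assert fp.representative_electrode == 20
        depth = -fp.sta.min(axis=1)
        assert depth[fp.representative_electrode] == depth.max()

    def test_sta_noise_shrinks_as_sqrt_n(self, small_layout, rng):
        u_wf = templates.make_template_waveform("somatic_type2", FS, amplitude_uV=150.0)
        ratios = []
        for _ in range(5):
            resid = []
            for n in (25, 400):
                snips = u_wf + rng.normal(0, 10.0, (n, u_wf.size))
                resid.append((snips.mean(0) - u_wf).std())
            ratios.append(resid[0] / resid[1])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.2)

    def test_spikes_outside_traces_skipped(self, small_layout):
        rec, u, train = _noise_free_recording(small_layout)
        bad = np.concatenate([train, [rec.duration_s + 1.0]])
        unit = sorting.SortedUnit(0, bad, np.arange(bad.size), 0.0)
        fp = sorting.footprint(unit, rec.traces, FS)
        assert fp.n_spikes == train.size


class TestAcceptUnits:
    def test_rpv_and_count_filter(self):
        mk = lambda uid, n, rpv: sorting.SortedUnit(
            uid, np.linspace(0, 10, n), np.arange(n), rpv
        )
        units = [mk(0, 300, 0.0), mk(1, 300, 0.02), mk(2, 50, 0.0)]
        kept = sorting.accept_units(units)
        assert [u.unit_id for u in kept] == [0]
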