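"""Generator: layout geometry, waveform calibration, trains, rendering."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from hdmea_eap import features, synthetic, templates
from hdmea_eap.synthetic import (
    GroundTruthUnit,
    make_layout,
    make_population,
    make_spike_train,
    render_recording,
)

from conftest import aligned_train

FS = 20_000.0
OS = 320_000.0


class TestLayout:
    @pytest.mark.parametrize(
        "n_rows,n_cols,pitch",
        [(1, 2, 17.8), (12, 6, 17.8), (2, 2, 10.0)],
    )
    def test_nearest_neighbor_distance_equals_pitch(self, n_rows, n_cols, pitch):
        lay = make_layout(n_rows, n_cols, pitch)
        assert lay.n_electrodes == n_rows * n_cols
        d = pdist(lay.positions)  # brute force over all pairs
        assert d.min() == pytest.approx(pitch, abs=1e-6)
        # every electrode's nearest neighbor sits at exactly one pitch
        if lay.n_electrodes > 1:
            sq = np.full((lay.n_electrodes, lay.n_electrodes), np.inf)
            iu = np.triu_indices(lay.n_electrodes, 1)
            sq[iu] = d
            sq.T[iu] = d
            nn = sq.min(axis=1)
            assert np.allclose(nn, pitch, atol=1e-6)

    def test_hexagonal_row_geometry(self):
        lay = make_layout(3, 4, 10.0)
        pos = lay.positions.reshape(3, 4, 2)
        row_spacing = pos[1, 0, 1] - pos[0, 0, 1]
        assert row_spacing == pytest.approx(10.0 * np.sqrt(3) / 2)
        assert pos[1, 0, 0] - pos[0, 0, 0] == pytest.approx(5.0)  # offset row

    def test_ids_contiguous(self):
        lay = make_layout(4, 5)
        assert np.array_equal(lay.electrode_id, np.arange(20))

    @pytest.mark.parametrize("args", [(0, 3, 10.0), (3, 0, 10.0), (2, 2, -1.0)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_layout(*args)


class TestTemplateWaveforms:
    # class medians: half-width 250/130 us, trough-peak 900/420 us,
    # checked to within one sample period at 320 kHz
    TOL_US = 1e6 / OS

    @pytest.mark.parametrize(
        "kind,hw,tpw",
        [
            ("somatic_type1", 250.0, 900.0),
            ("somatic_type2", 250.0, 900.0),
            ("neuritic_type3", 130.0, 420.0),
            ("neuritic_type4", 130.0, 420.0),
        ],
    )
    def test_default_feature_calibration(self, kind, hw, tpw):
        wf = templates.make_template_waveform(kind, OS)
        sp = 1e6 / OS
        assert features.half_width(wf, sp) == pytest.approx(hw, abs=self.TOL_US)
        assert features.trough_peak_width(wf, sp) == pytest.approx(tpw, abs=self.TOL_US)

    def test_type1_is_monophasic(self):
        wf = templates.make_template_waveform("somatic_type1", OS)
        assert wf.max() <= 0.1 * abs(wf.min())
        # exactly one global negative extremum
        assert np.sum(wf == wf.min()) == 1

    def test_type_shapes(self):
        sp = {k: templates.make_template_waveform(k, OS) for k in templates.SOURCE_KINDS}
        for k, wf in sp.items():
            tr = np.argmin(wf)
            pre, post = wf[:tr].max(), wf[tr:].max()
            if k == "somatic_type2":
                assert post > 3 * max(pre, 1e-9)  # biphasic, late positive peak
            if k == "neuritic_type3":
                assert pre > post > 0  # larger positive peak before the trough
            if k == "neuritic_type4":
                assert pre == pytest.approx(post, rel=0.05)  # symmetric triphasic

    def test_unknown_kind_and_low_rate(self):
        with pytest.raises(ValueError):
            templates.make_template_waveform("axonal_type9", OS)
        with pytest.raises(ValueError):
            templates.make_template_waveform("somatic_type1", 10_000.0)


class TestSpikeTrain:
    def test_expected_count_over_seeds(self):
        # expectation of the process: duration * burst_rate * burst_length
        counts = [
            make_spike_train(10.0, 0.5, 100.0, 5, seed=s).size for s in range(100)
        ]
        mean = np.mean(counts)
        # bursts ~ Poisson(5): sd(count) ~ sqrt(5)*5; 3 sigma of the mean
        assert abs(mean - 25.0) < 3 * np.sqrt(5) * 5 / np.sqrt(100) + 2.0

    @pytest.mark.parametrize("burst_length", [1, 5])
    def test_refractory_floor(self, burst_length):
        t = make_spike_train(20.0, 2.0, 100.0, burst_length, seed=3)
        assert t.size > 0
        assert np.all(np.diff(t) >= 1e-3 - 1e-12)
        assert np.all(np.diff(t) > 0)

    def test_short_window_valid(self):
        t = make_spike_train(0.001, 0.5, 100.0, 5, seed=1)
        assert t.size >= 0 and np.all(t < 0.001)

    def test_determinism_and_errors(self):
        a = make_spike_train(5.0, 1.0, 50.0, 4, seed=9)
        b = make_spike_train(5.0, 1.0, 50.0, 4, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            make_spike_train(-1.0, 0.5, 100.0, 5, seed=1)
        with pytest.raises(ValueError):
            make_spike_train(5.0, 0.5, 100.0, 5, seed=None)
        with pytest.raises(ValueError):
            make_spike_train(5.0, 10.0, 5.0, 5, seed=1)  # intra <= burst rate


def _unit_at(layout, electrode, kind="neuritic_type4", amp=120.0, adapt=None):
    none_adapt = {"amplitude": (0.0, 0.0, 1.0), "width": (0.0, 0.0, 1.0)}
    return GroundTruthUnit(
        0,
        kind,
        tuple(layout.positions[electrode]),
        amp,
        soma_position=None if kind.startswith("neuritic") else tuple(layout.positions[electrode]),
        adaptation_params=adapt or none_adapt,
    )


class TestRender:
    def test_zero_noise_peak_at_origin(self, small_layout):
        u = _unit_at(small_layout, 20)
        train = aligned_train(0.05, 10, 0.05, FS)
        rec = render_recording(small_layout, [u], [train], 0.0, FS, seed=1)
        expected = u.base_waveform(FS).min()
        assert rec.traces[20].min() == pytest.approx(expected, rel=1e-6)

    def test_exponential_decay_law(self, small_layout):
        u = _unit_at(small_layout, 20)
        train = aligned_train(0.05, 5, 0.05, FS)
        rec = render_recording(small_layout, [u], [train], 0.0, FS, seed=1)
        d = small_layout.distances_to(u.signal_origin)
        e = int(np.argmin(np.abs(d - u.decay_constant_um)))
        ratio = rec.traces[e].min() / rec.traces[20].min()
        assert ratio == pytest.approx(np.exp(-d[e] / u.decay_constant_um), rel=1e-4)

    def test_amplitude_monotone_in_distance(self, small_layout):
        u = _unit_at(small_layout, 20, amp=5000.0)  # keep far electrodes above cutoff
        train = aligned_train(0.05, 5, 0.05, FS)
        rec = render_recording(small_layout, [u], [train], 0.0, FS, seed=1)
        d = small_layout.distances_to(u.signal_origin)
        order = np.argsort(d)
        peaks = -rec.traces[order].min(axis=1)
        assert np.all(np.diff(peaks) <= 1e-3)

    def test_determinism_and_validation(self, small_layout):
        u = _unit_at(small_layout, 10)
        train = aligned_train(0.05, 5, 0.05, FS)
        r1 = render_recording(small_layout, [u], [train], 10.0, FS, seed=4)
        r2 = render_recording(small_layout, [u], [train], 10.0, FS, seed=4)
        assert np.array_equal(r1.traces, r2.traces)
        with pytest.raises(ValueError):
            render_recording(small_layout, [u], [], 10.0, FS, seed=4)
        with pytest.raises(ValueError):
            render_recording(small_layout, [u], [train], -1.0, FS, seed=4)

    def test_adaptation_modulates_amplitude(self, small_layout):
        adapt = {"amplitude": (0.3, -0.05, 0.7), "width": (0.0, 0.0, 1.0)}
        u = _unit_at(small_layout, 20, kind="somatic_type1", amp=150.0, adapt=adapt)
        # rapid regular train: cFR rises, so later spikes must shrink
        train = aligned_train(0.05, 20, 0.02, FS)
        rec = render_recording(small_layout, [u], [train], 0.0, FS, seed=1)
        n_w = int(round(2.5e-3 * FS))
        idx = np.round(train * FS).astype(int)
        first = rec.traces[20][idx[0] - 5 : idx[0] + 5].min()
        last = rec.traces[20][idx[-1] - 5 : idx[-1] + 5].min()
        assert abs(last) < 0.85 * abs(first)


class TestUnitsAndPopulation:
    def test_unit_invariants(self, small_layout):
        with pytest.raises(ValueError):  # somatic without soma
            GroundTruthUnit(0, "somatic_type1", (0, 0), 100.0)
        with pytest.raises(ValueError):  # neuritic too close to a soma
            GroundTruthUnit(0, "neuritic_type4", (0, 0), 100.0, soma_position=(10, 0))
        u = GroundTruthUnit(0, "neuritic_type4", (0, 0), 100.0, soma_position=(60, 0))
        assert u.template_type == 4
        wf = u.base_waveform(FS)
        assert np.sum(wf == wf.min()) == 1  # one global negative extremum

    def test_population_separations(self):
        lay = synthetic.make_layout(14, 28)
        units = make_population(lay, 24, 6, seed=5)
        assert len(units) == 30
        origins = np.array([u.signal_origin for u in units])
        assert pdist(origins).min() >= 53.0 - 1e-9
        somas = np.array([u.soma_position for u in units if u.soma_position])
        for u in units:
            if u.kind.startswith("neuritic"):
                d = np.hypot(*(somas - np.array(u.signal_origin)).T)
                assert d.min() > 50.0
        kinds = {u.kind for u in units}
        assert kinds == set(templates.SOURCE_KINDS)
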