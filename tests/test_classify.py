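"""Screening boundaries, template matching, distance rule, summaries."""

import numpy as np
import pytest

from hdmea_eap import classify
from hdmea_eap.classify import ClassificationResult, TemplateSet
from hdmea_eap.features import WaveformFeatures


def _feats(amp, rstd, n):
    return WaveformFeatures(amp, 200.0, 500.0, rstd, n)


class TestScreen:
    @pytest.mark.parametrize(
        "amp,rstd,n,expected",
        [
            (-100.0, 0.5, 101, True),  # amplitude boundary is inclusive
            (-99.9, 0.1, 1000, False),
            (-300.0, 1.0, 1000, False),  # RSTD must be strictly below 1
            (-300.0, 0.999, 1000, True),
            (-150.0, 0.5, 100, False),  # spike count must strictly exceed 100
            (-150.0, 0.5, 101, True),
            (-100.0, 1.0, 101, False),
            (-100.0, 0.0, 0, False),
        ],
    )
    def test_boundary_table(self, amp, rstd, n, expected):
        assert classify.screen(_feats(amp, rstd, n)) is expected


class TestMatchTemplate:
    def test_self_match_perfect_score(self, templates_320k):
        for t, wf in templates_320k.waveforms.items():
            res = classify.match_template(wf, templates_320k)
            assert res.assigned_type == t
            assert res.xcorr_scores[t] == pytest.approx(1.0, abs=1e-9)
            assert all(-1 - 1e-9 <= s <= 1 + 1e-9 for s in res.xcorr_scores.values())

    def test_scale_invariance(self, templates_320k):
        res = classify.match_template(0.4 * templates_320k.waveforms[2], templates_320k)
        assert res.assigned_type == 2
        assert res.xcorr_scores[2] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("shift_ms", [-0.25, -0.1, 0.1, 0.25])
    def test_shift_invariance_within_lag_window(self, templates_320k, shift_ms):
        shift = int(round(shift_ms * 1e-3 * templates_320k.sampling_rate))
        for t, wf in templates_320k.waveforms.items():
            res = classify.match_template(np.roll(wf, shift), templates_320k)
            assert res.assigned_type == t

    def test_superclass_confusion_zero_noise_free(self, templates_320k):
        # noise-free default templates never cross the somatic/neuritic line
        for t, wf in templates_320k.waveforms.items():
            for scale in (0.3, 1.0, 4.0):
                res = classify.match_template(scale * wf, templates_320k)
                expected = "somatic" if t in (1, 2) else "neuritic"
                assert res.source_class == expected

    def test_noise_monte_carlo_accuracy(self, templates_20k):
        rng = np.random.default_rng(42)
        n, correct = 400, 0
        for i in range(n):
            t = 1 + i % 4
            templ = templates_20k.waveforms[t]
            noise = rng.normal(0, abs(templ.min()) / 10.0, templ.size)  # SNR 10
            res = classify.match_template(templ + noise, templates_20k)
            correct += res.assigned_type == t
        assert correct / n >= 0.95

    def test_flat_waveform_rejected(self, templates_320k):
        with pytest.raises(ValueError):
            classify.match_template(np.zeros(800), templates_320k)

    def test_source_class_follows_type(self, templates_320k):
        res = classify.match_template(templates_320k.waveforms[4], templates_320k)
        assert res.assigned_type == 4 and res.source_class == "neuritic"


class TestTemplateSetIO:
    def test_csv_round_trip(self, tmp_path, templates_320k):
        path = tmp_path / "templates.csv"
        templates_320k.to_csv(path)
        back = TemplateSet.from_csv(path)
        assert back.sampling_rate == pytest.approx(templates_320k.sampling_rate)
        for t in (1, 2, 3, 4):
            assert np.allclose(back.waveforms[t], templates_320k.waveforms[t], atol=1e-6)

    def test_invalid_set_rejected(self):
        with pytest.raises(ValueError):
            TemplateSet({1: np.zeros(10), 2: np.zeros(10)}, 20_000.0)


class TestDistanceLabel:
    @pytest.mark.parametrize(
        "soma,expected",
        [([(49.9, 0.0)], "somatic"), ([(50.0, 0.0)], "neuritic"), ([], "neuritic")],
    )
    def test_strict_50um_rule(self, soma, expected):
        assert classify.distance_label((0.0, 0.0), soma) == expected

    def test_nearest_soma_wins(self):
        soma = [(200.0, 0.0), (30.0, 10.0)]
        assert classify.distance_label((0.0, 0.0), soma) == "somatic"


def _result(i, t):
    return ClassificationResult(
        i, t, {k: float(k == t) for k in (1, 2, 3, 4)},
        "somatic" if t in (1, 2) else "neuritic",
    )


class TestPopulationSummary:
    def test_counting(self):
        results = [_result(i, 1) for i in range(50)] + [_result(i, 2) for i in range(36)]
        results += [_result(i, 3) for i in range(10)] + [_result(i, 4) for i in range(4)]
        s = classify.population_summary(results).iloc[0]
        assert s["somatic_fraction"] == pytest.approx(0.86)
        assert s["neuritic_fraction"] == pytest.approx(0.14)
        fracs = sum(s[f"frac_type_{t}"] for t in (1, 2, 3, 4))
        assert fracs == pytest.approx(1.0, abs=1e-12)

    def test_single_type(self):
        s = classify.population_summary([_result(i, 3) for i in range(5)]).iloc[0]
        assert s["frac_type_3"] == 1.0
        assert s["frac_type_1"] == s["frac_type_2"] == s["frac_type_4"] == 0.0

    def test_grouped_with_pooled_row(self):
        results = [_result(0, 1), _result(1, 1), _result(2, 4)]
        out = classify.population_summary(results, groups=["a", "a", "b"])
        assert list(out["group"]) == ["a", "b", "pooled"]
        assert out.iloc[-1]["somatic_fraction"] == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify.population_summary([])
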