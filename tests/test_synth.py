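"""Synthetic multi-subject ECG generation: morphology, noise, imbalance."""

import numpy as np
import pytest

from wavebeat import synth
from wavebeat.synth import (BASE_WAVES, CLASS_TEMPLATES, SynthConfig,
                            generate_dataset, render_beat, sample_subject)


def _fwhm(y, fs):
    """Full width at half maximum of the dominant positive bump, seconds."""
    peak = y.max()
    above = np.nonzero(y >= peak / 2)[0]
    return (above[-1] - above[0]) / fs


class TestSampleSubject:
    def test_zero_spread_reproduces_hyper_means(self):
        cfg = SynthConfig(between_subject_sd=0.0)
        subjects = [sample_subject(cfg, i) for i in range(5)]
        for s in subjects:
            for name, (amp, center, width) in BASE_WAVES.items():
                w = s.waves[name]
                assert (w.amplitude, w.center, w.width) == (amp, center, width)

    def test_r_amplitude_spread_tracks_tau(self):
        cfg = SynthConfig(between_subject_sd=0.2)
        amps = [sample_subject(cfg, i).waves["R"].amplitude
                for i in range(300)]
        nominal_sd = 0.2 * BASE_WAVES["R"][0]
        assert np.std(amps) == pytest.approx(nominal_sd, rel=0.2)

    def test_deterministic_given_seed_and_index(self):
        cfg = SynthConfig(between_subject_sd=0.3, seed=5)
        a = sample_subject(cfg, 7)
        b = sample_subject(cfg, 7)
        assert a == b
        assert a != sample_subject(cfg, 8)


class TestRenderBeat:
    def test_normal_beat_peaks_at_r_position(self):
        cfg = SynthConfig(between_subject_sd=0.0)
        subject = sample_subject(cfg, 0)
        y = render_beat(CLASS_TEMPLATES["N"], subject, fs=360.0)
        assert y.size == 252
        assert abs(int(np.argmax(y)) - 90) <= 1

    def test_ventricular_complex_at_least_twice_as_wide(self):
        cfg = SynthConfig(between_subject_sd=0.0)
        subject = sample_subject(cfg, 0)
        n = render_beat(CLASS_TEMPLATES["N"], subject, fs=360.0)
        v = render_beat(CLASS_TEMPLATES["V"], subject, fs=360.0)
        assert _fwhm(v, 360.0) >= 2 * _fwhm(n, 360.0)

    def test_class_templates_are_mutually_distinct(self):
        cfg = SynthConfig(between_subject_sd=0.0)
        subject = sample_subject(cfg, 0)
        beats = {lab: render_beat(t, subject, fs=360.0)
                 for lab, t in CLASS_TEMPLATES.items()}
        labs = sorted(beats)
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                assert np.abs(beats[a] - beats[b]).max() > 0.05

    def test_zero_amplitude_morphology_renders_flat(self):
        subject = synth.SubjectMorphology(waves={
            name: synth.Wave(0.0, c, w)
            for name, (_, c, w) in BASE_WAVES.items()
        })
        y = render_beat(CLASS_TEMPLATES["N"], subject, fs=360.0)
        assert np.all(y == 0.0)


class TestGenerateDataset:
    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SynthConfig(n_records=3, beats_per_record=30, seed=9)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        for (r1, a1), (r2, a2) in zip(d1, d2):
            assert np.array_equal(r1.samples, r2.samples)
            assert a1 == a2

    def test_majority_class_fraction_near_seventy_percent(self):
        cfg = SynthConfig(n_records=10, beats_per_record=1000, seed=3,
                          noise_sd=0.0, baseline_amp=0.0)
        total = n_count = 0
        for _, anns in generate_dataset(cfg):
            total += len(anns)
            n_count += sum(1 for a in anns if a.label == "N")
        p = 0.70
        sd = np.sqrt(p * (1 - p) / total)
        assert abs(n_count / total - p) <= 3 * sd

    def test_degenerate_config_gives_identical_beats_across_records(self):
        # A beats are excluded here: their shortened pre-beat gap moves
        # neighbouring wave tails into the window, which is rhythm (not
        # morphology) variation
        props = {"N": 0.6, "L": 0.1, "P": 0.1, "R": 0.1, "V": 0.1}
        cfg = SynthConfig(n_records=3, beats_per_record=40, seed=2,
                          class_proportions=props,
                          between_subject_sd=0.0, noise_sd=0.0,
                          baseline_amp=0.0, rr_jitter=0.0)
        windows = {}
        for record, anns in generate_dataset(cfg):
            for a in anns:
                w = record.samples[a.sample_index - 60:a.sample_index + 60]
                windows.setdefault(a.label, []).append(w)
        assert len(windows) >= 4
        for label, group in windows.items():
            ref = group[0]
            for w in group[1:]:
                assert np.abs(w - ref).max() < 1e-9, label

    def test_annotation_marks_local_r_maximum_when_noise_free(self):
        cfg = SynthConfig(n_records=2, beats_per_record=50, seed=4,
                          noise_sd=0.0, baseline_amp=0.0)
        for record, anns in generate_dataset(cfg):
            for a in anns:
                lo = a.sample_index - 18
                hi = a.sample_index + 18
                local_max = lo + int(np.argmax(record.samples[lo:hi]))
                assert abs(local_max - a.sample_index) <= 2

    def test_between_record_distance_increases_with_tau(self):
        def mean_pairwise_distance(tau):
            cfg = SynthConfig(n_records=6, beats_per_record=80, seed=6,
                              between_subject_sd=tau, noise_sd=0.0,
                              baseline_amp=0.0)
            means = []
            for record, anns in generate_dataset(cfg):
                ws = [record.samples[a.sample_index - 90:a.sample_index + 162]
                      for a in anns if a.label == "N"]
                means.append(np.mean(ws, axis=0))
            d = [np.linalg.norm(a - b)
                 for i, a in enumerate(means) for b in means[i + 1:]]
            return np.mean(d)

        d0, d1, d3 = (mean_pairwise_distance(t) for t in (0.0, 0.1, 0.3))
        assert d0 < d1 < d3

    def test_round_trip_through_io_module(self, tmp_path):
        from wavebeat.io import read_annotations, read_record
        cfg = SynthConfig(n_records=2, beats_per_record=20, seed=8)
        dataset = generate_dataset(cfg)
        synth.write_dataset(dataset, tmp_path)
        for record, anns in dataset:
            back = read_record(tmp_path / f"{record.record_id}.hea")
            assert np.abs(back.samples - record.samples).max() <= 0.5 / 200.0
            back_anns = read_annotations(tmp_path / f"{record.record_id}.atr")
            assert [(a.sample_index, a.label) for a in back_anns] == \
                [(a.sample_index, a.label) for a in anns]
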