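"""Generator properties: montage, templates, semi-Markov labels, EEG, studies."""

import numpy as np
import pytest

import eegmicrostates as ms
from eegmicrostates.synthetic import CLASS_D


class TestMontage:
    def test_default_30_contains_midline_channels(self, montage):
        for name in ("Fz", "Cz", "Pz"):
            assert name in montage.channel_names
        assert montage.n_channels == 30
        assert len(set(map(tuple, montage.positions))) == 30

    def test_positions_on_unit_sphere(self, montage):
        norms = np.linalg.norm(montage.positions, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_unknown_channel_raises(self):
        with pytest.raises(ms.ChannelNotFoundError):
            ms.make_montage(channel_names=["Fz", "XX99"])

    def test_deterministic(self):
        a = ms.make_montage(30)
        b = ms.make_montage(30)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_old_temporal_labels_resolve(self):
        m = ms.make_montage(channel_names=["T3", "T7"])
        np.testing.assert_allclose(m.positions[0], m.positions[1])


class TestTemplates:
    def test_average_referenced_unit_norm(self, templates):
        np.testing.assert_allclose(templates.maps.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(templates.maps, axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, montage):
        a = ms.make_templates(5, montage, seed=1)
        b = ms.make_templates(5, montage, seed=1)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_pairwise_separation(self, templates):
        k = templates.k
        sims = [ms.spatial_similarity(templates.maps[i], templates.maps[j])
                for i in range(k) for j in range(i)]
        assert max(sims) < 0.7

    @pytest.mark.parametrize("k", [1, 8])
    def test_k_out_of_range_rejected(self, montage, k):
        with pytest.raises(ms.ParameterError):
            ms.make_templates(k, montage, seed=0)

    def test_study_templates_anchor_to_canonical(self, montage, study_templates):
        canon = ms.canonical_templates(montage)
        for i in range(5):
            assert ms.spatial_similarity(
                study_templates.maps[i], canon.maps[i]) >= 0.75


class TestStateSequence:
    def test_mean_run_length_calibration(self):
        # >= 3 simulated minutes at a planted 80 ms mean
        cfg = ms.GeneratorConfig(duration_s=200.0,
                                 mean_durations_ms=(80.0,) * 5, seed=11)
        seq = ms.simulate_state_sequence(cfg)
        params = ms.true_parameters(seq.labels, cfg.sfreq, list("ABCDE"))
        mean_ms = params["duration_ms"].mean()
        assert abs(mean_ms - 80.0) / 80.0 < 0.10

    def test_uniform_successors(self):
        cfg = ms.GeneratorConfig(duration_s=300.0, seed=12)
        seq = ms.simulate_state_sequence(cfg)
        change = np.flatnonzero(np.diff(seq.labels) != 0) + 1
        runs = seq.labels[np.concatenate(([0], change))]
        k = cfg.n_classes
        for a in range(k):
            succ = runs[1:][runs[:-1] == a]
            n = succ.size
            freqs = np.bincount(succ, minlength=k) / n
            # binomial CI around 1/(k-1) for the allowed successors
            p = 1.0 / (k - 1)
            half = 4.0 * np.sqrt(p * (1 - p) / n)
            assert freqs[a] == 0.0
            for b in range(k):
                if b != a:
                    assert abs(freqs[b] - p) < half

    def test_runs_always_alternate(self):
        cfg = ms.GeneratorConfig(duration_s=30.0, seed=13)
        seq = ms.simulate_state_sequence(cfg)
        change = np.flatnonzero(np.diff(seq.labels) != 0) + 1
        runs = seq.labels[np.concatenate(([0], change))]
        assert np.all(np.diff(runs) != 0)

    def test_zero_duration_gives_empty_sequence(self):
        cfg = ms.GeneratorConfig(duration_s=0.0, seed=0)
        assert ms.simulate_state_sequence(cfg).n_samples == 0

    def test_gamma_law_calibration(self):
        cfg = ms.GeneratorConfig(duration_s=200.0, run_length_law="gamma",
                                 mean_durations_ms=(80.0,) * 5, seed=14)
        seq = ms.simulate_state_sequence(cfg)
        params = ms.true_parameters(seq.labels, cfg.sfreq, list("ABCDE"))
        assert abs(params["duration_ms"].mean() - 80.0) / 80.0 < 0.10


class TestSynthesizeEEG:
    def test_noiseless_peak_maps_match_templates(self, noiseless_recording,
                                                 templates):
        rec, seq = noiseless_recording
        series = ms.gfp(rec)
        for idx in series.peak_indices[:50]:
            sim = ms.spatial_similarity(rec.data[:, idx],
                                        templates.maps[seq.labels[idx]])
            assert sim > 1.0 - 1e-6

    def test_gfp_peak_rate_tracks_envelope(self, noiseless_recording):
        # |sin| at 10 Hz has two maxima per cycle -> about 20 peaks/s
        rec, _ = noiseless_recording
        series = ms.gfp(rec)
        rate = series.peak_indices.size / rec.duration_s
        assert 17.0 < rate < 23.0

    def test_average_reference_closure(self, noisy_recording):
        rec, _ = noisy_recording
        np.testing.assert_allclose(rec.data.mean(axis=0), 0.0, atol=1e-9)

    def test_label_alphabet_must_match_templates(self, templates):
        seq = ms.LabelSequence(labels=np.array([0, 5, 1]), sfreq=500.0)
        with pytest.raises(ms.ParameterError):
            ms.synthesize_eeg(seq, templates, ms.GeneratorConfig())

    def test_determinism(self, montage, templates):
        cfg = ms.GeneratorConfig(duration_s=2.0, seed=21)
        a, _ = ms.simulate_recording(cfg, templates, montage=montage)
        b, _ = ms.simulate_recording(cfg, templates, montage=montage)
        np.testing.assert_array_equal(a.data, b.data)


@pytest.fixture(scope="module")
def small_study():
    return ms.simulate_paired_study(n_subjects=6, effect_ms=6.0, rho=0.6,
                                    seed=5, synthesize=False)


class TestPairedStudy:

    def test_balanced_design(self, small_study):
        for subj in small_study.subjects:
            assert set(subj.true_labels) == {
                (sess, t) for sess in ("DMPFC", "DLPFC") for t in ("pre", "post")}
            for sess in ("DMPFC", "DLPFC"):
                assert 20.0 <= subj.stai[sess]["pre"] <= 80.0
                assert 20.0 <= subj.stai[sess]["post"] <= 80.0

    def test_planted_duration_scale(self):
        # group-mean true class-D duration: ~73 ms pre, ~79 ms post
        study = ms.simulate_paired_study(n_subjects=19, effect_ms=6.0,
                                         rho=0.0, seed=6, synthesize=False)
        pre = np.mean([s.true_durations[(sess, "pre")][CLASS_D]
                       for s in study.subjects for sess in study.sessions])
        post = np.mean([s.true_durations[(sess, "post")][CLASS_D]
                        for s in study.subjects for sess in study.sessions])
        assert abs(pre - 73.0) < 4.0
        # independent per-recording jitter around the planted +6 ms shift
        assert abs(post - pre - 6.0) < 2.0

    def test_rho_controls_planted_correlation(self):
        study = ms.simulate_paired_study(n_subjects=200, effect_ms=0.0,
                                         rho=0.6, seed=7, synthesize=False)
        d_trans = [s.true_delta_transition["DLPFC"] for s in study.subjects]
        d_stai = [s.stai["DLPFC"]["post"] - s.stai["DLPFC"]["pre"]
                  for s in study.subjects]
        r = np.corrcoef(d_trans, d_stai)[0, 1]
        assert abs(r - 0.6) < 0.15

    def test_invalid_rho_rejected(self):
        with pytest.raises(ms.ParameterError):
            ms.simulate_paired_study(n_subjects=3, effect_ms=0.0, rho=1.5, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ms.ParameterError):
            ms.simulate_paired_study(n_subjects=2, effect_ms=0.0, rho=0.0, seed=0)

    def test_determinism(self):
        a = ms.simulate_paired_study(n_subjects=3, seed=8, synthesize=False)
        b = ms.simulate_paired_study(n_subjects=3, seed=8, synthesize=False)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.stai == sb.stai
            for key in sa.true_labels:
                np.testing.assert_array_equal(sa.true_labels[key].labels,
                                              sb.true_labels[key].labels)
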