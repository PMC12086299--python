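"""GFP, spatial correlation, modified k-means, alignment, canonical naming."""

import numpy as np
import pytest

import eegmicrostates as ms
from eegmicrostates.clustering import (
    alignment_objective,
    brute_force_alignment_objective,
    _normalize_maps,
)


def _rec(data, sfreq=500.0):
    return ms.EEGRecording(data=np.asarray(data, dtype=float), sfreq=sfreq,
                           channel_names=[f"c{i}" for i in range(len(data))])


class TestGFP:
    def test_two_channel_antisymmetric_map(self):
        rec = _rec([[1.0], [-1.0]])
        assert ms.gfp(rec).values[0] == pytest.approx(1.0)

    def test_constant_map_zero(self):
        rec = _rec([[3.0], [3.0], [3.0]])
        assert ms.gfp(rec).values[0] == pytest.approx(0.0)

    def test_formula_hand_value(self):
        # map (3,-1,-1,-1): mean 0, sqrt(mean of squares) = sqrt(3)
        rec = _rec([[3.0], [-1.0], [-1.0], [-1.0]])
        assert ms.gfp(rec).values[0] == pytest.approx(np.sqrt(3.0), abs=1e-9)

    def test_peaks_are_strict_local_maxima(self, noisy_recording):
        rec, _ = noisy_recording
        series = ms.gfp(rec)
        v = series.values
        for p in series.peak_indices:
            assert v[p] > v[p - 1] and v[p] > v[p + 1]

    def test_peaks_do_not_cross_splices(self, noisy_recording):
        rec, _ = noisy_recording
        spliced = rec.copy(splice_boundaries=[rec.n_samples // 2])
        series = ms.gfp(spliced)
        # the first sample of each block can never be a peak
        assert rec.n_samples // 2 not in series.peak_indices


class TestSpatialCorrelation:
    def test_polarity_invariance(self):
        u = np.array([1.0, -0.5, 0.25, -0.75])
        assert ms.spatial_correlation(u, -u) == pytest.approx(-1.0)
        assert ms.spatial_similarity(u, -u) == pytest.approx(1.0)

    def test_self_correlation(self):
        u = np.array([1.0, -1.0, 2.0, -2.0])
        assert ms.spatial_correlation(u, u) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0, -1.0])
        assert ms.spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ms.DegenerateDataError):
            ms.spatial_correlation(np.ones(4), np.array([1.0, -1, 1, -1]))


def _mixture_peaks(templates, n_per_class=40, seed=0, noise=0.0):
    """Peak maps drawn noiselessly (or noisily) from a template set."""
    rng = np.random.default_rng(seed)
    maps, labels = [], []
    for c in range(templates.k):
        for _ in range(n_per_class):
            gain = rng.uniform(0.5, 2.0)
            sign = rng.choice([-1.0, 1.0])
            m = sign * gain * templates.maps[c]
            if noise:
                m = m + noise * rng.standard_normal(m.size)
            maps.append(m)
            labels.append(c)
    order = rng.permutation(len(maps))
    return np.array(maps)[order], np.array(labels)[order]


class TestModifiedKMeans:
    def test_noiseless_identifiability(self, templates):
        peaks, _ = _mixture_peaks(templates)
        fit = ms.modified_kmeans(peaks, k=5, n_restarts=5, seed=0)
        assert fit.gev > 0.999
        for row in fit.maps:
            best = max(ms.spatial_similarity(row, t) for t in templates.maps)
            assert best > 0.999

    def test_polarity_invariance_of_fit(self, templates):
        peaks, _ = _mixture_peaks(templates)
        doubled = np.vstack([peaks, -peaks])
        a = ms.modified_kmeans(peaks, k=5, n_restarts=3, seed=1)
        b = ms.modified_kmeans(doubled, k=5, n_restarts=3, seed=1)
        assert b.gev == pytest.approx(a.gev, abs=1e-6)
        for row_b in b.maps:
            assert max(ms.spatial_similarity(row_b, row_a) for row_a in a.maps
                       ) > 0.999

    def test_gev_monotone_in_k(self, templates):
        peaks, _ = _mixture_peaks(templates, noise=0.5, seed=3)
        fits = ms.fit_k_range(peaks, 4, 7, n_restarts=10, seed=2)
        assert [f.k for f in fits] == [4, 5, 6, 7]
        gevs = [f.gev for f in fits]
        assert gevs[-1] >= gevs[0] - 1e-6
        assert all(b >= a - 0.01 for a, b in zip(gevs, gevs[1:]))

    def test_too_few_peaks_rejected(self, templates):
        with pytest.raises(ms.ParameterError):
            ms.modified_kmeans(templates.maps[:3], k=5)

    def test_kmin_above_kmax_rejected(self, templates):
        peaks, _ = _mixture_peaks(templates)
        with pytest.raises(ms.ParameterError):
            ms.fit_k_range(peaks, 6, 4)

    def test_single_k_range(self, templates):
        peaks, _ = _mixture_peaks(templates)
        fits = ms.fit_k_range(peaks, 5, 5, n_restarts=3, seed=0)
        assert len(fits) == 1 and fits[0].k == 5

    def test_maps_zero_mean_unit_norm(self, templates):
        peaks, _ = _mixture_peaks(templates, noise=0.3, seed=4)
        fit = ms.modified_kmeans(peaks, k=5, n_restarts=3, seed=5)
        np.testing.assert_allclose(fit.maps.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(fit.maps, axis=1), 1.0,
                                   atol=1e-9)


class TestAlignment:
    def test_identical_sets_align_trivially(self, templates):
        sets = [templates, templates, templates]
        res = ms.align_across_subjects(sets)
        assert res.mean_shared_variance == pytest.approx(1.0, abs=1e-9)
        for perm in res.permutations:
            assert sorted(perm) == list(range(5))

    def test_planted_permutations_recovered(self, templates):
        rng = np.random.default_rng(6)
        sets, perms, signs = [], [], []
        for _ in range(10):
            perm = rng.permutation(5)
            sgn = rng.choice([-1.0, 1.0], size=5)
            sets.append(ms.TemplateSet(
                maps=templates.maps[perm] * sgn[:, None],
                labels=[str(i) for i in range(5)]))
            perms.append(perm)
            signs.append(sgn)
        res = ms.align_across_subjects(sets)
        assert res.mean_shared_variance == pytest.approx(1.0, abs=1e-9)
        # aligned maps agree across subjects up to sign handled by alignment
        for c in range(5):
            stack = np.array([s.maps[c] for s in res.aligned_sets])
            for row in stack[1:]:
                assert ms.spatial_correlation(stack[0], row) == pytest.approx(
                    1.0, abs=1e-9)

    def test_matches_brute_force_joint_optimum(self, montage):
        # 2 subjects, k=4: exhaustive joint search over all 576 pairings
        rng = np.random.default_rng(7)
        sets = []
        for seed in (21, 22):
            t = ms.make_templates(4, montage, seed=seed)
            noisy = t.maps + 0.2 * rng.standard_normal(t.maps.shape)
            sets.append(ms.TemplateSet(maps=_normalize_maps(noisy),
                                       labels=list("0123")))
        res = ms.align_across_subjects(sets)
        best = brute_force_alignment_objective(sets)
        assert res.mean_shared_variance == pytest.approx(best, abs=1e-9)

    def test_mixed_k_rejected(self, montage):
        a = ms.make_templates(4, montage, seed=1)
        b = ms.make_templates(5, montage, seed=1)
        with pytest.raises(ms.ParameterError):
            ms.align_across_subjects([a, b])


class TestGrandMean:
    def test_identical_inputs_reproduced(self, templates):
        res = ms.align_across_subjects([templates, templates])
        gm = ms.grand_mean(res)
        for c in range(5):
            assert ms.spatial_similarity(gm.maps[c],
                                         res.aligned_sets[0].maps[c]) > 1 - 1e-9

    def test_polarity_invariant_mean(self, templates):
        u = templates.maps[0]
        a = ms.TemplateSet(maps=u[None, :], labels=["0"])
        b = ms.TemplateSet(maps=-u[None, :], labels=["0"])
        gm = ms.grand_mean([a, b])
        assert ms.spatial_similarity(gm.maps[0], u) == pytest.approx(1.0)

    def test_grand_mean_centrality(self, montage, templates):
        # grand mean is at least as close to each subject as the farthest pair
        rng = np.random.default_rng(8)
        sets = []
        for _ in range(6):
            noisy = templates.maps + 0.25 * rng.standard_normal(templates.maps.shape)
            sets.append(ms.TemplateSet(maps=_normalize_maps(noisy),
                                       labels=[str(i) for i in range(5)]))
        res = ms.align_across_subjects(sets)
        gm = ms.grand_mean(res)
        for c in range(5):
            gm_sims = [ms.spatial_similarity(gm.maps[c], s.maps[c])
                       for s in res.aligned_sets]
            pair_sims = [ms.spatial_similarity(a.maps[c], b.maps[c])
                         for i, a in enumerate(res.aligned_sets)
                         for b in res.aligned_sets[:i]]
            assert min(gm_sims) >= min(pair_sims) - 1e-9


class TestCanonicalLabeling:
    def test_canon_matches_itself_identically(self, montage):
        canon = ms.canonical_templates(montage)
        labeled = ms.label_canonical(canon, canon)
        assert labeled.labels == canon.labels
        np.testing.assert_allclose(labeled.maps, canon.maps)

    def test_names_invariant_to_input_order(self, montage):
        canon = ms.canonical_templates(montage)
        perm = [3, 0, 4, 1, 2]
        shuffled = canon.reordered(perm, labels=[str(i) for i in range(5)])
        labeled = ms.label_canonical(shuffled, canon)
        assert labeled.labels == ["A", "B", "C", "D", "E"]
        for name, row in zip(labeled.labels, labeled.maps):
            idx = canon.labels.index(name)
            assert ms.spatial_similarity(row, canon.maps[idx]) > 1 - 1e-9

    def test_noisy_copies_named_correctly(self, montage):
        rng = np.random.default_rng(9)
        canon = ms.canonical_templates(montage)
        noisy = canon.maps + 0.05 * rng.standard_normal(canon.maps.shape)
        tset = ms.TemplateSet(maps=_normalize_maps(noisy),
                              labels=[str(i) for i in range(5)])
        for i in range(5):
            assert ms.spatial_similarity(tset.maps[i], canon.maps[i]) > 0.9
        labeled = ms.label_canonical(tset, canon)
        assert labeled.labels == ["A", "B", "C", "D", "E"]

    def test_smallest_k_with_cd_rule(self, montage):
        canon = ms.canonical_templates(montage)
        # a 4-class set missing D and the full 5-class set: rule keeps k=5
        no_d = ms.TemplateSet(maps=canon.maps[[0, 1, 2, 4]],
                              labels=list("0123"))
        full = ms.TemplateSet(maps=canon.maps, labels=list("01234"))
        chosen = ms.select_k_with_cd([no_d, full], canon)
        assert chosen.k == 5
        assert set(chosen.labels) >= {"C", "D"}


class TestEndToEndPolarity:
    def test_recording_negation_changes_nothing_downstream(self, montage,
                                                           templates):
        cfg = ms.GeneratorConfig(duration_s=20.0, seed=31)
        rec, _ = ms.simulate_recording(cfg, templates, montage=montage)
        rec = ms.average_reference(ms.bandpass(rec, 2.0, 20.0))
        flipped = rec.copy(data=-rec.data)
        seg_a = ms.backfit(rec, templates)
        seg_b = ms.backfit(flipped, templates)
        np.testing.assert_array_equal(seg_a.labels, seg_b.labels)
        pa = ms.compute_parameters(seg_a)
        pb = ms.compute_parameters(seg_b)
        np.testing.assert_allclose(pa.to_numpy(), pb.to_numpy())
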