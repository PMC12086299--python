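"""Self-validation experiments: ground-truth recovery, oracles, power.

Each function simulates data with planted structure, runs the relevant
pipeline stages from scratch, and returns summary numbers. They are the
backbone of the acceptance checks and of the reproduction script; sizes
are chosen to give stable Monte-Carlo estimates on a single CPU within
minutes (the methods note records the problem sizes).
"""

from __future__ import annotations

import time
from itertools import product as iter_product

import numpy as np
from scipy import stats as sp_stats

from .backfitting import backfit, compute_parameters, true_parameters
from .clustering import (
    brute_force_alignment_objective,
    _normalize_maps,
    align_across_subjects,
    modified_kmeans,
    spatial_similarity,
)
from .containers import GeneratorConfig, TemplateSet
from .pipeline import PipelineConfig, analyze_recording, fit_templates, process_study_from_truth
from .preprocessing import average_reference, bandpass
from .stats import benjamini_hochberg, pearson_change_correlation, wilcoxon_signed_rank_exact
from .synthetic import (
    _biased_transition_matrix,
    make_montage,
    make_study_templates,
    make_templates,
    simulate_paired_study,
    simulate_recording,
    simulate_state_sequence,
)
from .transitions import transition_stats, transition_stats_from_runs
from .containers import Segmentation


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


# ---------------------------------------------------------------------------
# parameter recovery through the full pipeline
# ---------------------------------------------------------------------------


def parameter_recovery(seed: int = 0, n_recordings: int = 10,
                       duration_s: float = 120.0) -> dict:
    """Full-pipeline recovery of planted duration/occurrence/contribution.

    Simulates ``n_recordings`` five-class 30-channel recordings sharing one
    canonical-anchored template set, runs band-pass -> average reference ->
    per-recording clustering -> alignment -> grand mean -> canonical naming
    -> backfitting, and compares group-mean parameters against the planted
    values (durations) / ground-truth label sequences (occurrence,
    contribution).
    """
    t_start = time.perf_counter()
    montage = make_montage(30)
    seeds = _child_seeds(seed, n_recordings + 1)
    base = make_study_templates(montage, seed=seeds[-1])
    planted = None
    recs, seqs = [], []
    for s in seeds[:-1]:
        cfg = GeneratorConfig(duration_s=duration_s, seed=s)
        planted = np.array(cfg.mean_durations_ms)
        rec, seq = simulate_recording(cfg, base, montage=montage)
        recs.append(average_reference(bandpass(rec, 2.0, 20.0)))
        seqs.append(seq)
    config = PipelineConfig(skip_artifact_screening=True, seed=seed)
    grand, _ = fit_templates(recs, config, montage=montage)
    fitted, true_occ, true_con = [], [], []
    for rec, seq in zip(recs, seqs):
        params, _ = analyze_recording(rec, grand, config)
        fitted.append(params)
        tp = true_parameters(seq.labels, rec.sfreq, list("ABCDE"))
        true_occ.append(tp["occurrence_per_s"].to_numpy())
        true_con.append(tp["contribution"].to_numpy())
    mean_fit = sum(fitted) / len(fitted)
    dur = mean_fit["duration_ms"].to_numpy()
    occ = mean_fit["occurrence_per_s"].to_numpy()
    con = mean_fit["contribution"].to_numpy()
    true_occ = np.mean(true_occ, axis=0)
    true_con = np.mean(true_con, axis=0)
    return {
        "duration_max_rel_err": float(np.max(np.abs(dur - planted) / planted)),
        "occurrence_max_rel_err": float(
            np.max(np.abs(occ - true_occ) / true_occ)),
        "contribution_max_abs_err": float(np.max(np.abs(con - true_con))),
        "grand_mean_gev": float(grand.gev),
        "runtime_s": float(time.perf_counter() - t_start),
        "n": n_recordings,
    }


# ---------------------------------------------------------------------------
# clustering and alignment oracles
# ---------------------------------------------------------------------------


def clustering_oracle(seed: int = 0, n_per_class: int = 60) -> dict:
    """Noiseless identifiability and polarity invariance of modified k-means."""
    montage = make_montage(30)
    templates = make_templates(5, montage, seed=seed)
    rng = np.random.default_rng(seed + 1)
    maps, labels = [], []
    for c in range(5):
        for _ in range(n_per_class):
            maps.append(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
                        * templates.maps[c])
            labels.append(c)
    maps = np.array(maps)
    fit = modified_kmeans(maps, k=5, n_restarts=5, seed=seed)
    sims = [max(spatial_similarity(row, t) for t in templates.maps)
            for row in fit.maps]
    flipped = modified_kmeans(-maps, k=5, n_restarts=5, seed=seed)
    return {
        "gev": float(fit.gev),
        "min_template_similarity": float(min(sims)),
        "polarity_gev_diff": float(abs(fit.gev - flipped.gev)),
        "n": int(maps.shape[0]),
    }


def alignment_oracle(seed: int = 0) -> dict:
    """Alignment optimizer vs exhaustive joint search, and planted recovery."""
    montage = make_montage(30)
    rng = np.random.default_rng(seed)
    # 2 subjects, k = 4: exhaustive search over the 576 joint permutations
    sets = []
    for s in (seed + 10, seed + 11):
        t = make_templates(4, montage, seed=s)
        noisy = t.maps + 0.2 * rng.standard_normal(t.maps.shape)
        sets.append(TemplateSet(maps=_normalize_maps(noisy),
                                labels=list("0123")))
    res = align_across_subjects(sets)
    gap = brute_force_alignment_objective(sets) - res.mean_shared_variance
    # 10 subjects, k = 5: planted permutations and sign flips
    base = make_templates(5, montage, seed=seed + 20)
    planted_sets = []
    for _ in range(10):
        perm = rng.permutation(5)
        sgn = rng.choice([-1.0, 1.0], size=5)
        planted_sets.append(TemplateSet(maps=base.maps[perm] * sgn[:, None],
                                        labels=list("01234")))
    res10 = align_across_subjects(planted_sets)
    worst = 1.0
    for c in range(5):
        stack = np.array([s.maps[c] for s in res10.aligned_sets])
        for row in stack[1:]:
            worst = min(worst, float(stack[0] @ row /
                                     (np.linalg.norm(stack[0]) * np.linalg.norm(row))))
    return {
        "objective_gap_vs_bruteforce": float(gap),
        "planted_recovery_min_corr": float(worst),
        "planted_shared_variance": float(res10.mean_shared_variance),
        "n": 576,
    }


# ---------------------------------------------------------------------------
# transition null and planted enrichment
# ---------------------------------------------------------------------------


def transition_null(seed: int = 0, n_sequences: int = 200,
                    n_runs: int = 600) -> dict:
    """Mean deviation under the occurrence-matched (uniform) null, in MC SEs."""
    rng = np.random.default_rng(seed)
    devs = []
    for _ in range(n_sequences):
        runs = [int(rng.integers(5))]
        steps = rng.integers(4, size=n_runs - 1)
        for st in steps:
            runs.append(int((runs[-1] + 1 + st) % 5))
        stats = transition_stats_from_runs(runs, k=5,
                                           class_names=list("ABCDE"))
        devs.append(stats.deviation)
    devs = np.array(devs)
    mean_dev = devs.mean(axis=0)
    se = devs.std(axis=0, ddof=1) / np.sqrt(n_sequences)
    off = ~np.eye(5, dtype=bool)
    return {
        "max_abs_mean_dev_in_se": float(np.max(np.abs(mean_dev[off]) /
                                               se[off])),
        "max_abs_mean_dev": float(np.max(np.abs(mean_dev[off]))),
        "n": int(n_sequences * n_runs),
    }


def planted_enrichment_detection(seed: int = 0, n_seeds: int = 40,
                                 enrich: float = 0.10,
                                 duration_s: float = 60.0) -> dict:
    """Fraction of simulations in which a planted D->C bias gives dev_DC > 0."""
    positives = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = GeneratorConfig(
            duration_s=duration_s, seed=s,
            transition_matrix=_biased_transition_matrix(5, enrich))
        seq = simulate_state_sequence(cfg)
        seg = Segmentation(labels=seq.labels, sfreq=cfg.sfreq,
                           class_names=list("ABCDE"))
        if transition_stats(seg).dev_DC > 0:
            positives += 1
    return {"dev_dc_positive_rate": positives / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def _wilcoxon_enumeration(diffs: np.ndarray) -> tuple[float, float]:
    diffs = diffs[diffs != 0]
    ranks = sp_stats.rankdata(np.abs(diffs))
    v_obs = ranks[diffs > 0].sum()
    vs = np.array([ranks[list(signs)].sum() if any(signs) else 0.0
                   for signs in iter_product([False, True],
                                             repeat=diffs.size)])
    p_low = float(np.mean(vs <= v_obs + 1e-12))
    p_high = float(np.mean(vs >= v_obs - 1e-12))
    return float(v_obs), min(1.0, 2.0 * min(p_low, p_high))


def statistics_oracles(seed: int = 0, n_trials: int = 50) -> dict:
    """Exact Wilcoxon vs full enumeration, BH vs step-up, t-r identity."""
    rng = np.random.default_rng(seed)
    worst_p = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(3, 13))
        diffs = np.round(rng.normal(size=n), 1)
        if np.all(diffs == 0):
            continue
        res = wilcoxon_signed_rank_exact(np.zeros(n), diffs)
        v_ref, p_ref = _wilcoxon_enumeration(diffs)
        assert res.value == v_ref
        worst_p = max(worst_p, abs(res.p - p_ref))
    simple = wilcoxon_signed_rank_exact([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
    # BH vs direct evaluation of the step-up definition
    worst_bh = 0.0
    for _ in range(n_trials):
        m = int(rng.integers(1, 20))
        p = rng.uniform(size=m)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        ref = np.empty(m)
        for rank, i in enumerate(order, start=1):
            ref[i] = min(1.0, min(m * p[j] / (list(order).index(j) + 1)
                                  for j in order[rank - 1:]))
        worst_bh = max(worst_bh, float(np.max(np.abs(adj - ref))))
    # t-r identity on random correlations
    worst_tr = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(5, 40))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = pearson_change_correlation(x, y)
        t_ref = res.r * np.sqrt(res.df / (1.0 - res.r**2))
        worst_tr = max(worst_tr, abs(res.value - t_ref))
    return {
        "wilcoxon_enum_max_p_diff": float(worst_p),
        "wilcoxon_v_123": float(simple.value),
        "wilcoxon_p_123": float(simple.p),
        "bh_max_diff": float(worst_bh),
        "t_r_identity_max_diff": float(worst_tr),
        "n": n_trials,
    }


# ---------------------------------------------------------------------------
# study-level power and type-I error
# ---------------------------------------------------------------------------


def study_power(seed: int = 0, n_studies: int = 100, effect_ms: float = 8.0,
                n_subjects: int = 19) -> dict:
    """Fraction of simulated studies detecting the planted class-D effect.

    Each study is generated at full length (120 s recordings) with the
    planted duration increase; parameters come from the ground-truth label
    sequences (the statistical harness under test; the topographic
    measurement chain is validated by ``parameter_recovery``). Detection =
    BH-adjusted p < 0.05 for duration-D at both stimulation sites.
    """
    hits = 0
    for s in _child_seeds(seed, n_studies):
        study = simulate_paired_study(n_subjects=n_subjects,
                                      effect_ms=effect_ms, rho=0.6, seed=s,
                                      synthesize=False)
        report = process_study_from_truth(study)["report"]
        t4 = report["parameters_prepost"]
        dur_d = t4[t4["comparison"] == "Duration of microstate map D"]
        if (dur_d["p_adjusted"] < 0.05).all():
            hits += 1
    return {"power_duration_d": hits / n_studies, "n": n_studies}


def study_type_i(seed: int = 0, n_studies: int = 100,
                 n_subjects: int = 19) -> dict:
    """Per-comparison rejection rate for duration-D with no planted effect."""
    rejections = 0
    comparisons = 0
    for s in _child_seeds(seed + 1, n_studies):
        study = simulate_paired_study(n_subjects=n_subjects, effect_ms=0.0,
                                      rho=0.0, seed=s, synthesize=False)
        report = process_study_from_truth(study)["report"]
        t4 = report["parameters_prepost"]
        dur_d = t4[t4["comparison"] == "Duration of microstate map D"]
        rejections += int((dur_d["p_adjusted"] < 0.05).sum())
        comparisons += len(dur_d)
    return {"type_i_rate": rejections / comparisons, "n": comparisons}
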