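"""Polarity-invariant microstate clustering and template alignment.

Microstate templates are extracted from the maps at global-field-power
(GFP) peaks with a modified k-means: cluster membership uses the squared
spatial correlation (so a map and its negation are equivalent), and each
cluster centroid is the dominant eigenvector of its members' outer-product
sum rather than their plain mean — the plain mean is not polarity
invariant. Fit quality is the global explained variance

    GEV = sum_p gfp_p^2 * corr(map_p, template_{a(p)})^2 / sum_p gfp_p^2

over peak maps p with assignments a(p).

Individual subjects' template sets are aligned by permuting (and sign
flipping) each subject's maps to maximize the variance the classes share
across subjects — operationalized as the mean over classes and subjects of
the squared spatial correlation between each subject map and its class's
dominant-eigenvector mean. Grand-mean templates are those per-class
eigenvector means, and classes are named A-E by one-to-one best-similarity
matching against canonical topographies.
"""

from __future__ import annotations

from itertools import permutations as iter_permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import (
    AlignmentResult,
    DegenerateDataError,
    EEGRecording,
    GFPSeries,
    ParameterError,
    TemplateSet,
)

DEFAULT_N_RESTARTS = 20
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-7
CANONICAL_NAMES = ["A", "B", "C", "D", "E"]


# ---------------------------------------------------------------------------
# GFP and spatial correlation
# ---------------------------------------------------------------------------


def gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power per sample and the strict local maxima as peaks.

    GFP(t) is the spatial standard deviation of the (average-referenced)
    scalp map at time t. Peaks are strictly greater than both neighbors;
    peak search never crosses a splice boundary.
    """
    values = rec.data.std(axis=0)
    peaks = []
    bounds = [0] + list(rec.splice_boundaries) + [rec.n_samples]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = values[lo:hi]
        if seg.size < 3:
            continue
        idx = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        peaks.extend((idx + lo).tolist())
    return GFPSeries(values=values, peak_indices=np.array(peaks, dtype=int))


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two maps across channels (signed)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise DegenerateDataError("zero-variance map has no spatial correlation")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def spatial_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Polarity-invariant similarity: |spatial correlation|."""
    return abs(spatial_correlation(u, v))


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-norm each row (drops zero-variance rows' scale)."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _corr_matrix(peak_maps_n: np.ndarray, templates_n: np.ndarray) -> np.ndarray:
    """(n_peaks, k) signed correlations; rows/templates already normalized."""
    return peak_maps_n @ templates_n.T


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------


def _dominant_eigvec(members: np.ndarray) -> np.ndarray:
    """Dominant right singular vector of a (m, n_channels) member stack."""
    # eigenvector of sum of outer products == leading right singular vector
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    v = vt[0]
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateDataError("degenerate cluster eigenvector")
    v /= n
    # deterministic sign: strongest-amplitude channel positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def _gev(corr: np.ndarray, assign: np.ndarray, gfp2: np.ndarray) -> float:
    picked = corr[np.arange(corr.shape[0]), assign]
    return float(np.sum(gfp2 * picked**2) / np.sum(gfp2))


def modified_kmeans(peak_maps: np.ndarray, k: int,
                    n_restarts: int = DEFAULT_N_RESTARTS,
                    max_iter: int = DEFAULT_MAX_ITER,
                    tol: float = DEFAULT_TOL, seed: int = 0,
                    channel_names: list[str] | None = None) -> TemplateSet:
    """Polarity-invariant k-means on GFP-peak maps; best of ``n_restarts`` by GEV.

    Assignment maximizes squared spatial correlation; the update step takes
    the dominant eigenvector of each cluster's member maps. Emptied clusters
    are re-seeded from the currently worst-explained peak map. Convergence:
    GEV improvement below ``tol``.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2:
        raise ParameterError("peak_maps must be (n_peaks, n_channels)")
    n = peak_maps.shape[0]
    if n < k:
        raise ParameterError(f"need at least k={k} peak maps, got {n}")
    gfp2 = peak_maps.var(axis=1)  # squared GFP of each peak map
    if np.all(gfp2 == 0):
        raise DegenerateDataError("all peak maps have zero variance")
    maps_n = _normalize_maps(peak_maps)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_restarts):
        init = rng.choice(n, size=k, replace=False)
        templates = maps_n[init].copy()
        prev_gev = -np.inf
        for _ in range(max_iter):
            corr = _corr_matrix(maps_n, templates)
            assign = np.argmax(corr**2, axis=1)
            # re-seed empty clusters from the worst-explained map
            for c in range(k):
                if not np.any(assign == c):
                    explained = np.abs(corr[np.arange(n), assign])
                    worst = int(np.argmin(explained))
                    templates[c] = maps_n[worst]
                    assign[worst] = c
            cur_gev = _gev(_corr_matrix(maps_n, templates), assign, gfp2)
            for c in range(k):
                members = maps_n[assign == c]
                if members.shape[0]:
                    templates[c] = _dominant_eigvec(members)
            if cur_gev - prev_gev < tol:
                break
            prev_gev = cur_gev
        corr = _corr_matrix(maps_n, templates)
        assign = np.argmax(corr**2, axis=1)
        final_gev = _gev(corr, assign, gfp2)
        if best is None or final_gev > best[0]:
            best = (final_gev, templates.copy())

    assert best is not None
    gev_val, templates = best
    return TemplateSet(maps=templates, labels=[str(i) for i in range(k)],
                       gev=gev_val, channel_names=channel_names)


def extract_peak_maps(rec: EEGRecording, gfps: GFPSeries | None = None) -> np.ndarray:
    """The (n_peaks, n_channels) matrix of maps at GFP peaks."""
    if gfps is None:
        gfps = gfp(rec)
    return rec.data[:, gfps.peak_indices].T.copy()


def fit_k_range(peak_maps: np.ndarray, kmin: int = 4, kmax: int = 7,
                **kwargs) -> list[TemplateSet]:
    """One modified-k-means fit per k in [kmin, kmax]."""
    if kmin > kmax:
        raise ParameterError("kmin must be <= kmax")
    return [modified_kmeans(peak_maps, k, **kwargs) for k in range(kmin, kmax + 1)]


# ---------------------------------------------------------------------------
# across-subject alignment and the grand mean
# ---------------------------------------------------------------------------


def _class_mean(stack: np.ndarray) -> np.ndarray:
    """Polarity-invariant mean of a (n_subjects, n_channels) class stack."""
    return _dominant_eigvec(stack)


def alignment_objective(sets_maps: list[np.ndarray]) -> float:
    """Mean over classes and subjects of corr(subject map, class eigen-mean)^2."""
    k = sets_maps[0].shape[0]
    total = 0.0
    for c in range(k):
        stack = np.array([m[c] for m in sets_maps])
        center = _class_mean(stack)
        total += float(np.mean((stack @ center) ** 2))
    return total / k


def align_across_subjects(sets: list[TemplateSet],
                          max_sweeps: int = 50) -> AlignmentResult:
    """Align subjects' template sets by label permutation and sign flips.

    Two phases. First, fast coordinate ascent: sweeping over subjects, each
    subject's permutation is chosen by optimal linear assignment of its maps
    to the current leave-one-out class eigen-means (squared-correlation
    score). Second, verification: each subject's permutation is re-optimized
    by exhaustive search over all k! candidates under the exact global
    objective with the other subjects fixed, iterated to a fixed point (the
    assignment score approximates but does not equal the joint eigen-mean
    objective, so this pass is what guarantees per-subject optimality).
    Deterministic given input order. For two subjects the fixed point is the
    exhaustive joint optimum, since the objective depends only on the
    relative permutation (tested against the full joint search).
    """
    if not sets:
        raise ParameterError("no template sets to align")
    k = sets[0].k
    if any(s.k != k for s in sets):
        raise ParameterError("all template sets must have the same k")
    if k > 7:
        raise ParameterError("alignment supports k <= 7")
    n_sub = len(sets)
    maps = [_normalize_maps(s.maps.copy()) for s in sets]
    perms = [list(range(k)) for _ in range(n_sub)]

    def current() -> list[np.ndarray]:
        return [m[p] for m, p in zip(maps, perms)]

    prev_obj = alignment_objective(current())
    for _ in range(max_sweeps):
        for s in range(n_sub):
            if n_sub == 1:
                break
            others = [maps[j][perms[j]] for j in range(n_sub) if j != s]
            centers = np.array([
                _class_mean(np.array([o[c] for o in others])) if len(others) > 1
                else others[0][c]
                for c in range(k)
            ])
            score = (maps[s] @ centers.T) ** 2  # (source map, target class)
            rows, cols = linear_sum_assignment(-score)
            new_perm = [0] * k
            for r, c in zip(rows, cols):
                new_perm[c] = r
            perms[s] = new_perm
        obj = alignment_objective(current())
        if obj <= prev_obj + 1e-12:
            break
        prev_obj = obj

    # verification: exhaustive per-subject search under the exact objective
    all_perms = [list(p) for p in iter_permutations(range(k))]
    for _ in range(max_sweeps):
        improved = False
        for s in range(n_sub):
            if n_sub == 1:
                break
            best_perm = perms[s]
            best_obj = alignment_objective(current())
            for cand in all_perms:
                if cand == perms[s]:
                    continue
                saved = perms[s]
                perms[s] = cand
                cand_obj = alignment_objective(current())
                if cand_obj > best_obj + 1e-12:
                    best_obj, best_perm = cand_obj, cand
                perms[s] = saved
            if best_perm != perms[s]:
                perms[s] = best_perm
                improved = True
        if not improved:
            break

    # polarity: orient each subject map along its class eigen-mean
    aligned_maps = current()
    signs = np.ones((n_sub, k))
    for c in range(k):
        stack = np.array([m[c] for m in aligned_maps])
        center = _class_mean(stack)
        for s in range(n_sub):
            if stack[s] @ center < 0:
                signs[s, c] = -1.0
    aligned_sets = []
    for s in range(n_sub):
        m = maps[s][perms[s]] * signs[s][:, None]
        aligned_sets.append(TemplateSet(
            maps=m, labels=[str(i) for i in range(k)], gev=sets[s].gev,
            channel_names=sets[s].channel_names,
        ))
    return AlignmentResult(
        permutations=[list(p) for p in perms],
        polarity_signs=signs,
        mean_shared_variance=alignment_objective(current()),
        aligned_sets=aligned_sets,
    )


def brute_force_alignment_objective(sets: list[TemplateSet]) -> float:
    """Exhaustive-joint-search optimum of the alignment objective.

    Independent oracle for ``align_across_subjects`` on small instances;
    cost is k!^(n-1) objective evaluations (the objective is invariant to a
    common relabeling, so the first subject is pinned to identity).
    """
    k = sets[0].k
    maps = [_normalize_maps(s.maps.copy()) for s in sets]
    best = -np.inf
    rest = maps[1:]
    for combo in _product_permutations(k, len(rest)):
        trial = [maps[0]] + [m[list(p)] for m, p in zip(rest, combo)]
        best = max(best, alignment_objective(trial))
    return best


def _product_permutations(k: int, n: int):
    if n == 0:
        yield ()
        return
    for head in iter_permutations(range(k)):
        for tail in _product_permutations(k, n - 1):
            yield (head,) + tail


def grand_mean(aligned: AlignmentResult | list[TemplateSet]) -> TemplateSet:
    """Per-class dominant eigenvector across aligned subject maps."""
    sets = aligned.aligned_sets if isinstance(aligned, AlignmentResult) else aligned
    k = sets[0].k
    maps = np.array([
        _class_mean(np.array([s.maps[c] for s in sets])) for c in range(k)
    ])
    return TemplateSet(maps=maps, labels=[str(i) for i in range(k)],
                       gev=float(np.mean([s.gev for s in sets])),
                       channel_names=sets[0].channel_names)


# ---------------------------------------------------------------------------
# canonical A-E labeling
# ---------------------------------------------------------------------------


def canonical_templates(montage) -> TemplateSet:
    """Synthetic canonical A-E topographies on the given montage.

    Constructed from the field's verbal map descriptions — A: left-posterior
    to right-frontal diagonal gradient; B: the mirrored diagonal; C: an
    anterior-posterior axis; D: a fronto-central focal map; E: a
    centro-parietal focal map. These are synthetic stand-ins for published
    canonical maps, used only to attach names, never as fitted templates.
    """
    pos = montage.positions  # x: right, y: anterior, z: superior

    def bump(center: np.ndarray, width: float) -> np.ndarray:
        c = center / np.linalg.norm(center)
        return np.exp((pos @ c - 1.0) / width)

    # A/B diagonals are strongly lateralized (60 deg off the midline) so the
    # canonical set stays mutually distinct (|corr| well below 0.7)
    s60, c60 = np.sin(np.pi / 3.0), np.cos(np.pi / 3.0)
    raw = [
        pos @ np.array([s60, c60, 0.0]),                # A
        pos @ np.array([-s60, c60, 0.0]),               # B
        pos @ np.array([0.0, 1.0, 0.25]),               # C
        bump(np.array([0.0, 0.4, 0.92]), 0.40),         # D
        bump(np.array([0.0, -0.45, 0.89]), 0.40),       # E
    ]
    maps = _normalize_maps(np.array(raw))
    return TemplateSet(maps=maps, labels=list(CANONICAL_NAMES),
                       channel_names=list(montage.channel_names))


def label_canonical(tset: TemplateSet, canon: TemplateSet) -> TemplateSet:
    """Name templates A-E by one-to-one max-|correlation| matching to ``canon``."""
    if tset.k > canon.k:
        raise ParameterError("more templates than canonical classes")
    sim = np.zeros((tset.k, canon.k))
    for i in range(tset.k):
        for j in range(canon.k):
            sim[i, j] = spatial_similarity(tset.maps[i], canon.maps[j])
    rows, cols = linear_sum_assignment(-sim)
    name_of = {int(r): canon.labels[int(c)] for r, c in zip(rows, cols)}
    order = sorted(range(tset.k), key=lambda i: name_of[i])
    return TemplateSet(maps=tset.maps[order],
                       labels=[name_of[i] for i in order],
                       gev=tset.gev, channel_names=tset.channel_names)


def canonical_match_similarities(tset: TemplateSet, canon: TemplateSet) -> dict:
    """Per assigned name, the |correlation| achieved by the matching."""
    labeled = label_canonical(tset, canon)
    out = {}
    for name, row in zip(labeled.labels, labeled.maps):
        j = canon.labels.index(name)
        out[name] = spatial_similarity(row, canon.maps[j])
    return out


def select_k_with_cd(sets: list[TemplateSet], canon: TemplateSet,
                     min_similarity: float = 0.6) -> TemplateSet:
    """Smallest-k set whose canonical naming covers C and D convincingly.

    Mirrors the practice of scanning k = 4..7 and keeping the first solution
    in which both class C and class D appear (matching similarity at least
    ``min_similarity``). Falls back to the largest k if none qualifies.
    """
    for tset in sorted(sets, key=lambda s: s.k):
        sims = canonical_match_similarities(tset, canon)
        if sims.get("C", 0.0) >= min_similarity and sims.get("D", 0.0) >= min_similarity:
            return label_canonical(tset, canon)
    return label_canonical(max(sets, key=lambda s: s.k), canon)
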