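"""Synthetic resting-state EEG with planted microstate ground truth.

The generator emulates the study design the analysis pipeline targets: a
paired pre/post, two-session (DMPFC / DLPFC stimulation) resting-state EEG
study with ~19 subjects, 30 channels of the 10-10 system at 500 Hz, five
microstate classes whose mean durations lie on the 55-85 ms scale, and a
plantable post-stimulation increase in class-D duration plus a D->C
transition enrichment whose per-subject change correlates with a STAI-like
state-anxiety change score.

Construction, per recording:

1. a semi-Markov label sequence — run lengths drawn per class (geometric at
   sample resolution by default, optionally gamma), successor classes drawn
   from a zero-diagonal row-stochastic transition matrix;
2. a topography sequence — the active class's template map scaled by a
   rectified 10 Hz sinusoidal GFP envelope (so GFP peaks occur at the
   empirically typical ~20/s rate);
3. additive spatially correlated Gaussian noise (correlation decaying with
   inter-electrode angle), then average-referencing of every sample.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .containers import (
    ChannelNotFoundError,
    EEGRecording,
    GenerationError,
    GeneratorConfig,
    LabelSequence,
    Montage,
    ParameterError,
    StudyDataset,
    SubjectRecord,
    TemplateSet,
)

logger = logging.getLogger("eegmicrostates")

SESSIONS = ("DMPFC", "DLPFC")
TIMINGS = ("pre", "post")

#: The default 30-channel 10-10 analysis set. The source channel list this
#: mirrors contains a printing erratum (two labels duplicated); this is the
#: conventional 30-channel completion, documented in the methods note.
DEFAULT_30 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FT7 FC3 FCz FC4 FT8 T3 C3 Cz C4 T4 "
    "TP7 CP3 CPz CP4 TP8 T5 P3 Pz P4 T6 O1 Oz O2"
).split()

#: Old 10-20 temporal labels -> modern equivalents used by position tables.
_OLD_TO_MODERN = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_POSITION_TABLE: dict[str, np.ndarray] | None = None


def _ten_ten_table() -> dict[str, np.ndarray]:
    """Unit-sphere positions for the full 10-10 set, from mne's montage."""
    global _POSITION_TABLE
    if _POSITION_TABLE is not None:
        return _POSITION_TABLE
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    raw = montage.get_positions()["ch_pos"]
    pts = np.array([p for p in raw.values()])
    center = pts.mean(axis=0)
    table: dict[str, np.ndarray] = {}
    for name, pos in raw.items():
        v = np.asarray(pos, dtype=float) - center
        table[name] = v / np.linalg.norm(v)
    _POSITION_TABLE = table
    return table


def make_montage(n_channels: int = 30, channel_names: list[str] | None = None) -> Montage:
    """Build a deterministic unit-sphere montage from the built-in 10-10 table.

    With defaults this returns the 30-channel analysis set (``DEFAULT_30``).
    ``channel_names`` may name any subset of the 10-10 table (old temporal
    labels T3/T4/T5/T6 are accepted and resolved to T7/T8/P7/P8 positions).
    """
    table = _ten_ten_table()
    if channel_names is None:
        if n_channels == 30:
            channel_names = list(DEFAULT_30)
        elif n_channels < 30:
            channel_names = list(DEFAULT_30[:n_channels])
        else:
            raise ParameterError(
                "montages larger than 30 channels require explicit channel_names"
            )
    positions = []
    for name in channel_names:
        key = name if name in table else _OLD_TO_MODERN.get(name, name)
        if key not in table:
            raise ChannelNotFoundError(name)
        positions.append(table[key])
    return Montage(channel_names=list(channel_names), positions=np.array(positions))


# ---------------------------------------------------------------------------
# template topographies
# ---------------------------------------------------------------------------


def _smooth_dipolar_map(positions: np.ndarray, rng: np.random.Generator,
                        length_scale: float = 0.9) -> np.ndarray:
    """One smooth dipolar topography: a +/- pair of spherical Gaussians."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    # tilt the sink away from the antipode so maps are not pure cosines
    tilt = rng.normal(scale=0.6, size=3)
    sink = -axis + tilt
    sink /= np.linalg.norm(sink)
    v = (np.exp((positions @ axis - 1.0) / length_scale)
         - np.exp((positions @ sink - 1.0) / length_scale))
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise GenerationError("degenerate dipolar map")
    return v / n


def make_templates(k: int, montage: Montage, seed: int,
                   max_correlation: float = 0.7, max_tries: int = 2000) -> TemplateSet:
    """Generate ``k`` smooth, mutually distinct synthetic template maps.

    Maps are average-referenced, unit-norm, and pairwise distinct in the
    polarity-invariant sense (absolute spatial correlation below
    ``max_correlation``). Deterministic given ``seed``. These are synthetic
    stand-ins shaped like scalp topographies, not reproductions of any
    published map set.
    """
    if not (2 <= k <= 7):
        raise ParameterError("k must be between 2 and 7")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < k:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not generate {k} maps with |corr| < {max_correlation} "
                f"in {max_tries} tries"
            )
        cand = _smooth_dipolar_map(montage.positions, rng)
        ok = all(
            abs(float(np.corrcoef(cand, m)[0, 1])) < max_correlation for m in maps
        )
        if ok:
            maps.append(cand)
    labels = [chr(ord("A") + i) for i in range(k)]
    return TemplateSet(
        maps=np.array(maps), labels=labels, channel_names=list(montage.channel_names)
    )


def make_study_templates(montage: Montage, seed: int, jitter: float = 0.35,
                         min_canonical_similarity: float = 0.75,
                         max_correlation: float = 0.7,
                         max_tries: int = 200) -> TemplateSet:
    """Five canonical-anchored templates: A-E topographies plus smooth jitter.

    The paired-study generator uses these so that class identity (in
    particular the class-D planted effect) survives the pipeline's
    canonical A-E naming: each map stays recognizably its class
    (|corr| >= ``min_canonical_similarity`` with the canonical topography)
    while the jitter keeps study instances distinct. Deterministic given
    ``seed``.
    """
    from .clustering import canonical_templates  # local import avoids a cycle

    canon = canonical_templates(montage)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        maps = []
        for row in canon.maps:
            v = row + jitter * _smooth_dipolar_map(montage.positions, rng)
            v = v - v.mean()
            maps.append(v / np.linalg.norm(v))
        maps = np.array(maps)
        sims = [abs(float(np.corrcoef(maps[i], canon.maps[i])[0, 1]))
                for i in range(canon.k)]
        cross = [abs(float(np.corrcoef(maps[i], maps[j])[0, 1]))
                 for i in range(canon.k) for j in range(i)]
        if min(sims) >= min_canonical_similarity and max(cross) < max_correlation:
            return TemplateSet(maps=maps, labels=list(canon.labels),
                               channel_names=list(montage.channel_names))
    raise GenerationError("could not generate canonical-anchored templates")


# ---------------------------------------------------------------------------
# semi-Markov state sequence
# ---------------------------------------------------------------------------


def _run_class_chain(rng: np.random.Generator, transition: np.ndarray,
                     n_runs: int, start: int) -> np.ndarray:
    """Markov chain over run classes (never self-succeeding by construction)."""
    cum = np.cumsum(transition, axis=1)
    u = rng.random(n_runs)
    states = np.empty(n_runs, dtype=int)
    state = start
    for i in range(n_runs):
        states[i] = state
        state = int(np.searchsorted(cum[state], u[i], side="right"))
    return states


def _run_lengths(rng: np.random.Generator, states: np.ndarray,
                 mean_samples: np.ndarray, law: str,
                 gamma_shape: float) -> np.ndarray:
    means = mean_samples[states]
    if law == "geometric":
        return rng.geometric(1.0 / means)
    draws = rng.gamma(gamma_shape, means / gamma_shape)
    return np.maximum(1, np.rint(draws)).astype(int)


def simulate_state_sequence(config: GeneratorConfig,
                            rng: np.random.Generator | None = None) -> LabelSequence:
    """Draw a semi-Markov label sequence with the configured run-length law.

    Run lengths are geometric (default) or gamma draws with the per-class
    configured mean; successive runs always differ in class, with successors
    drawn from the zero-diagonal transition matrix rows.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.sfreq))
    if n_samples == 0:
        return LabelSequence(labels=np.empty(0, dtype=int), sfreq=config.sfreq)
    mean_samples = np.array(
        [d * config.sfreq / 1000.0 for d in config.mean_durations_ms])
    state = int(rng.integers(config.n_classes))
    chunks: list[np.ndarray] = []
    total = 0
    while total < n_samples:
        # draw runs in blocks; a small overshoot is truncated below
        n_runs = max(8, int(1.3 * (n_samples - total) / mean_samples.mean()))
        states = _run_class_chain(rng, config.transition_matrix, n_runs, state)
        lengths = _run_lengths(rng, states, mean_samples,
                               config.run_length_law, config.gamma_shape)
        chunks.append(np.repeat(states, lengths))
        total += int(lengths.sum())
        state = int(np.searchsorted(
            np.cumsum(config.transition_matrix[states[-1]]), rng.random(),
            side="right"))
    labels = np.concatenate(chunks)[:n_samples]
    return LabelSequence(labels=labels, sfreq=config.sfreq)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------


def _spatial_noise_chol(montage: Montage, length_scale: float) -> np.ndarray:
    """Factor of an angularly decaying channel covariance (cov = F F^T).

    The squared-exponential in geodesic angle is not guaranteed positive
    semi-definite on the sphere, so the factor comes from an
    eigendecomposition with negative eigenvalues clipped to zero.
    """
    g = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    angles = np.arccos(g)
    cov = np.exp(-0.5 * (angles / length_scale) ** 2)
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def synthesize_eeg(labels: LabelSequence, templates: TemplateSet,
                   config: GeneratorConfig,
                   rng: np.random.Generator | None = None,
                   montage: Montage | None = None) -> EEGRecording:
    """Render a label sequence into multichannel EEG.

    signal(t) = template[label(t)] * |sin(2*pi*f_env*t)| * gain + noise,
    average-referenced per sample. Noise is Gaussian with an inter-electrode
    angular correlation structure (or white if ``config.spatial_noise`` is
    false); ``config.noise_sd`` scales its RMS relative to the mean
    noiseless signal RMS.
    """
    if labels.labels.size and labels.labels.max() >= templates.k:
        raise ParameterError("label alphabet exceeds template count")
    if templates.n_channels != (montage.n_channels if montage else templates.n_channels):
        raise ParameterError("montage channel count does not match templates")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_ch = templates.n_channels
    n = labels.n_samples
    t = np.arange(n) / labels.sfreq
    envelope = np.abs(np.sin(2.0 * np.pi * config.envelope_freq_hz * t))
    clean = templates.maps[labels.labels].T * envelope * config.gain_uv
    if config.noise_sd > 0 and n > 0:
        white = rng.standard_normal((n_ch, n))
        if config.spatial_noise:
            if montage is None:
                montage = make_montage(n_ch)
            chol = _spatial_noise_chol(montage, config.noise_length_scale)
            noise = chol @ white
        else:
            noise = white
        signal_rms = float(np.sqrt(np.mean(clean**2))) if n else 0.0
        noise_rms = float(np.sqrt(np.mean(noise**2)))
        if noise_rms > 0:
            noise *= config.noise_sd * signal_rms / noise_rms
        data = clean + noise
    else:
        data = clean
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(
        data=data, sfreq=labels.sfreq,
        channel_names=list(templates.channel_names or
                           [f"ch{i}" for i in range(n_ch)]),
        meta={"synthetic": True, "noise_sd": config.noise_sd},
    )


def simulate_recording(config: GeneratorConfig, templates: TemplateSet,
                       rng: np.random.Generator | None = None,
                       montage: Montage | None = None
                       ) -> tuple[EEGRecording, LabelSequence]:
    """Convenience wrapper: sequence + synthesis with one RNG stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq = simulate_state_sequence(config, rng)
    rec = synthesize_eeg(seq, templates, config, rng, montage)
    return rec, seq


# ---------------------------------------------------------------------------
# paired pre/post study
# ---------------------------------------------------------------------------

#: Study-condition defaults for STAI-like state-anxiety scores: means/SDs on
#: the clinical scale (pre ~47 +/- 9, small mean decrease post).
_STAI_PRE_MEAN, _STAI_PRE_SD = 47.5, 8.8
_DELTA_STAI_MEAN, _DELTA_STAI_SD = -1.6, 5.0
_MADRS_MEAN, _MADRS_SD = 23.3, 6.4
#: Planted D->C enrichment scale (Table-3-like regime: deviations ~1e-2).
_ENRICH_PRE_MEAN, _ENRICH_PRE_SD = 0.004, 0.004
_DELTA_ENRICH_MEAN, _DELTA_ENRICH_SD = 0.001, 0.012
_SUBJECT_DURATION_CV = 0.10  # between-subject duration variability
_RECORDING_DURATION_CV = 0.04  # within-subject, between-recording jitter
_TEMPLATE_JITTER = 0.15  # subject-level template perturbation (map units)

CLASS_D = 3  # index of class D in the A..E labeling
CLASS_C = 2


def _clip_score(x: float, lo: float = 20.0, hi: float = 80.0, what: str = "STAI") -> float:
    if x < lo or x > hi:
        logger.info("clipping %s score %.1f into [%g, %g]", what, x, lo, hi)
        return float(min(hi, max(lo, x)))
    return float(x)


def _perturb_templates(base: TemplateSet, rng: np.random.Generator,
                       montage: Montage, jitter: float) -> TemplateSet:
    maps = []
    for row in base.maps:
        bump = _smooth_dipolar_map(montage.positions, rng)
        v = row + jitter * bump
        v = v - v.mean()
        maps.append(v / np.linalg.norm(v))
    return TemplateSet(maps=np.array(maps), labels=list(base.labels),
                       channel_names=base.channel_names)


def _biased_transition_matrix(k: int, enrich_dc: float) -> np.ndarray:
    """Uniform off-diagonal matrix with extra D->C mass ``enrich_dc``."""
    t = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(t, 0.0)
    eps = float(np.clip(enrich_dc, -0.5 / (k - 1), 0.5))
    t[CLASS_D, CLASS_C] += eps
    others = [j for j in range(k) if j not in (CLASS_D, CLASS_C)]
    t[CLASS_D, others] -= eps / len(others)
    t[CLASS_D] = np.clip(t[CLASS_D], 0.0, None)
    t[CLASS_D] /= t[CLASS_D].sum()
    np.fill_diagonal(t, 0.0)
    return t


def simulate_paired_study(n_subjects: int = 19, effect_ms: float = 6.0,
                          rho: float = 0.6, seed: int = 0,
                          config: GeneratorConfig | None = None,
                          synthesize: bool = True) -> StudyDataset:
    """Simulate a paired pre/post two-session study with known ground truth.

    Post-stimulation recordings are generated with class-D mean duration
    increased by ``effect_ms`` in both sessions. Each subject's change in
    D->C transition enrichment and change in STAI-like score are drawn with
    correlation ``rho``. All planted quantities are stored per subject and
    summarized in ``StudyDataset.ground_truth``.

    ``synthesize=False`` skips EEG rendering and keeps only the ground-truth
    label sequences and scores — the cheap mode used for large simulation
    batches that exercise the statistical harness rather than the
    topographic stages.
    """
    if n_subjects < 3:
        raise ParameterError("n_subjects must be >= 3")
    if not -1.0 <= rho <= 1.0:
        raise ParameterError("|rho| must be <= 1")
    if config is None:
        config = GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    montage = make_montage(config.n_channels)
    if config.n_classes == 5:
        base_templates = make_study_templates(montage,
                                              seed=int(rng.integers(2**31)))
    else:
        base_templates = make_templates(config.n_classes, montage,
                                        seed=int(rng.integers(2**31)))
    k = config.n_classes
    subjects: list[SubjectRecord] = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        templates = _perturb_templates(base_templates, rng, montage, _TEMPLATE_JITTER)
        subj_dur = np.array(config.mean_durations_ms) * rng.lognormal(
            mean=0.0, sigma=_SUBJECT_DURATION_CV, size=k
        )
        recordings: dict = {}
        true_labels: dict = {}
        true_durations: dict = {}
        stai: dict = {}
        true_delta: dict = {}
        for session in SESSIONS:
            # latent factor ties the planted transition change to the
            # STAI change at correlation rho
            z = float(rng.standard_normal())
            w = float(rng.standard_normal())
            enrich_pre = _ENRICH_PRE_MEAN + _ENRICH_PRE_SD * float(rng.standard_normal())
            delta_enrich = _DELTA_ENRICH_MEAN + _DELTA_ENRICH_SD * z
            delta_stai = _DELTA_STAI_MEAN + _DELTA_STAI_SD * (
                rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * w
            )
            pre_score = _clip_score(
                _STAI_PRE_MEAN + _STAI_PRE_SD * float(rng.standard_normal())
            )
            post_score = _clip_score(pre_score + delta_stai)
            stai[session] = {"pre": pre_score, "post": post_score}
            true_delta[session] = delta_enrich
            for timing in TIMINGS:
                durations = subj_dur * rng.lognormal(
                    mean=0.0, sigma=_RECORDING_DURATION_CV, size=k
                )
                if timing == "post":
                    durations = durations.copy()
                    durations[CLASS_D] += effect_ms
                enrich = enrich_pre + (delta_enrich if timing == "post" else 0.0)
                rec_cfg = GeneratorConfig(
                    n_channels=config.n_channels, sfreq=config.sfreq,
                    duration_s=config.duration_s, n_classes=k,
                    mean_durations_ms=tuple(durations),
                    transition_matrix=_biased_transition_matrix(k, enrich),
                    envelope_freq_hz=config.envelope_freq_hz,
                    noise_sd=config.noise_sd,
                    noise_length_scale=config.noise_length_scale,
                    spatial_noise=config.spatial_noise,
                    gain_uv=config.gain_uv,
                    run_length_law=config.run_length_law,
                    gamma_shape=config.gamma_shape,
                    seed=int(rng.integers(2**31)),
                )
                true_durations[(session, timing)] = tuple(durations)
                if synthesize:
                    rec, seq = simulate_recording(rec_cfg, templates,
                                                  rng=rng, montage=montage)
                    rec.meta.update(subject=sid, session=session,
                                    timing=timing,
                                    true_durations_ms=tuple(durations))
                    recordings[(session, timing)] = rec
                else:
                    seq = simulate_state_sequence(rec_cfg, rng)
                true_labels[(session, timing)] = seq
        madrs = float(np.clip(
            _MADRS_MEAN + _MADRS_SD * rng.standard_normal(), 0.0, 60.0))
        subjects.append(SubjectRecord(
            subject_id=sid, recordings=recordings, true_labels=true_labels,
            templates=templates, stai=stai, madrs=madrs,
            true_delta_transition=true_delta, true_durations=true_durations,
        ))
    ground_truth = {
        "effect_ms": float(effect_ms),
        "rho": float(rho),
        "base_mean_durations_ms": tuple(config.mean_durations_ms),
        "base_templates": base_templates,
        "montage": montage,
    }
    return StudyDataset(subjects=subjects, sessions=SESSIONS,
                        ground_truth=ground_truth)
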