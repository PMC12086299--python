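"""End-to-end pipeline: preprocess -> cluster -> grand mean -> backfit ->
parameters -> transitions -> group statistics.

``PipelineConfig`` gathers every stage parameter with the package's
provenance defaults (2-20 Hz band, 2 s artifact epochs at 5 SD, 120 s
windows, five microstate classes, 20 k-means restarts). ``run_pipeline``
drives a study directory (manifest + recordings) to a directory of CSV
report tables; ``process_study`` is the in-memory equivalent used by the
simulation harness. Per-recording failures are isolated and reported, not
fatal. Every output file embeds the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .backfitting import backfit, compute_parameters
from .clustering import (
    align_across_subjects,
    canonical_templates,
    extract_peak_maps,
    fit_k_range,
    gfp,
    grand_mean,
    label_canonical,
    modified_kmeans,
    select_k_with_cd,
)
from .containers import (
    EEGRecording,
    InsufficientCleanDataError,
    MicrostateError,
    StudyDataset,
    TemplateSet,
)
from .preprocessing import (
    average_reference,
    bandpass,
    flag_artifact_epochs,
    select_clean_window,
    subset_channels,
)
from .stats import run_study_analysis
from .synthetic import make_montage
from .transitions import transition_stats

logger = logging.getLogger("eegmicrostates")


@dataclass
class PipelineConfig:
    """All stage parameters, serializable and hashed into every output."""

    band: tuple = (2.0, 20.0)
    epoch_length_s: float = 2.0
    threshold_sd: float = 5.0
    target_s: float = 120.0
    min_clean_s: float = 60.0
    channels: list | None = None
    kmin: int = 5
    kmax: int = 5
    n_restarts: int = 20
    max_iter: int = 200
    tol: float = 1e-7
    seed: int = 0
    min_cd_similarity: float = 0.6
    include_edge_runs: bool = False
    bh_family: str = "per-table"
    skip_artifact_screening: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


def preprocess_recording(rec: EEGRecording, config: PipelineConfig) -> EEGRecording:
    """Canonical preprocessing order with a tolerant clean-window target.

    If fewer clean seconds than ``target_s`` survive artifact screening the
    window shrinks to what is available, down to ``min_clean_s`` (below
    which the recording fails). The shortfall is logged.
    """
    if config.channels is not None:
        rec = subset_channels(rec, config.channels)
    rec = bandpass(rec, *config.band)
    rec = average_reference(rec)
    if config.skip_artifact_screening:
        return rec
    mask = flag_artifact_epochs(rec, config.epoch_length_s, config.threshold_sd)
    epoch_len = int(round(config.epoch_length_s * rec.sfreq))
    clean_s = (np.count_nonzero(~mask.flags) * epoch_len) / rec.sfreq
    target = min(config.target_s, rec.duration_s, clean_s)
    floor = min(config.min_clean_s, config.target_s)
    if target < floor:
        raise InsufficientCleanDataError(clean_s, floor)
    if target < min(config.target_s, rec.duration_s):
        logger.info("clean window shortened to %.1f s (target %.1f s)",
                    target, config.target_s)
    return select_clean_window(rec, mask, target)


def fit_templates(recordings: list[EEGRecording], config: PipelineConfig,
                  montage=None) -> tuple[TemplateSet, list[TemplateSet]]:
    """Per-recording clustering, alignment, grand mean, canonical naming.

    With ``kmin == kmax`` the class count is fixed; otherwise each k in the
    range is fitted and the smallest k whose canonical naming covers both
    classes C and D (similarity >= ``min_cd_similarity``) wins.
    """
    if montage is None:
        montage = make_montage(channel_names=recordings[0].channel_names)
    canon = canonical_templates(montage)

    def grand_for_k(k: int) -> tuple[TemplateSet, list[TemplateSet]]:
        sets = []
        for i, rec in enumerate(recordings):
            peaks = extract_peak_maps(rec)
            sets.append(modified_kmeans(
                peaks, k, n_restarts=config.n_restarts,
                max_iter=config.max_iter, tol=config.tol,
                seed=config.seed + i,
                channel_names=list(rec.channel_names)))
        aligned = align_across_subjects(sets)
        return grand_mean(aligned), sets

    if config.kmin == config.kmax:
        gm, sets = grand_for_k(config.kmin)
        return label_canonical(gm, canon), sets
    candidates = []
    all_sets: list[TemplateSet] = []
    for k in range(config.kmin, config.kmax + 1):
        gm, sets = grand_for_k(k)
        candidates.append(gm)
        all_sets = sets
    chosen = select_k_with_cd(candidates, canon, config.min_cd_similarity)
    return chosen, all_sets


def analyze_recording(rec: EEGRecording, templates: TemplateSet,
                      config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Backfit one preprocessed recording; return parameters and deviations."""
    seg = backfit(rec, templates)
    params = compute_parameters(seg, include_edge_runs=config.include_edge_runs)
    tstats = transition_stats(seg)
    devs = {"dev_CD": tstats.dev_CD if {"C", "D"} <= set(tstats.classes) else np.nan,
            "dev_DC": tstats.dev_DC if {"C", "D"} <= set(tstats.classes) else np.nan}
    return params, devs


def process_study(study: StudyDataset, config: PipelineConfig | None = None,
                  templates: TemplateSet | None = None,
                  preprocess: bool = True) -> dict:
    """Run the full analysis on an in-memory study.

    ``templates=None`` fits templates from all recordings (per-recording
    clustering -> alignment -> grand mean -> canonical naming); passing a
    TemplateSet skips the clustering stage (used by reduced-scale
    simulation studies). Returns tidy ``params`` and ``transitions`` tables,
    the report tables, the template set, and a failures list.
    """
    if config is None:
        config = PipelineConfig()
    failures: list[dict] = []
    processed: dict = {}
    for subj in study.subjects:
        for key, rec in subj.recordings.items():
            try:
                processed[(subj.subject_id, *key)] = (
                    preprocess_recording(rec, config) if preprocess
                    else average_reference(rec))
            except MicrostateError as exc:
                failures.append({"subject": subj.subject_id, "session": key[0],
                                 "timing": key[1], "stage": "preprocess",
                                 "error": str(exc)})
    if templates is None:
        templates, _ = fit_templates(list(processed.values()), config)
    param_rows = []
    trans_rows = []
    for (sid, session, timing), rec in processed.items():
        try:
            params, devs = analyze_recording(rec, templates, config)
        except MicrostateError as exc:
            failures.append({"subject": sid, "session": session,
                             "timing": timing, "stage": "backfit",
                             "error": str(exc)})
            continue
        for cls, row in params.iterrows():
            param_rows.append({"subject": sid, "session": session,
                               "timing": timing, "class": cls, **row.to_dict()})
        trans_rows.append({"subject": sid, "session": session,
                           "timing": timing, **devs})
    params_df = pd.DataFrame(param_rows)
    trans_df = pd.DataFrame(trans_rows)
    report = run_study_analysis(study, params_df, trans_df)
    return {"templates": templates, "params": params_df,
            "transitions": trans_df, "report": report, "failures": failures,
            "config": config}


def process_study_from_truth(study: StudyDataset,
                             class_names: tuple = ("A", "B", "C", "D", "E"),
                             include_edge_runs: bool = True) -> dict:
    """Run the statistical harness on ground-truth label sequences.

    Parameters and transition deviations are computed directly from each
    recording's true label sequence (no topographies, no backfitting).
    This is the reduced-scale route for large simulation batches — it
    isolates the run-statistics and group-statistics stages from the
    topographic measurement chain, which is validated separately.
    """
    from .containers import Segmentation
    from .transitions import transition_stats as _tstats

    param_rows, trans_rows = [], []
    for subj in study.subjects:
        for (session, timing), seq in subj.true_labels.items():
            seg = Segmentation(labels=seq.labels, sfreq=seq.sfreq,
                               class_names=list(class_names))
            params = compute_parameters(seg, include_edge_runs=include_edge_runs)
            for cls, row in params.iterrows():
                param_rows.append({"subject": subj.subject_id,
                                   "session": session, "timing": timing,
                                   "class": cls, **row.to_dict()})
            ts = _tstats(seg)
            trans_rows.append({"subject": subj.subject_id, "session": session,
                               "timing": timing, "dev_CD": ts.dev_CD,
                               "dev_DC": ts.dev_DC})
    params_df = pd.DataFrame(param_rows)
    trans_df = pd.DataFrame(trans_rows)
    report = run_study_analysis(study, params_df, trans_df)
    return {"params": params_df, "transitions": trans_df, "report": report}


# ---------------------------------------------------------------------------
# directory-tree driver
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig, input_dir, output_dir) -> Path:
    """Drive a study directory (manifest + recordings) to report CSVs.

    Outputs: templates.json, parameters.csv (per subject/session/timing/
    class), transitions.csv, the four report tables, baseline_madrs.csv,
    failures.json, and config.json. Deterministic given the config seed.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = msio.load_manifest(input_dir)
    chash = config.config_hash()

    failures: list[dict] = []
    processed: dict = {}
    stai_rows = []
    madrs = {}
    sessions: list[str] = []
    for subj in manifest["subjects"]:
        sid = subj["id"]
        madrs[sid] = subj.get("madrs")
        for session, sess_entry in subj["sessions"].items():
            if session not in sessions:
                sessions.append(session)
            stai_rows.append({"subject": sid, "session": session,
                              **{f"stai_{t}": v
                                 for t, v in sess_entry["stai"].items()}})
            for timing, rel in sess_entry["recordings"].items():
                try:
                    rec = msio.read_recording(Path(manifest["_dir"]) / rel)
                    processed[(sid, session, timing)] = preprocess_recording(
                        rec, config)
                except (MicrostateError, OSError, ValueError) as exc:
                    failures.append({"subject": sid, "session": session,
                                     "timing": timing, "stage": "read/preprocess",
                                     "error": str(exc)})
    if not processed:
        raise MicrostateError("no recording survived preprocessing")
    templates, _ = fit_templates(list(processed.values()), config)

    param_rows, trans_rows = [], []
    for (sid, session, timing), rec in processed.items():
        try:
            params, devs = analyze_recording(rec, templates, config)
        except MicrostateError as exc:
            failures.append({"subject": sid, "session": session,
                             "timing": timing, "stage": "backfit",
                             "error": str(exc)})
            continue
        for cls, row in params.iterrows():
            param_rows.append({"subject": sid, "session": session,
                               "timing": timing, "class": cls, **row.to_dict()})
        trans_rows.append({"subject": sid, "session": session,
                           "timing": timing, **devs})
    params_df = pd.DataFrame(param_rows)
    trans_df = pd.DataFrame(trans_rows)

    # group statistics need the score fields; rebuild a light study shim
    stai_df = pd.DataFrame(stai_rows)
    study = _study_shim(stai_df, madrs, sessions)
    report = run_study_analysis(study, params_df, trans_df)

    msio.write_templates(templates, output_dir / "templates.json",
                         extra={"config_hash": chash})
    _write_csv(params_df, output_dir / "parameters.csv", chash)
    _write_csv(trans_df, output_dir / "transitions.csv", chash)
    table_names = {"parameters_prepost": "table_parameters_prepost.csv",
                   "transitions_prepost": "table_transitions_prepost.csv",
                   "parameters_vs_stai": "table_parameters_vs_stai.csv",
                   "transitions_vs_stai": "table_transitions_vs_stai.csv",
                   "baseline_madrs": "table_baseline_madrs.csv"}
    for key, fname in table_names.items():
        _write_csv(report[key], output_dir / fname, chash)
    (output_dir / "failures.json").write_text(json.dumps(
        {"config_hash": chash, "failures": failures}, indent=1))
    (output_dir / "config.json").write_text(json.dumps(
        {"config_hash": chash, **config.to_dict()}, indent=1))
    return output_dir


def _study_shim(stai_df: pd.DataFrame, madrs: dict, sessions: list) -> StudyDataset:
    """Minimal StudyDataset carrying only the score fields the stats need."""
    from .containers import SubjectRecord

    subjects = []
    for sid, group in stai_df.groupby("subject", sort=True):
        stai = {row["session"]: {"pre": row["stai_pre"], "post": row["stai_post"]}
                for _, row in group.iterrows()}
        subjects.append(SubjectRecord(
            subject_id=sid, recordings={}, true_labels={},
            templates=None, stai=stai,
            madrs=madrs.get(sid) if madrs.get(sid) is not None else np.nan,
            true_delta_transition={}))
    return StudyDataset(subjects=subjects, sessions=tuple(sessions))
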