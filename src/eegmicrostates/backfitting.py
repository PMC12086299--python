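"""Backfitting of templates at GFP peaks and microstate parameter extraction.

Grand-mean templates are assigned to each GFP peak of an individual
recording by maximal squared spatial correlation (polarity-invariant), the
assignment is spread to every sample by nearest-peak interpolation, and the
standard microstate parameters are computed from the resulting label runs:

* duration — mean lifetime of a class's runs, in ms;
* occurrence — number of its runs per second of assigned data;
* contribution — fraction of assigned time the class covers.

Runs that touch a recording edge or a splice boundary are censored (their
true length is unknown); by default they are excluded from duration and
occurrence but still counted in contribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    UNASSIGNED,
    DegenerateDataError,
    EEGRecording,
    GFPSeries,
    ParameterError,
    Segmentation,
    TemplateSet,
)
from .clustering import _normalize_maps, gfp


def assign_at_peaks(rec: EEGRecording, gfps: GFPSeries,
                    templates: TemplateSet) -> np.ndarray:
    """Label each GFP peak by max squared correlation with the templates.

    Ties go to the lowest class index; a zero-variance peak map gets
    UNASSIGNED.
    """
    if rec.n_channels != templates.n_channels:
        raise ParameterError("recording and templates differ in channel count")
    peaks = gfps.peak_indices
    labels = np.full(peaks.size, UNASSIGNED, dtype=int)
    if peaks.size == 0:
        return labels
    maps = rec.data[:, peaks].T
    var = maps.var(axis=1)
    ok = var > 0
    maps_n = _normalize_maps(maps[ok])
    tmpl_n = _normalize_maps(templates.maps.copy())
    corr2 = (maps_n @ tmpl_n.T) ** 2
    # argmax returns the lowest index on ties — the documented tie-break
    labels[ok] = np.argmax(corr2, axis=1)
    return labels


def interpolate_labels(peak_labels: np.ndarray, peak_indices: np.ndarray,
                       n_samples: int, sfreq: float,
                       class_names: list[str],
                       splices: list[int] | None = None) -> Segmentation:
    """Nearest-peak interpolation of peak labels to every sample.

    Exact midpoints between two peaks go to the earlier peak. Samples
    before the first / after the last peak of a block take that peak's
    label. Interpolation never crosses a splice boundary: each spliced
    block uses only its own peaks, and a block without peaks is left
    unassigned.
    """
    splices = list(splices or [])
    peak_indices = np.asarray(peak_indices, dtype=int)
    peak_labels = np.asarray(peak_labels, dtype=int)
    if peak_indices.size != peak_labels.size:
        raise ParameterError("peak_labels and peak_indices must align")
    labels = np.full(n_samples, UNASSIGNED, dtype=int)
    bounds = [0] + sorted(splices) + [n_samples]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_block = (peak_indices >= lo) & (peak_indices < hi)
        p_idx = peak_indices[in_block]
        p_lab = peak_labels[in_block]
        if p_idx.size == 0:
            continue
        samples = np.arange(lo, hi)
        # nearest peak; exact midpoint -> earlier peak
        pos = np.searchsorted(p_idx, samples)
        pos_left = np.clip(pos - 1, 0, p_idx.size - 1)
        pos_right = np.clip(pos, 0, p_idx.size - 1)
        d_left = np.abs(samples - p_idx[pos_left])
        d_right = np.abs(p_idx[pos_right] - samples)
        use_left = d_left <= d_right
        nearest = np.where(use_left, pos_left, pos_right)
        labels[lo:hi] = p_lab[nearest]
    return Segmentation(labels=labels, sfreq=sfreq, class_names=list(class_names),
                        splice_boundaries=sorted(splices))


def backfit(rec: EEGRecording, templates: TemplateSet,
            gfps: GFPSeries | None = None) -> Segmentation:
    """assign_at_peaks + interpolate_labels on one recording."""
    if gfps is None:
        gfps = gfp(rec)
    peak_labels = assign_at_peaks(rec, gfps, templates)
    return interpolate_labels(peak_labels, gfps.peak_indices, rec.n_samples,
                              rec.sfreq, list(templates.labels),
                              rec.splice_boundaries)


# ---------------------------------------------------------------------------
# runs and parameters
# ---------------------------------------------------------------------------


def extract_runs(seg: Segmentation) -> pd.DataFrame:
    """Maximal constant-label runs that never cross a splice boundary.

    Columns: class_index, start, length (samples), truncated (touches an
    edge or splice). Unassigned stretches are not runs.
    """
    frames = []
    bounds = [0] + sorted(seg.splice_boundaries) + [seg.n_samples]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        block = seg.labels[lo:hi]
        if block.size == 0:
            continue
        change = np.flatnonzero(np.diff(block) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [block.size]))
        classes = block[starts]
        truncated = (starts == 0) | (ends == block.size)
        keep = classes != UNASSIGNED
        frames.append(pd.DataFrame({
            "class_index": classes[keep].astype(int),
            "start": (lo + starts[keep]).astype(int),
            "length": (ends[keep] - starts[keep]).astype(int),
            "truncated": truncated[keep],
        }))
    if not frames:
        return pd.DataFrame(columns=["class_index", "start", "length",
                                     "truncated"])
    return pd.concat(frames, ignore_index=True)


def compute_parameters(seg: Segmentation,
                       include_edge_runs: bool = False) -> pd.DataFrame:
    """Duration (ms), occurrence (1/s) and contribution per microstate class.

    Censored runs (touching an edge or splice) are excluded from duration
    and occurrence unless ``include_edge_runs`` is set; contribution always
    counts every assigned sample. Returns a DataFrame indexed by class name
    with columns duration_ms, occurrence_per_s, contribution.
    """
    runs = extract_runs(seg)
    if runs.empty:
        raise DegenerateDataError("segmentation has no assigned samples")
    assigned_samples = int(runs["length"].sum())
    assigned_seconds = assigned_samples / seg.sfreq
    counted = runs if include_edge_runs else runs[~runs["truncated"]]
    out = []
    for c, name in enumerate(seg.class_names):
        cls_runs = counted[counted["class_index"] == c]
        all_cls = runs[runs["class_index"] == c]
        duration_ms = (float(cls_runs["length"].mean()) * 1000.0 / seg.sfreq
                       if len(cls_runs) else np.nan)
        occurrence = len(cls_runs) / assigned_seconds
        contribution = float(all_cls["length"].sum()) / assigned_samples
        out.append((name, duration_ms, occurrence, contribution))
    return pd.DataFrame(out, columns=["class", "duration_ms",
                                      "occurrence_per_s", "contribution"]
                        ).set_index("class")


def true_parameters(labels: np.ndarray, sfreq: float,
                    class_names: list[str],
                    include_edge_runs: bool = True) -> pd.DataFrame:
    """Parameters of a ground-truth label sequence (no backfitting)."""
    seg = Segmentation(labels=np.asarray(labels, dtype=int), sfreq=sfreq,
                       class_names=list(class_names))
    return compute_parameters(seg, include_edge_runs=include_edge_runs)
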