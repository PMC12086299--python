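"""Band-limiting, re-referencing, artifact screening, clean-window selection.

The canonical order for microstate work is: band-pass (2-20 Hz) ->
average reference -> artifact flagging -> earliest-clean-window selection
-> channel subsetting (with the average reference re-applied, since
dropping rows breaks the zero channel mean).

Artifact screening follows a per-epoch outlier rule: for each fixed-length
epoch, compute mean absolute amplitude, mean global field power, skewness
and kurtosis; flag the epoch if ANY statistic strictly exceeds its
across-epoch mean + threshold_sd x across-epoch SD (one-sided, 5 SD by
default). Ocular-artifact removal by ICA is intentionally out of scope; the
functions accept externally cleaned data unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .containers import (
    ArtifactMask,
    ChannelNotFoundError,
    EEGRecording,
    InsufficientCleanDataError,
    ParameterError,
)

DEFAULT_BAND = (2.0, 20.0)
DEFAULT_EPOCH_S = 2.0
DEFAULT_THRESHOLD_SD = 5.0
DEFAULT_TARGET_S = 120.0


def bandpass(rec: EEGRecording, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, default 2-20 Hz)."""
    nyq = rec.sfreq / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=rec.sfreq, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy(data=filtered,
                    filter=f"butter{order}-sosfiltfilt-{low_hz}-{high_hz}Hz")


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference so every sample's channel mean is zero. Idempotent."""
    if rec.n_channels < 2:
        raise ParameterError("average reference requires >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy(data=data, reference="average")


def _epoch_statistics(data: np.ndarray, starts: np.ndarray, epoch_len: int) -> dict:
    mean_amp = np.empty(starts.size)
    mean_gfp = np.empty(starts.size)
    skew = np.empty(starts.size)
    kurt = np.empty(starts.size)
    for i, s in enumerate(starts):
        chunk = data[:, s:s + epoch_len]
        mean_amp[i] = np.mean(np.abs(chunk))
        mean_gfp[i] = np.mean(chunk.std(axis=0))
        flat = chunk.ravel()
        skew[i] = sp_stats.skew(flat)
        kurt[i] = sp_stats.kurtosis(flat)
    return {"mean_amplitude": mean_amp, "mean_gfp": mean_gfp,
            "skewness": skew, "kurtosis": kurt}


def flag_artifact_epochs(rec: EEGRecording,
                         epoch_length_s: float = DEFAULT_EPOCH_S,
                         threshold_sd: float = DEFAULT_THRESHOLD_SD) -> ArtifactMask:
    """Flag epochs whose amplitude/GFP/skewness/kurtosis is a one-sided outlier.

    An epoch is flagged when any statistic strictly exceeds its across-epoch
    mean + ``threshold_sd`` x across-epoch SD. If a statistic's SD is zero
    (all epochs identical) nothing can strictly exceed the threshold, so no
    epoch is flagged on that statistic.
    """
    if epoch_length_s < 2.0 / rec.sfreq:
        raise ParameterError("epoch_length_s must cover at least 2 samples")
    if threshold_sd <= 0:
        raise ParameterError("threshold_sd must be positive")
    epoch_len = int(round(epoch_length_s * rec.sfreq))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 3:
        raise ParameterError(
            f"only {n_epochs} epochs available; need >= 3 for a usable SD"
        )
    starts = np.arange(n_epochs) * epoch_len
    stats = _epoch_statistics(rec.data, starts, epoch_len)
    flags = np.zeros(n_epochs, dtype=bool)
    for values in stats.values():
        mu, sd = float(np.mean(values)), float(np.std(values))
        flags |= values > mu + threshold_sd * sd
    return ArtifactMask(epoch_length_s=epoch_length_s, flags=flags, stats=stats)


def select_clean_window(rec: EEGRecording, mask: ArtifactMask,
                        target_s: float = DEFAULT_TARGET_S) -> EEGRecording:
    """Concatenate the earliest unflagged epochs totaling ``target_s`` seconds.

    Temporal order is preserved; sample indices where non-contiguous epochs
    were joined are recorded in ``meta['splice_boundaries']`` so that no
    downstream microstate segment or transition is measured across a splice.
    """
    if target_s > rec.duration_s:
        raise ParameterError("target_s exceeds the recording duration")
    epoch_len = int(round(mask.epoch_length_s * rec.sfreq))
    target_samples = int(round(target_s * rec.sfreq))
    clean_idx = np.flatnonzero(~mask.flags)
    available = clean_idx.size * epoch_len
    if available < target_samples:
        raise InsufficientCleanDataError(available / rec.sfreq, target_s)
    n_needed = int(np.ceil(target_samples / epoch_len))
    chosen = clean_idx[:n_needed]
    pieces = [rec.data[:, i * epoch_len:(i + 1) * epoch_len] for i in chosen]
    data = np.concatenate(pieces, axis=1)[:, :target_samples]
    splices = []
    offset = 0
    for prev, cur in zip(chosen[:-1], chosen[1:]):
        offset += epoch_len
        if cur != prev + 1 and offset < target_samples:
            splices.append(offset)
    out = rec.copy(data=data, splice_boundaries=splices,
                   selected_epochs=[int(i) for i in chosen])
    return out


def subset_channels(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Keep the named channels in the requested order, then re-average-reference."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    rows = []
    for name in names:
        if name not in index:
            raise ChannelNotFoundError(name)
        rows.append(index[name])
    sub = EEGRecording(data=rec.data[rows], sfreq=rec.sfreq,
                       channel_names=list(names), meta=dict(rec.meta))
    return average_reference(sub)


def preprocess(rec: EEGRecording, band: tuple = DEFAULT_BAND,
               epoch_length_s: float = DEFAULT_EPOCH_S,
               threshold_sd: float = DEFAULT_THRESHOLD_SD,
               target_s: float | None = DEFAULT_TARGET_S,
               channels: list[str] | None = None) -> EEGRecording:
    """Run the canonical order: subset -> bandpass -> avg ref -> flag -> select.

    ``target_s=None`` skips artifact screening/window selection (useful when
    the input is already a clean fixed-length segment).
    """
    if channels is not None:
        rec = subset_channels(rec, channels)
    rec = bandpass(rec, *band)
    rec = average_reference(rec)
    if target_s is not None:
        mask = flag_artifact_epochs(rec, epoch_length_s, threshold_sd)
        rec = select_clean_window(rec, mask, target_s)
    return rec
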