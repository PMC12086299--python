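"""File formats: EDF, delimited text matrices, template JSON, study manifests.

EDF reading goes through mne. Writing uses a minimal EDF implementation
(16-bit, one-second data records, per-channel physical scaling) kept here
because no installed library writes EDF; round-trip fidelity against the
mne reader is asserted in the test suite.

Delimited text recordings are one column per channel with a header row of
channel names (values at full repr precision, so round-trips are exact);
the sampling rate travels in a JSON sidecar or an explicit argument.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, ParameterError, StudyDataset, TemplateSet

# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    Requires an integer sampling rate; if the recording is not a whole
    number of seconds the final record is zero-padded (the pad length is
    recoverable from the stored durations).
    """
    path = Path(path)
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    data = rec.data
    if n_records * spr != rec.n_samples:
        pad = n_records * spr - rec.n_samples
        data = np.concatenate([data, np.zeros((n_ch, pad))], axis=1)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.rint((data - phys_min[:, None]) / scale[:, None]
                      + _EDF_DIG_MIN).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field("X X X X", 80))
        fh.write(_ascii_field("Startdate X X X X", 80))
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field("1", 8))
        fh.write(_ascii_field(n_ch, 4))
        for name in rec.channel_names:
            fh.write(_ascii_field(f"EEG {name}", 16))
        for _ in range(n_ch):
            fh.write(_ascii_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_ascii_field("uV", 8))
        for v in phys_min:
            fh.write(_ascii_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_ascii_field(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(_EDF_DIG_MIN, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(_EDF_DIG_MAX, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 80))
        for _ in range(n_ch):
            fh.write(_ascii_field(spr, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 32))
        for r in range(n_records):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())
    return path


def read_edf(path) -> EEGRecording:
    """Read an EDF file (via mne) into an EEGRecording in µV."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return EEGRecording(data=data, sfreq=float(raw.info["sfreq"]),
                        channel_names=names, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------


def write_delimited(rec: EEGRecording, path, sidecar: bool = True) -> Path:
    """One column per channel, header row of channel names, full precision."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False)
    if sidecar:
        meta = {"sfreq": rec.sfreq}
        if rec.splice_boundaries:
            meta["splice_boundaries"] = rec.splice_boundaries
        Path(str(path) + ".json").write_text(json.dumps(meta))
    return path


def read_delimited(path, sfreq: float | None = None) -> EEGRecording:
    """Read a delimited channels-in-columns matrix; sfreq from arg or sidecar."""
    path = Path(path)
    meta: dict = {}
    if sfreq is None:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise ParameterError(
                f"no sampling rate given and no sidecar {sidecar.name} found"
            )
        meta = json.loads(sidecar.read_text())
        if "sfreq" not in meta:
            raise ParameterError("sidecar lacks an 'sfreq' field")
        sfreq = float(meta["sfreq"])
    df = pd.read_csv(path, float_precision="round_trip")
    rec_meta = {"source": str(path)}
    if "splice_boundaries" in meta:
        rec_meta["splice_boundaries"] = list(meta["splice_boundaries"])
    return EEGRecording(data=df.to_numpy().T, sfreq=sfreq,
                        channel_names=list(df.columns), meta=rec_meta)


def read_recording(path, format: str = "auto", sfreq: float | None = None) -> EEGRecording:
    """Dispatch on ``format``: 'edf', 'delimited', or 'auto' (by extension)."""
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return read_edf(path)
    if format == "delimited":
        return read_delimited(path, sfreq=sfreq)
    raise ParameterError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# template sets
# ---------------------------------------------------------------------------


def write_templates(tset: TemplateSet, path, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "k": tset.k,
        "labels": tset.labels,
        "gev": None if np.isnan(tset.gev) else tset.gev,
        "channel_names": tset.channel_names,
        "maps": tset.maps.tolist(),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_templates(path) -> TemplateSet:
    payload = json.loads(Path(path).read_text())
    return TemplateSet(maps=np.array(payload["maps"]),
                       labels=payload["labels"],
                       gev=payload["gev"] if payload["gev"] is not None else float("nan"),
                       channel_names=payload["channel_names"])


# ---------------------------------------------------------------------------
# study directory trees
# ---------------------------------------------------------------------------


def write_study(study: StudyDataset, out_dir, file_format: str = "delimited") -> Path:
    """Write a study as a directory tree with a JSON manifest.

    Layout: ``<out>/manifest.json`` plus one recording file per
    subject/session/timing. The manifest carries subject ids, score fields
    and relative recording paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"file_format": file_format, "subjects": []}
    for subj in study.subjects:
        entry: dict = {"id": subj.subject_id, "madrs": subj.madrs, "sessions": {}}
        for session in study.sessions:
            sess_entry = {"stai": subj.stai[session], "recordings": {}}
            for timing in ("pre", "post"):
                rec = subj.recordings[(session, timing)]
                ext = "edf" if file_format == "edf" else "csv"
                rel = f"{subj.subject_id}_{session}_{timing}.{ext}"
                if file_format == "edf":
                    write_edf(rec, out_dir / rel)
                else:
                    write_delimited(rec, out_dir / rel)
                sess_entry["recordings"][timing] = rel
            entry["sessions"][session] = sess_entry
        manifest["subjects"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_manifest(study_dir) -> dict:
    study_dir = Path(study_dir)
    manifest_path = study_dir / "manifest.json"
    if not manifest_path.exists():
        raise ParameterError(f"no manifest.json in {study_dir}")
    manifest = json.loads(manifest_path.read_text())
    manifest["_dir"] = str(study_dir)
    return manifest


def load_study_recording(manifest: dict, subject_id: str, session: str,
                         timing: str) -> EEGRecording:
    base = Path(manifest["_dir"])
    for subj in manifest["subjects"]:
        if subj["id"] == subject_id:
            rel = subj["sessions"][session]["recordings"][timing]
            return read_recording(base / rel)
    raise ParameterError(f"subject {subject_id!r} not in manifest")
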