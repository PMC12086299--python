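"""Shared data containers and exceptions for the microstate pipeline.

The containers are deliberately thin: plain dataclasses around numpy arrays,
validated on construction, with pandas only at the reporting boundary.
Conventions used throughout the package:

* EEG data matrices are ``(n_channels, n_samples)`` float64 arrays in µV.
* Topographic maps (template rows) are average-referenced (zero channel
  mean) and, for templates, unit L2 norm.
* Class labels are integer indices into a template set; the canonical
  microstate names A–E are attached at the template-set level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

UNASSIGNED = -1  # segmentation label for samples no template could claim


class MicrostateError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(MicrostateError, ValueError):
    """An argument violates a precondition (bad band, |rho|>1, kmin>kmax...)."""


class ChannelNotFoundError(MicrostateError, KeyError):
    """A requested channel name is absent from the montage or recording."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"channel {self.name!r} not found"


class InsufficientCleanDataError(MicrostateError):
    """Fewer clean seconds are available than the requested window length."""

    def __init__(self, available_s: float, target_s: float):
        self.available_s = float(available_s)
        self.target_s = float(target_s)
        super().__init__(
            f"{self.available_s:.1f} s clean available, {self.target_s:.1f} s requested"
        )


class GenerationError(MicrostateError):
    """The synthetic generator could not satisfy its constraints."""


class DegenerateDataError(MicrostateError, ValueError):
    """Input is degenerate for the requested statistic (zero variance etc.)."""


# ---------------------------------------------------------------------------
# recordings and montages
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """A multichannel EEG segment: ``data`` is (n_channels, n_samples) in µV."""

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D (channels x samples) array")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains NaN or Inf")
        if self.sfreq <= 0:
            raise ParameterError("sfreq must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def splice_boundaries(self) -> list[int]:
        """Sample indices where non-contiguous epochs were joined."""
        return list(self.meta.get("splice_boundaries", []))

    def copy(self, data: np.ndarray | None = None, **meta_updates) -> "EEGRecording":
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            meta=new_meta,
        )


@dataclass
class Montage:
    """Electrode names and unit-sphere 3-D positions (rows match names)."""

    channel_names: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channel_names), 3):
            raise ParameterError("positions must be (n_channels, 3)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError("channel names must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


# ---------------------------------------------------------------------------
# synthetic-study containers
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic resting-state EEG generator.

    Defaults mirror the acquisition and analysis regime the pipeline
    targets: 30 channels of the 10-10 system sampled at 500 Hz, 120 s
    epochs, five microstate classes with mean durations on the 55-85 ms
    scale, and a 10 Hz GFP envelope (≈20 GFP peaks/s).
    """

    n_channels: int = 30
    sfreq: float = 500.0
    duration_s: float = 120.0
    n_classes: int = 5
    mean_durations_ms: tuple = (58.0, 56.0, 59.0, 73.0, 64.0)
    transition_matrix: np.ndarray | None = None
    envelope_freq_hz: float = 10.0
    noise_sd: float = 0.5
    noise_length_scale: float = 1.0
    spatial_noise: bool = True
    gain_uv: float = 10.0
    run_length_law: str = "geometric"  # or "gamma"
    gamma_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_durations_ms = tuple(float(d) for d in self.mean_durations_ms)
        if len(self.mean_durations_ms) != self.n_classes:
            raise ParameterError("mean_durations_ms length must equal n_classes")
        min_ms = 2.0 * 1000.0 / self.sfreq
        if any(d <= min_ms for d in self.mean_durations_ms):
            raise ParameterError(
                f"mean durations must exceed {min_ms:.1f} ms (2 samples)"
            )
        if self.transition_matrix is None:
            k = self.n_classes
            t = np.full((k, k), 1.0 / (k - 1))
            np.fill_diagonal(t, 0.0)
            self.transition_matrix = t
        else:
            t = np.asarray(self.transition_matrix, dtype=float)
            if t.shape != (self.n_classes, self.n_classes):
                raise ParameterError("transition_matrix must be k x k")
            if np.any(np.diag(t) != 0.0):
                raise ParameterError("transition_matrix diagonal must be exactly 0")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ParameterError("transition_matrix rows must sum to 1")
            self.transition_matrix = t
        if self.run_length_law not in ("geometric", "gamma"):
            raise ParameterError("run_length_law must be 'geometric' or 'gamma'")


@dataclass
class LabelSequence:
    """Per-sample ground-truth class indices for a synthetic recording."""

    labels: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ParameterError("labels must be 1-D")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class SubjectRecord:
    """One subject's four recordings (2 sessions x pre/post) plus scores."""

    subject_id: str
    recordings: dict  # (session, timing) -> EEGRecording (may be empty)
    true_labels: dict  # (session, timing) -> LabelSequence
    templates: "TemplateSet | None"
    stai: dict  # session -> {"pre": float, "post": float}
    madrs: float
    true_delta_transition: dict  # session -> planted change in D->C enrichment
    true_durations: dict = field(default_factory=dict)  # (session, timing) -> tuple (ms)


@dataclass
class StudyDataset:
    """A balanced paired pre/post, two-session synthetic study."""

    subjects: list
    sessions: tuple = ("DMPFC", "DLPFC")
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# clustering containers
# ---------------------------------------------------------------------------


@dataclass
class GFPSeries:
    """Global field power per sample with strict local-maxima indices."""

    values: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(self.values < 0):
            raise ParameterError("GFP values must be non-negative")
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ParameterError("peak indices must be strictly increasing")


@dataclass
class TemplateSet:
    """k topographic templates: zero-mean, unit-norm rows with class labels."""

    maps: np.ndarray
    labels: list[str]
    gev: float = float("nan")
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ParameterError("maps must be (k, n_channels)")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.maps.shape[0]:
            raise ParameterError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def reordered(self, order: Sequence[int], labels: Sequence[str] | None = None) -> "TemplateSet":
        order = list(order)
        return TemplateSet(
            maps=self.maps[order],
            labels=[self.labels[i] for i in order] if labels is None else list(labels),
            gev=self.gev,
            channel_names=self.channel_names,
        )


@dataclass
class AlignmentResult:
    """Outcome of across-subject template alignment."""

    permutations: list  # per subject: list of source indices, target order
    polarity_signs: np.ndarray  # (n_subjects, k) of ±1
    mean_shared_variance: float
    aligned_sets: list  # per subject TemplateSet in the common order


# ---------------------------------------------------------------------------
# segmentation, parameters, transitions
# ---------------------------------------------------------------------------


@dataclass
class ArtifactMask:
    """Per-epoch artifact flags plus the statistics that produced them."""

    epoch_length_s: float
    flags: np.ndarray
    stats: dict  # name -> per-epoch array

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.flags.size

    def to_frame(self):
        """Tidy per-epoch table: index, the four statistics, and the flag."""
        import pandas as pd

        out = pd.DataFrame({"epoch": range(self.n_epochs), **self.stats,
                            "flag": self.flags})
        return out


@dataclass
class Segmentation:
    """Per-sample integer class labels (UNASSIGNED = -1) plus splices."""

    labels: np.ndarray
    sfreq: float
    class_names: list[str]
    splice_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ParameterError("label index outside class_names")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class TransitionStats:
    """Observed / expected / deviation run-transition matrices."""

    classes: list[str]
    counts: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    deviation: np.ndarray

    def _cell(self, matrix: np.ndarray, a: str, b: str) -> float:
        ia, ib = self.classes.index(a), self.classes.index(b)
        return float(matrix[ia, ib])

    def dev(self, a: str, b: str) -> float:
        return self._cell(self.deviation, a, b)

    @property
    def dev_CD(self) -> float:
        return self.dev("C", "D")

    @property
    def dev_DC(self) -> float:
        return self.dev("D", "C")


@dataclass
class TestResult:
    """A single statistical test outcome (Wilcoxon V, t, r, or W)."""

    statistic_name: str
    value: float
    p: float
    df: int | None = None
    r: float | None = None
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"p={self.p} outside [0, 1]")
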