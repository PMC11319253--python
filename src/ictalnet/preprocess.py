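"""Epoching, Chebyshev band-pass filtering, and the nine binary tasks.

Records are cut into non-overlapping fixed-length epochs (default 1,024
samples, turning each 4,096-sample Bonn record into four classification
instances).  Epochs are band-pass filtered with a zero-phase Chebyshev
type-I filter (3–40 Hz by default) before feature extraction.

The nine standard binary tasks pit combinations of the five Bonn classes
against each other; the seizure/epileptic side is the *positive* class so
that sensitivity always reads as seizure detection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .bonn import CLASS_LABELS, EEGRecord


@dataclass
class EpochSet:
    """A stack of equal-length epochs with per-epoch labels and provenance.

    ``labels`` holds class letters for per-class sets or 0/1 integers after
    :func:`build_task`.  ``provenance`` records ``(record_id, offset)`` for
    each epoch, with offsets in samples from the start of the source record.
    """

    epochs: np.ndarray  # (n_epochs, epoch_len)
    labels: np.ndarray  # (n_epochs,)
    fs: float
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be 2-D (n_epochs, epoch_len)")
        if self.labels.shape[0] != self.epochs.shape[0]:
            raise ValueError(
                f"{self.labels.shape[0]} labels for {self.epochs.shape[0]} epochs"
            )
        if self.provenance and len(self.provenance) != self.epochs.shape[0]:
            raise ValueError("provenance length must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[1]

    def __len__(self) -> int:
        return self.n_epochs


def segment(record: EEGRecord, epoch_len: int = 1024) -> EpochSet:
    """Cut a record into non-overlapping epochs of ``epoch_len`` samples.

    The window stride equals the window length, so ``floor(len/epoch_len)``
    epochs are produced in temporal order and any trailing remainder is
    dropped.  An epoch length exceeding the record yields zero epochs and a
    warning rather than an exception.
    """
    if epoch_len < 1:
        raise ValueError(f"epoch_len must be >= 1, got {epoch_len}")
    n = len(record) // epoch_len
    if n == 0:
        warnings.warn(
            f"record {record.record_id!r} ({len(record)} samples) is shorter than "
            f"epoch_len={epoch_len}; produced 0 epochs",
            stacklevel=2,
        )
        return EpochSet(
            epochs=np.empty((0, epoch_len)),
            labels=np.empty((0,), dtype=object),
            fs=record.fs,
            provenance=[],
        )
    data = record.samples[: n * epoch_len].reshape(n, epoch_len)
    labels = np.array([record.class_label] * n, dtype=object)
    provenance = [(record.record_id, i * epoch_len) for i in range(n)]
    return EpochSet(epochs=data, labels=labels, fs=record.fs, provenance=provenance)


def segment_class(records: Sequence[EEGRecord], epoch_len: int = 1024) -> EpochSet:
    """Segment several records (one class) into a single EpochSet."""
    parts = [segment(r, epoch_len) for r in records]
    parts = [p for p in parts if p.n_epochs > 0]
    if not parts:
        raise ValueError("no record produced any epoch")
    return EpochSet(
        epochs=np.concatenate([p.epochs for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        fs=parts[0].fs,
        provenance=[pv for p in parts for pv in p.provenance],
    )


def bandpass_design(
    fs: float,
    low_hz: float = 3.0,
    high_hz: float = 40.0,
    order: int = 4,
    ripple_db: float = 0.5,
) -> np.ndarray:
    """Design the Chebyshev type-I band-pass filter (second-order sections)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low_hz}, high={high_hz}, fs={fs}"
        )
    return signal.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(
    epochs: EpochSet,
    low_hz: float = 3.0,
    high_hz: float = 40.0,
    order: int = 4,
    ripple_db: float = 0.5,
) -> EpochSet:
    """Zero-phase Chebyshev type-I band-pass of every epoch.

    Applied forward-backward (``sosfiltfilt``) so the passband is traversed
    twice in magnitude but with no phase distortion.  Labels and provenance
    are carried through unchanged.
    """
    sos = bandpass_design(epochs.fs, low_hz, high_hz, order, ripple_db)
    if epochs.n_epochs == 0:
        return epochs
    filtered = signal.sosfiltfilt(sos, epochs.epochs, axis=1)
    return EpochSet(
        epochs=filtered,
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        provenance=list(epochs.provenance),
    )


def bandpass_record(record: EEGRecord, **kwargs) -> EEGRecord:
    """Zero-phase band-pass of a whole record (filter-then-segment mode)."""
    sos = bandpass_design(record.fs, **kwargs) if kwargs else bandpass_design(record.fs)
    return EEGRecord(
        samples=signal.sosfiltfilt(sos, record.samples),
        fs=record.fs,
        class_label=record.class_label,
        record_id=record.record_id,
    )


@dataclass(frozen=True)
class TaskSpec:
    """A binary task: which classes are positive (abnormal) vs negative."""

    name: str
    positive_classes: frozenset[str]
    negative_classes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive_classes or not self.negative_classes:
            raise ValueError(f"task {self.name!r}: both class sets must be non-empty")
        if self.positive_classes & self.negative_classes:
            raise ValueError(
                f"task {self.name!r}: classes "
                f"{sorted(self.positive_classes & self.negative_classes)} "
                "appear on both sides"
            )
        unknown = (self.positive_classes | self.negative_classes) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"task {self.name!r}: unknown classes {sorted(unknown)}")

    @property
    def classes(self) -> tuple[str, ...]:
        """All classes in the task, canonical A<B<C<D<E order."""
        return tuple(sorted(self.positive_classes | self.negative_classes))


def _task(name: str, neg: str, pos: str) -> TaskSpec:
    return TaskSpec(name, frozenset(pos), frozenset(neg))


#: The nine standard binary tasks.  The ictal class E is positive wherever it
#: appears; in AB vs CD the interictal (epileptic) CD side is positive.
TASKS: dict[str, TaskSpec] = {
    t.name: t
    for t in (
        _task("A_vs_E", "A", "E"),
        _task("B_vs_E", "B", "E"),
        _task("AB_vs_E", "AB", "E"),
        _task("C_vs_E", "C", "E"),
        _task("D_vs_E", "D", "E"),
        _task("CD_vs_E", "CD", "E"),
        _task("AB_vs_CD", "AB", "CD"),
        _task("AB_vs_CDE", "AB", "CDE"),
        _task("ABCD_vs_E", "ABCD", "E"),
    )
}


def build_task(classes: Mapping[str, EpochSet], spec: TaskSpec) -> EpochSet:
    """Assemble a binary task dataset from per-class epoch sets.

    Epochs are concatenated in canonical class order (A<B<C<D<E), preserving
    record order within each class; labels are 1 for the positive side.
    """
    missing = [c for c in spec.classes if c not in classes]
    if missing:
        raise KeyError(f"task {spec.name!r} needs classes {missing} not provided")
    blocks, labels, prov = [], [], []
    fs = None
    for label in spec.classes:
        es = classes[label]
        fs = es.fs if fs is None else fs
        blocks.append(es.epochs)
        labels.append(
            np.full(es.n_epochs, 1 if label in spec.positive_classes else 0, dtype=int)
        )
        prov.extend(es.provenance if es.provenance else [("", 0)] * es.n_epochs)
    return EpochSet(
        epochs=np.concatenate(blocks, axis=0),
        labels=np.concatenate(labels),
        fs=fs,
        provenance=prov,
    )
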