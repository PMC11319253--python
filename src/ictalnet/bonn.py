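"""Reading and writing single-channel EEG records in the Bonn ASCII dialect.

The Bonn epilepsy corpus ships each record as a plain-text file with one
integer amplitude sample (µV) per line and no header; records are grouped in
one directory per class.  The five classes are

    A  surface EEG, healthy volunteer, eyes open
    B  surface EEG, healthy volunteer, eyes closed
    C  intracranial, epileptic patient, interictal, contralateral hippocampus
    D  intracranial, epileptic patient, interictal, epileptogenic zone
    E  intracranial, epileptic patient, ictal (seizure)

Files carry no sampling-rate metadata, so ``fs`` is supplied by the caller
(default 173.61 Hz, the corpus' digitisation rate).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The five Bonn class labels, in canonical order.
CLASS_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Digitisation rate of the Bonn corpus, in Hz.
DEFAULT_FS: float = 173.61

#: Samples per record in the Bonn corpus.
BONN_RECORD_LEN: int = 4096


class BonnParseError(ValueError):
    """A record file contains a line that does not parse as an integer."""


@dataclass
class EEGRecord:
    """One labelled single-channel EEG signal.

    Parameters
    ----------
    samples:
        Amplitude samples in µV (the file dialect stores integers, but
        synthetic float-mode records are allowed in memory).
    fs:
        Sampling rate in Hz; must be positive.
    class_label:
        One of ``A``..``E``, or ``None`` for unlabelled signals.
    record_id:
        Identifier, typically the source file stem.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    class_label: str | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs


@dataclass
class ClassSet:
    """All records of one Bonn class, sharing label and sampling rate."""

    label: str
    records: list[EEGRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")
        for rec in self.records:
            if rec.class_label != self.label:
                raise ValueError(
                    f"record {rec.record_id!r} has class {rec.class_label!r}, "
                    f"expected {self.label!r}"
                )
        fss = {rec.fs for rec in self.records}
        if len(fss) > 1:
            raise ValueError(f"records mix sampling rates: {sorted(fss)}")

    def __len__(self) -> int:
        return len(self.records)


def read_record(
    path: str | os.PathLike,
    fs: float = DEFAULT_FS,
    class_label: str | None = None,
    record_id: str | None = None,
) -> EEGRecord:
    """Read one Bonn-dialect record: one ASCII integer per line.

    Blank lines are ignored; surrounding whitespace is tolerated.  A
    non-numeric line raises :class:`BonnParseError` naming the line number;
    an empty file raises :class:`BonnParseError` as well.
    """
    path = Path(path)
    values: list[int] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(int(stripped))
            except ValueError:
                raise BonnParseError(
                    f"{path}: line {lineno}: {stripped!r} is not an integer"
                ) from None
    if not values:
        raise BonnParseError(f"{path}: file contains no samples")
    return EEGRecord(
        samples=np.asarray(values, dtype=np.float64),
        fs=fs,
        class_label=class_label,
        record_id=record_id if record_id is not None else path.stem,
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # round to nearest, ties away from zero (np.round ties to even)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_record(
    record: EEGRecord, path: str | os.PathLike, precise: bool = False
) -> Path:
    """Write a record in the Bonn dialect, one sample per line.

    By default samples are rounded to the nearest integer with ties away
    from zero, keeping the file in-dialect.  ``precise=True`` writes full
    ``repr`` precision for synthetic float-mode data.
    """
    path = Path(path)
    if record.samples.size == 0:  # defensive; EEGRecord forbids this
        raise ValueError("refusing to write an empty record")
    if precise:
        lines = [repr(float(v)) for v in record.samples]
    else:
        lines = [str(int(v)) for v in _round_half_away(record.samples)]
    path.write_text("\n".join(lines) + "\n")
    return path


def load_dataset(
    root: str | os.PathLike,
    classes: Sequence[str] = CLASS_LABELS,
    fs: float = DEFAULT_FS,
) -> dict[str, ClassSet]:
    """Load a ``<root>/<class>/<record>.txt`` tree into per-class sets.

    Record ordering within a class is lexicographic by filename, so two
    invocations always produce the same dataset.  A requested class whose
    directory is missing (or empty) raises ``FileNotFoundError`` listing
    what was found instead.
    """
    root = Path(root)
    for label in classes:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class {label!r}; valid: {CLASS_LABELS}")
    found = sorted(p.name for p in root.iterdir() if p.is_dir()) if root.is_dir() else []
    out: dict[str, ClassSet] = {}
    for label in classes:
        class_dir = root / label
        if not class_dir.is_dir():
            raise FileNotFoundError(
                f"class directory {class_dir} not found; directories present "
                f"under {root}: {found or 'none'}"
            )
        files = sorted(
            p for p in class_dir.iterdir() if p.is_file() and not p.name.startswith(".")
        )
        if not files:
            raise FileNotFoundError(f"class directory {class_dir} contains no records")
        records = [
            read_record(p, fs=fs, class_label=label, record_id=p.stem) for p in files
        ]
        out[label] = ClassSet(label=label, records=records)
    return out
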