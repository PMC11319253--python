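"""Feature extraction dispatch and the on-disk feature container.

Four feature kinds are supported per epoch:

    fft   m×n FFT magnitude matrix (default 32×32 for 1,024-sample epochs)
    dwt   concatenated DWT subband coefficients (db4, 5 levels)
    emd   first five intrinsic mode functions stacked as channels
    raw   the band-passed samples themselves

Every kind is max-magnitude normalised per epoch before the classifier
(an explicit default; disable with ``normalize=False``), so the network
sees shape, not absolute amplitude.

Dumps are single ``.npz`` files keyed by epoch with labels and
``(record_id, offset)`` provenance, plus a JSON metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .emd import emd_feature
from .fourier import fft_feature
from .preprocess import EpochSet
from .wavelet import dwt_feature

FEATURE_KINDS = ("fft", "dwt", "emd", "raw")

#: Natural network input layout for each feature kind.
FEATURE_LAYOUTS = {
    "fft": "matrix_rows_as_steps",
    "dwt": "flat_sequence",
    "emd": "flat_sequence",
    "raw": "flat_sequence",
}


def _normalize(f: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def extract_epoch(epoch: np.ndarray, kind: str, normalize: bool = True, **opts):
    """Feature array for a single epoch."""
    if kind == "fft":
        f = fft_feature(epoch, m=opts.get("m", 32), n=opts.get("n", 32))
    elif kind == "dwt":
        f = dwt_feature(
            epoch,
            levels=opts.get("levels", 5),
            wavelet=opts.get("wavelet", "db4"),
            mode=opts.get("mode", "periodization"),
        )
    elif kind == "emd":
        f = emd_feature(epoch, n_channels=opts.get("n_channels", 5))
    elif kind == "raw":
        f = np.asarray(epoch, dtype=np.float64)
    else:
        raise ValueError(f"unknown feature kind {kind!r}; valid: {FEATURE_KINDS}")
    return _normalize(f) if normalize else f


def extract(epochs: EpochSet, kind: str, normalize: bool = True, **opts) -> np.ndarray:
    """Features for every epoch, stacked along axis 0."""
    return np.stack(
        [extract_epoch(e, kind, normalize=normalize, **opts) for e in epochs.epochs]
    )


def dump_features(
    path: str | Path,
    features: np.ndarray,
    labels: np.ndarray,
    provenance: list[tuple[str, int]],
    task: str = "",
    kind: str = "",
) -> Path:
    """Write one feature record per epoch with (task, record_id, offset) keys."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "task": task,
        "kind": kind,
        "shape": list(features.shape),
    }
    np.savez(
        path,
        meta=json.dumps(meta),
        features=np.asarray(features, dtype=np.float64),
        labels=np.asarray(labels, dtype="U8"),
        record_ids=np.asarray([p[0] for p in provenance], dtype="U64"),
        offsets=np.asarray([p[1] for p in provenance], dtype=np.int64),
    )
    return path


def load_features(path: str | Path):
    """Read back a feature dump: (features, labels, provenance, meta)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        features = data["features"]
        labels = data["labels"]
        provenance = list(
            zip(data["record_ids"].tolist(), data["offsets"].tolist())
        )
    return features, labels, provenance, meta
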