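"""10-fold cross-validation, confusion counts, Sen/Spe/Acc, task comparison.

The convention throughout: the seizure/epileptic side of a task is the
positive class, so sensitivity Sen = TP/(TP+FN) is the seizure detection
rate, specificity Spe = TN/(TN+FP) the normal recognition rate, and
Acc = (TP+TN)/total.  Folds are stratified by label and shuffled by a
recorded seed; each fold trains a fresh model.  Reports keep full-precision
proportions internally and round half-up to four decimals only for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feature_mod
from . import model as model_mod
from .model import ModelConfig, TrainedModel
from .preprocess import EpochSet


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class FoldResult:
    fold: int  # 1-based, K1..K10
    counts: ConfusionCounts
    acc: float
    sen: float | None
    spe: float | None


@dataclass
class CVReport:
    task: str
    folds: list[FoldResult]
    mean_acc: float
    mean_sen: float
    mean_spe: float
    seed: int
    feature_kind: str = ""

    def accuracies(self) -> np.ndarray:
        return np.array([f.acc for f in self.folds])

    def to_frame(self) -> pd.DataFrame:
        """Per-fold table: rows K1..K10 + Mean, columns Acc/Sen/Spe."""
        rows = {
            f"K{f.fold}": [f.acc, f.sen, f.spe] for f in self.folds
        }
        rows["Mean"] = [self.mean_acc, self.mean_sen, self.mean_spe]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=["Acc", "Sen", "Spe"])
        return df.map(lambda v: round_half_up(v) if v is not None else None)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="Fold")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "task": self.task,
            "feature_kind": self.feature_kind,
            "seed": self.seed,
            "folds": [
                {
                    "fold": f.fold,
                    "tp": f.counts.tp,
                    "fn": f.counts.fn,
                    "tn": f.counts.tn,
                    "fp": f.counts.fp,
                    "acc": f.acc,
                    "sen": f.sen,
                    "spe": f.spe,
                }
                for f in self.folds
            ],
            "mean_acc": self.mean_acc,
            "mean_sen": self.mean_sen,
            "mean_spe": self.mean_spe,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def round_half_up(x: float, decimals: int = 4) -> float:
    """Display rounding: half-up to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def kfold_split(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Stratified, seeded k-fold test-index sets.

    The k sets partition ``0..n−1``; per-class counts per fold differ by at
    most one (extras go to the currently smallest folds, ties to the lowest
    fold index), which also keeps total fold sizes within one of each other
    for the balanced datasets used here.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"cannot split {n} epochs into {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        base, extra = divmod(idx.size, k)
        # give the `extra` surplus indices to the currently smallest folds
        order = sorted(range(k), key=lambda j: (len(folds[j]), j))
        sizes = [base] * k
        for j in order[:extra]:
            sizes[j] += 1
        pos = 0
        for j in range(k):
            folds[j].extend(idx[pos : pos + sizes[j]].tolist())
            pos += sizes[j]
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Exhaustive, exclusive TP/FN/TN/FP counting for binary labels."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not np.isin(yt, (0, 1)).all() or not np.isin(yp, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(Acc, Sen, Spe).  A zero-denominator ratio is returned as None."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, sen, spe


def aggregate(values) -> float:
    """Arithmetic mean of exactly 10 fold proportions (full precision)."""
    v = np.asarray(values, dtype=np.float64)
    if v.shape != (10,):
        raise ValueError(f"expected exactly 10 fold values, got shape {v.shape}")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("fold values must lie in [0, 1]")
    return float(v.mean())


def _fold_seed(seed: int, fold: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    task_set: EpochSet,
    feature_kind: str,
    model_config: ModelConfig,
    seed: int = 0,
    task_name: str = "",
    k: int = 10,
    **feature_opts,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline on one task.

    Features are extracted once; each fold trains a fresh model (seeded
    deterministically from ``seed`` and the fold index) on the other k−1
    folds and is scored on its own.  Mean fields are full-precision
    arithmetic means of the fold values.
    """
    y = np.asarray(task_set.labels, dtype=int)
    feats = feature_mod.extract(task_set, feature_kind, **feature_opts)
    layout = feature_mod.FEATURE_LAYOUTS[feature_kind]
    folds = kfold_split(y, k=k, seed=seed)
    results: list[FoldResult] = []
    all_idx = np.arange(y.size)
    for j, test_idx in enumerate(folds, start=1):
        train_idx = np.setdiff1d(all_idx, test_idx)
        cfg = model_mod.ModelConfig.from_dict(
            {
                **model_config.to_dict(),
                "seed": _fold_seed(seed, j),
                "input_layout": layout,
            }
        )
        trained = model_mod.train(feats[train_idx], y[train_idx], cfg)
        pred, _ = model_mod.predict(trained, feats[test_idx])
        c = confusion(y[test_idx], pred)
        acc, sen, spe = metrics(c)
        results.append(FoldResult(fold=j, counts=c, acc=acc, sen=sen, spe=spe))
    def _mean_defined(values: list[float | None]) -> float:
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else float("nan")

    return CVReport(
        task=task_name,
        folds=results,
        mean_acc=float(np.mean([r.acc for r in results])),
        mean_sen=_mean_defined([r.sen for r in results]),
        mean_spe=_mean_defined([r.spe for r in results]),
        seed=seed,
        feature_kind=feature_kind,
    )


def compare_tasks(report1: CVReport, report2: CVReport) -> float:
    """Two-sided Welch t-test p-value on the two fold-accuracy vectors.

    When both vectors have zero variance the t statistic is undefined; the
    documented sentinel is 1.0 for identical means and 0.0 otherwise.
    """
    a = report1.accuracies()
    b = report2.accuracies()
    if a.size != b.size or a.size < 2:
        raise ValueError("both reports need the same number (>=2) of folds")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
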