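"""Folds, confusion counts, Sen/Spe/Acc, aggregation, task comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ictalnet.benchmarks import PUBLISHED_FOLDS
from ictalnet.evaluation import (
    ConfusionCounts,
    CVReport,
    FoldResult,
    aggregate,
    compare_tasks,
    confusion,
    cross_validate,
    kfold_split,
    metrics,
    round_half_up,
)


def make_report(accs, task="T", seed=0):
    folds = [
        FoldResult(
            fold=i + 1,
            counts=ConfusionCounts(tp=1, fn=0, tn=1, fp=0),
            acc=a,
            sen=1.0,
            spe=1.0,
        )
        for i, a in enumerate(accs)
    ]
    return CVReport(
        task=task,
        folds=folds,
        mean_acc=float(np.mean(accs)),
        mean_sen=1.0,
        mean_spe=1.0,
        seed=seed,
    )


class TestKFold:
    def test_balanced_800_gives_ten_stratified_folds_of_80(self):
        y = np.array([0] * 400 + [1] * 400)
        folds = kfold_split(y, k=10, seed=3)
        assert len(folds) == 10
        for f in folds:
            assert f.size == 80
            assert np.sum(y[f] == 0) == 40 and np.sum(y[f] == 1) == 40

    def test_partition_property(self):
        y = np.array([0] * 37 + [1] * 23)
        folds = kfold_split(y, k=7, seed=1)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(60))

    @given(
        st.integers(0, 2**31 - 1),
        st.lists(st.sampled_from([0, 1]), min_size=12, max_size=60),
    )
    def test_stratification_within_one(self, seed, labels):
        y = np.array(labels)
        if np.unique(y).size < 2:
            y[0] = 1 - y[0]
        folds = kfold_split(y, k=5, seed=seed)
        sizes = [f.size for f in folds]
        assert max(sizes) - min(sizes) <= 1
        for cls in (0, 1):
            counts = [int(np.sum(y[f] == cls)) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_same_seed_identical_folds(self):
        y = np.array([0, 1] * 30)
        f1 = kfold_split(y, seed=9)
        f2 = kfold_split(y, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_matches_sklearn_stratification_behaviour(self):
        """Cross-check per-fold class counts against StratifiedKFold."""
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 43 + [1] * 57)
        ours = kfold_split(y, k=10, seed=0)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        theirs = [test for _, test in skf.split(np.zeros_like(y), y)]
        ours_counts = sorted(
            (int(np.sum(y[f] == 0)), int(np.sum(y[f] == 1))) for f in ours
        )
        theirs_counts = sorted(
            (int(np.sum(y[f] == 0)), int(np.sum(y[f] == 1))) for f in theirs
        )
        assert ours_counts == theirs_counts

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(np.array([0, 1, 0]), k=5)


class TestConfusion:
    def test_enumeration_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fn == 0 and c.fp == 0

    def test_brute_force_tally_oracle(self, rng):
        yt = rng.integers(0, 2, 100)
        yp = rng.integers(0, 2, 100)
        c = confusion(yt, yp)
        tally = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
        for a, b in zip(yt, yp):
            key = ("t" if a == b else "f") + ("p" if b == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fn, c.tn, c.fp) == (
            tally["tp"], tally["fn"], tally["tn"], tally["fp"],
        )
        assert c.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_hand_arithmetic_example(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=40, fn=1, tn=39, fp=0))
        assert acc == pytest.approx(0.9875)
        assert sen == pytest.approx(40 / 41)
        assert round_half_up(sen) == 0.9756
        assert spe == 1.0

    def test_perfect_counts(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert acc == sen == spe == 1.0

    def test_zero_denominator_flags_absent(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=0, fn=0, tn=10, fp=0))
        assert sen is None and spe == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_accuracy_is_convex_combination_of_sen_spe(self, rng):
        for _ in range(200):
            tp, fn, tn, fp = rng.integers(0, 50, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            acc, sen, spe = metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            assert min(sen, spe) - 1e-12 <= acc <= max(sen, spe) + 1e-12


class TestAggregate:
    def test_published_abcd_vs_e_mean(self):
        folds, printed = PUBLISHED_FOLDS["ABCD_vs_E"]["acc"]
        assert round_half_up(aggregate(folds)) == printed == 0.9815

    def test_published_ab_vs_cd_mean(self):
        folds, printed = PUBLISHED_FOLDS["AB_vs_CD"]["acc"]
        assert round_half_up(aggregate(folds)) == printed == 0.9906

    def test_ten_perfect_folds(self):
        assert aggregate([1.0] * 10) == 1.0

    def test_wrong_fold_count_rejected(self):
        with pytest.raises(ValueError, match="10"):
            aggregate([0.9] * 9)

    @pytest.mark.parametrize(
        "value,expected", [(0.97625, 0.9763), (0.99625, 0.9963), (0.5, 0.5)]
    )
    def test_display_rounding_is_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestCompareTasks:
    def test_matches_welch_formula_on_three_element_vectors(self):
        a = np.array([0.90, 0.95, 0.92])
        b = np.array([0.80, 0.85, 0.78])
        # closed-form Welch t and dof, evaluated with the t survival function
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(tstat), dof)
        assert compare_tasks(make_report(a), make_report(b)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_null_behaviour_rarely_rejects(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            base = 0.95 + 0.01 * rng.standard_normal(10)
            noise = base + 1e-4 * rng.standard_normal(10)
            p = compare_tasks(make_report(base), make_report(noise))
            if p < 0.05:
                rejections += 1
        assert rejections / reps < 0.10

    def test_separated_accuracy_vectors_give_small_p(self, rng):
        a = 0.90 + 1e-3 * rng.standard_normal(10)
        b = 0.99 + 1e-3 * rng.standard_normal(10)
        assert compare_tasks(make_report(a), make_report(b)) < 0.01

    def test_zero_variance_sentinel(self):
        same = make_report([0.9] * 10)
        other = make_report([0.8] * 10)
        assert compare_tasks(same, make_report([0.9] * 10)) == 1.0
        assert compare_tasks(same, other) == 0.0


@pytest.fixture(scope="module")
def tiny_task():
    from ictalnet.preprocess import TASKS, bandpass, build_task, segment_class
    from ictalnet.synth import SynthConfig, generate_classes

    cfg = SynthConfig(seed=5, n_records_per_class=8, record_len=1024)
    classes = generate_classes(cfg)
    per = {
        lab: bandpass(segment_class(cs.records, 256))
        for lab, cs in classes.items()
        if lab in "AE"
    }
    return build_task(per, TASKS["A_vs_E"])


@pytest.fixture(scope="module")
def tiny_report(tiny_task):
    from ictalnet.model import ConvSpec, ModelConfig

    cfg = ModelConfig(
        conv=(ConvSpec(3, 4, 1), ConvSpec(3, 4, 1), ConvSpec(2, 4, 1)),
        hidden=8,
        inner_hidden=8,
        fc_width=8,
        epochs=40,
        batch_size=8,
        lr=1e-2,
    )
    return cross_validate(
        tiny_task, "fft", cfg, seed=11, task_name="A_vs_E", m=16, n=16
    )


class TestCrossValidate:
    def test_report_has_ten_folds(self, tiny_report):
        assert len(tiny_report.folds) == 10
        assert [f.fold for f in tiny_report.folds] == list(range(1, 11))

    def test_separable_synthetic_task_classified_well(self, tiny_report):
        assert tiny_report.mean_acc >= 0.95

    def test_means_equal_recomputed_fold_means(self, tiny_report):
        assert tiny_report.mean_acc == pytest.approx(
            np.mean([f.acc for f in tiny_report.folds]), abs=1e-12
        )
        assert tiny_report.mean_sen == pytest.approx(
            np.mean([f.sen for f in tiny_report.folds]), abs=1e-12
        )

    def test_fold_counts_partition_test_sets(self, tiny_report, tiny_task):
        per_fold_totals = [f.counts.total for f in tiny_report.folds]
        assert sum(per_fold_totals) == tiny_task.n_epochs

    def test_serialization_shapes(self, tiny_report, tmp_path):
        df_path = tiny_report.to_csv(tmp_path / "r.csv")
        js_path = tiny_report.to_json(tmp_path / "r.json")
        text = df_path.read_text()
        assert text.splitlines()[0] == "Fold,Acc,Sen,Spe"
        assert "Mean" in text and "K10" in text
        import json

        payload = json.loads(js_path.read_text())
        assert len(payload["folds"]) == 10
        assert payload["task"] == "A_vs_E"
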