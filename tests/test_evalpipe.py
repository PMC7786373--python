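import numpy as np
import pytest

from lesionview.errors import ValidationError
from lesionview.evalpipe import (
    FoldPlan,
    TrainConfig,
    evaluate,
    make_fold_plan,
    metrics_from_confusion,
    run_repeated_cv,
    train,
)
from lesionview.models import build_model


class TestFoldPlan:
    def test_study_size_group_sizes(self):
        ids = [f"s{i}" for i in range(88)]
        plan = make_fold_plan(ids, k=5, repeats=3, master_seed=0)
        for groups in plan.assignments:
            assert sorted(len(g) for g in groups) == [17, 17, 18, 18, 18]
            covered = [s for g in groups for s in g]
            assert sorted(covered) == sorted(ids)

    def test_even_split(self):
        plan = make_fold_plan([f"s{i}" for i in range(10)], k=5, repeats=1)
        assert all(len(g) == 2 for g in plan.assignments[0])

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(20)]
        a = make_fold_plan(ids, 5, 4, master_seed=7)
        b = make_fold_plan(ids, 5, 4, master_seed=7)
        assert a == b

    def test_repeats_reshuffle(self):
        ids = [f"s{i}" for i in range(20)]
        plan = make_fold_plan(ids, 5, 2, master_seed=7)
        assert plan.assignments[0] != plan.assignments[1]

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            make_fold_plan(["a", "b"], k=5, repeats=1)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            FoldPlan(k=2, repeats=1, assignments=((("a", "b"), ("b",)),), master_seed=0)


class TestLearningRateSchedule:
    def test_decay_by_ten_percent_every_ten_epochs(self):
        cfg = TrainConfig(epochs=1)
        assert all(cfg.lr_at(e) == pytest.approx(0.01) for e in range(10))
        assert all(cfg.lr_at(e) == pytest.approx(0.009) for e in range(10, 20))
        assert cfg.lr_at(25) == pytest.approx(0.0081)

    def test_recorded_history_follows_formula(self, tiny_spec, tiny_easy_cohort):
        cfg = TrainConfig(epochs=12, seed=0)
        model = build_model(tiny_spec, seed=0)
        _, history = train(model, tiny_easy_cohort[:4] + tiny_easy_cohort[-4:], cfg)
        for h in history:
            assert h["lr"] == pytest.approx(0.01 * 0.9 ** (h["epoch"] // 10))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)
        with pytest.raises(ValidationError):
            TrainConfig(epochs=1, initial_lr=0.0)


class TestTrain:
    def test_single_class_rejected(self, tiny_spec, tiny_easy_cohort):
        ms_only = [s for s in tiny_easy_cohort if s.label == "MS"]
        with pytest.raises(ValidationError):
            train(build_model(tiny_spec), ms_only, TrainConfig(epochs=1))

    def test_loss_decreases_on_separable_data(self, tiny_spec, tiny_easy_cohort):
        cfg = TrainConfig(epochs=30, seed=1)
        model = build_model(tiny_spec, seed=1)
        _, history = train(model, tiny_easy_cohort[:4] + tiny_easy_cohort[-4:], cfg)
        # single-batch SGD losses are spiky; compare a late-phase average
        late = np.mean([h["loss"] for h in history[-10:]])
        assert late < history[0]["loss"]

    def test_deterministic_under_seed(self, tiny_spec, tiny_easy_cohort):
        subjects = tiny_easy_cohort[:3] + tiny_easy_cohort[-3:]
        runs = []
        for _ in range(2):
            model = build_model(tiny_spec, seed=2)
            model, history = train(model, subjects, TrainConfig(epochs=2, seed=3))
            runs.append((history, model.state_dict()))
        assert runs[0][0] == runs[1][0]
        for k in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][k], runs[1][1][k])

    def test_augmentation_expands_training_set_only(self, tiny_spec, tiny_easy_cohort):
        from lesionview.preprocess import AugmentSpec

        subjects = tiny_easy_cohort[:3] + tiny_easy_cohort[-3:]
        cfg = TrainConfig(epochs=1, seed=0, augment=AugmentSpec(n_per_subject=2))
        model = build_model(tiny_spec, seed=0)
        model, history = train(model, subjects, cfg)
        # evaluation still sees the 6 original subjects only
        entry = evaluate(model, subjects)
        assert entry["n"] == 6


class TestEvaluate:
    def test_metric_formulas(self):
        m = metrics_from_confusion(tp=5, fp=3, tn=7, fn=5)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["accuracy"] == pytest.approx(0.6)

    def test_perfect_predictions(self, tiny_spec, tiny_easy_cohort):
        model = build_model(tiny_spec, seed=0)
        model, _ = train(model, tiny_easy_cohort, TrainConfig(epochs=25, seed=4))
        entry = evaluate(model, tiny_easy_cohort)
        if entry["accuracy"] == 1.0:  # fully fit training data
            assert entry["sensitivity"] == 1.0 and entry["specificity"] == 1.0
        assert entry["tp"] + entry["fp"] + entry["tn"] + entry["fn"] == len(tiny_easy_cohort)

    def test_no_positive_subjects_flagged(self, tiny_spec, tiny_easy_cohort):
        model = build_model(tiny_spec, seed=0)
        model.classes_ = ["MS", "NMOSD"]
        ms_only = [s for s in tiny_easy_cohort if s.label == "MS"]
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            entry = evaluate(model, ms_only, positive_class="NMOSD")
        assert np.isnan(entry["sensitivity"])


def _check_report_invariants(report):
    """Metric algebra and no-leakage, asserted from the provenance log."""
    for fold in report.provenance["folds"]:
        assert not (set(fold["train_ids"]) & set(fold["val_ids"]))
        c = fold["confusion"]
        n = sum(c.values())
        m = fold["metrics"]
        assert m["accuracy"] * n == pytest.approx(c["tp"] + c["tn"])
        if c["tp"] + c["fn"]:
            assert m["sensitivity"] == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        if c["tn"] + c["fp"]:
            assert m["specificity"] == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))
    for rep in report.per_repeat:
        n = rep["tp"] + rep["fp"] + rep["tn"] + rep["fn"]
        assert rep["accuracy"] * n == pytest.approx(rep["tp"] + rep["tn"])


@pytest.fixture(scope="module")
def small_report(tiny_spec, tiny_easy_cohort):
    plan = make_fold_plan([s.subject_id for s in tiny_easy_cohort],
                          k=2, repeats=2, master_seed=5)
    cfg = TrainConfig(epochs=2, seed=5)
    return run_repeated_cv(tiny_easy_cohort, tiny_spec, cfg, plan), plan


class TestRepeatedCV:

    def test_every_subject_predicted_once_per_repeat(self, small_report, tiny_easy_cohort):
        report, plan = small_report
        ids = {s.subject_id for s in tiny_easy_cohort}
        for r in range(plan.repeats):
            validated = [sid for f in report.provenance["folds"] if f["repeat"] == r
                         for sid in f["val_ids"]]
            assert sorted(validated) == sorted(ids)

    def test_invariants_hold(self, small_report):
        report, _ = small_report
        _check_report_invariants(report)

    def test_aggregate_is_mean_of_repeats(self, small_report):
        report, _ = small_report
        accs = [rep["accuracy"] for rep in report.per_repeat]
        assert report.aggregate["accuracy"]["mean"] == pytest.approx(np.mean(accs))
        assert report.aggregate["accuracy"]["sd"] == pytest.approx(np.std(accs))

    def test_determinism(self, tiny_spec, tiny_easy_cohort, small_report):
        report, plan = small_report
        again = run_repeated_cv(tiny_easy_cohort, tiny_spec,
                                TrainConfig(epochs=2, seed=5), plan)
        assert again.to_dict() == report.to_dict()

    def test_report_serializes(self, small_report, tmp_path):
        report, _ = small_report
        path = report.save(tmp_path / "report.json")
        import json

        loaded = json.loads(path.read_text())
        assert loaded["aggregate"].keys() == report.aggregate.keys()

    def test_plan_cohort_mismatch_rejected(self, tiny_spec, tiny_easy_cohort):
        plan = make_fold_plan(["x", "y", "z"], k=3, repeats=1)
        with pytest.raises(ValidationError):
            run_repeated_cv(tiny_easy_cohort, tiny_spec, TrainConfig(epochs=1), plan)
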