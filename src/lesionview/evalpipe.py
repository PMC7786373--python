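"""Training, repeated random k-fold cross-validation and metric reporting.

Protocol: subjects are randomly divided into five near-equal groups (not
stratified); four train, one validates; the whole division is repeated 15
times with fresh shuffles and the accuracy / sensitivity / specificity are
reported as mean ± sd across repeats.  Training is mini-batch SGD with
momentum on two-class cross-entropy; the learning rate starts at 0.01 and
decays by 10% every ten epochs; dropout (0.15) is active only in training;
augmentation, when configured, is applied to training folds only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .errors import ValidationError
from .io_formats import SubjectRecord
from .models import ModelSpec, _subject_input, build_model, load_pretrained_backbone
from .preprocess import AugmentSpec, augment


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int
    initial_lr: float = 0.01
    lr_decay_factor: float = 0.9
    lr_decay_every: int = 10
    momentum: float = 0.9
    batch_size: int = 4
    seed: int = 0
    augment: AugmentSpec | None = None
    input_mode: str = "mask"

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValidationError("initial_lr must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """0.01 · 0.9^floor(epoch / 10) with the defaults."""
        return self.initial_lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass(frozen=True)
class FoldPlan:
    """Per repeat, a partition of subject ids into k near-equal groups."""

    k: int
    repeats: int
    assignments: tuple  # repeats x k tuple of tuples of subject ids
    master_seed: int

    def __post_init__(self):
        for groups in self.assignments:
            ids = [sid for g in groups for sid in g]
            if len(ids) != len(set(ids)):
                raise ValidationError("fold groups overlap within a repeat")
            sizes = sorted(len(g) for g in groups)
            if sizes[-1] - sizes[0] > 1:
                raise ValidationError(f"group sizes differ by more than 1: {sizes}")


def make_fold_plan(subject_ids: list[str], k: int = 5, repeats: int = 15,
                   master_seed: int = 0) -> FoldPlan:
    """Independent random k-way partitions, one per repeat, seeded from the
    master seed and the repeat index."""
    ids = list(subject_ids)
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds number of subjects {len(ids)}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    assignments = []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, r]))
        perm = [ids[i] for i in rng.permutation(len(ids))]
        groups = [tuple(g) for g in np.array_split(perm, k)]
        assignments.append(tuple(tuple(str(s) for s in g) for g in groups))
    return FoldPlan(k=k, repeats=repeats, assignments=tuple(assignments),
                    master_seed=master_seed)


def _dataset(subjects: list[SubjectRecord], input_mode: str,
             classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([_subject_input(s, input_mode) for s in subjects])
    y = np.array([classes.index(s.label) for s in subjects], dtype=np.int64)
    return x, y


def train(model: nn.Module, train_subjects: list[SubjectRecord],
          cfg: TrainConfig) -> tuple[nn.Module, list[dict]]:
    """Mini-batch SGD; returns the model and a per-epoch history of
    ``{"epoch", "lr", "loss"}``.  Deterministic under ``cfg.seed``."""
    classes = sorted({s.label for s in train_subjects})
    if len(classes) < 2:
        raise ValidationError("training set must contain both classes")
    model.classes_ = classes

    subjects = list(train_subjects)
    if cfg.augment is not None:
        for i, s in enumerate(train_subjects):
            spec = replace(cfg.augment, seed=_derive_seed(cfg.seed, 101, i))
            subjects.extend(augment(s, spec))

    x, y = _dataset(subjects, cfg.input_mode, classes)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    model.set_rng(np.random.default_rng(np.random.SeedSequence([cfg.seed, 11])))
    opt = nn.SGD(model.parameters(), momentum=cfg.momentum)
    model.train()
    history = []
    n = len(subjects)
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model(x[idx])
            loss, grad = nn.cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step(lr)
            losses.append(loss)
        history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    return model, history


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict:
    total = tp + fp + tn + fn
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
           "accuracy": (tp + tn) / total if total else float("nan")}
    for name, num, den in (("sensitivity", tp, tp + fn), ("specificity", tn, tn + fp)):
        if den == 0:
            warnings.warn(f"{name} undefined: denominator is 0", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = num / den
    return out


def evaluate(model: nn.Module, subjects: list[SubjectRecord],
             positive_class: str = "NMOSD", input_mode: str = "mask") -> dict:
    """Argmax predictions and confusion-matrix metrics on a subject list."""
    if not subjects:
        raise ValidationError("evaluate needs a nonempty subject list")
    classes = getattr(model, "classes_", sorted({s.label for s in subjects}))
    x, y = _dataset(subjects, input_mode, classes)
    model.eval()
    preds = []
    for start in range(0, len(subjects), 8):
        logits = model(x[start:start + 8])
        preds.append(logits.argmax(axis=1))
    pred = np.concatenate(preds)
    if positive_class in classes:
        pos = classes.index(positive_class)
    else:
        pos = 1
    tp = int(((pred == pos) & (y == pos)).sum())
    fn = int(((pred != pos) & (y == pos)).sum())
    tn = int(((pred != pos) & (y != pos)).sum())
    fp = int(((pred == pos) & (y != pos)).sum())
    entry = metrics_from_confusion(tp, fp, tn, fn)
    entry["n"] = len(subjects)
    entry["positive_class"] = positive_class
    entry["predictions"] = {s.subject_id: classes[int(p)] for s, p in zip(subjects, pred)}
    return entry


@dataclass
class MetricsReport:
    """Per-repeat and aggregate accuracy/sensitivity/specificity plus full
    provenance (who trained on whom, with which seeds)."""

    positive_class: str
    per_repeat: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    confusion_totals: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"positive_class": self.positive_class,
                "per_repeat": self.per_repeat,
                "aggregate": self.aggregate,
                "confusion_totals": self.confusion_totals,
                "provenance": self.provenance}

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def run_repeated_cv(cohort: list[SubjectRecord], spec: ModelSpec, cfg: TrainConfig,
                    plan: FoldPlan, weight_source=None, positive_class: str = "NMOSD",
                    pool_folds: bool = True) -> MetricsReport:
    """For every repeat and fold: fresh (optionally pretrained) model, train
    on k-1 groups, evaluate on the held-out group.  Per-repeat metrics pool
    the folds' confusion counts (set ``pool_folds=False`` to average fold
    metrics instead); the aggregate is mean ± sd across repeats."""
    by_id = {s.subject_id: s for s in cohort}
    plan_ids = {sid for groups in plan.assignments for g in groups for sid in g}
    if plan_ids != set(by_id):
        raise ValidationError("fold plan subject ids do not match the cohort")
    if spec.pretrained and weight_source is None:
        raise ValidationError("spec.pretrained requires a weight_source")

    report = MetricsReport(positive_class=positive_class)
    fold_log = []
    totals = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for r, groups in enumerate(plan.assignments):
        fold_entries = []
        for f, val_ids in enumerate(groups):
            train_ids = [sid for g, grp in enumerate(groups) if g != f for sid in grp]
            seed = _derive_seed(plan.master_seed, cfg.seed, r, f)
            model = build_model(spec, seed=seed)
            if spec.pretrained:
                load_pretrained_backbone(model, weight_source)
            try:
                model, history = train(model, [by_id[s] for s in train_ids],
                                       replace(cfg, seed=seed))
                entry = evaluate(model, [by_id[s] for s in val_ids],
                                 positive_class, cfg.input_mode)
            except Exception as e:
                raise type(e)(f"repeat {r}, fold {f}: {e}") from e
            entry["final_loss"] = history[-1]["loss"]
            fold_entries.append(entry)
            fold_log.append({"repeat": r, "fold": f, "seed": seed,
                             "train_ids": list(train_ids), "val_ids": list(val_ids),
                             "confusion": {k: entry[k] for k in ("tp", "fp", "tn", "fn")},
                             "metrics": {k: entry[k] for k in
                                         ("accuracy", "sensitivity", "specificity")}})
        if pool_folds:
            pooled = {k: sum(e[k] for e in fold_entries) for k in ("tp", "fp", "tn", "fn")}
            rep = metrics_from_confusion(**pooled)
        else:
            rep = {k: float(np.nanmean([e[k] for e in fold_entries]))
                   for k in ("accuracy", "sensitivity", "specificity")}
            rep.update({k: sum(e[k] for e in fold_entries) for k in ("tp", "fp", "tn", "fn")})
        rep["repeat"] = r
        report.per_repeat.append(rep)
        for k in totals:
            totals[k] += rep[k]

    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = np.array([rep[metric] for rep in report.per_repeat], dtype=float)
        report.aggregate[metric] = {"mean": float(np.nanmean(vals)),
                                    "sd": float(np.nanstd(vals, ddof=0))}
    report.confusion_totals = totals
    report.provenance = {
        "master_seed": plan.master_seed, "k": plan.k, "repeats": plan.repeats,
        "config_seed": cfg.seed, "folds": fold_log,
        "model": spec.to_dict(),
    }
    return report
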