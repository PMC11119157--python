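"""Trial-stratified nested cross-validation, metrics, and run outputs.

The outer loop is a stratified 5-fold split **by trial**: one fifth of each
class's trials is held out as the test fold. Within each outer training
set, a stratified 4-fold inner loop drives early stopping and model
selection; the selected model is then fine-tuned on the full outer training
set (adjacencies rebuilt from it) and evaluated once on the untouched test
trials. All assignments are keyed on trial ids; every segment inherits its
parent trial's assignment, so no window of a test trial ever reaches
adjacency construction, training, validation or fine-tuning.

Per-segment connectivity matrices depend only on the segment itself, so
they are computed once per dataset and fold-wise adjacencies are averages
over the fold's training rows — numerically identical to recomputing from
scratch per fold.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone

from .connectivity import build_task_adjacency, connectivity_matrix
from .data import SegmentationConfig, bandpass, segment_trials
from .estimator import TSANNClassifier

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "SegmentedDataset",
    "make_fold_plan",
    "compute_metrics",
    "prepare_dataset",
    "train_fold",
    "finetune_and_test",
    "nested_cross_validate",
]


@dataclass
class InnerFold:
    train: list
    val: list


@dataclass
class OuterFold:
    test: list
    inner: list


@dataclass
class FoldPlan:
    n_outer: int
    n_inner: int
    seed: int
    outer: list

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self):
        all_test = [tid for f in self.outer for tid in f.test]
        if len(all_test) != len(set(all_test)):
            raise AssertionError("a trial appears in more than one outer test fold")
        for k, f in enumerate(self.outer):
            test = set(f.test)
            for inner in f.inner:
                if test & (set(inner.train) | set(inner.val)):
                    raise AssertionError(f"outer fold {k}: test trials leak into training")
                if set(inner.train) & set(inner.val):
                    raise AssertionError(f"outer fold {k}: train/validation overlap")


@dataclass
class MetricsReport:
    """Confusion counts and the derived rates for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    precision: float
    recall: float
    f1: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """ACC / Precision / Recall / F1 from confusion counts.

    Rates whose denominator is zero are reported as 0 with a warning.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no test samples")
    acc = (tp + tn) / total

    def _rate(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    precision = _rate(tp, tp + fp, "precision")
    recall = _rate(tp, tp + fn, "recall")
    f1 = _rate(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(tp, tn, fp, fn, acc, precision, recall, f1)


def make_fold_plan(trials, n_outer: int = 5, n_inner: int = 4, seed: int = 0) -> FoldPlan:
    """Stratified nested fold assignment keyed on trial ids.

    ``trials`` is a sequence of objects with ``trial_id`` and ``label`` (or
    ``(trial_id, label)`` pairs). Per class, trials are shuffled once
    (seeded) and cut into ``n_outer`` near-equal outer folds; the remaining
    trials of each outer fold are cut into ``n_inner`` inner folds.
    """
    pairs = [
        (t.trial_id, t.label) if hasattr(t, "trial_id") else tuple(t) for t in trials
    ]
    ids = [p[0] for p in pairs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate trial ids")
    labels = sorted({p[1] for p in pairs})
    rng = np.random.default_rng(seed)
    by_class = {}
    for lab in labels:
        tids = sorted(p[0] for p in pairs if p[1] == lab)
        if len(tids) < n_outer:
            raise ValueError(
                f"class {lab!r} has {len(tids)} trials; need at least n_outer={n_outer}"
            )
        by_class[lab] = [list(c) for c in np.array_split(rng.permutation(tids), n_outer)]
    outer = []
    for k in range(n_outer):
        test = sorted(tid for lab in labels for tid in by_class[lab][k])
        rest = {
            lab: [tid for i, chunk in enumerate(by_class[lab]) if i != k for tid in chunk]
            for lab in labels
        }
        inner = []
        chunks = {lab: [list(c) for c in np.array_split(np.array(rest[lab]), n_inner)] for lab in labels}
        for i in range(n_inner):
            val = sorted(tid for lab in labels for tid in chunks[lab][i])
            train = sorted(
                tid for lab in labels for j, c in enumerate(chunks[lab]) if j != i for tid in c
            )
            inner.append(InnerFold(train=train, val=val))
        outer.append(OuterFold(test=test, inner=inner))
    plan = FoldPlan(n_outer=n_outer, n_inner=n_inner, seed=seed, outer=outer)
    plan.validate()
    return plan


@dataclass
class SegmentedDataset:
    """Preprocessed segments as arrays, plus cached per-segment connectivity."""

    X: np.ndarray  # (n_segments, C, T)
    y: np.ndarray  # label strings
    trial_ids: np.ndarray  # parent trial id per segment
    fs: float
    segments: list
    labels: tuple
    _conn_cache: dict = field(default_factory=dict)

    def indices_for(self, trial_ids) -> np.ndarray:
        wanted = set(trial_ids)
        return np.flatnonzero([tid in wanted for tid in self.trial_ids])

    def adjacency_for(self, trial_ids, estimator: TSANNClassifier) -> dict:
        """Task adjacency per variant from the given trials' segments only."""
        idx = self.indices_for(trial_ids)
        segs = [self.segments[i] for i in idx]
        out = {}
        for v in estimator.variants:
            cfg = estimator._conn_cfg(v)
            key = (v, cfg.band, cfg.welch_seg_s, cfg.welch_overlap)
            if key not in self._conn_cache:
                self._conn_cache[key] = np.stack(
                    [connectivity_matrix(s, cfg) for s in self.segments]
                )
            out[v] = build_task_adjacency(
                segs, cfg, labels=self.labels, matrices=self._conn_cache[key][idx]
            )
        return out


def prepare_dataset(
    trials,
    segmentation: SegmentationConfig | None = None,
    preprocess_band: tuple | None = (4.0, 45.0),
) -> SegmentedDataset:
    """Band-pass filter trials, segment them, and pack arrays."""
    segmentation = segmentation or SegmentationConfig()
    if preprocess_band is not None:
        trials = [bandpass(t, *preprocess_band) for t in trials]
    segs = segment_trials(trials, segmentation)
    labels = tuple(sorted({s.label for s in segs}))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    return SegmentedDataset(
        X=np.stack([s.data for s in segs]),
        y=np.array([s.label for s in segs]),
        trial_ids=np.array([s.parent_trial_id for s in segs]),
        fs=float(trials[0].fs),
        segments=segs,
        labels=labels,
    )


def train_fold(
    dataset: SegmentedDataset,
    plan: FoldPlan,
    outer_idx: int,
    inner_idx: int,
    estimator: TSANNClassifier,
) -> TSANNClassifier:
    """Train one inner fold: adjacency from inner-train segments only,
    early stopping on the validation fold."""
    fold = plan.outer[outer_idx].inner[inner_idx]
    tr = dataset.indices_for(fold.train)
    va = dataset.indices_for(fold.val)
    est = clone(estimator)
    adjacency = dataset.adjacency_for(fold.train, est) if est.use_gcn else None
    est.fit(dataset.X[tr], dataset.y[tr], X_val=dataset.X[va], y_val=dataset.y[va],
            adjacency=adjacency)
    return est


def finetune_and_test(
    dataset: SegmentedDataset,
    plan: FoldPlan,
    outer_idx: int,
    best_model: TSANNClassifier,
    fine_tune_epochs: int = 5,
) -> dict:
    """Fine-tune the selected inner model on all train+validation trials,
    then evaluate once on the outer test trials (segment-level metrics plus
    a trial-level majority vote)."""
    outer = plan.outer[outer_idx]
    trainval_ids = sorted(set(outer.inner[0].train) | set(outer.inner[0].val))
    assert not set(trainval_ids) & set(outer.test), "test trials leaked into fine-tuning"
    tv = dataset.indices_for(trainval_ids)
    te = dataset.indices_for(outer.test)
    if fine_tune_epochs > 0:
        adjacency = (
            dataset.adjacency_for(trainval_ids, best_model) if best_model.use_gcn else None
        )
        best_model.finetune(dataset.X[tv], dataset.y[tv], fine_tune_epochs, adjacency=adjacency)
    pred = best_model.predict(dataset.X[te])
    truth = dataset.y[te]
    pos, neg = dataset.labels[1], dataset.labels[0]
    tp = int(((pred == pos) & (truth == pos)).sum())
    tn = int(((pred == neg) & (truth == neg)).sum())
    fp = int(((pred == pos) & (truth == neg)).sum())
    fn = int(((pred == neg) & (truth == pos)).sum())
    metrics = compute_metrics(tp, tn, fp, fn)
    # trial-level majority vote (secondary report)
    votes = {}
    for tid, p in zip(dataset.trial_ids[te], pred):
        votes.setdefault(tid, []).append(p == pos)
    trial_truth = {tid: lab for tid, lab in zip(dataset.trial_ids[te], truth)}
    trial_correct = sum(
        ((np.mean(v) > 0.5) == (trial_truth[tid] == pos)) for tid, v in votes.items()
    )
    return {
        "metrics": metrics,
        "trial_acc": trial_correct / len(votes),
        "n_test_segments": int(len(te)),
        "n_test_trials": len(votes),
    }


def nested_cross_validate(
    trials,
    estimator: TSANNClassifier | None = None,
    *,
    segmentation: SegmentationConfig | None = None,
    preprocess_band: tuple | None = (4.0, 45.0),
    n_outer: int = 5,
    n_inner: int = 4,
    fine_tune_epochs: int = 5,
    seed: int = 0,
    out_dir=None,
    verbose: int = 0,
) -> dict:
    """Full nested cross-validation over trials; returns the summary report.

    With ``out_dir`` set, writes ``fold_plan.json``, per-fold
    ``metrics.csv`` and ``summary.json`` (with the seed and a config hash).
    """
    estimator = estimator or TSANNClassifier(fs=trials[0].fs, random_state=seed)
    plan = make_fold_plan(trials, n_outer=n_outer, n_inner=n_inner, seed=seed)
    dataset = prepare_dataset(trials, segmentation=segmentation, preprocess_band=preprocess_band)
    rows, fold_details = [], []
    for k in range(n_outer):
        inner_models = []
        for i in range(n_inner):
            est = train_fold(dataset, plan, k, i, estimator)
            inner_models.append(est)
            if verbose:
                print(f"outer {k} inner {i}: val_acc={est.validation_accuracy_:.3f}")
        accs = [m.validation_accuracy_ for m in inner_models]
        best_i = int(np.argmax(accs))  # ties -> lowest fold index
        result = finetune_and_test(
            dataset, plan, k, inner_models[best_i], fine_tune_epochs=fine_tune_epochs
        )
        m = result["metrics"]
        rows.append(
            {"fold": k, "ACC": m.acc, "Precision": m.precision, "Recall": m.recall,
             "F1": m.f1, "TP": m.tp, "TN": m.tn, "FP": m.fp, "FN": m.fn,
             "best_inner_fold": best_i, "inner_val_acc": accs[best_i],
             "trial_ACC": result["trial_acc"]}
        )
        fold_details.append(result)
        if verbose:
            print(f"outer {k}: test ACC={m.acc:.3f} (trial-level {result['trial_acc']:.3f})")
    df = pd.DataFrame(rows)
    summary = {
        "seed": seed,
        "n_outer": n_outer,
        "n_inner": n_inner,
        "mean_ACC": float(df["ACC"].mean()),
        "sd_ACC": float(df["ACC"].std(ddof=1)),
        "mean_F1": float(df["F1"].mean()),
        "sd_F1": float(df["F1"].std(ddof=1)),
        "mean_trial_ACC": float(df["trial_ACC"].mean()),
        "config_hash": _config_hash(estimator, segmentation, preprocess_band, seed),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "fold_plan.json").write_text(json.dumps(plan.to_dict(), indent=1))
        df.to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"plan": plan, "folds": rows, "fold_details": fold_details,
            "summary": summary, "metrics_frame": df}


def _config_hash(estimator, segmentation, band, seed) -> str:
    blob = json.dumps(
        {"est": {k: str(v) for k, v in estimator.get_params().items()},
         "seg": str(segmentation), "band": str(band), "seed": seed},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
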