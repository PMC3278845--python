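"""One-hidden-layer neural network for multilabel dinucleotide contacts.

The residue model maps a windowed sequence-feature vector to 16
independent logistic outputs, one per dinucleotide class (a residue may
contact several classes, so no softmax).  Training is classic online
backpropagation on squared error with logistic units throughout, halted
by early stopping on a held-out stop set; model selection and evaluation
use five-fold cross-validation with folds assigned at the protein level
(per cycle: three folds train, one fold determines the stopping point,
one fold is scored).  The same machinery trains the single-output
fragment-pair classifier.

Everything is seeded and deterministic: identical seed and data give
bit-identical weights.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .alphabets import DINUCLEOTIDES
from .evaluate import roc_auc
from .features import FeatureMatrix
from .structure_io import ContactProfile

__all__ = [
    "Hyper",
    "MLPModel",
    "PredictionMatrix",
    "CVPlan",
    "CVResult",
    "train_with_early_stopping",
    "predict",
    "cross_validate",
    "train_classwise",
    "FUNCTIONAL_CLASSES",
]

FUNCTIONAL_CLASSES = ("viral", "mRNA", "tRNA", "rRNA")

#: Minimum proteins a functional class needs for its own cross-validation.
MIN_CLASS_SIZE = 5


@dataclass
class Hyper:
    """Training hyper-parameters for classic online standard backprop."""

    n_hidden: int = 10
    learning_rate: float = 0.05
    max_epochs: int = 500
    patience: int = 10
    seed: int = 0
    negative_subsample: float | None = None  # negatives per positive, train set only


@dataclass
class MLPModel:
    """Weights of a trained three-layer (one hidden layer) network."""

    n_in: int
    n_hidden: int
    n_out: int
    weights_in_hidden: np.ndarray  # (n_in, n_hidden)
    bias_hidden: np.ndarray  # (n_hidden,)
    weights_hidden_out: np.ndarray  # (n_hidden, n_out)
    bias_out: np.ndarray  # (n_out,)
    train_meta: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_in:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_in}, "
                f"got {x.shape[1]}"
            )
        h = _sigmoid(x @ self.weights_in_hidden + self.bias_hidden)
        return _sigmoid(h @ self.weights_hidden_out + self.bias_out)

    def to_json(self) -> str:
        payload = {
            "n_in": self.n_in,
            "n_hidden": self.n_hidden,
            "n_out": self.n_out,
            "weights_in_hidden": self.weights_in_hidden.tolist(),
            "bias_hidden": self.bias_hidden.tolist(),
            "weights_hidden_out": self.weights_hidden_out.tolist(),
            "bias_out": self.bias_out.tolist(),
            "train_meta": self.train_meta,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            n_in=d["n_in"],
            n_hidden=d["n_hidden"],
            n_out=d["n_out"],
            weights_in_hidden=np.asarray(d["weights_in_hidden"]),
            bias_hidden=np.asarray(d["bias_hidden"]),
            weights_hidden_out=np.asarray(d["weights_hidden_out"]),
            bias_out=np.asarray(d["bias_out"]),
            train_meta=d.get("train_meta", {}),
        )


@dataclass
class PredictionMatrix:
    """Per-residue (or per-pattern) scores in (0,1), one column per output."""

    protein_id: str
    scores: np.ndarray


@dataclass
class CVPlan:
    """Protein-to-fold assignment plus the role rotation of the 5 cycles."""

    fold_assignment: dict[str, int]
    cycles: list[dict]  # per cycle: {"train": [...], "stop": fold, "test": fold}


@dataclass
class CVResult:
    models: list[MLPModel]
    plan: CVPlan
    predictions: dict[str, PredictionMatrix]  # out-of-fold only
    auc_per_class: np.ndarray  # (n_out,), NaN where undefined
    meta: dict = field(default_factory=dict)

    @property
    def macro_auc(self) -> float:
        return float(np.nanmean(self.auc_per_class))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _targets_of(item) -> np.ndarray:
    if isinstance(item, ContactProfile):
        return item.matrix.astype(float)
    return np.atleast_2d(np.asarray(item, dtype=float))


def _stack(dataset: list[tuple[FeatureMatrix, object]]) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for fm, target in dataset:
        t = _targets_of(target)
        if np.isnan(fm.rows).any():
            bad = int(np.argwhere(np.isnan(fm.rows))[0][0])
            raise ValueError(
                f"NaN feature in protein {fm.protein_id!r} at residue {bad}"
            )
        if len(t) != len(fm):
            raise ValueError(
                f"{fm.protein_id!r}: {len(fm)} feature rows vs {len(t)} targets"
            )
        xs.append(fm.rows)
        ts.append(t)
    return np.vstack(xs), np.vstack(ts)


def _config_hash(hyper: Hyper, n_in: int, n_out: int) -> str:
    blob = json.dumps({**asdict(hyper), "n_in": n_in, "n_out": n_out},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def train_with_early_stopping(
    train: list[tuple[FeatureMatrix, object]],
    stop: list[tuple[FeatureMatrix, object]],
    hyper: Hyper,
) -> MLPModel:
    """Train by online backpropagation, returning best-stop-epoch weights.

    After each epoch the mean squared error on the stop set is evaluated;
    training halts when it has not improved for ``hyper.patience`` epochs
    (or at ``max_epochs``), and the weights of the best stop-set epoch are
    returned.  Fully reproducible for a fixed seed.
    """
    if not train:
        raise ValueError("empty training set")
    X, T = _stack(train)
    Xs, Ts = _stack(stop)
    n_in, n_out = X.shape[1], T.shape[1]
    rng = np.random.default_rng(hyper.seed)

    if hyper.negative_subsample is not None:
        pos = T.any(axis=1)
        neg_idx = np.flatnonzero(~pos)
        keep_n = min(len(neg_idx),
                     int(np.ceil(hyper.negative_subsample * max(pos.sum(), 1))))
        kept = rng.choice(neg_idx, size=keep_n, replace=False)
        sel = np.sort(np.concatenate([np.flatnonzero(pos), kept]))
        X, T = X[sel], T[sel]

    lr = hyper.learning_rate
    w1 = rng.uniform(-0.1, 0.1, size=(n_in, hyper.n_hidden))
    b1 = rng.uniform(-0.1, 0.1, size=hyper.n_hidden)
    w2 = rng.uniform(-0.1, 0.1, size=(hyper.n_hidden, n_out))
    b2 = rng.uniform(-0.1, 0.1, size=n_out)

    def stop_error() -> float:
        h = _sigmoid(Xs @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        return float(np.mean((o - Ts) ** 2))

    best = (np.inf, -1, None)
    wait = 0
    epochs_run = 0
    for epoch in range(hyper.max_epochs):
        for i in rng.permutation(len(X)):
            x, t = X[i], T[i]
            h = _sigmoid(x @ w1 + b1)
            o = _sigmoid(h @ w2 + b2)
            delta_o = (o - t) * o * (1.0 - o)
            delta_h = (w2 @ delta_o) * h * (1.0 - h)
            w2 -= lr * np.outer(h, delta_o)
            b2 -= lr * delta_o
            w1 -= lr * np.outer(x, delta_h)
            b1 -= lr * delta_h
        epochs_run = epoch + 1
        err = stop_error()
        if err < best[0]:
            best = (err, epoch, (w1.copy(), b1.copy(), w2.copy(), b2.copy()))
            wait = 0
        else:
            wait += 1
            if wait >= hyper.patience:
                break
    assert best[2] is not None
    w1, b1, w2, b2 = best[2]
    return MLPModel(
        n_in=n_in,
        n_hidden=hyper.n_hidden,
        n_out=n_out,
        weights_in_hidden=w1,
        bias_hidden=b1,
        weights_hidden_out=w2,
        bias_out=b2,
        train_meta={
            "seed": hyper.seed,
            "epochs_run": epochs_run,
            "stopping_epoch": best[1],
            "stop_error": best[0],
            "config_hash": _config_hash(hyper, n_in, n_out),
        },
    )


def predict(model: MLPModel, features: FeatureMatrix) -> PredictionMatrix:
    """Forward pass over all residues; every score lies in (0,1)."""
    return PredictionMatrix(protein_id=features.protein_id,
                            scores=model.forward(features.rows))


def _assign_folds(ids: list[str], n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    order = list(rng.permutation(len(ids)))
    return {ids[j]: k % n_folds for k, j in enumerate(order)}


def cross_validate(
    dataset: list[tuple[FeatureMatrix, object]],
    hyper: Hyper,
    n_folds: int = 5,
) -> CVResult:
    """Protein-level five-fold cross-validation.

    Folds partition the proteins; in cycle c, fold c is scored, fold
    (c+1) mod 5 drives early stopping, and the remaining three train.
    Every protein is scored exactly once, by a model that never saw it.
    Per-class AUC is computed on the pooled out-of-fold scores.
    """
    ids = [fm.protein_id for fm, _ in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in dataset")
    if len(dataset) < n_folds:
        raise ValueError(f"need at least {n_folds} proteins, got {len(dataset)}")
    rng = np.random.default_rng(hyper.seed)
    fold_of = _assign_folds(ids, n_folds, rng)
    by_fold: dict[int, list] = {k: [] for k in range(n_folds)}
    for entry in dataset:
        by_fold[fold_of[entry[0].protein_id]].append(entry)

    models: list[MLPModel] = []
    cycles: list[dict] = []
    predictions: dict[str, PredictionMatrix] = {}
    oof_scores, oof_targets = [], []
    for c in range(n_folds):
        test_fold, stop_fold = c, (c + 1) % n_folds
        train_folds = [k for k in range(n_folds) if k not in (test_fold, stop_fold)]
        train = [e for k in train_folds for e in by_fold[k]]
        stop = by_fold[stop_fold]
        cycle_seed = (hyper.seed * n_folds + c) % (2**31)
        cycle_hyper = Hyper(**{**asdict(hyper), "seed": cycle_seed})
        model = train_with_early_stopping(train, stop, cycle_hyper)
        models.append(model)
        cycles.append({"train": train_folds, "stop": stop_fold, "test": test_fold})
        for fm, target in by_fold[test_fold]:
            pm = predict(model, fm)
            predictions[fm.protein_id] = pm
            oof_scores.append(pm.scores)
            oof_targets.append(_targets_of(target))

    S = np.vstack(oof_scores)
    T = np.vstack(oof_targets)
    auc = np.full(S.shape[1], np.nan)
    for j in range(S.shape[1]):
        col = T[:, j].astype(int)
        if 0 < col.sum() < len(col):
            auc[j] = roc_auc(S[:, j], col).auc
    return CVResult(
        models=models,
        plan=CVPlan(fold_assignment=fold_of, cycles=cycles),
        predictions=predictions,
        auc_per_class=auc,
        meta={"hyper": asdict(hyper), "n_proteins": len(dataset)},
    )


def train_classwise(
    dataset: list[tuple[FeatureMatrix, object]],
    class_labels: dict[str, str],
    hyper: Hyper,
    per_class_hyper: dict[str, Hyper] | None = None,
) -> dict[str, CVResult]:
    """Independent cross-validation per RNA functional class.

    ``class_labels`` maps protein_id to one of viral/mRNA/tRNA/rRNA.
    Classes with fewer than 5 proteins are skipped with a warning.
    Per-class hyper-parameter overrides are honoured and recorded in the
    result metadata.
    """
    groups: dict[str, list] = {}
    for entry in dataset:
        pid = entry[0].protein_id
        label = class_labels.get(pid)
        if label is None:
            raise ValueError(f"no functional class label for protein {pid!r}")
        if label not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {label!r} for {pid!r}")
        groups.setdefault(label, []).append(entry)

    results: dict[str, CVResult] = {}
    for label in FUNCTIONAL_CLASSES:
        entries = groups.get(label, [])
        if not entries:
            continue
        if len(entries) < MIN_CLASS_SIZE:
            warnings.warn(
                f"functional class {label!r} has only {len(entries)} proteins; "
                f"skipped (minimum {MIN_CLASS_SIZE})",
                stacklevel=2,
            )
            continue
        h = (per_class_hyper or {}).get(label, hyper)
        res = cross_validate(entries, h)
        res.meta["functional_class"] = label
        res.meta["hyper"] = asdict(h)
        results[label] = res
    return results


def write_cv_report_tsv(path, result: CVResult, class_names=DINUCLEOTIDES) -> None:
    """Per-class AUC (and sample sizes) of a cross-validation run as TSV."""
    with open(path, "w") as fh:
        fh.write("# dinucleotide column order: " + " ".join(DINUCLEOTIDES) + "\n")
        fh.write("class\tauc\n")
        for name, a in zip(class_names, result.auc_per_class):
            fh.write(f"{name}\t{'NA' if np.isnan(a) else f'{a:.6f}'}\n")
        fh.write(f"macro\t{result.macro_auc:.6f}\n")
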