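"""Training loop, metric suite, cross-validation and cross-dataset splits.

Evaluation follows the standard protein-classifier protocol: confusion
counts with Acr as the positive class; accuracy, precision, recall,
specificity, F1 and the Matthews correlation coefficient derived from
them; stratified 5-fold cross-validation; and a harder cross-dataset
protocol in which whole Acr types (and a held-out negative set) are
excluded from training, probing generalization to unseen protein
families. Averaging over several random seeds removes the dependence of
any single number on initialization and fold assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io import LABEL_POSITIVE, ProteinRecord
from .model import (
    FeatureBundle,
    Model,
    ModelConfig,
    POSITIVE_INDEX,
    build_model,
    pack_batch,
)

#: Acr types whose members form the positive *test* set of each
#: cross-dataset separation; training positives are all remaining types.
SEPARATION_TEST_TYPES: Mapping[int, frozenset[str]] = {
    1: frozenset({"I-F", "II-C", "I-D"}),
    2: frozenset(
        {"I-F", "I-E", "V-A", "I-C", "VI-A", "VI-B", "III-I", "III-B", "I-B"}
    ),
    3: frozenset(
        {"I-D", "II-C", "I-E", "V-A", "I-C", "VI-A", "VI-B", "III-I",
         "III-B", "I-B"}
    ),
}


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Binary confusion counts with Acr as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    """Confusion counts and the derived binary metrics."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    roc_points: list[tuple[float, float]] | None = None
    roc_auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with Acr (or 1) as the positive class."""
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            out[i] = 1 if lab == LABEL_POSITIVE else 0
        else:
            out[i] = int(lab)
    return out


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Count TP/FN/FP/TN; labels may be 'Acr'/'non-Acr' strings or 0/1."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> EvalReport:
    """Derive the full metric suite from confusion counts.

    Any 0/0 denominator yields 0 with a warning rather than an exception,
    so metric sweeps never abort on a degenerate fold.
    """
    if c.total <= 0:
        raise ValueError("confusion counts are empty")
    tp, fn, fp, tn = (float(c.tp), float(c.fn), float(c.fp), float(c.tn))
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return EvalReport(
        counts=c,
        accuracy=_ratio(tp + tn, tp + fn + fp + tn, "accuracy"),
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        mcc=_ratio(tp * tn - fp * fn, mcc_den, "mcc"),
    )


@dataclass
class MulticlassReport:
    """One-vs-rest reports per class plus unweighted macro averages."""

    per_class: list[EvalReport]
    macro: dict[str, float]
    accuracy: float


def multiclass_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int
) -> MulticlassReport:
    """One-vs-rest metric suite for a multiclass task."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    reports = []
    for cls in range(n_classes):
        reports.append(metrics(confusion((t == cls), (p == cls))))
    macro = {
        key: float(np.mean([getattr(r, key) for r in reports]))
        for key in ("precision", "recall", "specificity", "f1", "mcc")
    }
    return MulticlassReport(
        per_class=reports,
        macro=macro,
        accuracy=float((t == p).mean()),
    )


def roc(scores: Sequence[float], y_true: Sequence) -> tuple[
    list[tuple[float, float]], float
]:
    """ROC points (fpr, tpr) by threshold sweep and trapezoid-rule area."""
    t = _as_binary(y_true)
    if len(set(t.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(t, np.asarray(scores, dtype=float))
    area = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), area


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """A reusable train/test assignment.

    ``kind`` is ``"kfold"`` (``folds`` holds k (train_ids, test_ids)
    pairs) or ``"cross_dataset"`` (one pair; ``separation`` records which
    type set forms the positive test side).
    """

    kind: str
    folds: list[tuple[list[str], list[str]]]
    seed: int | None = None
    separation: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "folds": [
                {"train": list(tr), "test": list(te)} for tr, te in self.folds
            ],
            "seed": self.seed,
            "separation": self.separation,
        }


def kfold_split(
    ids: Sequence[str],
    labels: Sequence,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified k-fold plan: fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least {k} ids for {k}-fold splitting")
    ids = list(ids)
    y = _as_binary(labels) if not isinstance(labels[0], (tuple,)) else labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
        folds.append(
            ([ids[i] for i in train_idx], [ids[i] for i in test_idx])
        )
    return SplitPlan(kind="kfold", folds=folds, seed=seed)


def cross_dataset_split(
    records: Sequence[ProteinRecord],
    separation: int,
    negative_test_ids: Sequence[str],
) -> SplitPlan:
    """Type-holdout split: whole Acr types form the positive test set.

    Positive records whose ``acr_type`` belongs to the separation's type
    set are assigned to the test side, the remaining positives to the
    train side; negatives follow the supplied test membership.
    """
    if separation not in SEPARATION_TEST_TYPES:
        raise ValueError(
            f"unknown separation {separation!r}; expected 1, 2 or 3"
        )
    test_types = SEPARATION_TEST_TYPES[separation]
    neg_test = set(negative_test_ids)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for rec in records:
        if rec.label == LABEL_POSITIVE:
            if rec.acr_type is None:
                raise ValueError(
                    f"{rec.id}: positive record lacks an Acr type"
                )
            (test_ids if rec.acr_type in test_types else train_ids).append(
                rec.id
            )
        else:
            (test_ids if rec.id in neg_test else train_ids).append(rec.id)
    return SplitPlan(
        kind="cross_dataset",
        folds=[(train_ids, test_ids)],
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization hyperparameters: Adam with a fixed epoch budget.

    ``weight_decay`` is decoupled (AdamW-style) and applied to weight
    matrices only; it counteracts memorization of small training sets,
    which would otherwise swamp the generalizable motif signal.

    Setting ``val_fraction`` > 0 enables early stopping on a held-out
    validation split with the given ``patience``, restoring the
    best-validation parameters. It is off by default: at the dataset
    sizes this package targets the validation split is too small to
    select parameters reliably, and a fixed budget with weight decay
    generalizes better.
    """

    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 30
    val_fraction: float = 0.0
    weight_decay: float = 1e-3
    block_dropout: float = 0.5
    seed: int = 0


class _Adam:
    """Adam optimizer with decoupled weight decay over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and key.endswith("_w"):
                update = update + self.weight_decay * params[key]
            params[key] -= self.lr * update


@dataclass
class TrainResult:
    model: Model
    loss_history: list[float]
    val_loss_history: list[float] = field(default_factory=list)


def _eval_loss(model: Model, arrays: dict, y: np.ndarray) -> float:
    loss, _ = model.loss_and_grads(arrays, y, dropout_rng=None)
    return loss


def train(
    model: Model,
    dataset: Sequence[tuple[FeatureBundle, int]],
    train_config: TrainConfig | None = None,
) -> TrainResult:
    """Minibatch training with cross-entropy loss and Adam.

    A validation split (``val_fraction``) drives early stopping with the
    configured patience; the best-validation parameters are restored at
    the end. The per-epoch ``loss_history`` records the evaluation-mode
    (dropout-free) loss over the training split, so it is an exact
    function of the parameter trajectory. All randomness (validation
    split, shuffling, dropout) derives from ``train_config.seed``.
    """
    cfg = train_config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    labels = np.array([y for _, y in dataset], dtype=int)
    if labels.max() >= model.config.n_outputs:
        raise ValueError(
            f"label {labels.max()} out of range for "
            f"{model.config.n_outputs}-way model"
        )
    if model.config.n_outputs == 2 and len(set(labels.tolist())) < 2:
        warnings.warn(
            "single-class dataset for binary training; metrics will be "
            "degenerate",
            stacklevel=2,
        )
    rng = np.random.Generator(np.random.PCG64(cfg.seed))

    indices = np.arange(len(dataset))
    use_val = cfg.val_fraction > 0 and len(dataset) >= 10
    if use_val:
        strat = labels if len(set(labels.tolist())) > 1 else None
        split_seed = int(rng.integers(2**31))
        try:
            train_idx, val_idx = train_test_split(
                indices,
                test_size=cfg.val_fraction,
                random_state=split_seed,
                stratify=strat,
            )
        except ValueError:  # val slice smaller than the class count
            train_idx, val_idx = train_test_split(
                indices,
                test_size=cfg.val_fraction,
                random_state=split_seed,
                stratify=None,
            )
    else:
        train_idx, val_idx = indices, np.array([], dtype=int)

    bundles = [dataset[i][0] for i in train_idx]
    y_train = labels[train_idx]
    if len(val_idx):
        val_arrays = pack_batch(
            [dataset[i][0] for i in val_idx], model.config
        )
        y_val = labels[val_idx]

    optimizer = _Adam(
        model.params, cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    best_params = None
    stale = 0
    # Minibatches are bucketed by sequence length (padding waste stays
    # small) and packed once; each epoch shuffles the batch order.
    if "onehot" in model.config.enabled_blocks:
        length_order = np.argsort(
            [b.channels.values.shape[0] for b in bundles], kind="stable"
        )
    else:
        length_order = np.arange(len(bundles))
    batches = []
    for start in range(0, len(length_order), cfg.batch_size):
        sel = length_order[start : start + cfg.batch_size]
        batches.append(
            (
                pack_batch([bundles[i] for i in sel], model.config),
                y_train[sel],
            )
        )
    batch_order = np.arange(len(batches))
    norm_arrays: dict[str, np.ndarray] = {}
    for key in ("evo", "emb"):
        if key in batches[0][0]:
            norm_arrays[key] = np.concatenate(
                [arr[key] for arr, _ in batches]
            )
    model.fit_normalizer(norm_arrays)

    def epoch_loss() -> float:
        # evaluation-mode loss over the training split, batch-weighted
        total = 0.0
        for arrays, y_batch in batches:
            total += _eval_loss(model, arrays, y_batch) * len(y_batch)
        return total / len(y_train)

    for _epoch in range(cfg.max_epochs):
        rng.shuffle(batch_order)
        for bi in batch_order:
            arrays, y_batch = batches[bi]
            _, grads = model.loss_and_grads(
                arrays,
                y_batch,
                dropout_rng=rng,
                block_dropout=cfg.block_dropout,
            )
            optimizer.step(model.params, grads)
        history.append(epoch_loss())
        if use_val and len(val_idx):
            val_loss = _eval_loss(model, val_arrays, y_val)
            val_history.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return TrainResult(
        model=model, loss_history=history, val_loss_history=val_history
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation protocols
# ---------------------------------------------------------------------------

def evaluate_split(
    dataset: Sequence[tuple[FeatureBundle, int]],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    model_config: ModelConfig,
    train_config: TrainConfig,
    threshold: float = 0.5,
) -> tuple[EvalReport | MulticlassReport, Model]:
    """Train on one split and report test metrics (binary or multiclass)."""
    model = build_model(model_config)
    result = train(
        model, [dataset[i] for i in train_idx], train_config
    )
    test_bundles = [dataset[i][0] for i in test_idx]
    y_test = np.array([dataset[i][1] for i in test_idx], dtype=int)
    probs = result.model.forward(test_bundles)
    if model_config.n_outputs == 2:
        y_pred = (probs[:, POSITIVE_INDEX] >= threshold).astype(int)
        report = metrics(confusion(y_test, y_pred))
        try:
            report.roc_points, report.roc_auc = roc(
                probs[:, POSITIVE_INDEX], y_test
            )
        except ValueError:
            pass
        return report, result.model
    y_pred = probs.argmax(axis=1)
    return multiclass_metrics(y_test, y_pred, model_config.n_outputs), (
        result.model
    )


@dataclass
class MultiseedReport:
    """Per-seed evaluation reports and their arithmetic mean."""

    per_seed: list[dict[str, float]]
    mean: dict[str, float]


def _mean_of_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def evaluate_multiseed(
    dataset: Sequence[tuple[FeatureBundle, int]],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    n_seeds: int = 10,
    test_fraction: float = 0.2,
    master_seed: int = 0,
) -> MultiseedReport:
    """Repeat train/test with fresh seeds and average the metric suite.

    Each repetition re-seeds both parameter initialization and the
    train/test sample split, then the per-seed metrics are averaged
    arithmetically.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    base = train_config or TrainConfig()
    labels = np.array([y for _, y in dataset], dtype=int)
    rng = np.random.Generator(np.random.PCG64(master_seed))
    per_seed = []
    for _ in range(n_seeds):
        seed = int(rng.integers(2**31))
        strat = labels if len(set(labels.tolist())) > 1 else None
        train_idx, test_idx = train_test_split(
            np.arange(len(dataset)),
            test_size=test_fraction,
            random_state=seed % (2**31),
            stratify=strat,
        )
        mc = ModelConfig(**{**model_config.to_dict(), "seed": seed})
        tc = TrainConfig(**{**base.__dict__, "seed": seed})
        report, _model = evaluate_split(
            dataset, train_idx, test_idx, mc, tc
        )
        if isinstance(report, EvalReport):
            per_seed.append(report.as_dict())
        else:
            row = {"accuracy": report.accuracy}
            row.update({f"macro_{k}": v for k, v in report.macro.items()})
            per_seed.append(row)
    return MultiseedReport(per_seed=per_seed, mean=_mean_of_dicts(per_seed))


def evaluate_kfold(
    dataset: Sequence[tuple[FeatureBundle, int]],
    ids: Sequence[str],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[EvalReport | MulticlassReport, SplitPlan]:
    """Stratified k-fold protocol; pools test predictions over all folds."""
    labels = [y for _, y in dataset]
    plan = kfold_split(ids, labels, k=k, seed=seed)
    id_index = {rec_id: i for i, rec_id in enumerate(ids)}
    tc = train_config or TrainConfig()
    y_all: list[int] = []
    p_all: list[int] = []
    scores: list[float] = []
    for fold_i, (train_ids, test_ids) in enumerate(plan.folds):
        train_idx = [id_index[i] for i in train_ids]
        test_idx = [id_index[i] for i in test_ids]
        mc = ModelConfig(
            **{**model_config.to_dict(), "seed": model_config.seed + fold_i}
        )
        model = build_model(mc)
        result = train(model, [dataset[i] for i in train_idx], tc)
        probs = result.model.forward([dataset[i][0] for i in test_idx])
        y_all.extend(dataset[i][1] for i in test_idx)
        if model_config.n_outputs == 2:
            p_all.extend(
                (probs[:, POSITIVE_INDEX] >= 0.5).astype(int).tolist()
            )
            scores.extend(probs[:, POSITIVE_INDEX].tolist())
        else:
            p_all.extend(probs.argmax(axis=1).tolist())
    if model_config.n_outputs == 2:
        report: EvalReport | MulticlassReport = metrics(
            confusion(y_all, p_all)
        )
        try:
            report.roc_points, report.roc_auc = roc(scores, y_all)
        except ValueError:
            pass
    else:
        report = multiclass_metrics(y_all, p_all, model_config.n_outputs)
    return report, plan
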