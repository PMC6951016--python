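"""Masked losses, metrics, training loop, and the three-repeat protocol.

Missing labels never contribute: the losses average only over observed cells
(and have exactly zero gradient at masked ones), and the per-task metrics
are computed over observed cells only. A task whose observed test labels
contain a single class has no defined ranking metric; it is reported as NaN
and excluded from the aggregate.

Model selection is by best validation epoch: the parameter snapshot from the
epoch with the best validation metric supplies the reported test metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import autodiff as ad
from .autodiff import Tensor
from .chem_graph import batch_graphs, featurize_molecule, AtomFeatureSchema
from .datasets import NormalizationStats, SplitSpec, fit_normalization, \
    random_split, scaffold_split
from .models import ModelConfig, build_model
from .preprocess import TaskTable

logger = logging.getLogger(__name__)

__all__ = ["masked_classification_loss", "masked_regression_loss",
           "evaluate_predictions", "train", "repeat_protocol",
           "TrainResult", "EvalReport", "CLASSIFICATION_METRICS",
           "REGRESSION_METRICS"]

CLASSIFICATION_METRICS = ("roc-auc", "prc-auc")
REGRESSION_METRICS = ("rmse", "mae")
_HIGHER_IS_BETTER = {"roc-auc": True, "prc-auc": True,
                     "rmse": False, "mae": False}


# ---- losses ---------------------------------------------------------------

def _masked_mean(cellwise: Tensor, mask: np.ndarray) -> Tensor:
    # Observed cells are selected by index (not multiplied by a 0/1 mask) so
    # that appending fully-missing rows leaves the summation order — and
    # hence the loss — bit-for-bit unchanged.
    mask = np.asarray(mask, dtype=bool)
    flat = np.flatnonzero(mask)
    if len(flat) == 0:
        warnings.warn("no observed cells in batch; loss defined as 0")
        return Tensor(0.0)
    return ad.gather_flat(cellwise, flat).sum() * (1.0 / len(flat))


def masked_classification_loss(scores: Tensor, labels: np.ndarray,
                               mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over observed cells (scores pre-sigmoid)."""
    labels = np.where(np.asarray(mask, dtype=bool), labels, 0.0)
    return _masked_mean(ad.bce_with_logits(scores, labels), mask)


def masked_regression_loss(preds: Tensor, labels: np.ndarray,
                           mask: np.ndarray) -> Tensor:
    """Mean squared error over observed cells, in normalized target space."""
    labels = np.where(np.asarray(mask, dtype=bool), labels, 0.0)
    diff = preds - Tensor(labels)
    return _masked_mean(diff * diff, mask)


# ---- metrics --------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def evaluate_predictions(preds: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray, metric: str) -> np.ndarray:
    """Per-task metric values over observed cells; NaN where not computable.

    Classification expects pre-sigmoid scores in ``preds``; regression
    expects predictions already in original (inverse-normalized) units.
    """
    if metric not in CLASSIFICATION_METRICS + REGRESSION_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n_tasks = labels.shape[1]
    out = np.full(n_tasks, np.nan)
    for j in range(n_tasks):
        obs = mask[:, j]
        if obs.sum() == 0:
            continue
        y, p = labels[obs, j], preds[obs, j]
        if metric in CLASSIFICATION_METRICS:
            if len(np.unique(y)) < 2:
                continue  # single-class task: metric undefined
            s = _sigmoid(p)
            out[j] = (roc_auc_score(y, s) if metric == "roc-auc"
                      else average_precision_score(y, s))
        elif metric == "rmse":
            out[j] = float(np.sqrt(np.mean((p - y) ** 2)))
        else:
            out[j] = float(np.mean(np.abs(p - y)))
    return out


def _aggregate(per_task: np.ndarray) -> float:
    vals = per_task[~np.isnan(per_task)]
    return float(vals.mean()) if len(vals) else float("nan")


# ---- reports --------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-task metrics per repeat plus the mean/std aggregation."""

    metric: str
    task_names: list[str]
    repeat_per_task: list[np.ndarray] = field(default_factory=list)

    def add_repeat(self, per_task: np.ndarray) -> None:
        self.repeat_per_task.append(np.asarray(per_task, dtype=np.float64))

    @property
    def repeat_aggregates(self) -> list[float]:
        return [_aggregate(pt) for pt in self.repeat_per_task]

    @property
    def mean(self) -> float:
        return float(np.mean(self.repeat_aggregates))

    @property
    def std(self) -> float:
        return float(np.std(self.repeat_aggregates, ddof=1)) \
            if len(self.repeat_per_task) > 1 else 0.0

    def to_dict(self) -> dict:
        return {"metric": self.metric, "task_names": self.task_names,
                "repeats": [list(map(float, pt)) for pt in self.repeat_per_task],
                "repeat_aggregates": self.repeat_aggregates,
                "mean": self.mean, "std": self.std}


@dataclass
class TrainResult:
    model: object
    metric: str
    best_epoch: int
    valid_score: float
    test_per_task: np.ndarray
    test_aggregate: float
    history: list[dict]
    norm_stats: NormalizationStats | None = None


# ---- training -------------------------------------------------------------

def _featurize_table(table: TaskTable, schema: AtomFeatureSchema):
    return [featurize_molecule(s, schema) for s in table.smiles]


def _predict(model, graphs, indices, batch_size=200) -> np.ndarray:
    rows = []
    for lo in range(0, len(indices), batch_size):
        chunk = [graphs[i] for i in indices[lo:lo + batch_size]]
        rows.append(model.forward(batch_graphs(chunk), training=False).data)
    return np.concatenate(rows, axis=0)


def _snapshot(params):
    return [p.data.copy() for p in params]


def _restore(params, snap):
    for p, s in zip(params, snap):
        p.data = s.copy()


def train(config: ModelConfig, table: TaskTable, split: SplitSpec,
          seed: int = 0, metric: str | None = None, epochs: int = 500,
          batch_size: int = 50, patience: int = 20,
          schema: AtomFeatureSchema | None = None) -> TrainResult:
    """Train one model on one split with best-validation-epoch selection.

    Deterministic for fixed (config, table, split, seed): the seed drives
    weight initialization, minibatch shuffling, and dropout.
    """
    schema = schema or AtomFeatureSchema()
    is_regression = table.task_kind == "regression"
    if metric is None:
        metric = "rmse" if is_regression else "roc-auc"
    higher_better = _HIGHER_IS_BETTER[metric]

    graphs = _featurize_table(table, schema)
    labels, mask = table.labels, table.mask

    norm = None
    train_labels = labels
    if is_regression:
        norm = fit_normalization(labels[split.train], mask[split.train],
                                 table.task_names)
        train_labels = norm.transform(labels)

    model = build_model(config, schema.width, table.n_tasks, seed=seed)
    params = model.parameters()
    opt = ad.Adam(params, lr=config.learn_rate)
    shuffle_rng = np.random.default_rng(seed + 1)
    loss_fn = masked_regression_loss if is_regression \
        else masked_classification_loss

    def valid_score_fn() -> float:
        preds = _predict(model, graphs, split.valid)
        if is_regression:
            preds = norm.inverse(preds)
        return _aggregate(evaluate_predictions(
            preds, labels[split.valid], mask[split.valid], metric))

    best = -np.inf if higher_better else np.inf
    best_epoch, best_snap = -1, _snapshot(params)
    history, since_best = [], 0
    train_idx = np.asarray(split.train)

    for epoch in range(epochs):
        order = shuffle_rng.permutation(len(train_idx))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), batch_size):
            idx = train_idx[order[lo:lo + batch_size]]
            batch = batch_graphs([graphs[i] for i in idx])
            preds = model.forward(batch, training=True)
            loss = loss_fn(preds, train_labels[idx], mask[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r} "
                    f"(lr={config.learn_rate}, arch={config.architecture})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        vscore = valid_score_fn()
        history.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                        "valid_" + metric: vscore})
        logger.info("epoch %d train_loss %.5f valid_%s %.5f",
                    epoch, history[-1]["train_loss"], metric, vscore)
        improved = not np.isnan(vscore) and (
            vscore > best if higher_better else vscore < best)
        if improved:
            best, best_epoch, since_best = vscore, epoch, 0
            best_snap = _snapshot(params)
        else:
            since_best += 1
            if since_best >= patience:
                break

    _restore(params, best_snap)
    test_preds = _predict(model, graphs, split.test)
    if is_regression:
        test_preds = norm.inverse(test_preds)
    per_task = evaluate_predictions(test_preds, labels[split.test],
                                    mask[split.test], metric)
    return TrainResult(model, metric, best_epoch, float(best), per_task,
                       _aggregate(per_task), history, norm)


def repeat_protocol(config: ModelConfig, table: TaskTable,
                    split_method: str = "random", ratios=(0.8, 0.1, 0.1),
                    metric: str | None = None, seeds=(0, 1, 2),
                    **train_kwargs) -> EvalReport:
    """The three-repeat protocol.

    Random splitting: each repeat uses its own fixed split seed (three
    memberships). Scaffold splitting: one membership shared by all repeats;
    the repeats differ only in weight initialization.
    """
    if metric is None:
        metric = "rmse" if table.task_kind == "regression" else "roc-auc"
    report = EvalReport(metric, list(table.task_names))
    scaffold = split_method == "scaffold"
    shared_split = scaffold_split(table.smiles, ratios) if scaffold else None
    for s in seeds:
        split = shared_split if scaffold else \
            random_split(table.n_molecules, ratios, seed=s)
        result = train(config, table, split, seed=s, metric=metric,
                       **train_kwargs)
        report.add_repeat(result.test_per_task)
    return report
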