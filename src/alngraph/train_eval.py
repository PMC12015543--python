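"""Training and clinical evaluation of the node classifiers.

Training is transductive and full-graph: every epoch runs one
forward/backward pass over the whole cohort graph followed by an Adam
update.  An optional minibatch mode restricts the *loss* to a random
subset of labelled nodes per step while keeping the full-graph forward
pass, which preserves message-passing semantics.  Trained weights are
applied inductively to the separate test graph.

Evaluation follows standard clinical-classifier practice: confusion
matrix at a fixed probability threshold, sensitivity / specificity /
predictive values / accuracy / F1, ROC with trapezoidal AUC plus a
class-stratified percentile bootstrap CI, precision-recall with
step-weighted average precision, and the phi coefficient for
between-model prediction agreement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (auc as _sk_auc, average_precision_score,
                             precision_recall_curve, roc_curve)

from . import gnn_core
from .gnn_core import ModelConfig, init_adam_state, loss_and_grads, adam_step
from .patient_graph import PatientGraph


class EvalInputError(ValueError):
    """Raised for invalid evaluation inputs."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch, loss):
        self.epoch, self.loss = epoch, loss
        super().__init__(f"non-finite loss {loss} at epoch {epoch}")


@dataclass
class TrainConfig:
    """Optimisation settings.

    `batch_size=None` trains full-batch (the default); an integer
    enables the loss-subsampling minibatch mode with that many labelled
    nodes per step.
    """

    epochs: int = 1000
    lr: float = 1e-4
    batch_size: int | None = None
    seed: int = 0
    log_every: int = 100

    def validate(self) -> None:
        if self.epochs < 1:
            raise EvalInputError("epochs must be >= 1")
        if self.lr <= 0:
            raise EvalInputError("learning rate must be > 0")
        if self.batch_size is not None and self.batch_size < 1:
            raise EvalInputError("batch_size must be >= 1 or None")


def train_model(graph: PatientGraph, config: ModelConfig, tc: TrainConfig,
                verbose: bool = False):
    """Train one architecture on a cohort graph.

    Returns (params, loss_history).  Reproducible under
    (config.init_seed, tc.seed); aborts with epoch and loss if the
    loss leaves the finite range.
    """
    config.validate()
    tc.validate()
    mat = gnn_core.propagation_matrix(graph.A, config)
    params = gnn_core.init_params(config, graph.X.shape[1])
    state = init_adam_state(params, lr=tc.lr)
    rng = np.random.default_rng(tc.seed)
    n = graph.n_nodes
    history = []
    for epoch in range(tc.epochs):
        if tc.batch_size is not None and tc.batch_size < n:
            node_idx = rng.choice(n, size=tc.batch_size, replace=False)
        else:
            node_idx = None
        drop_rng = rng if config.dropout > 0 else None
        loss, grads, _ = loss_and_grads(mat, graph.X, graph.Y, params, config,
                                        node_idx=node_idx, rng=drop_rng)
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch, loss)
        params, state = adam_step(params, grads, state)
        history.append(loss)
        if verbose and (epoch % tc.log_every == 0 or epoch == tc.epochs - 1):
            print(f"epoch {epoch:5d}  loss {loss:.6f}")
    return params, history


def predict(graph: PatientGraph, params: dict, config: ModelConfig):
    """Class-1 (metastasis) probabilities and hard labels at 0.5.

    Ties at exactly 0.5 are classified positive (>= rule).
    """
    mat = gnn_core.propagation_matrix(graph.A, config)
    logits = gnn_core.model_forward(mat, graph.X, params, config)
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    p1 = probs[:, 1]
    return p1, (p1 >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true, y_hat) -> ConfusionMatrix:
    """2x2 cross-tabulation; positive class = metastasis (label 1)."""
    y_true = np.asarray(y_true)
    y_hat = np.asarray(y_hat)
    if y_true.shape != y_hat.shape:
        raise EvalInputError("prediction/label length mismatch")
    if not (np.isin(y_true, [0, 1]).all() and np.isin(y_hat, [0, 1]).all()):
        raise EvalInputError("labels and predictions must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_hat == 1))),
        fp=int(np.sum((y_true == 0) & (y_hat == 1))),
        tn=int(np.sum((y_true == 0) & (y_hat == 0))),
        fn=int(np.sum((y_true == 1) & (y_hat == 0))),
    )


def _ratio(num, den):
    return num / den if den > 0 else float("nan")


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Threshold metrics from a confusion matrix.

    sen = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), acc = (tp+tn)/total, f1 = harmonic mean of ppv
    and sen.  A metric whose denominator is empty is NaN.
    """
    sen = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sen / (ppv + sen)
    return {"sen": sen, "spec": spec, "ppv": ppv, "npv": npv, "acc": acc, "f1": f1}


def roc_auc(probabilities, y_true):
    """ROC curve over all score thresholds and its trapezoidal area.

    Ties are handled by simultaneous inclusion, which makes the area
    identical to the Mann-Whitney U statistic normalised by n1*n0.
    Returns (points, auc) with points as (fpr, tpr, threshold) rows.
    """
    y = np.asarray(y_true)
    s = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise EvalInputError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    return np.column_stack([fpr, tpr, thr]), float(_sk_auc(fpr, tpr))


def auc_ci(probabilities, y_true, n_boot: int = 2000, seed: int = 0,
           level: float = 0.95):
    """Class-stratified percentile bootstrap CI for the AUC."""
    if n_boot < 100:
        raise EvalInputError("n_boot must be >= 100")
    y = np.asarray(y_true)
    s = np.asarray(probabilities, dtype=float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise EvalInputError("bootstrap CI requires both classes present")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([bp, bn])
        _, stats[b] = roc_auc(s[idx], y[idx])
    lo = (1.0 - level) / 2.0
    return float(np.quantile(stats, lo)), float(np.quantile(stats, 1.0 - lo))


def pr_curve(probabilities, y_true):
    """Precision-recall curve and step-weighted average precision
    (AP = sum over thresholds of (R_k - R_{k-1}) * P_k)."""
    y = np.asarray(y_true)
    s = np.asarray(probabilities, dtype=float)
    if np.sum(y == 1) == 0:
        raise EvalInputError("PR curve requires positive cases")
    precision, recall, thr = precision_recall_curve(y, s)
    points = np.column_stack([recall, precision])
    return points, float(average_precision_score(y, s))


def model_agreement(pred_a, pred_b) -> float:
    """Pearson correlation of two binary prediction vectors (phi)."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise EvalInputError("prediction vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        raise EvalInputError("agreement undefined for constant predictions")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# full report

@dataclass
class EvalReport:
    """Complete evaluation of one model on one cohort graph."""

    confusion: ConfusionMatrix
    metrics: dict
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    roc_points: np.ndarray
    pr_points: np.ndarray
    avg_precision: float
    node_ids: tuple
    probabilities: np.ndarray
    predictions: np.ndarray
    y_true: np.ndarray
    extras: dict = field(default_factory=dict)


def evaluate(graph: PatientGraph, params: dict, config: ModelConfig,
             n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Predict on a graph and compute the full evaluation battery."""
    p1, y_hat = predict(graph, params, config)
    y = graph.labels
    cm = confusion_from_predictions(y, y_hat)
    roc_points, auc_value = roc_auc(p1, y)
    ci_lo, ci_hi = auc_ci(p1, y, n_boot=n_boot, seed=seed)
    pr_points, ap = pr_curve(p1, y)
    return EvalReport(
        confusion=cm,
        metrics=classification_metrics(cm),
        auc=auc_value, auc_ci_low=ci_lo, auc_ci_high=ci_hi,
        roc_points=roc_points, pr_points=pr_points, avg_precision=ap,
        node_ids=graph.node_ids, probabilities=p1, predictions=y_hat,
        y_true=y,
    )


def report_to_dict(report: EvalReport) -> dict:
    return {
        "confusion": dataclasses.asdict(report.confusion),
        "metrics": {k: (None if np.isnan(v) else round(float(v), 6))
                    for k, v in report.metrics.items()},
        "auc": round(float(report.auc), 6),
        "auc_ci": [round(report.auc_ci_low, 6), round(report.auc_ci_high, 6)],
        "avg_precision": round(float(report.avg_precision), 6),
        "n_nodes": len(report.node_ids),
    }


def write_report(report: EvalReport, outdir, prefix: str) -> None:
    """Serialize a report as JSON summary plus flat CSVs."""
    outdir = str(outdir)
    with open(f"{outdir}/{prefix}_report.json", "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
    row = {"model": prefix, **report.metrics, "auc": report.auc,
           "auc_ci_low": report.auc_ci_low, "auc_ci_high": report.auc_ci_high,
           "avg_precision": report.avg_precision,
           **dataclasses.asdict(report.confusion)}
    pd.DataFrame([row]).to_csv(f"{outdir}/{prefix}_metrics.csv", index=False)
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr", "threshold"]).to_csv(
        f"{outdir}/{prefix}_roc.csv", index=False)
    pd.DataFrame(report.pr_points, columns=["recall", "precision"]).to_csv(
        f"{outdir}/{prefix}_pr.csv", index=False)
    pd.DataFrame({
        "id": report.node_ids,
        "probability": report.probabilities,
        "prediction": report.predictions,
        "label": report.y_true,
    }).to_csv(f"{outdir}/{prefix}_predictions.csv", index=False)
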