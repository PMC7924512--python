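"""Training schedule and AAMI evaluation metrics.

Training follows the reference recipe: Adam, batch size 512, up to 50
epochs, initial learning rate 1e-3 multiplied by 0.1 every 10 epochs
(0-based: decays take effect at epochs 10, 20, 30, 40), and an l2 penalty
of 1e-3 applied to convolution and dense weight kernels only (not biases or
batch-norm parameters).  Batches are reshuffled every epoch from the run
seed and the final partial batch is kept.

Evaluation is the AAMI suite on the 4x4 confusion matrix (rows = ground
truth, columns = predicted, class order N, SVEB, VEB, F): per-class PPV
(precision), SE (sensitivity/recall), one-vs-rest ACC and F1, their
unweighted means over the four classes, and the overall (trace/total)
accuracy.  The mean per-class ACC and the overall accuracy are different
statistics and are reported under distinct names.

``REFERENCE_CONFUSION_FOCAL`` / ``REFERENCE_CONFUSION_CROSS_ENTROPY`` hold
the published DS2 confusion matrices of this classifier on the MIT-BIH
inter-patient benchmark (focal-loss and cross-entropy training); they serve
as fixed inputs for verifying the metric computations without any data
download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .losses import LossConfig, compute_loss, softmax_loss_gradient
from .mitdb_io import AAMIClass
from .network import HybridNet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "lr_at_epoch",
    "train",
    "predict",
    "confusion_matrix",
    "per_class_metrics",
    "evaluate",
    "format_report",
    "REFERENCE_CONFUSION_FOCAL",
    "REFERENCE_CONFUSION_CROSS_ENTROPY",
]

N_CLASSES = 4

REFERENCE_CONFUSION_FOCAL = np.array(
    [
        [41420, 671, 206, 1921],
        [282, 1494, 57, 3],
        [141, 21, 3017, 40],
        [336, 0, 31, 21],
    ]
)

REFERENCE_CONFUSION_CROSS_ENTROPY = np.array(
    [
        [40866, 1082, 462, 1808],
        [246, 1482, 95, 13],
        [173, 31, 3008, 7],
        [368, 0, 18, 2],
    ]
)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 512
    max_epochs: int = 50
    base_lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every_epochs: int = 10
    l2_penalty: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.base_lr <= 0 or self.l2_penalty < 0:
            raise ValueError("base_lr must be > 0 and l2_penalty >= 0")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: base_lr * factor^(epoch // every), 0-based."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return cfg.base_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every_epochs)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    eye = np.eye(N_CLASSES)
    return eye[np.asarray(labels, dtype=int)]


def train(
    model: HybridNet,
    train_set: dict,
    cfg: TrainConfig | None = None,
    loss: LossConfig | None = None,
) -> dict:
    """Mini-batch Adam training; returns a history dict.

    ``train_set`` needs keys ``segments`` (n, 200), ``rr`` (n, 4) and
    ``labels`` (n,).  The reported per-epoch loss is the mean total training
    objective (data loss + l2 term).  Reproducible from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    loss = loss or LossConfig()
    segments = np.asarray(train_set["segments"], dtype=float)
    rr = np.asarray(train_set["rr"], dtype=float)
    labels = np.asarray(train_set["labels"], dtype=int)
    n = segments.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    present = set(np.unique(labels).tolist())
    if present != set(range(N_CLASSES)):
        logger.warning(
            "training set covers classes %s only (of %d)", sorted(present), N_CLASSES
        )
    targets = _one_hot(labels)

    rng = np.random.default_rng(cfg.seed)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-7
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    step = 0
    history: dict = {"epoch_loss": [], "epoch_lr": []}
    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            seg_b, rr_b, t_b = segments[idx], rr[idx], targets[idx]
            probs, cache = model.forward(seg_b, rr_b, training=True)
            grads = model.backward(cache, softmax_loss_gradient(t_b, probs, loss))
            batch_loss = compute_loss(t_b, probs, loss)
            if cfg.l2_penalty > 0:
                for key in model.KERNEL_KEYS:
                    w = model.params[key]
                    grads[key] = grads[key] + 2.0 * cfg.l2_penalty * w
                    batch_loss += cfg.l2_penalty * float(np.sum(w * w))
            step += 1
            for key, gval in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * gval
                v[key] = beta2 * v[key] + (1 - beta2) * gval * gval
                m_hat = m[key] / (1 - beta1**step)
                v_hat = v[key] / (1 - beta2**step)
                model.params[key] -= lr * m_hat / (np.sqrt(v_hat) + adam_eps)
            epoch_losses.append(batch_loss)
        history["epoch_loss"].append(float(np.mean(epoch_losses)))
        history["epoch_lr"].append(lr)
        logger.info(
            "epoch %d/%d  lr %.2g  loss %.5f",
            epoch + 1, cfg.max_epochs, lr, history["epoch_loss"][-1],
        )
    return history


def predict(model: HybridNet, segments, rr, batch_size: int = 2048) -> np.ndarray:
    """Class predictions (argmax of inference-mode probabilities)."""
    segments = np.asarray(segments, dtype=float)
    rr = np.asarray(rr, dtype=float)
    preds = []
    for start in range(0, segments.shape[0], batch_size):
        probs, _ = model.forward(
            segments[start : start + batch_size], rr[start : start + batch_size]
        )
        preds.append(np.argmax(probs, axis=1))  # argmax ties -> lowest index
    return np.concatenate(preds) if preds else np.empty(0, dtype=int)


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """4x4 counts, rows = ground truth, columns = predicted (N, SVEB, VEB, F)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    return _sk_confusion(y_true, y_pred, labels=list(range(N_CLASSES)))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and averaged AAMI metrics, all in percent."""

    ppv_pct: np.ndarray
    se_pct: np.ndarray
    f1_pct: np.ndarray
    acc_pct: np.ndarray
    avg_ppv_pct: float
    avg_se_pct: float
    avg_f1_pct: float
    avg_acc_pct: float
    overall_accuracy_pct: float
    n_correct: int
    n_total: int


def per_class_metrics(matrix: np.ndarray) -> MetricsReport:
    """AAMI metric suite from a 4x4 confusion matrix.

    Per class i: TP = m[i,i], FP = column sum - TP, FN = row sum - TP,
    TN = total - TP - FP - FN; PPV = TP/(TP+FP), SE = TP/(TP+FN),
    ACC = (TP+TN)/total, F1 = 2*PPV*SE/(PPV+SE) (0 when PPV+SE = 0).
    Averages are unweighted means over the four classes; the overall
    accuracy is trace/total — a different statistic from the mean ACC.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (N_CLASSES, N_CLASSES) or np.any(m < 0):
        raise ValueError("confusion matrix must be 4x4 with nonnegative counts")
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        se = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(ppv + se > 0, 2 * ppv * se / (ppv + se), 0.0)
    acc = (tp + tn) / total
    return MetricsReport(
        ppv_pct=100 * ppv,
        se_pct=100 * se,
        f1_pct=100 * f1,
        acc_pct=100 * acc,
        avg_ppv_pct=float(100 * ppv.mean()),
        avg_se_pct=float(100 * se.mean()),
        avg_f1_pct=float(100 * f1.mean()),
        avg_acc_pct=float(100 * acc.mean()),
        overall_accuracy_pct=float(100 * tp.sum() / total),
        n_correct=int(round(tp.sum())),
        n_total=int(round(total)),
    )


def evaluate(
    model: HybridNet,
    test_set: dict,
    train_record_ids: set[str] | None = None,
) -> tuple[np.ndarray, MetricsReport]:
    """Predict the test set and compute the AAMI metric suite.

    If ``train_record_ids`` is given, any overlap with the test set's record
    ids raises — the inter-patient guarantee that no patient contributes to
    both training and evaluation.
    """
    if train_record_ids is not None and "record_ids" in test_set:
        overlap = set(map(str, np.unique(test_set["record_ids"]))) & set(
            map(str, train_record_ids)
        )
        if overlap:
            raise ValueError(
                f"inter-patient violation: records {sorted(overlap)} appear in "
                "both training and test sets"
            )
    y_pred = predict(model, test_set["segments"], test_set["rr"])
    y_true = np.asarray(test_set["labels"], dtype=int)
    matrix = confusion_matrix(y_true, y_pred)
    return matrix, per_class_metrics(matrix)


def format_report(matrix: np.ndarray, report: MetricsReport) -> str:
    """Human-readable confusion matrix + metric table (two decimals)."""
    names = [c.name for c in AAMIClass]
    lines = ["Confusion matrix (rows = ground truth, columns = predicted)"]
    header = f"{'':>6}" + "".join(f"{nm:>8}" for nm in names) + f"{'Total':>8}"
    lines.append(header)
    m = np.asarray(matrix, dtype=int)
    for i, nm in enumerate(names):
        lines.append(
            f"{nm:>6}" + "".join(f"{m[i, j]:>8d}" for j in range(4)) + f"{m[i].sum():>8d}"
        )
    lines.append(
        f"{'Total':>6}" + "".join(f"{m[:, j].sum():>8d}" for j in range(4))
        + f"{m.sum():>8d}"
    )
    lines.append("")
    lines.append(f"{'class':>6}{'PPV%':>8}{'SE%':>8}{'F1%':>8}{'ACC%':>8}")
    for i, nm in enumerate(names):
        lines.append(
            f"{nm:>6}{report.ppv_pct[i]:>8.2f}{report.se_pct[i]:>8.2f}"
            f"{report.f1_pct[i]:>8.2f}{report.acc_pct[i]:>8.2f}"
        )
    lines.append(
        f"{'Avg':>6}{report.avg_ppv_pct:>8.2f}{report.avg_se_pct:>8.2f}"
        f"{report.avg_f1_pct:>8.2f}{report.avg_acc_pct:>8.2f}"
    )
    lines.append(
        f"Overall accuracy {report.overall_accuracy_pct:.2f}% "
        f"({report.n_correct}/{report.n_total} correct)"
    )
    return "\n".join(lines)
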