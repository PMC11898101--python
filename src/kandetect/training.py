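"""Training and evaluation of the KAN seizure detector.

Covers dataset assembly at a fixed background:seizure ratio, mini-batch
cross-entropy training with Adam, weight selection at the epoch where the
validation AUROC stops improving, and the window-level metric suite (AUROC
by the rank statistic, AUPRC by precision-recall step integration, and
thresholded precision/recall/F1 on the seizure-class probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .kan import Adam, KANModel
from .preprocess import FeatureSet, flatten_features, standardize_features

__all__ = [
    "TrainConfig",
    "History",
    "EvalReport",
    "Splits",
    "assemble_splits",
    "train",
    "select_weights",
    "compute_metrics",
    "cross_dataset_eval",
    "band_power_features",
    "generalization_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 100 epochs of Adam at batch size 64 by default."""

    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    early_stop_patience: int = 10
    class_ratio: tuple[float, float] = (75.0, 25.0)  # background : seizure

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.early_stop_patience > self.epochs:
            raise ValueError("early_stop_patience cannot exceed epochs")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class History:
    """Per-epoch training trace; epochs are 1-based."""

    train_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)
    val_precision: list[float] = field(default_factory=list)
    val_recall: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    selected_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_auroc": self.val_auroc,
                "val_auprc": self.val_auprc,
                "val_precision": self.val_precision,
                "val_recall": self.val_recall,
                "val_f1": self.val_f1,
            }
        )


@dataclass
class EvalReport:
    """Window-level detector quality at a decision threshold."""

    auroc: float
    auprc: float
    precision: float
    recall: float
    f1: float
    decision_threshold: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Splits:
    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    stats: tuple[np.ndarray, np.ndarray] | None = None  # training standardization


# -- metrics -----------------------------------------------------------------


def auroc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank statistic (ties get half credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUPRC by step integration of the precision-recall curve.

    Equivalent to average precision: sum over descending-score cuts of
    (recall step) x (precision at the cut), with ties handled as one block.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        return float("nan")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # merge tied scores into single thresholds
    boundaries = np.where(np.diff(s) != 0)[0]
    cut_idx = np.concatenate([boundaries, [s.size - 1]])
    tp_cum = np.cumsum(y)
    tp = tp_cum[cut_idx].astype(float)
    n_at = (cut_idx + 1).astype(float)
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Full metric suite on seizure-class probabilities vs binary labels.

    With a single class present the ranking metrics are undefined and are
    reported as NaN; the thresholded metrics are still computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalReport(
        auroc=auroc_score(scores, labels),
        auprc=auprc_score(scores, labels),
        precision=precision,
        recall=recall,
        f1=f1,
        decision_threshold=threshold,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def best_f1_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing F1 (reporting mode)."""
    candidates = np.unique(np.asarray(scores, dtype=float))
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        rep = compute_metrics(scores, labels, threshold=t)
        if rep.f1 > best_f1:
            best_t, best_f1 = float(t), rep.f1
    return best_t


# -- split assembly ----------------------------------------------------------


def assemble_splits(
    features: FeatureSet | np.ndarray,
    labels: np.ndarray | None = None,
    class_ratio: tuple[float, float] = (75.0, 25.0),
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    standardize: bool = True,
) -> Splits:
    """Subsample to the target background:seizure ratio and split disjointly.

    The majority side is down-sampled (seeded) until the background:seizure
    ratio matches ``class_ratio``; windows are then partitioned into
    train/val/test per ``fractions`` with stratification.  Standardization
    stats come from the training split only.
    """
    if isinstance(features, FeatureSet):
        x, y = flatten_features(features.x), features.y
    else:
        x, y = flatten_features(np.asarray(features)), np.asarray(labels, dtype=int)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    bg_idx = np.where(y == 0)[0]
    sz_idx = np.where(y == 1)[0]
    if len(bg_idx) == 0 or len(sz_idx) == 0:
        raise ValueError("need windows of both classes to assemble splits")
    r_bg, r_sz = class_ratio
    # largest subset achieving the ratio
    k_sz = min(len(sz_idx), int(math.floor(len(bg_idx) * r_sz / r_bg)))
    if k_sz < 1:
        raise ValueError(
            f"ratio {r_bg}:{r_sz} infeasible with {len(bg_idx)} background / "
            f"{len(sz_idx)} seizure windows; achievable seizure count is 0"
        )
    k_bg = min(len(bg_idx), int(round(k_sz * r_bg / r_sz)))
    bg_idx = rng.permutation(bg_idx)[:k_bg]
    sz_idx = rng.permutation(sz_idx)[:k_sz]

    def split(idx: np.ndarray):
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        return idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va :]

    tr_b, va_b, te_b = split(bg_idx)
    tr_s, va_s, te_s = split(sz_idx)
    tr = rng.permutation(np.concatenate([tr_b, tr_s]))
    va = np.concatenate([va_b, va_s])
    te = np.concatenate([te_b, te_s])

    x_tr, y_tr = x[tr], y[tr]
    stats = None
    if standardize:
        x_tr, stats = standardize_features(x_tr)
        x_va = standardize_features(x[va], stats)[0]
        x_te = standardize_features(x[te], stats)[0] if len(te) else x[te]
    else:
        x_va, x_te = x[va], x[te]
    return Splits(x_tr, y_tr, x_va, y[va], x_te, y[te], stats=stats)


# -- training ----------------------------------------------------------------


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = y.size
    loss = -float(logp[np.arange(n), y].mean())
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train(model: KANModel, splits: Splits, cfg: TrainConfig | None = None) -> History:
    """Mini-batch cross-entropy training with per-epoch validation metrics.

    Tracks validation AUROC each epoch, keeps the best-epoch weights, stops
    early once the AUROC has not improved for ``early_stop_patience`` epochs,
    and restores the selected weights on the model before returning.
    """
    cfg = cfg or TrainConfig()
    if model.input_dim != splits.x_train.shape[1]:
        raise ValueError(
            f"model input_dim {model.input_dim} != feature dim {splits.x_train.shape[1]}"
        )
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.lr)
    hist = History()
    best_state = model.get_state()
    best_auroc = -np.inf
    best_epoch = 0
    stall = 0
    n = splits.x_train.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(splits.x_train[idx], cache=True)
            loss, grad = _softmax_ce(logits, splits.y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {i // cfg.batch_size} "
                    f"(lr={cfg.lr})"
                )
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        hist.train_loss.append(ep_loss / n)

        proba = model.predict_proba(splits.x_val)[:, 1]
        rep = compute_metrics(proba, splits.y_val)
        hist.val_auroc.append(rep.auroc)
        hist.val_auprc.append(rep.auprc)
        hist.val_precision.append(rep.precision)
        hist.val_recall.append(rep.recall)
        hist.val_f1.append(rep.f1)

        if rep.auroc > best_auroc:
            best_auroc = rep.auroc
            best_epoch = epoch
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                break
    hist.selected_epoch = best_epoch
    model.set_state(best_state)
    return hist


def select_weights(val_auroc: list[float] | "History", patience: int = 10) -> int:
    """Epoch (1-based) whose weights the plateau rule selects.

    Scans the validation-AUROC trace and stops once the metric has failed to
    improve for ``patience`` consecutive epochs, returning the best epoch up
    to that point; ties resolve to the earliest epoch.
    """
    trace = val_auroc.val_auroc if isinstance(val_auroc, History) else list(val_auroc)
    if not trace:
        raise ValueError("empty AUROC trace")
    best_epoch, best = 1, trace[0]
    stall = 0
    for epoch, v in enumerate(trace[1:], start=2):
        if v > best:
            best, best_epoch = v, epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return best_epoch


def cross_dataset_eval(
    model: KANModel,
    features: FeatureSet | np.ndarray,
    labels: np.ndarray | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate fixed weights on another dataset — no refitting of anything.

    ``stats`` must be the *training* standardization statistics; they are
    applied unchanged to the new data.
    """
    if isinstance(features, FeatureSet):
        x, y = flatten_features(features.x), features.y
    else:
        x, y = flatten_features(np.asarray(features)), np.asarray(labels, dtype=int)
    if stats is not None:
        x = standardize_features(x, stats)[0]
    proba = model.predict_proba(x)[:, 1]
    return compute_metrics(proba, y, threshold=threshold)


# -- generalization experiment ------------------------------------------------


#: Default band edges (Hz): ~1 Hz resolution over the delta/theta range where
#: spike-wave fundamentals live, coarsening logarithmically toward high beta.
BAND_EDGES_HZ = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 16, 20, 26, 34, 45, 60, 80, 105, 125)


def band_power_features(
    x: np.ndarray, band_edges_hz=BAND_EDGES_HZ, freq_resolution_hz: float = 1.0
) -> np.ndarray:
    """Pool (n, ch, frames, freqs) tensors into per-channel band powers.

    Averages over time frames and over frequency bands (log-ish spacing by
    default: fine where seizure fundamentals live, coarse at high
    frequencies), yielding ``ch * n_bands`` features per window.  A compact
    input representation for width-comparison experiments where the wide
    model would otherwise dominate runtime.  ``freq_resolution_hz`` is the
    Hz-per-bin of the feature tensor (1 Hz for the default 250-sample STFT
    with DC dropped, where bin ``i`` is ``(i + 1)`` Hz).
    """
    x = np.asarray(x)
    n, ch, fr, fq = x.shape
    edges = [min(fq, max(0, int(round(e / freq_resolution_hz)) - 1)) for e in band_edges_hz]
    pooled = np.stack(
        [
            x[:, :, :, edges[b] : edges[b + 1]].mean(axis=(2, 3))
            for b in range(len(edges) - 1)
            if edges[b + 1] > edges[b]
        ],
        axis=2,
    )
    return pooled.reshape(n, -1)


def generalization_experiment(
    train_sets: dict[str, tuple[np.ndarray, np.ndarray]],
    specs: tuple[str, str] = ("I-764-256-O", "I-32-16-O"),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    cfg: TrainConfig | None = None,
    spline_cfg=None,
) -> "pd.DataFrame":
    """Small-vs-large width comparison on in- vs out-of-distribution data.

    ``train_sets`` maps ``{"id": (x, y), "ood": (x, y)}`` (flattened feature
    matrices).  For each spec and seed, a model is trained on the ID training
    split and evaluated, with fixed weights and training statistics, on the
    ID test split and the OOD set.  Returns one row per spec with median
    in-sample and OOD AUROC and the generalization gap.
    """
    import pandas as pd

    cfg = cfg or TrainConfig(epochs=10, early_stop_patience=10)
    x_id, y_id = train_sets["id"]
    x_ood, y_ood = train_sets["ood"]
    rows = []
    for spec in specs:
        id_scores, ood_scores = [], []
        for seed in seeds:
            splits = assemble_splits(
                x_id.reshape(x_id.shape[0], 1, 1, -1), y_id, seed=seed,
                class_ratio=cfg.class_ratio,
            )
            model = KANModel.from_spec(
                spec, splits.x_train.shape[1], output_dim=2, cfg=spline_cfg, seed=seed
            )
            run_cfg = TrainConfig(
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                lr=cfg.lr,
                seed=seed,
                early_stop_patience=cfg.early_stop_patience,
                class_ratio=cfg.class_ratio,
            )
            train(model, splits, run_cfg)
            rep_id = cross_dataset_eval(model, splits.x_test.reshape(-1, 1, 1, splits.x_test.shape[1]),
                                        splits.y_test)
            rep_ood = cross_dataset_eval(
                model, x_ood.reshape(x_ood.shape[0], 1, 1, -1), y_ood, stats=splits.stats
            )
            id_scores.append(rep_id.auroc)
            ood_scores.append(rep_ood.auroc)
        rows.append(
            {
                "spec": spec,
                "median_id_auroc": float(np.median(id_scores)),
                "median_ood_auroc": float(np.median(ood_scores)),
                "median_gap": float(np.median(np.array(id_scores) - np.array(ood_scores))),
                "n_seeds": len(seeds),
            }
        )
    return pd.DataFrame(rows)
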