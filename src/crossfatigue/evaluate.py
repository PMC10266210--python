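"""Metrics: three-state discretization, per-class precision/recall/F1,
accuracy, RMSE, the analytic random baseline, and an embedding plot helper.

The continuous fatigue index is discretized into awake / fatigue / drowsy
with thresholds 0.35 and 0.7 (half-open upward: [0.35, 0.7) is fatigue).
Classification metrics are one-vs-rest confusion counts per class;
zero-denominator cells yield 0.  Percentages are on a 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASSES",
    "MetricsReport",
    "discretize",
    "classification_metrics",
    "rmse",
    "random_baseline_accuracy",
    "embed_plot",
]

CLASSES = ("awake", "fatigue", "drowsy")
DEFAULT_THRESHOLDS = (0.35, 0.7)


@dataclass
class MetricsReport:
    per_class: dict
    macro: dict
    accuracy: float
    rmse: float | None
    n: int
    confusion: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "rmse": self.rmse,
            "n": self.n,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }


def discretize(index_value, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS):
    """Map a [0, 1] index to awake/fatigue/drowsy (values clipped first).

    Convention: value < thresholds[0] -> awake; [t0, t1) -> fatigue;
    >= t1 -> drowsy.
    """
    t0, t1 = thresholds
    if not t0 < t1:
        raise ValueError("thresholds must be strictly increasing")
    arr = np.clip(np.asarray(index_value, dtype=float), 0.0, 1.0)
    idx = np.digitize(arr, [t0, t1], right=False)
    classes = np.asarray(CLASSES, dtype=object)[idx]
    if np.isscalar(index_value) or arr.ndim == 0:
        return str(classes)
    return classes


def _class_indices(values) -> np.ndarray:
    arr = np.asarray(values, dtype=object).ravel()
    lookup = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([lookup[v] for v in arr], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


def classification_metrics(pred_classes, true_classes,
                           pred_index=None, true_index=None) -> MetricsReport:
    """Per-class precision/recall/F1 (%), overall accuracy (%), optional RMSE.

    Accuracy is the overall fraction of correct predictions (the multi-class
    form of the binary (TP+TN)/total); macro metrics are unweighted means
    over the three classes; any 0/0 metric is reported as 0.
    """
    yp = _class_indices(pred_classes)
    yt = _class_indices(true_classes)
    if yp.shape != yt.shape:
        raise ValueError("prediction/truth length mismatch")
    n = yp.size
    k = len(CLASSES)
    conf = np.zeros((k, k), dtype=int)  # rows: truth, cols: prediction
    np.add.at(conf, (yt, yp), 1)

    per_class = {}
    for i, cls in enumerate(CLASSES):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    macro = {
        m: float(np.mean([per_class[c][m] for c in CLASSES]))
        for m in ("precision", "recall", "f1")
    }
    accuracy = 100.0 * conf.trace() / n if n else 0.0
    err = None
    if pred_index is not None and true_index is not None:
        err = rmse(pred_index, true_index)
    return MetricsReport(per_class=per_class, macro=macro,
                         accuracy=float(accuracy), rmse=err, n=n,
                         confusion=conf)


def rmse(pred_index, true_index) -> float:
    """Root mean squared error of the continuous index prediction."""
    p = np.asarray(pred_index, dtype=float).ravel()
    t = np.asarray(true_index, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def random_baseline_accuracy(n_classes: int = 3) -> float:
    """Expected accuracy (%) of uniform random class assignment."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / n_classes


def embed_plot(features, labels, out_path, method: str = "pca",
               seed: int = 0) -> str:
    """Scatter plot of a 2-D embedding of feature vectors (diagnostic only).

    ``method`` is ``"pca"`` (default, dependency-free) or ``"umap"``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.asarray(features, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points to embed")
    if method == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    else:
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        emb = Xc @ vt[:2].T
    labels = np.asarray(labels, dtype=object).ravel()
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(set(labels), key=str):
        m = labels == lab
        ax.scatter(emb[m, 0], emb[m, 1], s=12, label=str(lab), alpha=0.7)
    ax.legend(fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)
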