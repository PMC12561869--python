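"""Confusion-matrix construction and the sleep-staging metric suite.

All quantities derive from a single 5x5 confusion matrix (rows = true stage,
columns = predicted stage) through one-vs-rest reduction: per class k,
TP = C[k,k], FP = column k minus TP, FN = row k minus TP, TN = the rest.

    ACC   = trace / total
    SEN_k = TP/(TP+FN)     SPE_k = TN/(TN+FP)     PRE_k = TP/(TP+FP)
    F1_k  = 2 PRE_k SEN_k / (PRE_k + SEN_k)
    Kappa = (P0 - Pe)/(1 - Pe),  P0 = ACC,
            Pe = sum_k row_k * col_k / total^2

Overall SEN/SPE/PRE/F1 are unweighted (macro) means over the five classes.
A class absent from both truth and prediction would make a ratio 0/0; such
ratios are reported as 0 with a logged warning so pooled cross-fold reports
never crash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import N_CLASSES, STAGE_NAMES

logger = logging.getLogger(__name__)

#: conventional ordinate order for hypnogram plots, top to bottom
HYPNOGRAM_ORDER = ("W", "REM", "N1", "N2", "N3")
_PLOT_POSITION = {0: 4, 4: 3, 1: 2, 2: 1, 3: 0}  # class -> height on axis
_POSITION_TO_CLASS = {v: k for k, v in _PLOT_POSITION.items()}


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path):
        pd.DataFrame(self.counts, index=list(STAGE_NAMES),
                     columns=list(STAGE_NAMES)).to_csv(path)


@dataclass
class MetricsReport:
    """Overall and per-class evaluation quantities, all on [0, 1] scale
    except Kappa which lies in [-1, 1]."""

    accuracy: float
    f1_macro: float
    kappa: float
    sensitivity: float
    specificity: float
    precision: float
    per_class: pd.DataFrame  # rows = stages; PRE/SEN/SPE/F1 columns

    def to_row(self, scale: float = 100.0) -> dict:
        return {"ACC": self.accuracy * scale,
                "F1_Macro": self.f1_macro * scale,
                "Kappa": self.kappa * scale,
                "Sen": self.sensitivity * scale,
                "Spe": self.specificity * scale,
                "Pre": self.precision * scale}

    def to_text(self) -> str:
        lines = [f"{k}: {v:.2f}" for k, v in self.to_row().items()]
        return "\n".join(lines) + "\n\nPer-class (%):\n" + (
            self.per_class * 100).round(2).to_string()


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count matrix C[i, j] = #{epochs with true stage i predicted as j}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and not ((0 <= t.min()) and (t.max() < N_CLASSES)
                       and (0 <= p.min()) and (p.max() < N_CLASSES)):
        raise ValueError("labels must lie in 0..4")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def one_vs_rest(conf: ConfusionMatrix, k: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for class k under one-vs-rest reduction."""
    if not 0 <= k < N_CLASSES:
        raise ValueError("class index must be in 0..4")
    c = conf.counts
    tp = int(c[k, k])
    fp = int(c[:, k].sum() - tp)
    fn = int(c[k, :].sum() - tp)
    tn = conf.total - tp - fp - fn
    return tp, fp, tn, fn


def _ratio(num: float, den: float, name: str, k: int) -> float:
    if den == 0:
        logger.warning("%s undefined for class %s (0/0); reporting 0",
                       name, STAGE_NAMES[k])
        return 0.0
    return num / den


def compute_metrics(conf: ConfusionMatrix) -> MetricsReport:
    """All evaluation quantities from one confusion matrix."""
    total = conf.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(conf.counts)) / total

    rows = []
    for k in range(N_CLASSES):
        tp, fp, tn, fn = one_vs_rest(conf, k)
        pre = _ratio(tp, tp + fp, "precision", k)
        sen = _ratio(tp, tp + fn, "sensitivity", k)
        spe = _ratio(tn, tn + fp, "specificity", k)
        f1 = _ratio(2 * pre * sen, pre + sen, "F1", k)
        rows.append({"PRE": pre, "SEN": sen, "SPE": spe, "F1": f1})
    per_class = pd.DataFrame(rows, index=list(STAGE_NAMES))

    marg_true = conf.counts.sum(axis=1).astype(float)
    marg_pred = conf.counts.sum(axis=0).astype(float)
    pe = float((marg_true * marg_pred).sum()) / total ** 2
    kappa = (acc - pe) / (1.0 - pe) if pe < 1.0 else 1.0

    return MetricsReport(
        accuracy=acc,
        f1_macro=float(per_class["F1"].mean()),
        kappa=kappa,
        sensitivity=float(per_class["SEN"].mean()),
        specificity=float(per_class["SPE"].mean()),
        precision=float(per_class["PRE"].mean()),
        per_class=per_class)


def hypnogram_series(labels, predictions=None):
    """Stage-vs-epoch step traces in conventional plotting order.

    Returns a DataFrame with epoch index and the plotted height of each
    trace; heights follow :data:`HYPNOGRAM_ORDER` top to bottom so W sits on
    top and N3 at the bottom, as clinical hypnograms are drawn.
    """
    labels = np.asarray(labels, dtype=np.int64)
    data = {"epoch": np.arange(len(labels)),
            "truth": np.array([_PLOT_POSITION[int(v)] for v in labels])}
    if predictions is not None:
        predictions = np.asarray(predictions, dtype=np.int64)
        if len(predictions) != len(labels):
            raise ValueError("labels and predictions differ in length")
        data["predicted"] = np.array([_PLOT_POSITION[int(v)]
                                      for v in predictions])
    return pd.DataFrame(data)


def plot_position_to_class(position: int) -> int:
    """Invert the hypnogram ordinate mapping (for tick labeling)."""
    return _POSITION_TO_CLASS[int(position)]


def plot_hypnogram(series: pd.DataFrame, path=None):
    """Render truth (and predicted) hypnogram traces to a figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in ("truth", "predicted") if c in series]
    fig, axes = plt.subplots(len(cols), 1, figsize=(10, 2.2 * len(cols)),
                             sharex=True, squeeze=False)
    for ax, col in zip(axes[:, 0], cols):
        ax.step(series["epoch"], series[col], where="post", lw=0.8)
        ax.set_yticks(range(len(HYPNOGRAM_ORDER)),
                      list(reversed(HYPNOGRAM_ORDER)))
        ax.set_ylabel(col)
    axes[-1, 0].set_xlabel("epoch (30 s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_confusion(conf: ConfusionMatrix, path=None):
    """Row-normalized confusion-matrix heat map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = conf.counts.astype(float)
    norm = c / np.maximum(c.sum(axis=1, keepdims=True), 1)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(N_CLASSES), STAGE_NAMES)
    ax.set_yticks(range(N_CLASSES), STAGE_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, f"{int(c[i, j])}", ha="center", va="center",
                    fontsize=8, color="black" if norm[i, j] < 0.5 else "white")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
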