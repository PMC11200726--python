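"""Optional matplotlib figures: ROC curve and embedding scatter.

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency (install the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import RocResult
from .lle import Embedding


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plot' extra)") from exc
    return plt


def plot_roc(roc: RocResult, path: str | Path) -> None:
    """ROC curve with the chosen (Youden-optimal) operating point marked."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.points[:, 2], roc.points[:, 1], drawstyle="steps-post", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.plot(roc.false_positive_rate, roc.sensitivity, "ro",
            label=f"w2u = {roc.best_threshold:.4f}")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("sensitivity (failure = positive)")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(
    emb: Embedding,
    twl: np.ndarray,
    path: str | Path,
    projected: np.ndarray | None = None,
    projected_twl: np.ndarray | None = None,
    cutoff: float = 30.0,
) -> None:
    """w1/w2 scatter of the training embedding, coloured by outcome class.

    Optionally overlays projected validation patients (open markers).
    """
    plt = _pyplot()
    if emb.selected_coord is None:
        raise ValueError("orient the embedding to the outcome before plotting")
    others = [j for j in range(emb.d) if j != emb.selected_coord]
    x = emb.W[:, others[0]]
    y = emb.orientation * emb.W[:, emb.selected_coord]
    success = np.asarray(twl) >= cutoff
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(x[success], y[success], c="tab:blue", s=22, label="success (train)")
    ax.scatter(x[~success], y[~success], c="tab:red", s=22, label="failure (train)")
    if projected is not None:
        px = projected[:, others[0]]
        py = emb.orientation * projected[:, emb.selected_coord]
        if projected_twl is not None:
            ps = np.asarray(projected_twl) >= cutoff
            ax.scatter(px[ps], py[ps], facecolors="none", edgecolors="black",
                       s=30, label="success (valid)")
            ax.scatter(px[~ps], py[~ps], facecolors="none", edgecolors="magenta",
                       s=30, label="failure (valid)")
        else:
            ax.scatter(px, py, facecolors="none", edgecolors="black", s=30,
                       label="projected")
    ax.set_xlabel("w1")
    ax.set_ylabel("w2 (outcome-aligned)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
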