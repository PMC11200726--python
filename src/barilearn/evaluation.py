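"""Threshold classification on w2, ROC analysis, and variable relevance.

The classifier is a single threshold w2u on the outcome-aligned latent
coordinate: a patient with w2 < w2u is predicted to have an unsatisfactory
intervention (%TWL < 30, the *positive* class here), w2 >= w2u a
satisfactory one. The full ROC curve is traced by sweeping w2u over every
midpoint between adjacent distinct w2 values (plus -inf/+inf sentinels),
which realizes "all possible thresholds" exactly; AUC is the trapezoidal
area, identical to the Mann-Whitney concordance probability. The reported
operating point maximizes Youden's J = sensitivity - FPR (ties resolved
toward the lower threshold).

Variable relevance mirrors the consensus reading of the evolved exponents:
a variable is consensus-high when its alpha exceeds the high cutoff
(default 2.4) in every GA run, consensus-low when below the low cutoff
(default -2.4, a symmetric convention) in every run, and mixed otherwise.
`prune_and_reembed` drops the low-relevance variables (alpha < cutoff) and
re-evaluates the downstream pipeline, either reusing the surviving
exponents or refitting them from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lle
from .evolve import EAConfig, best_alpha_vector, evolve, select_best_run
from .projection import DEFAULT_M, project_cohort
from .weighting import AlphaVector, apply_weights

__all__ = [
    "RocResult",
    "RelevanceTable",
    "sweep_thresholds",
    "classify_at",
    "confusion_at",
    "rank_variables",
    "prune_and_reembed",
    "HIGH_ALPHA_CUT",
    "LOW_ALPHA_CUT",
]

#: Exponent above which a variable counts as high-relevance (the pruning cutoff).
HIGH_ALPHA_CUT = 2.4
#: Symmetric convention for the low-relevance consensus.
LOW_ALPHA_CUT = -2.4


@dataclass
class RocResult:
    """A full threshold sweep: curve points, AUC and the chosen cutoff.

    ``points`` columns are (threshold, sensitivity, false-positive rate),
    ordered by ascending threshold; ``confusion`` holds TP/FP/TN/FN at
    ``best_threshold`` with *failure* (%TWL < 30) as the positive class.
    """

    points: np.ndarray
    auc: float
    best_threshold: float
    confusion: dict[str, int]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")

    @property
    def sensitivity(self) -> float:
        c = self.confusion
        return c["TP"] / (c["TP"] + c["FN"])

    @property
    def false_positive_rate(self) -> float:
        c = self.confusion
        return c["FP"] / (c["FP"] + c["TN"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "sensitivity", "fpr"])


def classify_at(w2, w2u: float):
    """Predicted label at threshold w2u: True (success) iff w2 >= w2u."""
    arr = np.asarray(w2, dtype=float)
    out = arr >= w2u
    return bool(out) if out.ndim == 0 else out


def confusion_at(w2: np.ndarray, labels: np.ndarray, w2u: float) -> dict[str, int]:
    """TP/FP/TN/FN at a threshold, failure (label False) as positive class."""
    w2 = np.asarray(w2, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred_success = classify_at(w2, w2u)
    return {
        "TP": int(np.sum(~pred_success & ~labels)),
        "FP": int(np.sum(~pred_success & labels)),
        "TN": int(np.sum(pred_success & labels)),
        "FN": int(np.sum(pred_success & ~labels)),
    }


def sweep_thresholds(w2: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve over all distinct-value midpoints of w2.

    ``labels`` are success booleans (True = %TWL >= 30); the ROC positive
    class is failure. Sensitivity at a threshold t is the fraction of
    failures with w2 < t; FPR is the fraction of successes with w2 < t.
    """
    w2 = np.asarray(w2, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(np.sum(~labels))  # failures
    n_neg = int(np.sum(labels))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present to sweep thresholds")

    distinct = np.unique(w2)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    # predicted failure iff w2 < t
    fail_w2 = np.sort(w2[~labels])
    succ_w2 = np.sort(w2[labels])
    tp = np.searchsorted(fail_w2, thresholds, side="left")
    fp = np.searchsorted(succ_w2, thresholds, side="left")
    tpr = tp / n_pos
    fpr = fp / n_neg

    # trapezoidal area computed in integer arithmetic so that it equals the
    # Mann-Whitney concordance probability exactly, ties counted half
    num = int(np.sum(np.diff(fp) * (tp[:-1] + tp[1:])))
    auc = num / (2 * n_pos * n_neg)
    j = tpr - fpr
    best_i = int(np.argmax(j))  # argmax takes the first (lowest threshold) on ties
    best_threshold = float(thresholds[best_i])
    points = np.column_stack([thresholds, tpr, fpr])
    return RocResult(
        points=points,
        auc=auc,
        best_threshold=best_threshold,
        confusion=confusion_at(w2, labels, best_threshold),
    )


@dataclass
class RelevanceTable:
    """Per-variable exponents across runs with a consensus flag."""

    table: pd.DataFrame

    def consensus_high(self) -> list[str]:
        return self.table.loc[self.table["consensus"] == "high", "name"].tolist()

    def consensus_low(self) -> list[str]:
        return self.table.loc[self.table["consensus"] == "low", "name"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_variables(
    runs,
    names: list[str] | None = None,
    high_cut: float = HIGH_ALPHA_CUT,
    low_cut: float = LOW_ALPHA_CUT,
) -> RelevanceTable:
    """Consensus relevance of each variable across independent GA runs.

    ``runs`` may be a list of :class:`~barilearn.evolve.RunResult` or a
    list of alpha arrays. A variable is consensus-high when alpha >=
    ``high_cut`` in every run, consensus-low when alpha <= ``low_cut`` in
    every run, mixed otherwise.
    """
    if not runs:
        raise ValueError("need at least one run")
    alphas = np.stack(
        [r.best.alphas if hasattr(r, "best") else np.asarray(r, dtype=float) for r in runs]
    )
    n_vars = alphas.shape[1]
    if names is None:
        names = [f"v{i + 1}" for i in range(n_vars)]
    high = np.all(alphas >= high_cut, axis=0)
    low = np.all(alphas <= low_cut, axis=0)
    consensus = np.where(high, "high", np.where(low, "low", "mixed"))
    cols = {"name": names, "index": np.arange(1, n_vars + 1)}
    for r_i in range(alphas.shape[0]):
        cols[f"alpha_run{r_i + 1}"] = alphas[r_i]
    cols["consensus"] = consensus
    return RelevanceTable(table=pd.DataFrame(cols))


@dataclass
class PrunedResult:
    """Downstream evaluation after dropping low-relevance variables."""

    surviving: np.ndarray
    alphas: AlphaVector
    roc: RocResult
    train_r_squared: float


def prune_and_reembed(
    alphas: AlphaVector,
    Y_train: np.ndarray,
    Y_valid: np.ndarray,
    twl_train: np.ndarray,
    labels_valid: np.ndarray,
    cutoff: float = HIGH_ALPHA_CUT,
    mode: str = "reuse",
    k: int = lle.DEFAULT_K,
    d: int = lle.DEFAULT_DIM,
    m: int = DEFAULT_M,
    reg: float = lle.DEFAULT_REG,
    ea_config: EAConfig | None = None,
) -> PrunedResult:
    """Drop variables with alpha < cutoff and re-run embedding + evaluation.

    ``mode='reuse'`` keeps the surviving exponents fixed; ``mode='refit'``
    re-runs the evolutionary search on the reduced variable panel (the
    reference variable is re-pinned to the first survivor if the original
    reference was pruned). Both matrices must already be normalized.
    """
    if mode not in ("reuse", "refit"):
        raise ValueError("mode must be 'reuse' or 'refit'")
    keep = np.flatnonzero(alphas.alpha >= cutoff)
    if keep.size < 2:
        raise ValueError(
            f"pruning at alpha < {cutoff} leaves {keep.size} variable(s); need >= 2"
        )
    Y_train = np.asarray(Y_train, dtype=float)[:, keep]
    Y_valid = np.asarray(Y_valid, dtype=float)[:, keep]

    ref_pos = np.flatnonzero(keep == alphas.reference_index)
    if mode == "refit":
        if ea_config is None:
            raise ValueError("mode='refit' requires an ea_config")
        # if the original reference was pruned, pin the first survivor instead
        new_ref = int(ref_pos[0]) if ref_pos.size else 0
        runs = evolve(Y_train, twl_train, ea_config, reference_index=new_ref, k=k, d=d, reg=reg)
        new_alphas = best_alpha_vector(select_best_run(runs), reference_index=new_ref)
    else:
        sub = alphas.alpha[keep].copy()
        if ref_pos.size:
            new_alphas = AlphaVector(alpha=sub, reference_index=int(ref_pos[0]))
        else:
            # Original reference pruned: re-base so the first survivor has
            # exponent 0. A uniform shift rescales every column by the same
            # constant, which leaves neighbourhoods, barycentric weights and
            # hence the embedding unchanged.
            vals = sub - sub[0]
            new_alphas = AlphaVector(
                alpha=vals,
                reference_index=0,
                bounds=(min(-4.0, float(vals.min())), max(4.0, float(vals.max()))),
            )

    Zt = apply_weights(Y_train, new_alphas)
    Zv = apply_weights(Y_valid, new_alphas)
    emb, _, _ = lle.fit_lle(Zt, k=k, d=d, reg=reg, twl=twl_train)
    w2_train = emb.outcome_coordinate()
    r = np.corrcoef(w2_train, twl_train)[0, 1]
    coords, _ = project_cohort(Zv, Zt, emb, m=m, reg=reg)
    w2_valid = emb.orientation * coords[:, emb.selected_coord]
    roc = sweep_thresholds(w2_valid, labels_valid)
    return PrunedResult(
        surviving=keep, alphas=new_alphas, roc=roc, train_r_squared=float(r * r)
    )
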