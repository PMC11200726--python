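"""Out-of-sample projection into the trained low-dimensional space.

A held-out patient is placed in the latent space by the same barycentric
logic LLE uses internally: find the m = 7 nearest training patients in the
weighted-normalized 60-variable space (Euclidean distance D), solve for
influence weights beta_i that reconstruct the patient from those
neighbours subject to sum(beta) = 1, and carry the weights over to the
embedding:

    W_v = sum_i beta_i * W_ti.

Because the betas sum to one the projection is affine-equivariant:
translating the training embedding translates every projection identically.
Everything in this module is deterministic — there is no randomness.

Distances are computed in the weighted space (z = 10**alpha * y) so that
the learned variable relevances shape the neighbourhoods; an unweighted
mode (pass the normalized matrix instead) is available for sensitivity
analysis, as is an unconstrained least-squares mode for the betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lle import DEFAULT_REG, Embedding, barycentric_weights
from .weighting import WeightedMatrix

__all__ = [
    "ProjectionRecord",
    "patient_distance",
    "find_training_neighbors",
    "solve_beta",
    "project",
    "project_cohort",
    "DEFAULT_M",
]

#: Number of training neighbours used for the barycentric projection.
DEFAULT_M = 7


def _as_matrix(Z) -> np.ndarray:
    if isinstance(Z, WeightedMatrix):
        return Z.Z
    return np.asarray(Z, dtype=float)


@dataclass
class ProjectionRecord:
    """One projected patient: neighbours, influences, latent coordinates."""

    patient: str
    neighbor_ids: np.ndarray
    beta: np.ndarray
    Wv: np.ndarray

    def __post_init__(self) -> None:
        self.neighbor_ids = np.asarray(self.neighbor_ids, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        self.Wv = np.asarray(self.Wv, dtype=float)
        if not np.all(np.isfinite(self.Wv)):
            raise ValueError("projected coordinates must be finite")


def patient_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two patients in variable space."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def find_training_neighbors(
    v: np.ndarray, train, m: int = DEFAULT_M
) -> tuple[np.ndarray, np.ndarray]:
    """The m training rows closest to ``v``; ties broken by lower index."""
    T = _as_matrix(train)
    v = np.asarray(v, dtype=float)
    if m < 1 or m > T.shape[0]:
        raise ValueError(f"m={m} must be in [1, {T.shape[0]}]")
    d = np.linalg.norm(T - v, axis=1)
    order = np.argsort(d, kind="stable")[:m]
    return order, d[order]


def solve_beta(
    v: np.ndarray,
    neighbors: np.ndarray,
    reg: float = DEFAULT_REG,
    sum_constraint: bool = True,
) -> np.ndarray:
    """Influence weights reconstructing ``v`` from its training neighbours.

    Default is the sum-to-one constrained least squares shared with the
    LLE reconstruction stage; ``sum_constraint=False`` solves the plain
    (ridge-regularized) least-squares system instead.
    """
    v = np.asarray(v, dtype=float)
    nb = np.asarray(neighbors, dtype=float)
    if nb.ndim != 2 or nb.shape[1] != v.shape[0]:
        raise ValueError("neighbors must be an (m, V) matrix matching v")
    if sum_constraint:
        return barycentric_weights(v, nb, reg=reg)
    G = nb @ nb.T
    if reg > 0:
        tr = np.trace(G)
        G = G + (reg * tr if tr > 0 else reg) * np.eye(G.shape[0])
    try:
        return np.linalg.solve(G, nb @ v)
    except np.linalg.LinAlgError:
        if reg == 0:
            raise
        return np.linalg.lstsq(G, nb @ v, rcond=None)[0]


def project(beta: np.ndarray, W_train: np.ndarray) -> np.ndarray:
    """Latent coordinates of a projected patient: W_v = sum_i beta_i W_ti."""
    beta = np.asarray(beta, dtype=float)
    W_train = np.asarray(W_train, dtype=float)
    if W_train.shape[0] != beta.shape[0]:
        raise ValueError("beta length must match number of neighbour rows")
    return beta @ W_train


def project_cohort(
    valid_Z,
    train_Z,
    embedding: Embedding,
    m: int = DEFAULT_M,
    reg: float = DEFAULT_REG,
    sum_constraint: bool = True,
    patient_ids: list[str] | None = None,
) -> tuple[np.ndarray, list[ProjectionRecord]]:
    """Project every validation patient; returns (n_valid, d) coordinates.

    ``valid_Z`` and ``train_Z`` must live in the same (weighted,
    normalized) variable space; ``embedding`` rows align with ``train_Z``
    rows.
    """
    V = _as_matrix(valid_Z)
    T = _as_matrix(train_Z)
    if V.shape[1] != T.shape[1]:
        raise ValueError("validation and training matrices differ in width")
    if embedding.W.shape[0] != T.shape[0]:
        raise ValueError("embedding rows must align with training rows")
    if patient_ids is None:
        patient_ids = [f"valid{i}" for i in range(V.shape[0])]
    coords = np.empty((V.shape[0], embedding.d))
    records: list[ProjectionRecord] = []
    for i in range(V.shape[0]):
        nbr, _ = find_training_neighbors(V[i], T, m)
        beta = solve_beta(V[i], T[nbr], reg=reg, sum_constraint=sum_constraint)
        Wv = project(beta, embedding.W[nbr])
        coords[i] = Wv
        records.append(
            ProjectionRecord(patient=patient_ids[i], neighbor_ids=nbr, beta=beta, Wv=Wv)
        )
    return coords, records
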