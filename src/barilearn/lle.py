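"""Locally linear embedding of the weighted training matrix.

Classic three-stage LLE: (1) k nearest neighbours under Euclidean distance,
(2) barycentric reconstruction weights solving the local Gram system with a
sum-to-one constraint, (3) the bottom non-constant eigenvectors of
M = (I - W)^T (I - W) as the embedded coordinates. The embedding here is
always low-dimensional (d = 3 by default, coordinates w1, w2, w3) and the
coordinate most correlated with the outcome — called w2 in this pipeline —
is discovered a posteriori by `orient_to_outcome`, which also fixes the
eigenvector sign so that low w2 means low weight loss.

Default k = 7, matching the seven-neighbour barycentric scheme used to
project held-out patients into the trained space (`barilearn.projection`).

The eigenproblem is solved densely: cohorts here are a few hundred patients
at most, where a dense symmetric solver is both faster and more robust than
sparse iterative alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .weighting import WeightedMatrix

__all__ = [
    "NeighborGraph",
    "Embedding",
    "knn",
    "reconstruction_weights",
    "embed",
    "orient_to_outcome",
    "fit_lle",
    "barycentric_weights",
    "DEFAULT_K",
    "DEFAULT_DIM",
    "DEFAULT_REG",
]

DEFAULT_K = 7
DEFAULT_DIM = 3
#: Gram-matrix ridge, as a fraction of the trace (standard LLE conditioning).
DEFAULT_REG = 1e-3


def _as_matrix(Z) -> np.ndarray:
    if isinstance(Z, WeightedMatrix):
        return Z.Z
    return np.asarray(Z, dtype=float)


@dataclass
class NeighborGraph:
    """k-nearest-neighbour table: row i lists the neighbours of point i.

    Distances are non-decreasing along each row; ties are broken toward the
    lower row index, and a point is never its own neighbour.
    """

    indices: np.ndarray
    distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have the same shape")
        if self.indices.shape[1] != self.k:
            raise ValueError("table width must equal k")
        n = self.indices.shape[0]
        if (self.indices == np.arange(n)[:, None]).any():
            raise ValueError("self-neighbours are not allowed")


def _pairwise_sq_dists(Z: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", Z, Z)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def knn(Z, k: int) -> NeighborGraph:
    """Exact k nearest rows by Euclidean distance, excluding self.

    Deterministic under ties: equal distances are ordered by row index
    (numpy's stable sort on the distance matrix guarantees this).
    """
    Zm = _as_matrix(Z)
    n = Zm.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = _pairwise_sq_dists(Zm)
    np.fill_diagonal(d2, np.inf)
    # stable sort keeps lower indices first among exact ties
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    dists = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighborGraph(indices=order, distances=dists, k=k)


def barycentric_weights(
    point: np.ndarray, neighbors: np.ndarray, reg: float = DEFAULT_REG
) -> np.ndarray:
    """Sum-to-one least-squares weights reconstructing ``point`` from rows
    of ``neighbors``.

    Solves min ||point - sum_j w_j * neighbor_j||^2 s.t. sum_j w_j = 1 via
    the local Gram system G w = 1 followed by normalization, with G
    ridge-regularized by ``reg * trace(G)`` (or an absolute floor when the
    neighbourhood is degenerate, e.g. all neighbours coincident with the
    point).
    """
    point = np.asarray(point, dtype=float)
    nb = np.asarray(neighbors, dtype=float)
    diff = nb - point
    G = diff @ diff.T
    m = G.shape[0]
    if reg > 0:
        tr = np.trace(G)
        G = G + (reg * tr if tr > 0 else reg) * np.eye(m)
    try:
        w = np.linalg.solve(G, np.ones(m))
    except np.linalg.LinAlgError:
        if reg == 0:
            raise np.linalg.LinAlgError(
                "singular local Gram system; pass reg > 0 to regularize"
            ) from None
        w = np.linalg.lstsq(G, np.ones(m), rcond=None)[0]
    s = w.sum()
    if s == 0:
        raise np.linalg.LinAlgError(
            "degenerate local system: weights sum to zero; increase reg"
        )
    return w / s


def _batched_weights(Z: np.ndarray, indices: np.ndarray, reg: float) -> np.ndarray:
    """Vectorized sum-to-one reconstruction weights for every row at once."""
    n, k = indices.shape
    diffs = Z[indices] - Z[:, None, :]               # (n, k, V)
    G = np.einsum("nik,njk->nij", diffs, diffs)      # (n, k, k)
    if reg > 0:
        tr = np.einsum("nii->n", G)
        ridge = np.where(tr > 0, reg * tr, reg)
        G = G + ridge[:, None, None] * np.eye(k)
    ones = np.ones((n, k, 1))
    try:
        w = np.linalg.solve(G, ones)[..., 0]
    except np.linalg.LinAlgError:
        w = np.stack(
            [np.linalg.lstsq(G[i], np.ones(k), rcond=None)[0] for i in range(n)]
        )
    sums = w.sum(axis=1)
    if np.any(sums == 0):
        raise np.linalg.LinAlgError("degenerate local system: weights sum to zero")
    return w / sums[:, None]


def reconstruction_weights(Z, graph: NeighborGraph, reg: float = DEFAULT_REG) -> np.ndarray:
    """Per-point barycentric reconstruction weights (n x k), rows sum to 1."""
    Zm = _as_matrix(Z)
    if reg < 0:
        raise ValueError("reg must be >= 0")
    if reg == 0:
        # unregularized path kept scalar for clear singularity errors
        return np.stack(
            [
                barycentric_weights(Zm[i], Zm[graph.indices[i]], reg=0.0)
                for i in range(Zm.shape[0])
            ]
        )
    return _batched_weights(Zm, graph.indices, reg)


@dataclass
class Embedding:
    """Per-patient latent coordinates (w1, w2, w3 for d = 3).

    ``selected_coord`` and ``orientation`` are set by `orient_to_outcome`:
    the selected column is the outcome-aligned coordinate (reported as w2)
    and its sign is fixed so that it correlates positively with %TWL.
    """

    W: np.ndarray
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]
    selected_coord: int | None = None
    orientation: int = 1

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.eigenvalues is not None:
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def outcome_coordinate(self) -> np.ndarray:
        """The oriented outcome-aligned coordinate (w2)."""
        if self.selected_coord is None:
            raise ValueError("call orient_to_outcome first")
        return self.orientation * self.W[:, self.selected_coord]


def _embedding_matrix(weights: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Dense M = (I - W)^T (I - W) from the sparse neighbour weights."""
    n = weights.shape[0]
    A = np.eye(n)
    rows = np.repeat(np.arange(n), indices.shape[1])
    np.subtract.at(A, (rows, indices.ravel()), weights.ravel())
    return A.T @ A


def embed(
    weights: np.ndarray,
    graph: NeighborGraph,
    d: int = DEFAULT_DIM,
) -> Embedding:
    """Bottom non-constant eigenvectors of (I - W)^T (I - W).

    The all-ones eigenvector (eigenvalue ~ 0, guaranteed by the sum-to-one
    weight rows) is discarded; columns are the next ``d`` eigenvectors in
    ascending eigenvalue order, unit-norm as returned by the symmetric
    eigensolver. Eigenvalues are kept for diagnostics.
    """
    n = weights.shape[0]
    if d >= n:
        raise ValueError(f"d={d} must be smaller than n={n}")
    M = _embedding_matrix(weights, graph.indices)
    try:
        vals, vecs = scipy.linalg.eigh(M, subset_by_index=(0, d))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise scipy.linalg.LinAlgError(
            f"eigendecomposition failed (cond(M)={np.linalg.cond(M):.3e})"
        ) from exc
    # drop the constant bottom eigenvector, keep the next d
    return Embedding(W=vecs[:, 1 : d + 1], eigenvalues=vals)


def _safe_r2(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    r = (xc @ yc) / denom
    return float(r * r)


def orient_to_outcome(emb: Embedding, twl: np.ndarray) -> Embedding:
    """Select and orient the outcome-aligned coordinate.

    The coordinate with the highest squared Pearson correlation with the
    training %TWL becomes the reported w2; its sign is flipped if needed so
    that low coordinate values correspond to low weight loss.
    """
    twl = np.asarray(twl, dtype=float)
    if twl.shape[0] != emb.n:
        raise ValueError("outcome length does not match embedding rows")
    r2 = np.array([_safe_r2(emb.W[:, j], twl) for j in range(emb.d)])
    if np.all(emb.W.std(axis=0) == 0):
        raise ValueError("all embedding coordinates have zero variance")
    best = int(np.argmax(r2))
    col = emb.W[:, best]
    r = np.corrcoef(col, twl)[0, 1] if col.std() > 0 else 0.0
    orientation = -1 if r < 0 else 1
    return Embedding(
        W=emb.W,
        eigenvalues=emb.eigenvalues,
        selected_coord=best,
        orientation=orientation,
    )


def fit_lle(
    Z,
    k: int = DEFAULT_K,
    d: int = DEFAULT_DIM,
    reg: float = DEFAULT_REG,
    twl: np.ndarray | None = None,
) -> tuple[Embedding, NeighborGraph, np.ndarray]:
    """Run the full LLE stack; optionally orient to an outcome vector.

    Returns (embedding, neighbour graph, reconstruction weights).
    """
    graph = knn(Z, k)
    w = reconstruction_weights(Z, graph, reg)
    emb = embed(w, graph, d)
    if twl is not None:
        emb = orient_to_outcome(emb, twl)
    return emb, graph, w
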