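"""Exponential per-variable weighting of the normalized feature matrix.

Each z-scored variable y_v is scaled by a power of ten,

    z[i, v] = 10**alpha_v * y[i, v],       alpha_v in [-4, +4],

so variable weights span 0.0001 to 10,000. The alpha exponents are the
tunable relevance parameters of the model: one variable (by convention the
gender indicator) is pinned at alpha = 0 as the reference, leaving V - 1
free exponents for the evolutionary optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import NormalizedMatrix, NormStats

__all__ = ["AlphaVector", "WeightedMatrix", "alpha_to_weight", "apply_weights", "ALPHA_BOUNDS"]

#: Allowed exponent range.
ALPHA_BOUNDS = (-4.0, 4.0)


@dataclass
class AlphaVector:
    """The per-variable weighting exponents (the EA genome).

    The entry at ``reference_index`` is always exactly 0 (weight 1); all
    entries lie inside ``bounds``.
    """

    alpha: np.ndarray
    reference_index: int = 0
    bounds: tuple[float, float] = ALPHA_BOUNDS

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        v = self.alpha.shape[0]
        if not 0 <= self.reference_index < v:
            raise ValueError(f"reference index {self.reference_index} out of range for V={v}")
        if self.alpha[self.reference_index] != 0.0:
            raise ValueError("reference exponent must be exactly 0")
        lo, hi = self.bounds
        if np.any(self.alpha < lo) or np.any(self.alpha > hi):
            raise ValueError(f"exponents must lie in [{lo}, {hi}]")

    @classmethod
    def zeros(cls, n_variables: int, reference_index: int = 0) -> "AlphaVector":
        """All-zero exponents: every variable weighted by 1 (the unweighted model)."""
        return cls(alpha=np.zeros(n_variables), reference_index=reference_index)

    @property
    def n_variables(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_free(self) -> int:
        """Number of exponents the optimizer may move (all but the reference)."""
        return self.n_variables - 1

    def weights(self) -> np.ndarray:
        return 10.0 ** self.alpha

    def to_json(self, path: str | Path, names: list[str] | None = None) -> None:
        if names is None:
            names = [f"v{i + 1}" for i in range(self.n_variables)]
        payload = {
            "reference": names[self.reference_index],
            "bounds": list(self.bounds),
            "alpha": {name: float(a) for name, a in zip(names, self.alpha)},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlphaVector":
        payload = json.loads(Path(path).read_text())
        names = list(payload["alpha"])
        alpha = np.array([payload["alpha"][n] for n in names], dtype=float)
        ref = names.index(payload["reference"])
        return cls(alpha=alpha, reference_index=ref, bounds=tuple(payload["bounds"]))


def alpha_to_weight(alpha, bounds: tuple[float, float] = ALPHA_BOUNDS):
    """Map an exponent (scalar or array) to its multiplicative weight 10**alpha."""
    arr = np.asarray(alpha, dtype=float)
    lo, hi = bounds
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"exponent outside [{lo}, {hi}]")
    out = 10.0 ** arr
    return float(out) if out.ndim == 0 else out


@dataclass
class WeightedMatrix:
    """Normalized-and-weighted data: Z = Y * 10**alpha, columnwise."""

    Z: np.ndarray
    alphas: AlphaVector
    stats: NormStats | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[1] != self.alphas.n_variables:
            raise ValueError("matrix width does not match exponent vector length")


def apply_weights(Y: NormalizedMatrix | np.ndarray, alphas: AlphaVector) -> WeightedMatrix:
    """Scale each normalized column by 10**alpha_v; the input is not modified."""
    if isinstance(Y, NormalizedMatrix):
        mat, stats = Y.Y, Y.stats
    else:
        mat, stats = np.asarray(Y, dtype=float), None
    if mat.shape[1] != alphas.n_variables:
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but alphas cover {alphas.n_variables}"
        )
    return WeightedMatrix(Z=mat * alphas.weights(), alphas=alphas, stats=stats)
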