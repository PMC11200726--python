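"""Cohort loading, outcome computation, normalization and splitting.

The unit of analysis is a cohort of bariatric-surgery patients described by
a patient-by-variable table of preoperative measurements together with two
weights: the basal weight measured just before the pre-surgical
very-low-calorie diet (VLCD) and the weight one year after surgery. The
outcome is the percent total weight loss,

    %TWL = 100 * (basal - one_year) / basal,

and a procedure is labelled a *success* when %TWL >= 30 (boundary
inclusive).

Variables are z-scored before any downstream modelling:

    y[i, v] = (x[i, v] - mean_v) / sd_v,

with the population SD convention (denominator n). The statistics can be
fitted on the training rows only (default, sound out-of-sample practice) or
on the whole sample (the behaviour of the original analysis); the
provenance is recorded on the :class:`NormStats` object.

Missing values are a hard error throughout: the upstream study handled
missingness by dropping variables before analysis, so this pipeline never
imputes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "Cohort",
    "NormStats",
    "NormalizedMatrix",
    "SplitResult",
    "MissingDataError",
    "compute_twl",
    "label_success",
    "fit_norm_stats",
    "normalize",
    "split_cohort",
    "load_cohort",
    "load_schema",
    "write_schema",
    "SUCCESS_CUTOFF",
    "ID_COLUMN",
    "BASAL_COLUMN",
    "WEIGHT_1Y_COLUMN",
]

#: %TWL at or above which the intervention counts as successful.
SUCCESS_CUTOFF = 30.0

ID_COLUMN = "patient_id"
BASAL_COLUMN = "basal_weight_kg"
WEIGHT_1Y_COLUMN = "weight_1y_kg"

_VALID_KINDS = ("continuous", "binary", "ordered-categorical")


class MissingDataError(ValueError):
    """A retained variable has a missing value for some patient."""


@dataclass(frozen=True)
class VariableSpec:
    """One preoperative input variable.

    Parameters
    ----------
    name
        Human-readable label, unique within a cohort.
    index
        1-based position in the variable panel.
    kind
        ``continuous``, ``binary`` (0/1 coded) or ``ordered-categorical``
        (consecutive integers from 0, in the order given by the schema).
    units
        Free-text units, for documentation only.
    """

    name: str
    index: int
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(
                f"variable {self.name!r}: kind must be one of {_VALID_KINDS}, "
                f"got {self.kind!r}"
            )
        if self.index < 1:
            raise ValueError(f"variable {self.name!r}: index must be >= 1")


def compute_twl(basal_weight, weight_1y):
    """Percent total weight loss from basal (pre-VLCD) and one-year weights.

    Accepts scalars or arrays; returns 100*(basal - one_year)/basal.
    Negative values (weight gain) are allowed; non-positive weights are not.
    """
    basal = np.asarray(basal_weight, dtype=float)
    one_year = np.asarray(weight_1y, dtype=float)
    if np.any(basal <= 0) or np.any(one_year <= 0):
        raise ValueError("weights must be strictly positive")
    twl = 100.0 * (basal - one_year) / basal
    return float(twl) if twl.ndim == 0 else twl


def label_success(twl, cutoff: float = SUCCESS_CUTOFF):
    """Success/failure labels from %TWL; the cutoff itself counts as success.

    Returns a boolean (array): True = success (%TWL >= cutoff).
    """
    arr = np.asarray(twl, dtype=float)
    out = arr >= cutoff
    return bool(out) if out.ndim == 0 else out


@dataclass
class Cohort:
    """A fully observed patient-by-variable table with the derived outcome.

    ``twl`` and ``label`` are always derived from the two weight columns at
    construction time, so they cannot drift out of sync with the data.
    """

    patients: list[str]
    X: np.ndarray
    specs: list[VariableSpec]
    basal_weight: np.ndarray
    weight_1y: np.ndarray
    twl: np.ndarray = field(init=False)
    label: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.basal_weight = np.asarray(self.basal_weight, dtype=float)
        self.weight_1y = np.asarray(self.weight_1y, dtype=float)
        n, v = self.X.shape
        if len(self.patients) != n:
            raise ValueError(f"{len(self.patients)} ids for {n} rows")
        if len(self.specs) != v:
            raise ValueError(f"{len(self.specs)} specs for {v} columns")
        indices = [s.index for s in self.specs]
        if len(set(indices)) != len(indices):
            raise ValueError("variable indices must be unique")
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise MissingDataError(
                f"missing value for patient {self.patients[i]!r}, "
                f"variable {self.specs[j].name!r}"
            )
        for j, spec in enumerate(self.specs):
            if spec.kind == "binary":
                col = self.X[:, j]
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(
                        f"binary variable {spec.name!r} has values outside {{0, 1}}"
                    )
        self.twl = compute_twl(self.basal_weight, self.weight_1y)
        self.label = label_success(self.twl)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def variable_names(self) -> list[str]:
        return [s.name for s in self.specs]


@dataclass
class NormStats:
    """Per-variable mean and population SD with provenance."""

    mean: np.ndarray
    sd: np.ndarray
    source: str = "training-only"  # or "whole-sample"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")
        if np.any(self.sd <= 0):
            raise ValueError("all SDs must be strictly positive")
        if self.source not in ("training-only", "whole-sample"):
            raise ValueError(f"unknown provenance {self.source!r}")

    def to_json(self, path: str | Path, names: list[str] | None = None) -> None:
        payload = {
            "source": self.source,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        if names is not None:
            payload["names"] = list(names)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        payload = json.loads(Path(path).read_text())
        return cls(mean=payload["mean"], sd=payload["sd"], source=payload["source"])


@dataclass
class NormalizedMatrix:
    """Z-scored data together with the statistics that produced it."""

    Y: np.ndarray
    stats: NormStats

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape[1] != self.mean.shape[0]:
            raise ValueError("matrix width does not match stats length")

    @property
    def mean(self) -> np.ndarray:
        return self.stats.mean


def fit_norm_stats(
    X: np.ndarray,
    rows: np.ndarray | None = None,
    source: str = "training-only",
    names: list[str] | None = None,
) -> NormStats:
    """Per-column mean and population SD over the selected rows.

    Raises on zero-variance columns, naming the offending variable: the
    pipeline presumes every retained variable varies in the sample.
    """
    X = np.asarray(X, dtype=float)
    sub = X if rows is None else X[np.asarray(rows)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit normalization statistics")
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    if np.any(sd == 0):
        j = int(np.argwhere(sd == 0)[0][0])
        label = names[j] if names is not None else f"column {j}"
        raise ValueError(f"zero-variance variable: {label}")
    return NormStats(mean=mean, sd=sd, source=source)


def normalize(X: np.ndarray, stats: NormStats) -> NormalizedMatrix:
    """Apply ``(x - mean)/sd`` columnwise with the given statistics."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != stats.mean.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns but stats cover {stats.mean.shape[0]}"
        )
    return NormalizedMatrix(Y=(X - stats.mean) / stats.sd, stats=stats)


@dataclass
class SplitResult:
    """A reproducible train/validation partition."""

    train_idx: np.ndarray
    valid_idx: np.ndarray
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.valid_idx = np.asarray(self.valid_idx, dtype=int)
        overlap = np.intersect1d(self.train_idx, self.valid_idx)
        if overlap.size:
            raise ValueError("train and validation indices overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_cohort(
    cohort: Cohort | int,
    fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = False,
) -> SplitResult:
    """Uniform random train/validation partition, round-half-up sizing.

    With the study dimensions (n=118, fraction=0.7) the training set has
    exactly 83 patients. ``stratify=True`` balances the success/failure mix
    across the two groups (off by default; the original analysis used a
    plain random split).
    """
    if isinstance(cohort, Cohort):
        n = cohort.n
        labels = cohort.label
    else:
        n = int(cohort)
        labels = None
        if stratify:
            raise ValueError("stratified split requires a Cohort, not a size")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    n_train = _round_half_up(fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError("split produces an empty partition")
    rng = np.random.default_rng(seed)
    if stratify:
        train_parts = []
        for cls in (True, False):
            cls_idx = np.flatnonzero(labels == cls)
            k = _round_half_up(fraction * cls_idx.size)
            train_parts.append(rng.permutation(cls_idx)[:k])
        train = np.sort(np.concatenate(train_parts))
    else:
        train = np.sort(rng.permutation(n)[:n_train])
    valid = np.setdiff1d(np.arange(n), train)
    if valid.size == 0:
        raise ValueError("split produces an empty validation set")
    return SplitResult(train_idx=train, valid_idx=valid, seed=seed, fraction=fraction)


def load_schema(path: str | Path) -> list[VariableSpec]:
    """Read a variable schema from YAML (list of name/index/kind/units)."""
    entries = yaml.safe_load(Path(path).read_text())
    return [
        VariableSpec(
            name=e["name"],
            index=int(e["index"]),
            kind=e["kind"],
            units=e.get("units", ""),
        )
        for e in entries
    ]


def write_schema(specs: list[VariableSpec], path: str | Path) -> None:
    entries = [
        {"name": s.name, "index": s.index, "kind": s.kind, "units": s.units}
        for s in specs
    ]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False, allow_unicode=True))


def load_cohort(path: str | Path, schema: list[VariableSpec]) -> Cohort:
    """Read a cohort table (CSV, or TSV by ``.tsv`` extension).

    The file must carry a header row with one column per schema variable
    plus ``patient_id``, ``basal_weight_kg`` and ``weight_1y_kg``. Any
    missing value in a retained column is a :class:`MissingDataError`
    naming the patient and variable — the pipeline never imputes.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round_trip parsing: re-reading a file we wrote reproduces the exact
    # float64 values (the default fast parser is not correctly rounded)
    df = pd.read_csv(path, sep=sep, dtype={ID_COLUMN: str}, float_precision="round_trip")

    required = [ID_COLUMN, BASAL_COLUMN, WEIGHT_1Y_COLUMN] + [s.name for s in schema]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path.name}: {missing_cols}")

    patients = df[ID_COLUMN].tolist()
    data_cols = [s.name for s in schema] + [BASAL_COLUMN, WEIGHT_1Y_COLUMN]
    for col in data_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row} (patient {patients[row]!r})"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise MissingDataError(
                f"missing value in column {col!r} for patient {patients[row]!r}"
            )
        df[col] = numeric

    X = df[[s.name for s in schema]].to_numpy(dtype=float)
    return Cohort(
        patients=patients,
        X=X,
        specs=list(schema),
        basal_weight=df[BASAL_COLUMN].to_numpy(dtype=float),
        weight_1y=df[WEIGHT_1Y_COLUMN].to_numpy(dtype=float),
    )
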