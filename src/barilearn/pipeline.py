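"""End-to-end orchestration: load/simulate -> split -> fit -> project -> evaluate.

`fit_model` / `evaluate_model` are the in-memory workhorses; `run_fit` /
`run_evaluate` wrap them with a serialized run directory (manifest with
config hash and seeds, normalization statistics, evolved exponents,
training embedding, fitness traces, ROC and projection tables) so that
every figure-equivalent output can be regenerated from artifacts without
re-running the optimizer. A pipeline run is a pure function of its inputs,
configuration and seeds: re-running a config writes byte-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, lle
from .cohort import (
    Cohort,
    NormStats,
    SplitResult,
    fit_norm_stats,
    load_cohort,
    load_schema,
    normalize,
    split_cohort,
)
from .evaluation import (
    HIGH_ALPHA_CUT,
    LOW_ALPHA_CUT,
    RelevanceTable,
    RocResult,
    rank_variables,
    sweep_thresholds,
)
from .evolve import EAConfig, RunResult, best_alpha_vector, evolve, select_best_run
from .projection import DEFAULT_M, project_cohort
from .synthetic import GeneratorConfig, generate
from .weighting import AlphaVector, apply_weights

__all__ = [
    "PipelineConfig",
    "FitBundle",
    "EvalReport",
    "fit_model",
    "evaluate_model",
    "run_fit",
    "run_evaluate",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of a full pipeline run, with explicit seeds throughout."""

    data_path: str | None = None
    schema_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_fraction: float = 0.7
    split_seed: int = 1
    ea: EAConfig = field(default_factory=EAConfig.desk_scale)
    k: int = lle.DEFAULT_K
    d: int = lle.DEFAULT_DIM
    m: int = DEFAULT_M
    reg: float = lle.DEFAULT_REG
    normalization: str = "training-only"  # or "whole-sample" (study-faithful)
    weighted_distances: bool = True
    high_cut: float = HIGH_ALPHA_CUT
    low_cut: float = LOW_ALPHA_CUT

    def __post_init__(self) -> None:
        if self.normalization not in ("training-only", "whole-sample"):
            raise ValueError("normalization must be 'training-only' or 'whole-sample'")

    def to_yaml(self) -> str:
        payload = asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "generator" in payload and payload["generator"] is not None:
            gen = dict(payload["generator"])
            for key in ("informative", "effect_sizes"):
                if gen.get(key) is not None:
                    gen[key] = tuple(gen[key])
            gen["correlation_blocks"] = tuple(
                tuple(b) for b in gen.get("correlation_blocks", ())
            )
            payload["generator"] = GeneratorConfig(**gen)
        if "ea" in payload and payload["ea"] is not None:
            ea = dict(payload["ea"])
            if "bounds" in ea:
                ea["bounds"] = tuple(ea["bounds"])
            payload["ea"] = EAConfig(**ea)
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _reference_index(cohort: Cohort) -> int:
    """The weighting reference: the first binary (sex/gender-style) variable."""
    for j, spec in enumerate(cohort.specs):
        if spec.kind == "binary":
            return j
    return 0


@dataclass
class FitBundle:
    """Everything produced by the training stage."""

    cohort: Cohort
    split: SplitResult
    stats: NormStats
    alphas: AlphaVector
    runs: list[RunResult]
    embedding: lle.Embedding
    Z_train: np.ndarray
    reference_index: int
    config: PipelineConfig

    @property
    def train_r_squared(self) -> float:
        return select_best_run(self.runs).best.r_squared

    def relevance(self) -> RelevanceTable:
        return rank_variables(
            self.runs,
            names=self.cohort.variable_names(),
            high_cut=self.config.high_cut,
            low_cut=self.config.low_cut,
        )


def _obtain_cohort(config: PipelineConfig) -> Cohort:
    if config.data_path is not None:
        if config.schema_path is None:
            raise ValueError("schema_path is required when data_path is given")
        return load_cohort(config.data_path, load_schema(config.schema_path))
    cohort, _ = generate(config.generator)
    return cohort


def fit_model(cohort: Cohort, config: PipelineConfig) -> FitBundle:
    """Split, normalize, evolve the exponents, and embed the training set."""
    split = split_cohort(cohort, fraction=config.split_fraction, seed=config.split_seed)
    rows = None if config.normalization == "whole-sample" else split.train_idx
    source = "whole-sample" if rows is None else "training-only"
    stats = fit_norm_stats(cohort.X, rows=rows, source=source, names=cohort.variable_names())
    Y = normalize(cohort.X, stats)
    Y_train = Y.Y[split.train_idx]
    twl_train = cohort.twl[split.train_idx]

    ref = _reference_index(cohort)
    runs = evolve(
        Y_train, twl_train, config.ea, reference_index=ref,
        k=config.k, d=config.d, reg=config.reg,
    )
    alphas = best_alpha_vector(select_best_run(runs), reference_index=ref)
    Z_train = apply_weights(Y_train, alphas).Z
    emb, _, _ = lle.fit_lle(Z_train, k=config.k, d=config.d, reg=config.reg, twl=twl_train)
    return FitBundle(
        cohort=cohort,
        split=split,
        stats=stats,
        alphas=alphas,
        runs=runs,
        embedding=emb,
        Z_train=Z_train,
        reference_index=ref,
        config=config,
    )


@dataclass
class EvalReport:
    """Validation-set performance of a fitted bundle."""

    roc: RocResult
    w2_valid: np.ndarray
    twl_valid: np.ndarray
    labels_valid: np.ndarray
    r_w2_twl: float
    projections: pd.DataFrame

    @property
    def auc(self) -> float:
        return self.roc.auc

    def summary(self) -> str:
        c = self.roc.confusion
        lines = [
            f"validation n        : {len(self.twl_valid)}",
            f"AUC                 : {self.roc.auc:.3f}",
            f"best threshold w2u  : {self.roc.best_threshold:.4f}",
            f"sensitivity         : {self.roc.sensitivity:.3f}",
            f"false-positive rate : {self.roc.false_positive_rate:.3f}",
            f"confusion (failure+): TP={c['TP']} FP={c['FP']} TN={c['TN']} FN={c['FN']}",
            f"r(w2, %TWL)         : {self.r_w2_twl:.3f}",
        ]
        return "\n".join(lines)


def evaluate_model(bundle: FitBundle, valid_idx: np.ndarray | None = None) -> EvalReport:
    """Project held-out patients and sweep the w2 threshold.

    By default evaluates the bundle's own validation split; pass explicit
    indices (e.g. the training indices) for resubstitution diagnostics.
    """
    cohort = bundle.cohort
    config = bundle.config
    idx = bundle.split.valid_idx if valid_idx is None else np.asarray(valid_idx, dtype=int)
    Y = normalize(cohort.X, bundle.stats)
    if config.weighted_distances:
        space_valid = apply_weights(Y.Y[idx], bundle.alphas).Z
        space_train = bundle.Z_train
    else:
        space_valid = Y.Y[idx]
        space_train = Y.Y[bundle.split.train_idx]
    ids = [cohort.patients[i] for i in idx]
    coords, records = project_cohort(
        space_valid, space_train, bundle.embedding,
        m=config.m, reg=config.reg, patient_ids=ids,
    )
    emb = bundle.embedding
    w2 = emb.orientation * coords[:, emb.selected_coord]
    twl_valid = cohort.twl[idx]
    labels_valid = cohort.label[idx]
    if len(np.unique(labels_valid)) < 2:
        raise ValueError("validation set contains a single outcome class")
    roc = sweep_thresholds(w2, labels_valid)
    r = float(np.corrcoef(w2, twl_valid)[0, 1]) if w2.std() > 0 else 0.0
    proj_rows = pd.DataFrame(
        {
            "patient_id": ids,
            **{f"w{j + 1}": coords[:, j] for j in range(coords.shape[1])},
            "w2_oriented": w2,
            "twl": twl_valid,
            "label": np.where(labels_valid, "success", "failure"),
            "neighbors": [";".join(map(str, r_.neighbor_ids)) for r_ in records],
            "beta": [";".join(f"{b:.6g}" for b in r_.beta) for r_ in records],
        }
    )
    return EvalReport(
        roc=roc,
        w2_valid=w2,
        twl_valid=twl_valid,
        labels_valid=labels_valid,
        r_w2_twl=r,
        projections=proj_rows,
    )


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_fit(config: PipelineConfig, outdir: str | Path) -> FitBundle:
    """Fit the full model and serialize a run directory.

    Artifacts: ``manifest.json`` (version, seeds, config hash),
    ``config.yaml``, ``normstats.json``, ``alphas.json``,
    ``embedding.tsv`` (patient id, w1..wd, %TWL, label),
    ``fitness_traces.json`` and ``relevance.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _obtain_cohort(config)
    bundle = fit_model(cohort, config)

    (outdir / "config.yaml").write_text(config.to_yaml())
    _write_json(
        outdir / "manifest.json",
        {
            "barilearn_version": __version__,
            "config_hash": config.config_hash(),
            "split_seed": config.split_seed,
            "ea_seed": config.ea.seed,
            "generator_seed": config.generator.seed if config.data_path is None else None,
            "n_patients": cohort.n,
            "n_variables": cohort.n_variables,
            "n_train": int(bundle.split.train_idx.size),
            "reference_variable": cohort.specs[bundle.reference_index].name,
            "best_r_squared": bundle.train_r_squared,
        },
    )
    bundle.stats.to_json(outdir / "normstats.json", names=cohort.variable_names())
    bundle.alphas.to_json(outdir / "alphas.json", names=cohort.variable_names())
    _write_json(
        outdir / "split.json",
        {
            "seed": bundle.split.seed,
            "fraction": bundle.split.fraction,
            "train_idx": bundle.split.train_idx.tolist(),
            "valid_idx": bundle.split.valid_idx.tolist(),
        },
    )
    emb = bundle.embedding
    emb_df = pd.DataFrame(
        {
            "patient_id": [cohort.patients[i] for i in bundle.split.train_idx],
            **{f"w{j + 1}": emb.W[:, j] for j in range(emb.d)},
            "twl": cohort.twl[bundle.split.train_idx],
            "label": np.where(cohort.label[bundle.split.train_idx], "success", "failure"),
        }
    )
    emb_df.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    _write_json(
        outdir / "fitness_traces.json",
        {
            "runs": [
                {
                    "run_index": r.run_index,
                    "seed": r.seed,
                    "best_r_squared": r.best.r_squared,
                    "best_generation": r.best.generation,
                    "selected_coord": r.best.selected_coord,
                    "history": r.history,
                }
                for r in bundle.runs
            ],
            "selected_run": select_best_run(bundle.runs).run_index,
            "embedding_diagnostics": {
                "eigenvalues": emb.eigenvalues.tolist(),
                "selected_coord": emb.selected_coord,
                "orientation": emb.orientation,
            },
        },
    )
    bundle.relevance().to_tsv(outdir / "relevance.tsv")
    return bundle


def run_evaluate(bundle: FitBundle, outdir: str | Path) -> EvalReport:
    """Evaluate a fitted bundle on its validation split and write reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = evaluate_model(bundle)
    roc = report.roc
    roc.to_frame().to_csv(outdir / "roc.tsv", sep="\t", index=False)
    report.projections.to_csv(outdir / "projections.tsv", sep="\t", index=False)
    _write_json(
        outdir / "metrics.json",
        {
            "auc": roc.auc,
            "w2u": roc.best_threshold,
            "sensitivity": roc.sensitivity,
            "false_positive_rate": roc.false_positive_rate,
            "confusion": roc.confusion,
            "r_w2_twl": report.r_w2_twl,
            "train_r_squared": bundle.train_r_squared,
        },
    )
    (outdir / "report.txt").write_text(report.summary() + "\n")
    return report
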