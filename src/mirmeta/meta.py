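"""Routing meta-predictor: eleven availability-specific modules.

A miRNA:mRNA pair scored by k >= 2 of the four base predictors is routed
to the module trained for exactly that predictor combination (one
four-predictor, four three-predictor and six two-predictor modules).
Each module couples the tuned voting tree with a small neural network;
three variants are supported:

* ``C1``   — voting tree alone;
* ``C2``   — neural network on the raw scaled scores;
* ``DANN`` — neural network on the tree-encoded features (default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ann as ann_mod
from .ann import AnnConfig, AnnModel, init_model
from .data import (
    SUBSETS,
    SubsetKey,
    assign_subset,
    assign_subsets,
    deduplicate,
    make_cv_folds,
    scale_records,
)
from .metrics import confusion, metrics as compute_metrics
from .predictors import PREDICTOR_ORDER
from .tree import ThresholdSet, VotingTreeClassifier, encode_features, tree_classify

__all__ = [
    "DannModule",
    "DannMetaPredictor",
    "route",
    "train_module",
    "evaluate_module",
    "cross_subset_evaluate",
    "merge_and_retrain",
    "predict_pair",
]

VARIANTS = ("C1", "C2", "DANN")


@dataclass
class DannModule:
    """One trained availability-pattern module."""

    key: SubsetKey
    variant: str
    thresholds: ThresholdSet | None = None
    ann: AnnModel | None = None
    fold_anns: list[AnnModel] = field(default_factory=list)
    cv_metrics: dict = field(default_factory=dict)
    aggregate: str = "euclidean"
    tie_break: str = "false"

    @property
    def name(self) -> str:
        return f"DANN-{self.key.name[1:]}"

    def features(self, X: np.ndarray) -> np.ndarray:
        if self.variant == "C2":
            return X
        return encode_features(X, self.thresholds, aggregate=self.aggregate)

    def predict_scores(self, X) -> np.ndarray:
        """p_true per sample (tree votes map to exactly 0/1 for C1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.variant == "C1":
            labels, _ = tree_classify(
                X, self.thresholds, aggregate=self.aggregate, tie_break=self.tie_break
            )
            return labels.astype(float)
        return ann_mod.forward(self.ann, self.features(X))[:, 0]

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) > 0.5).astype(int)


def _scaled_matrix(df: pd.DataFrame, predictors) -> np.ndarray:
    cols = [f"scaled_{p}" for p in predictors]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing scaled score columns {missing}")
    return df[cols].to_numpy(float)


def _labels(df: pd.DataFrame) -> np.ndarray:
    return (df["label"] == "positive").to_numpy().astype(int)


def route(modules: dict[str, "DannModule"], mask) -> "DannModule":
    """Select the module whose predictor combination equals the mask."""
    key = assign_subset(mask)
    if key is None:
        raise ValueError(f"unroutable record: fewer than two scores in mask {set(mask)!r}")
    if key.name not in modules:
        raise KeyError(f"no trained module for subset {key.name}")
    return modules[key.name]


def train_module(
    dataset: pd.DataFrame,
    key: SubsetKey | str,
    variant: str = "DANN",
    seed: int = 0,
    ann_params: dict | None = None,
    tune: bool = True,
    cv_size_threshold: int = 1000,
    aggregate: str = "euclidean",
    tie_break: str = "false",
) -> DannModule:
    """Train one module on its (labeled, scaled) subset dataset.

    Thresholds are tuned once on the whole training set; the network is
    then trained per CV fold (metrics kept as mean +/- sd across folds)
    and finally on all samples for the deployed model.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    key = SUBSETS[key] if isinstance(key, str) else key
    y = _labels(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{key.name}: single-class dataset")
    X = _scaled_matrix(dataset, key.predictors)

    module = DannModule(key=key, variant=variant, aggregate=aggregate, tie_break=tie_break)
    if variant in ("C1", "DANN"):
        vt = VotingTreeClassifier(
            predictors=key.predictors, tune=tune, aggregate=aggregate, tie_break=tie_break
        ).fit(X, y)
        module.thresholds = vt.thresholds_

    folds = make_cv_folds(dataset, seed=seed, size_threshold=cv_size_threshold)
    fold_scores: list[dict] = []
    if variant == "C1":
        for _, va in folds:
            fold_scores.append(_score(y[va], module.predict(X[va])))
    else:
        F = module.features(X)
        params = dict(ann_params or {})
        for i, (tr, va) in enumerate(folds):
            cfg = AnnConfig(input_dim=F.shape[1], seed=seed + i, **params)
            fitted = ann_mod.train(init_model(cfg), F[tr], y[tr], validation=(F[va], y[va]))
            module.fold_anns.append(fitted)
            pred = (ann_mod.forward(fitted, F[va])[:, 0] > 0.5).astype(int)
            fold_scores.append(_score(y[va], pred))
        cfg = AnnConfig(input_dim=F.shape[1], seed=seed, **params)
        tr_idx, va_idx = folds[0]
        module.ann = ann_mod.train(init_model(cfg), F[tr_idx], y[tr_idx], validation=(F[va_idx], y[va_idx]))
    module.cv_metrics = _aggregate_folds(fold_scores)
    return module


def _score(y_true, y_pred) -> dict:
    return compute_metrics(confusion(y_true, y_pred))


def _aggregate_folds(fold_scores: list[dict]) -> dict:
    out = {}
    for name in fold_scores[0]:
        vals = np.array([f[name] for f in fold_scores])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


def evaluate_module(module: DannModule, dataset: pd.DataFrame, per_fold: bool = False) -> dict:
    """Metrics of a module on a labeled scaled dataset.

    With ``per_fold=True`` (network variants) every fold model is
    evaluated and metrics come back as mean +/- sd across folds.
    """
    X = _scaled_matrix(dataset, module.key.predictors)
    y = _labels(dataset)
    if per_fold and module.fold_anns:
        scores = []
        for m in module.fold_anns:
            pred = (ann_mod.forward(m, module.features(X))[:, 0] > 0.5).astype(int)
            scores.append(_score(y, pred))
        return _aggregate_folds(scores)
    return _score(y, module.predict(X))


def cross_subset_evaluate(module: DannModule, dataset: pd.DataFrame) -> dict:
    """Evaluate a module on a foreign subset with more predictors.

    The foreign records are projected onto the module's predictor
    columns; the foreign predictor set must be a superset of the
    module's.
    """
    foreign_preds = _dataset_predictors(dataset)
    if not set(module.key.predictors) <= foreign_preds:
        raise ValueError(
            f"dataset predictors {sorted(foreign_preds)} do not cover "
            f"module {module.key.name} ({module.key.predictors})"
        )
    return evaluate_module(module, dataset)


def _dataset_predictors(df: pd.DataFrame) -> set:
    present = df[list(PREDICTOR_ORDER)].notna()
    full = present.all(axis=0)
    return {p for p in PREDICTOR_ORDER if full[p]}


def project_records(df: pd.DataFrame, predictors) -> pd.DataFrame:
    """Restrict records to a predictor combination (mask the rest)."""
    out = df.copy()
    for p in PREDICTOR_ORDER:
        if p not in predictors:
            out[p] = np.nan
            if f"scaled_{p}" in out.columns:
                out[f"scaled_{p}"] = np.nan
    if "subset" in out.columns:
        key = assign_subset(predictors)
        out["subset"] = key.name if key else None
    return out


def merge_and_retrain(
    target: SubsetKey | str,
    datasets: list[pd.DataFrame],
    variant: str = "DANN",
    seed: int = 0,
    dedup_tolerance: float = 0.04,
    **train_kwargs,
) -> tuple[DannModule, pd.DataFrame]:
    """Merge richer subsets into a target pattern and retrain its module.

    Every contributed dataset must carry scores for all of the target's
    predictors (merging in the opposite direction would create
    score-less cells and is rejected).  Records are projected onto the
    target combination, concatenated, re-deduplicated and used to train
    a fresh module.  Returns (module, merged dataset).
    """
    target = SUBSETS[target] if isinstance(target, str) else target
    projected = []
    for df in datasets:
        preds = _dataset_predictors(df)
        if not set(target.predictors) <= preds:
            raise ValueError(
                f"cannot merge a {sorted(preds)} subset into {target.name}: "
                "reversed-direction merge would leave unscored predictors"
            )
        projected.append(project_records(df, target.predictors))
    merged = pd.concat(projected, ignore_index=True)
    merged = deduplicate(merged, tolerance=dedup_tolerance, seed=seed)
    module = train_module(merged, target, variant=variant, seed=seed, **train_kwargs)
    return module, merged


def predict_pair(modules: dict[str, DannModule], record) -> tuple[str, float, str]:
    """Route one pair and return (label, p_true, module name).

    ``record`` may be a mapping of raw predictor scores, a ScoreRecord,
    or a DataFrame row; raw scores are scaled internally.
    """
    from .data import ScoreRecord

    if isinstance(record, ScoreRecord):
        raw = record.raw_scores
    elif isinstance(record, pd.Series):
        raw = {p: float(record[p]) for p in PREDICTOR_ORDER if p in record and pd.notna(record[p])}
    else:
        raw = {p: float(v) for p, v in dict(record).items() if p in PREDICTOR_ORDER and pd.notna(v)}
    from .predictors import scale_score

    scaled = {p: scale_score(p, v) for p, v in raw.items()}
    module = route(modules, scaled.keys())
    x = np.array([scaled[p] for p in module.key.predictors])
    score = float(module.predict_scores(x[None, :])[0])
    label = "positive" if score > 0.5 else "negative"
    return label, score, module.key.name


def save_modules(modules: dict[str, DannModule], path) -> None:
    """Serialize trained modules (thresholds + network) to one JSON file."""
    import json

    payload = {}
    for name, m in modules.items():
        payload[name] = {
            "variant": m.variant,
            "aggregate": m.aggregate,
            "tie_break": m.tie_break,
            "thresholds": m.thresholds.to_dict() if m.thresholds else None,
            "ann": json.loads(m.ann.to_json()) if m.ann else None,
            "cv_metrics": m.cv_metrics,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_modules(path) -> dict[str, DannModule]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    modules = {}
    for name, d in payload.items():
        modules[name] = DannModule(
            key=SUBSETS[name],
            variant=d["variant"],
            thresholds=ThresholdSet.from_dict(d["thresholds"]) if d["thresholds"] else None,
            ann=AnnModel.from_json(json.dumps(d["ann"])) if d["ann"] else None,
            cv_metrics=d.get("cv_metrics", {}),
            aggregate=d.get("aggregate", "euclidean"),
            tie_break=d.get("tie_break", "false"),
        )
    return modules


class DannMetaPredictor:
    """Routing meta-classifier over the eleven availability modules.

    Sklearn-style estimator: ``fit`` takes the canonical score
    DataFrame (raw predictor columns, NaN for unscored) and a binary
    label vector (or a ``label`` column); ``predict`` routes each row to
    its module.  Subsets with too few samples or one class are skipped
    with a warning and left unrouteable.

    Parameters
    ----------
    variant : {'DANN', 'C1', 'C2'}
    seed : int
        Drives threshold tie-breaks, CV folds and network init.
    min_subset_size : int
        Smallest per-subset sample count worth training (default 30).
    ann_params : dict, optional
        Overrides for :class:`mirmeta.ann.AnnConfig` fields.
    """

    def __init__(
        self,
        variant: str = "DANN",
        seed: int = 0,
        min_subset_size: int = 30,
        ann_params: dict | None = None,
        tune: bool = True,
        cv_size_threshold: int = 1000,
        aggregate: str = "euclidean",
        tie_break: str = "false",
    ):
        self.variant = variant
        self.seed = seed
        self.min_subset_size = min_subset_size
        self.ann_params = ann_params
        self.tune = tune
        self.cv_size_threshold = cv_size_threshold
        self.aggregate = aggregate
        self.tie_break = tie_break

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "variant", "seed", "min_subset_size", "ann_params",
                "tune", "cv_size_threshold", "aggregate", "tie_break",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        if not {f"scaled_{p}" for p in PREDICTOR_ORDER} <= set(df.columns):
            df = scale_records(df)
        if "subset" not in df.columns:
            df = assign_subsets(df)
        return df

    def fit(self, X: pd.DataFrame, y=None):
        df = self._prepare(X)
        if y is not None:
            df["label"] = np.where(np.asarray(y).astype(int) == 1, "positive", "negative")
        if "label" not in df.columns:
            raise ValueError("fit needs y or a 'label' column")
        self.modules_: dict[str, DannModule] = {}
        for name, sub in df.groupby("subset", sort=False):
            if name not in SUBSETS:
                continue
            if len(sub) < self.min_subset_size or sub["label"].nunique() < 2:
                warnings.warn(f"subset {name}: too few samples or one class; skipped")
                continue
            self.modules_[name] = train_module(
                sub,
                SUBSETS[name],
                variant=self.variant,
                seed=self.seed,
                ann_params=self.ann_params,
                tune=self.tune,
                cv_size_threshold=self.cv_size_threshold,
                aggregate=self.aggregate,
                tie_break=self.tie_break,
            )
        return self

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        df = self._prepare(X).reset_index(drop=True)
        out = np.full(len(df), np.nan)
        for name, sub in df.groupby("subset", sort=False):
            if name not in self.modules_:
                raise KeyError(f"no trained module for subset {name}")
            module = self.modules_[name]
            M = _scaled_matrix(sub, module.key.predictors)
            out[df.index.get_indexer(sub.index)] = module.predict_scores(M)
        if df["subset"].isna().any():
            raise ValueError("unroutable records (fewer than two scores)")
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) > 0.5).astype(int)
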