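"""Dual-threshold two-step significance-voting decision tree.

Each base predictor holds two pairs of cutoffs on the common scaled
axis: a stringent 1st-step pair and a relaxed 2nd-step pair.  A
predictor votes "true" when its score falls below the true cutoff,
"false" when above the false cutoff, and abstains in between.  A sample
is resolved by majority at step 1; on a tie, by majority under the
relaxed step-2 cutoffs; on a second tie, by significance voting — the
side whose scores lie further beyond their step-2 cutoffs (aggregate
distance) wins.

The tree's intermediate quantities (vote counts and aggregate
distances) double as the engineered features fed to the downstream
neural network, alongside the raw scaled scores: n + 6 features for an
n-predictor module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .predictors import PREDICTOR_ORDER

__all__ = [
    "ThresholdSet",
    "TreeDecision",
    "vote_counts",
    "signed_distances",
    "significance_distances",
    "tree_classify",
    "encode_features",
    "VotingTreeClassifier",
    "load_threshold_sets",
    "dump_threshold_sets",
    "d4_thresholds",
]

_FIELDS = ("t_true_1", "t_false_1", "t_true_2", "t_false_2")

STAGE_STEP1, STAGE_STEP2, STAGE_SIGNIFICANCE = "step1", "step2", "significance"


@dataclass(frozen=True)
class ThresholdSet:
    """Per-predictor dual thresholds for one module.

    For each predictor ``p`` the four cutoffs satisfy
    ``t_true_1(p) <= t_true_2(p) < t_false_2(p) <= t_false_1(p)``:
    step-1 cutoffs are stricter (true lower, false higher) than step-2,
    and true cutoffs sit below false cutoffs because positives score low
    on the scaled axis.
    """

    predictors: tuple[str, ...]
    t_true_1: tuple[float, ...]
    t_false_1: tuple[float, ...]
    t_true_2: tuple[float, ...]
    t_false_2: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.predictors)
        for f in _FIELDS:
            vals = getattr(self, f)
            if len(vals) != n:
                raise ValueError(f"{f} must have {n} values")
            object.__setattr__(self, f, tuple(float(v) for v in vals))
        object.__setattr__(self, "predictors", tuple(self.predictors))
        self.validate()

    def validate(self) -> None:
        for i, p in enumerate(self.predictors):
            tt1, tf1 = self.t_true_1[i], self.t_false_1[i]
            tt2, tf2 = self.t_true_2[i], self.t_false_2[i]
            if not (tt1 <= tt2 < tf2 <= tf1):
                raise ValueError(
                    f"{p}: thresholds violate ordering "
                    f"t_true_1 <= t_true_2 < t_false_2 <= t_false_1: "
                    f"({tt1}, {tt2}, {tf2}, {tf1})"
                )

    def level(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """(true cutoffs, false cutoffs) at the given step as arrays."""
        if level == 1:
            return np.asarray(self.t_true_1), np.asarray(self.t_false_1)
        if level == 2:
            return np.asarray(self.t_true_2), np.asarray(self.t_false_2)
        raise ValueError(f"level must be 1 or 2, got {level}")

    def replace(self, predictor: str, field: str, value: float) -> "ThresholdSet":
        i = self.predictors.index(predictor)
        kwargs = {f: list(getattr(self, f)) for f in _FIELDS}
        kwargs[field][i] = value
        return ThresholdSet(
            self.predictors, **{f: tuple(v) for f, v in kwargs.items()}
        )

    def to_dict(self) -> dict:
        return {
            p: {f: getattr(self, f)[i] for f in _FIELDS}
            for i, p in enumerate(self.predictors)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        preds = tuple(sorted(d, key=PREDICTOR_ORDER.index))
        return cls(
            preds,
            **{f: tuple(d[p][f] for p in preds) for f in _FIELDS},
        )


@dataclass(frozen=True)
class TreeDecision:
    """Outcome of the voting tree for one sample."""

    label: bool
    stage: str
    encoding: dict


def _prep(scores, thresholds: ThresholdSet):
    X = np.asarray(scores, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X)
    n = len(thresholds.predictors)
    if X.shape[1] != n:
        raise ValueError(f"expected {n} scores per sample, got {X.shape[1]}")
    if np.isnan(X).any():
        raise ValueError("missing score passed to the voting tree")
    return X, squeeze


def vote_counts(scores, thresholds: ThresholdSet, level: int):
    """Count true and false votes at the given step.

    Predictor p votes true iff ``score(p) < t_true`` and false iff
    ``score(p) > t_false``; scores in the abstention band vote neither.
    """
    X, squeeze = _prep(scores, thresholds)
    t_true, t_false = thresholds.level(level)
    n_t = (X < t_true).sum(axis=1)
    n_f = (X > t_false).sum(axis=1)
    if squeeze:
        return int(n_t[0]), int(n_f[0])
    return n_t, n_f


def signed_distances(scores, thresholds: ThresholdSet, level: int):
    """Per-predictor signed margins beyond the cutoffs (diagnostics).

    Returns (to_true, to_false): ``t_true - score`` (positive when the
    score clears the true cutoff) and ``score - t_false``.
    """
    X, squeeze = _prep(scores, thresholds)
    t_true, t_false = thresholds.level(level)
    to_true = t_true - X
    to_false = X - t_false
    if squeeze:
        return to_true[0], to_false[0]
    return to_true, to_false


def significance_distances(scores, thresholds: ThresholdSet, aggregate: str = "euclidean"):
    """Aggregate distances of scores beyond their step-2 cutoffs.

    Per predictor, the contribution is the positive part of the margin
    (abstaining predictors contribute zero); aggregation is the
    Euclidean norm by default, or a plain sum when ``aggregate='sum'``.
    """
    X, squeeze = _prep(scores, thresholds)
    t_true, t_false = thresholds.level(2)
    c_t = np.maximum(0.0, t_true - X)
    c_f = np.maximum(0.0, X - t_false)
    if aggregate == "euclidean":
        d_t = np.sqrt((c_t**2).sum(axis=1))
        d_f = np.sqrt((c_f**2).sum(axis=1))
    elif aggregate == "sum":
        d_t = c_t.sum(axis=1)
        d_f = c_f.sum(axis=1)
    else:
        raise ValueError(f"aggregate must be 'euclidean' or 'sum', got {aggregate!r}")
    if squeeze:
        return float(d_t[0]), float(d_f[0])
    return d_t, d_f


def _classify_arrays(X, thresholds, aggregate, tie_break):
    n_t1, n_f1 = vote_counts(X, thresholds, 1)
    n_t2, n_f2 = vote_counts(X, thresholds, 2)
    d_t2, d_f2 = significance_distances(X, thresholds, aggregate)
    labels = np.empty(len(X), dtype=bool)
    stages = np.empty(len(X), dtype=object)

    step1 = n_t1 != n_f1
    labels[step1] = n_t1[step1] > n_f1[step1]
    stages[step1] = STAGE_STEP1

    tied1 = ~step1
    step2 = tied1 & (n_t2 != n_f2)
    labels[step2] = n_t2[step2] > n_f2[step2]
    stages[step2] = STAGE_STEP2

    sig = tied1 & ~step2
    if tie_break == "false":
        labels[sig] = d_t2[sig] > d_f2[sig]
    elif tie_break == "true":
        labels[sig] = d_t2[sig] >= d_f2[sig]
    else:
        raise ValueError(f"tie_break must be 'true' or 'false', got {tie_break!r}")
    stages[sig] = STAGE_SIGNIFICANCE
    enc = dict(
        n_t1=n_t1, n_f1=n_f1, n_t2=n_t2, n_f2=n_f2, d_t2=d_t2, d_f2=d_f2
    )
    return labels, stages, enc


def tree_classify(
    scores,
    thresholds: ThresholdSet,
    aggregate: str = "euclidean",
    tie_break: str = "false",
):
    """Run the two-step significance-voting tree.

    1-D input returns a :class:`TreeDecision`; 2-D input returns
    (labels, stages) arrays.  The final tie ``d_T2 == d_F2`` (including
    the all-abstain case) resolves to the majority class, false, unless
    ``tie_break='true'``.
    """
    X, squeeze = _prep(scores, thresholds)
    labels, stages, enc = _classify_arrays(X, thresholds, aggregate, tie_break)
    if squeeze:
        return TreeDecision(
            bool(labels[0]),
            str(stages[0]),
            {k: (float(v[0]) if v.dtype.kind == "f" else int(v[0])) for k, v in enc.items()},
        )
    return labels, stages


def encode_features(
    scores, thresholds: ThresholdSet, aggregate: str = "euclidean"
) -> np.ndarray:
    """Feature vector(s) for the neural network: scores then tree stats.

    Layout: the n scaled scores in canonical predictor order, followed
    by N_T1, N_F1, N_T2, N_F2, d_T2, d_F2 — width n + 6 (10/9/8 for
    4/3/2-predictor modules).
    """
    X, squeeze = _prep(scores, thresholds)
    n_t1, n_f1 = vote_counts(X, thresholds, 1)
    n_t2, n_f2 = vote_counts(X, thresholds, 2)
    d_t2, d_f2 = significance_distances(X, thresholds, aggregate)
    F = np.column_stack([X, n_t1, n_f1, n_t2, n_f2, d_t2, d_f2])
    return F[0] if squeeze else F


# ---------------------------------------------------------------------------
# Estimator


class VotingTreeClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style classifier wrapping the voting tree.

    ``fit`` selects the per-predictor dual thresholds by information-gain
    spike candidates followed by four-phase coordinate tuning (see
    :mod:`mirmeta.infogain`); ``predict`` applies the tree.  Input X is
    an (m, n) array of scaled scores with no missing values, y a binary
    label vector (1 = positive interaction).

    Parameters
    ----------
    predictors : tuple of str, optional
        Predictor ids, canonical order; defaults to all four.
    initial_thresholds : ThresholdSet, optional
        Starting point; by default built from the top IG spikes.
    tune : bool
        Run coordinate tuning after candidate selection (default True).
    n_spikes : int
        Spike candidates kept per predictor (default 4).
    grid_resolution : int
        IG evaluation grid density (default 1000).
    aggregate : {'euclidean', 'sum'}
        Significance-distance aggregation.
    tie_break : {'false', 'true'}
        Label on a final exact distance tie.
    """

    def __init__(
        self,
        predictors: tuple[str, ...] | None = None,
        initial_thresholds: ThresholdSet | None = None,
        tune: bool = True,
        n_spikes: int = 4,
        grid_resolution: int = 1000,
        aggregate: str = "euclidean",
        tie_break: str = "false",
    ):
        self.predictors = predictors
        self.initial_thresholds = initial_thresholds
        self.tune = tune
        self.n_spikes = n_spikes
        self.grid_resolution = grid_resolution
        self.aggregate = aggregate
        self.tie_break = tie_break

    def fit(self, X, y):
        from . import infogain

        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        preds = tuple(self.predictors) if self.predictors else PREDICTOR_ORDER[: X.shape[1]]
        if X.shape[1] != len(preds):
            raise ValueError("X width does not match predictor list")

        candidates: dict[str, list[float]] = {}
        grid_steps: dict[str, float] = {}
        for i, p in enumerate(preds):
            curve = infogain.ig_curve(y, X[:, i], grid_resolution=self.grid_resolution)
            spikes = infogain.find_spikes(curve, k=self.n_spikes)
            candidates[p] = [s for s, _ in spikes]
            grid_steps[p] = float(curve.grid[1] - curve.grid[0]) if len(curve.grid) > 1 else 0.01

        initial = self.initial_thresholds or infogain.initial_thresholds(
            preds, candidates, X, y
        )
        evaluator = self._make_evaluator(X, y)
        if self.tune:
            self.thresholds_ = infogain.tune_thresholds(
                initial, candidates, evaluator, grid_steps=grid_steps
            )
        else:
            self.thresholds_ = initial
        self.candidates_ = candidates
        self.classes_ = np.array([0, 1])
        self.train_accuracy_ = evaluator(self.thresholds_)
        return self

    def _make_evaluator(self, X, y):
        def evaluator(ts: ThresholdSet) -> float:
            labels, _ = tree_classify(
                X, ts, aggregate=self.aggregate, tie_break=self.tie_break
            )
            return float((labels.astype(int) == y).mean())

        return evaluator

    def predict(self, X) -> np.ndarray:
        labels, _ = tree_classify(
            np.atleast_2d(np.asarray(X, dtype=float)),
            self.thresholds_,
            aggregate=self.aggregate,
            tie_break=self.tie_break,
        )
        return labels.astype(int)

    def decide(self, X):
        """Full decisions with resolving stage, for diagnostics."""
        return tree_classify(
            X, self.thresholds_, aggregate=self.aggregate, tie_break=self.tie_break
        )


# ---------------------------------------------------------------------------
# Serialization of threshold sets


def dump_threshold_sets(sets: dict[str, ThresholdSet], path) -> None:
    """Write module-name -> ThresholdSet mappings as JSON."""
    payload = {name: ts.to_dict() for name, ts in sets.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_threshold_sets(path) -> dict[str, ThresholdSet]:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: ThresholdSet.from_dict(d) for name, d in payload.items()}


def d4_thresholds() -> ThresholdSet:
    """The packaged four-predictor module thresholds."""
    from importlib.resources import files

    path = files("mirmeta.resources").joinpath("d4_thresholds.json")
    with path.open() as fh:
        payload = json.load(fh)
    return ThresholdSet.from_dict(payload["D4"])
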