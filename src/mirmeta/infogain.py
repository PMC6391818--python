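"""Information-gain threshold selection and four-phase coordinate tuning.

A candidate cutoff x splits a labeled score set into the group above x
and the group at or below x; its information gain is the parent entropy
minus the split-weighted child entropies (log base 2).  Spikes — local
maxima of IG as a function of x — mark scores that separate positives
from negatives well and serve as threshold candidates.

Tuning then walks the four threshold families in a fixed order
(step-1 true, step-2 true, step-1 false, step-2 false), one predictor
at a time, stepping each cutoff through its spike candidates; a move is
kept when the evaluator's accuracy does not decrease, and a cutoff is
frozen after two consecutive decreasing evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tree import ThresholdSet

__all__ = [
    "IGCurve",
    "TuningState",
    "information_gain",
    "ig_curve",
    "find_spikes",
    "initial_thresholds",
    "tune_thresholds",
]

#: Tuning phases in execution order: (phase name, ThresholdSet field).
PHASES = (
    ("step1_true", "t_true_1"),
    ("step2_true", "t_true_2"),
    ("step1_false", "t_false_1"),
    ("step2_false", "t_false_2"),
)

_SMALL_SET = 5000  # below this, observed-score midpoints join the grid


@dataclass(frozen=True)
class IGCurve:
    """IG evaluated on a grid of candidate cutoffs."""

    grid: np.ndarray
    ig: np.ndarray
    base_entropy: float


@dataclass
class TuningState:
    """Bookkeeping of the coordinate-tuning walk."""

    current: ThresholdSet
    phase: str = ""
    accuracy_history: dict = field(default_factory=dict)
    decreasing_streak: int = 0


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector (0 log 0 := 0)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(labels, scores, x: float) -> float:
    """IG of splitting at x into groups score > x and score <= x.

    ``labels`` is binary (1 = positive).  Empty groups contribute zero;
    entropies are in bits.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("information_gain requires at least one sample")
    parent = _entropy(np.bincount(y, minlength=2))
    hi = s > x
    n = y.size
    child = 0.0
    for grp in (hi, ~hi):
        cnt = grp.sum()
        if cnt:
            child += cnt / n * _entropy(np.bincount(y[grp], minlength=2))
    return parent - child


def ig_curve(labels, scores, grid_resolution: int = 1000) -> IGCurve:
    """Evaluate IG on an even grid over the observed score range.

    For small sets (< 5000 samples) every midpoint between consecutive
    distinct observed scores is added to the grid, so no attainable
    split is missed.  An all-one-class input yields a zero curve with a
    warning.
    """
    if grid_resolution < 10:
        raise ValueError("grid_resolution must be >= 10")
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    lo, hi = float(s.min()), float(s.max())
    grid = np.linspace(lo, hi, grid_resolution)
    if y.size < _SMALL_SET:
        uniq = np.unique(s)
        if len(uniq) > 1:
            grid = np.union1d(grid, (uniq[:-1] + uniq[1:]) / 2.0)
    parent = _entropy(np.bincount(y, minlength=2))
    if len(np.unique(y)) < 2:
        warnings.warn("all samples share one label; IG curve is identically zero")
        return IGCurve(grid, np.zeros_like(grid), parent)

    # cumulative class counts over sorted scores -> IG at every x in one pass
    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    n = y.size
    n_pos = int(cum_pos[-1])
    # samples with score <= x
    idx = np.searchsorted(s_sorted, grid, side="right")
    lo_pos = cum_pos[idx]
    lo_tot = idx
    hi_pos = n_pos - lo_pos
    hi_tot = n - lo_tot

    def h(pos, tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.zeros_like(pos, dtype=float)
            for cls in (pos, tot - pos):
                frac = np.where(tot > 0, cls / np.maximum(tot, 1), 0.0)
                term = np.where(frac > 0, -frac * np.log2(np.where(frac > 0, frac, 1.0)), 0.0)
                out += term
        return out

    child = np.where(lo_tot > 0, lo_tot / n * h(lo_pos, lo_tot), 0.0) + np.where(
        hi_tot > 0, hi_tot / n * h(hi_pos, hi_tot), 0.0
    )
    return IGCurve(grid, parent - child, parent)


def find_spikes(curve: IGCurve, k: int = 4) -> list[tuple[float, float]]:
    """Top-k local maxima of the IG curve as (score, ig) pairs.

    Plateaus (runs of equal IG) are merged and represented by their
    lower-score end; a point is a spike when strictly above both
    neighbouring plateaus, and curve endpoints count when above their
    single inner neighbour.  Spikes are ranked by IG descending, ties
    broken toward the smaller score.  If fewer than ``k`` exist, all are
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid, ig = curve.grid, curve.ig
    # merge plateaus: representative index = first point of each run
    reps = [0]
    for i in range(1, len(ig)):
        if ig[i] != ig[reps[-1]]:
            reps.append(i)
    vals = ig[reps]
    peaks = []
    for j in range(len(reps)):
        left_ok = j == 0 or vals[j] > vals[j - 1]
        right_ok = j == len(reps) - 1 or vals[j] > vals[j + 1]
        if left_ok and right_ok:
            peaks.append((float(grid[reps[j]]), float(vals[j])))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    if len(peaks) < k:
        warnings.warn(f"only {len(peaks)} IG spikes found (requested {k})")
        return peaks
    return peaks[:k]


def initial_thresholds(
    predictors: tuple[str, ...],
    candidates: dict[str, list[float]],
    X=None,
    y=None,
) -> ThresholdSet:
    """Build an ordering-valid starting ThresholdSet from spike scores.

    Per predictor the four spike scores, sorted ascending, become
    (t_true_1, t_true_2, t_false_2, t_false_1).  When fewer than four
    distinct candidates exist, score quantiles (10/40/60/90%) fill in.
    """
    t1t, t1f, t2t, t2f = [], [], [], []
    X = None if X is None else np.asarray(X, dtype=float)
    for i, p in enumerate(predictors):
        vals = sorted(set(candidates.get(p, [])))
        if len(vals) < 4:
            if X is None:
                raise ValueError(f"{p}: need 4 distinct candidates or score data")
            q = np.quantile(X[:, i], [0.1, 0.4, 0.6, 0.9])
            vals = sorted(set(vals) | set(np.round(q, 12)))
        if len(vals) < 4:  # pathological: nearly constant scores
            lo, hi = vals[0], vals[-1] if len(vals) > 1 else vals[0] + 1e-3
            vals = [lo, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3, hi]
            if vals[1] >= vals[2]:
                vals = [lo - 2e-3, lo - 1e-3, lo + 1e-3, lo + 2e-3]
        a, b, c, d = vals[0], vals[1], vals[-2], vals[-1]
        if not b < c:
            b, c = a, d
        t1t.append(a)
        t2t.append(b)
        t2f.append(c)
        t1f.append(d)
    return ThresholdSet(tuple(predictors), tuple(t1t), tuple(t1f), tuple(t2t), tuple(t2f))


def _admissible(ts: ThresholdSet, pred: str, fld: str, value: float) -> bool:
    i = ts.predictors.index(pred)
    tt1 = value if fld == "t_true_1" else ts.t_true_1[i]
    tt2 = value if fld == "t_true_2" else ts.t_true_2[i]
    tf2 = value if fld == "t_false_2" else ts.t_false_2[i]
    tf1 = value if fld == "t_false_1" else ts.t_false_1[i]
    return tt1 <= tt2 < tf2 <= tf1


def _multi_replace(ts: ThresholdSet, pred: str, updates: dict[str, float]) -> ThresholdSet | None:
    """New set with several cutoffs of one predictor changed at once;
    None when the result would violate the ordering invariants."""
    i = ts.predictors.index(pred)
    kwargs = {}
    for f in ("t_true_1", "t_false_1", "t_true_2", "t_false_2"):
        vals = list(getattr(ts, f))
        if f in updates:
            vals[i] = updates[f]
        kwargs[f] = tuple(vals)
    try:
        return ThresholdSet(ts.predictors, **kwargs)
    except ValueError:
        return None


def _propose(
    ts: ThresholdSet, pred: str, fld: str, value: float, cands: list[float]
) -> ThresholdSet | None:
    """Move one cutoff, repairing the dependent step-2 cutoff if needed.

    A step-1 move that breaks the ordering drags its step-2 partner to
    the nearest admissible candidate (or to the moved value itself).
    A step-2 move that breaks the ordering is infeasible -> None.
    """
    if _admissible(ts, pred, fld, value):
        return _multi_replace(ts, pred, {fld: value})
    i = ts.predictors.index(pred)
    if fld == "t_true_1":
        # need t_true_2 >= value (and still < t_false_2)
        opts = [c for c in sorted(set(cands) | {value}) if c >= value and c < ts.t_false_2[i]]
        if not opts:
            return None
        repair = min(opts, key=lambda c: abs(c - ts.t_true_2[i]))
        return _multi_replace(ts, pred, {fld: value, "t_true_2": repair})
    if fld == "t_false_1":
        opts = [c for c in sorted(set(cands) | {value}) if c <= value and c > ts.t_true_2[i]]
        if not opts:
            return None
        repair = min(opts, key=lambda c: abs(c - ts.t_false_2[i]))
        return _multi_replace(ts, pred, {fld: value, "t_false_2": repair})
    return None


def tune_thresholds(
    initial: ThresholdSet,
    candidates: dict[str, list[float]],
    evaluator,
    grid_steps: dict[str, float] | None = None,
    return_state: bool = False,
):
    """Four-phase coordinate tuning of a ThresholdSet.

    Phases run in order step1_true -> step2_true -> step1_false ->
    step2_false, over each predictor in the set's canonical order.  The
    active cutoff steps through the spike candidates (plus one grid step
    either side of the current value), nearest first; a move is accepted
    when ``evaluator`` (higher is better, tree accuracy by default in
    callers) does not decrease, and the cutoff is frozen after two
    consecutive strictly-decreasing evaluations.  The returned set never
    scores below the initial one and always satisfies the ordering
    invariants.
    """
    initial.validate()
    state = TuningState(current=initial)
    try:
        current_acc = evaluator(initial)
    except Exception as exc:  # pragma: no cover - surfaced to caller
        raise RuntimeError(f"evaluator failed on the initial set: {exc}") from exc

    for phase, fld in PHASES:
        state.phase = phase
        for pred in initial.predictors:
            i = initial.predictors.index(pred)
            step = (grid_steps or {}).get(pred, 0.0)
            cur_val = getattr(state.current, fld)[i]
            pool = set(candidates.get(pred, []))
            if step:
                pool |= {cur_val - step, cur_val + step}
            pool.discard(cur_val)
            ordered = sorted(pool, key=lambda c: (abs(c - cur_val), c))
            streak = 0
            history = state.accuracy_history.setdefault((phase, pred), [current_acc])
            for cand in ordered:
                proposal = _propose(state.current, pred, fld, cand, sorted(candidates.get(pred, [])))
                if proposal is None:
                    continue
                try:
                    acc = evaluator(proposal)
                except Exception as exc:
                    raise RuntimeError(
                        f"evaluator failed during phase {phase}, predictor {pred}: {exc}"
                    ) from exc
                history.append(acc)
                if acc >= current_acc:
                    state.current = proposal
                    current_acc = acc
                    streak = 0
                else:
                    streak += 1
                    if streak >= 2:
                        break
            state.decreasing_streak = streak
    state.current.validate()
    if return_state:
        return state.current, state
    return state.current
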