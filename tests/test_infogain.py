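"""Information gain, spike finding and four-phase threshold tuning."""

import math
from collections import Counter

import numpy as np
import pytest

from mirmeta import infogain
from mirmeta.infogain import (
    IGCurve,
    find_spikes,
    ig_curve,
    information_gain,
    initial_thresholds,
    tune_thresholds,
)
from mirmeta.tree import ThresholdSet, VotingTreeClassifier


def ig_oracle(labels, scores, x) -> float:
    """Contingency-table entropy arithmetic, independent of the
    vectorized implementation."""

    def entropy(items):
        n = len(items)
        if n == 0:
            return 0.0
        return -sum(c / n * math.log2(c / n) for c in Counter(items).values())

    labels = list(labels)
    hi = [l for l, s in zip(labels, scores) if s > x]
    lo = [l for l, s in zip(labels, scores) if s <= x]
    n = len(labels)
    return entropy(labels) - len(hi) / n * entropy(hi) - len(lo) / n * entropy(lo)


def test_information_gain_examples():
    assert information_gain([1, 1, 0, 0], [-0.9, -0.8, 0.8, 0.9], 0.0) == pytest.approx(1.0)
    assert information_gain([1, 1, 0, 0], [0.5] * 4, 0.0) == pytest.approx(0.0)
    # hand-computed: split (1 pos | 3 neg), both children pure
    got = information_gain([1, 0, 0, 0], [-0.9, -0.5, 0.2, 0.7], -0.7)
    assert got == pytest.approx(-(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)))


def test_information_gain_matches_oracle():
    """1e-12 agreement with contingency-table arithmetic on 200 random
    small instances."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = rng.integers(1, 30)
        y = rng.integers(0, 2, n)
        s = np.round(rng.uniform(-1, 1, n), 2)
        x = float(rng.uniform(-1.1, 1.1))
        assert information_gain(y, s, x) == pytest.approx(ig_oracle(y, s, x), abs=1e-12)


def test_ig_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 50)
    s = rng.uniform(-1, 1, 50)
    x = 0.2
    # strictly monotone map preserving membership of the split at x
    t = np.where(s > x, 1 + (s - x), -1 + (s - x))
    assert information_gain(y, s, x) == pytest.approx(
        information_gain(y, t, 0.0), abs=1e-12
    )


def test_ig_curve_bounds_and_resolution():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 300)
    s = rng.uniform(-1, 1, 300)
    curve = ig_curve(y, s, grid_resolution=50)
    assert len(curve.grid) >= 50
    assert np.all(curve.ig >= -1e-12)
    assert np.all(curve.ig <= curve.base_entropy + 1e-12)
    with pytest.raises(ValueError):
        ig_curve(y, s, grid_resolution=5)


def test_ig_curve_perfect_separation_hits_base_entropy():
    y = np.array([1] * 10 + [0] * 10)
    s = np.concatenate([np.linspace(-0.9, -0.5, 10), np.linspace(0.2, 0.9, 10)])
    curve = ig_curve(y, s)
    assert curve.ig.max() == pytest.approx(curve.base_entropy)  # = 1 bit
    assert curve.base_entropy == pytest.approx(1.0)


def test_ig_curve_shuffled_labels_near_zero():
    rng = np.random.default_rng(11)
    y = rng.permutation([1] * 500 + [0] * 500)
    s = rng.uniform(-1, 1, 1000)
    assert ig_curve(y, s).ig.max() < 0.05


def test_ig_curve_single_class_warns():
    with pytest.warns(UserWarning, match="one label"):
        curve = ig_curve([1, 1, 1], [0.1, 0.2, 0.3])
    assert np.all(curve.ig == 0)


# ---------------------------------------------------------------------------
# Spikes


def test_find_spikes_single_peak():
    grid = np.linspace(-1, 1, 101)
    ig = np.exp(-((grid - 0.2) ** 2) / 0.02)
    [(score, val)] = find_spikes(IGCurve(grid, ig, 1.0), k=1)
    assert score == pytest.approx(0.2, abs=0.02)


def test_find_spikes_tie_breaks_to_smaller_score():
    grid = np.linspace(-1, 1, 201)
    ig = np.exp(-((grid + 0.5) ** 2) / 0.005) + np.exp(-((grid - 0.5) ** 2) / 0.005)
    [(score, _)] = find_spikes(IGCurve(grid, ig, 1.0), k=1)
    assert score == pytest.approx(-0.5, abs=0.02)


def test_find_spikes_monotone_curve_returns_endpoint():
    grid = np.linspace(-1, 1, 50)
    with pytest.warns(UserWarning, match="spikes"):
        spikes = find_spikes(IGCurve(grid, grid + 1.0, 2.0), k=4)
    assert len(spikes) == 1
    assert spikes[0][0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Tuning


def _planted_problem(seed=42, n=400):
    """Predictor A separates classes perfectly inside (-0.5, -0.45);
    predictor B is uninformative background."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    a = np.where(y == 1, rng.uniform(-1, -0.5, n), rng.uniform(-0.45, 1, n))
    b = rng.uniform(0.1, 0.5, n)
    return np.column_stack([a, b]), y, a


def test_tune_recovers_planted_cutoff():
    X, y, a = _planted_problem()
    vt = VotingTreeClassifier(predictors=("miranda", "mirdb")).fit(X, y)
    curve = ig_curve(y, a)
    step = float(curve.grid[1] - curve.grid[0])
    gap_lo = a[y == 1].max()  # any cutoff in (gap_lo, gap_hi) is optimal
    gap_hi = a[y == 0].min()
    assert gap_lo - step <= vt.thresholds_.t_true_1[0] <= gap_hi + step


def test_tune_never_decreases_accuracy():
    X, y, _ = _planted_problem(seed=9)
    vt = VotingTreeClassifier(predictors=("miranda", "mirdb"), tune=False).fit(X, y)
    initial = vt.thresholds_
    evaluator = vt._make_evaluator(X, y)
    tuned = tune_thresholds(initial, vt.candidates_, evaluator)
    assert evaluator(tuned) >= evaluator(initial)
    tuned.validate()


def test_tune_already_optimal_unchanged():
    """With no accuracy-improving candidate move, the set is returned
    as-is (equal-accuracy moves are only taken if they appear, so we
    use an evaluator that strictly penalizes any change)."""
    ts = ThresholdSet(("miranda",), (-0.5,), (0.5,), (-0.25,), (0.25,))

    def evaluator(s):
        return 1.0 if s.to_dict() == ts.to_dict() else 0.5

    out = tune_thresholds(ts, {"miranda": [-0.6, -0.1, 0.3]}, evaluator)
    assert out.to_dict() == ts.to_dict()


def test_tune_repairs_dependent_threshold():
    """A step-1 candidate crossing its step-2 partner drags the partner
    along; the result still satisfies the ordering invariants."""
    ts = ThresholdSet(("miranda",), (-0.5,), (0.5,), (-0.25,), (0.25,))
    calls = []

    def evaluator(s):
        calls.append(s)
        return float(s.t_true_1[0])  # reward raising t_true_1

    out = tune_thresholds(ts, {"miranda": [-0.1, 0.0]}, evaluator)
    out.validate()
    assert out.t_true_1[0] == pytest.approx(0.0)
    assert out.t_true_2[0] >= out.t_true_1[0]


def test_initial_thresholds_orders_candidates():
    ts = initial_thresholds(("miranda",), {"miranda": [0.3, -0.2, 0.6, -0.7]})
    assert ts.t_true_1 == (-0.7,)
    assert ts.t_true_2 == (-0.2,)
    assert ts.t_false_2 == (0.3,)
    assert ts.t_false_1 == (0.6,)
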