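"""The dual-threshold two-step significance-voting tree."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmeta.tree import (
    ThresholdSet,
    encode_features,
    significance_distances,
    tree_classify,
    vote_counts,
)


def symmetric_ts(n: int, t_true=-0.5, t_false=0.5, t_true2=-0.25, t_false2=0.25):
    preds = ("miranda", "mirdb", "pita", "targetscan")[:n]
    return ThresholdSet(
        preds,
        t_true_1=(t_true,) * n,
        t_false_1=(t_false,) * n,
        t_true_2=(t_true2,) * n,
        t_false_2=(t_false2,) * n,
    )


def flowchart_oracle(scores, ts: ThresholdSet) -> bool:
    """Literal transcription of the decision flowchart, kept independent
    of the vectorized implementation."""
    n_t1 = sum(s < t for s, t in zip(scores, ts.t_true_1))
    n_f1 = sum(s > t for s, t in zip(scores, ts.t_false_1))
    if n_t1 != n_f1:
        return n_t1 > n_f1
    n_t2 = sum(s < t for s, t in zip(scores, ts.t_true_2))
    n_f2 = sum(s > t for s, t in zip(scores, ts.t_false_2))
    if n_t2 != n_f2:
        return n_t2 > n_f2
    d_t = math.sqrt(sum(max(0.0, t - s) ** 2 for s, t in zip(scores, ts.t_true_2)))
    d_f = math.sqrt(sum(max(0.0, s - t) ** 2 for s, t in zip(scores, ts.t_false_2)))
    return d_t > d_f


# ---------------------------------------------------------------------------
# Vote counting and distances


def test_vote_counts_examples():
    ts = symmetric_ts(2)
    assert vote_counts((-0.9, -0.8), ts, 1) == (2, 0)
    assert vote_counts((0.9, -0.9), ts, 1) == (1, 1)
    assert vote_counts((0.0, 0.0), ts, 1) == (0, 0)


def test_vote_counts_rejects_missing_scores():
    with pytest.raises(ValueError, match="missing"):
        vote_counts((np.nan, 0.0), symmetric_ts(2), 1)


def test_significance_distances():
    ts = symmetric_ts(2)
    d_t, d_f = significance_distances((-0.55, -0.25), ts)
    assert d_t == pytest.approx(0.3)
    assert d_f == 0.0
    d_t, _ = significance_distances((-0.55, -0.55), ts)
    assert d_t == pytest.approx(0.3 * math.sqrt(2))
    assert significance_distances((0.0, 0.1), ts) == (0.0, 0.0)


def test_significance_distances_sum_variant():
    ts = symmetric_ts(2)
    d_t, _ = significance_distances((-0.55, -0.55), ts, aggregate="sum")
    assert d_t == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# Classification


def test_tree_classify_stages():
    ts = symmetric_ts(4)
    d = tree_classify((-0.9, -0.8, -0.7, 0.9), ts)  # 3 true vs 1 false
    assert d.label is True and d.stage == "step1"

    # step-1 tie 0:0, step-2 majority 1:2 -> false at stage step2
    ts3 = symmetric_ts(3, t_true=-0.8, t_false=0.8, t_true2=-0.3, t_false2=0.3)
    d = tree_classify((-0.35, 0.4, 0.45), ts3)
    assert d.label is False and d.stage == "step2"

    ts2 = symmetric_ts(2, t_true=-0.8, t_false=0.8, t_true2=-0.3, t_false2=0.3)

    # all counts tied, distances decide
    d = tree_classify((-0.75, 0.45), ts2)  # c_T = 0.45, c_F = 0.15
    assert d.label is True and d.stage == "significance"


def test_tree_classify_distance_tie_defaults_false():
    ts = symmetric_ts(2)
    d = tree_classify((0.0, 0.0), ts)  # everything abstains: 0 == 0
    assert d.label is False and d.stage == "significance"
    d = tree_classify((0.0, 0.0), ts, tie_break="true")
    assert d.label is True


@pytest.mark.parametrize("n", [2, 3, 4])
def test_tree_matches_flowchart_oracle(n, d4_ts):
    """Exhaustive/randomized equivalence with the literal flowchart."""
    d = d4_ts.to_dict()
    ts = ThresholdSet.from_dict({p: d[p] for p in list(d)[:n]})
    if n == 2:
        axis = np.linspace(-1, 1, 21)
        pts = np.array([(a, b) for a in axis for b in axis])
    else:
        rng = np.random.default_rng(n)
        pts = rng.uniform(-1, 1, size=(2000, n))
    labels, _ = tree_classify(pts, ts)
    expected = [flowchart_oracle(p, ts) for p in pts]
    assert labels.tolist() == expected


@settings(deadline=None, max_examples=120, derandomize=True)
@given(st.data())
def test_count_consistency_and_monotonicity(data):
    """Relaxing thresholds never loses votes; lowering a score never
    flips a true decision to false."""
    n = data.draw(st.integers(2, 4))
    cuts = []
    for _ in range(n):
        vals = sorted(
            data.draw(
                st.lists(
                    st.floats(-1, 1, allow_nan=False, width=32),
                    min_size=4,
                    max_size=4,
                    unique=True,
                )
            )
        )
        cuts.append(vals)  # t1t <= t2t < t2f <= t1f
    preds = ("miranda", "mirdb", "pita", "targetscan")[:n]
    ts = ThresholdSet(
        preds,
        t_true_1=tuple(c[0] for c in cuts),
        t_false_1=tuple(c[3] for c in cuts),
        t_true_2=tuple(c[1] for c in cuts),
        t_false_2=tuple(c[2] for c in cuts),
    )
    scores = np.array(
        data.draw(
            st.lists(
                st.floats(-1, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
    )
    nt1, nf1 = vote_counts(scores, ts, 1)
    nt2, nf2 = vote_counts(scores, ts, 2)
    assert nt1 <= nt2 and nf1 <= nf2
    assert nt1 + nf1 <= n

    if tree_classify(scores, ts).label:
        i = data.draw(st.integers(0, n - 1))
        lowered = scores.copy()
        lowered[i] = data.draw(st.floats(-1, float(scores[i]), allow_nan=False, width=32))
        assert tree_classify(lowered, ts).label


# ---------------------------------------------------------------------------
# Feature encoding


@pytest.mark.parametrize("n,width", [(4, 10), (3, 9), (2, 8)])
def test_encode_features_width(n, width):
    ts = symmetric_ts(n)
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(5, n))
    F = encode_features(X, ts)
    assert F.shape == (5, width)
    assert encode_features(X[0], ts).shape == (width,)


def test_encode_features_content_and_determinism():
    ts = symmetric_ts(2)
    f = encode_features((0.0, 0.1), ts)
    np.testing.assert_allclose(f, [0.0, 0.1, 0, 0, 0, 0, 0.0, 0.0])
    f2 = encode_features((0.0, 0.1), ts)
    np.testing.assert_array_equal(f, f2)


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError, match="ordering"):
        ThresholdSet(("miranda",), (0.5,), (0.4,), (0.6,), (0.45,))
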