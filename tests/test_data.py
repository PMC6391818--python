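"""Table IO, labelling, deduplication, subset assignment and splits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirmeta import data
from mirmeta.predictors import PREDICTOR_ORDER

from conftest import make_scaled_frame


# ---------------------------------------------------------------------------
# IO


def test_load_score_table_masks(tmp_path):
    path = tmp_path / "scores.tsv"
    path.write_text(
        "mirna_id\tgene_id\tmiranda\tmirdb\tpita\ttargetscan\n"
        "m1\tg1\t-1.2\t85\t-20\t-1.5\n"
        "m2\tg2\t-0.9\tNA\t-5\t-0.2\n"
        "m3\tg3\t-\t70\t\tnull\n"
    )
    df = data.load_score_table(path)
    assert len(df) == 3
    present = df[list(PREDICTOR_ORDER)].notna().sum(axis=1).tolist()
    assert present == [4, 3, 1]
    assert np.isnan(df.loc[1, "mirdb"])


def test_load_score_table_errors(tmp_path):
    bad_col = tmp_path / "bad_col.tsv"
    bad_col.write_text("mirna_id\tgene_id\tfrobnicator\nm\tg\t1.0\n")
    with pytest.raises(ValueError, match="unknown predictor"):
        data.load_score_table(bad_col)

    bad_cell = tmp_path / "bad_cell.tsv"
    bad_cell.write_text("mirna_id\tgene_id\tmiranda\nm1\tg1\t-1.0\nm2\tg2\tabc\n")
    with pytest.raises(ValueError, match="line 3"):
        data.load_score_table(bad_cell)


def test_table_roundtrip(tmp_path):
    df = make_scaled_frame([{"miranda": -0.5, "mirdb": 0.2}, {"pita": 0.1}])
    out = tmp_path / "out.tsv"
    data.write_score_table(df, out)
    back = data.load_score_table(out)
    for p in PREDICTOR_ORDER:
        np.testing.assert_allclose(back[p], df[p], equal_nan=True)


# ---------------------------------------------------------------------------
# Labelling


def test_label_records_membership():
    df = make_scaled_frame([{"miranda": 0.0}] * 3)
    df.loc[1, "mirna_id"], df.loc[1, "gene_id"] = "m1", "g1"
    labeled = data.label_records(df, {("m1", "g1")})
    assert labeled["label"].tolist() == ["negative", "positive", "negative"]
    assert (data.label_records(df, set())["label"] == "negative").all()


# ---------------------------------------------------------------------------
# Deduplication


def test_deduplicate_examples():
    near = make_scaled_frame(
        [{"miranda": 0.10, "mirdb": 0.50}, {"miranda": 0.11, "mirdb": 0.51}]
    )
    assert len(data.deduplicate(near, tolerance=0.04, seed=0)) == 1

    far = make_scaled_frame(
        [{"miranda": 0.10, "mirdb": 0.50}, {"miranda": 0.20, "mirdb": 0.51}]
    )
    assert len(data.deduplicate(far, tolerance=0.04, seed=0)) == 2

    single = make_scaled_frame([{"miranda": 0.3, "mirdb": 0.3}])
    assert len(data.deduplicate(single, seed=0)) == 1


def test_deduplicate_respects_masks():
    """Records in different availability patterns are never duplicates."""
    df = make_scaled_frame(
        [{"miranda": 0.10, "mirdb": 0.50}, {"miranda": 0.10, "pita": 0.50}]
    )
    assert len(data.deduplicate(df, seed=0)) == 2


def test_deduplicate_idempotent(prepared_dataset):
    once = data.deduplicate(prepared_dataset, seed=11)
    twice = data.deduplicate(once, seed=12)
    pd.testing.assert_frame_equal(once, twice)


def test_deduplicate_leaves_no_near_pair():
    rng = np.random.default_rng(5)
    rows = [
        {"miranda": float(a), "mirdb": float(b)}
        for a, b in rng.uniform(-0.2, 0.2, size=(120, 2))
    ]
    kept = data.deduplicate(make_scaled_frame(rows), tolerance=0.04, seed=5)
    scores = kept[["scaled_miranda", "scaled_mirdb"]].to_numpy()
    for i, j in itertools.combinations(range(len(scores)), 2):
        assert not np.all(np.abs(scores[i] - scores[j]) < 0.04)


# ---------------------------------------------------------------------------
# Subset assignment


def test_assign_subset_examples():
    assert data.assign_subset(("miranda", "mirdb", "pita", "targetscan")).name == "D4"
    assert data.assign_subset(("miranda", "mirdb")).name == "D2-1"
    assert data.assign_subset(("pita",)) is None


def test_assign_subset_partitions_all_masks():
    """Exactly 11 subsets for the >=2-predictor masks, none for the rest."""
    names = set()
    none_count = 0
    for r in range(5):
        for combo in itertools.combinations(PREDICTOR_ORDER, r):
            key = data.assign_subset(combo)
            if key is None:
                none_count += 1
                assert len(combo) < 2
            else:
                assert set(key.predictors) == set(combo)
                names.add(key.name)
    assert len(names) == 11
    assert none_count == 5
    assert data.SUBSETS["D3-1"].predictors == ("miranda", "mirdb", "pita")
    assert data.SUBSETS["D2-6"].predictors == ("pita", "targetscan")


# ---------------------------------------------------------------------------
# Splits


def _labeled_frame(n=100, n_pos=20):
    df = make_scaled_frame([{"miranda": 0.0, "mirdb": 0.0}] * n)
    df["label"] = ["positive"] * n_pos + ["negative"] * (n - n_pos)
    return df


def test_split_train_test_stratified():
    train, test = data.split_train_test(_labeled_frame(), 0.2, seed=4)
    assert len(test) == 20
    assert (test["label"] == "positive").sum() == 4
    train2, test2 = data.split_train_test(_labeled_frame(), 0.2, seed=4)
    assert list(test.index) == list(test2.index)


def test_split_train_test_rejects_bad_fraction():
    with pytest.raises(ValueError):
        data.split_train_test(_labeled_frame(), 0.0)


def test_split_falls_back_when_class_too_small():
    df = _labeled_frame(10, n_pos=1)
    with pytest.warns(UserWarning, match="unstratified"):
        data.split_train_test(df, 0.3, seed=0)


def test_make_cv_folds_size_rule():
    big = _labeled_frame(1500, 300)
    folds = data.make_cv_folds(big, seed=0)
    assert len(folds) == 5
    assert sorted(len(va) for _, va in folds) == [300] * 5

    small = _labeled_frame(300, 60)
    folds = data.make_cv_folds(small, seed=0)
    assert len(folds) == 3
    assert sorted(len(va) for _, va in folds) == [100] * 3


def test_make_cv_folds_partition():
    df = _labeled_frame(97, 21)
    folds = data.make_cv_folds(df, seed=1)
    vals = np.concatenate([va for _, va in folds])
    assert sorted(vals.tolist()) == list(range(97))
    for (_, a), (_, b) in itertools.combinations(folds, 2):
        assert not set(a) & set(b)


def test_make_cv_folds_too_few_records():
    with pytest.raises(ValueError):
        data.make_cv_folds(_labeled_frame(2, 1), seed=0)
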