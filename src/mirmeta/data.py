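"""Score-table IO, labelling, deduplication and subset partitioning.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per miRNA:mRNA pair and columns::

    mirna_id  gene_id  miranda  mirdb  pita  targetscan
    scaled_miranda ... scaled_targetscan  label  subset

Raw predictor columns hold NaN where a predictor produced no scored
prediction; the availability mask is simply the non-NaN pattern.  Pairs
scored by fewer than two predictors cannot be meta-predicted and are
assigned no subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .predictors import PREDICTOR_ORDER, PREDICTORS, scale_score

__all__ = [
    "ScoreRecord",
    "SubsetKey",
    "SUBSETS",
    "MISSING_MARKERS",
    "load_score_table",
    "load_positive_pairs",
    "write_score_table",
    "scale_records",
    "label_records",
    "deduplicate",
    "assign_subset",
    "assign_subsets",
    "split_train_test",
    "make_cv_folds",
]

#: Cell contents denoting an unscored prediction in input TSV tables.
MISSING_MARKERS = {"", "NA", "-", "null"}

DEFAULT_DEDUP_TOLERANCE = 0.04  # 2% of the scaled range width (2)
DEFAULT_CV_SIZE_THRESHOLD = 1000


@dataclass(frozen=True)
class SubsetKey:
    """One of the eleven predictor-availability patterns."""

    name: str
    predictors: tuple[str, ...]

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)


def _subset_table() -> dict[str, SubsetKey]:
    combos = {
        "D4": ("miranda", "mirdb", "pita", "targetscan"),
        "D3-1": ("miranda", "mirdb", "pita"),
        "D3-2": ("miranda", "mirdb", "targetscan"),
        "D3-3": ("miranda", "pita", "targetscan"),
        "D3-4": ("mirdb", "pita", "targetscan"),
        "D2-1": ("miranda", "mirdb"),
        "D2-2": ("miranda", "pita"),
        "D2-3": ("miranda", "targetscan"),
        "D2-4": ("mirdb", "pita"),
        "D2-5": ("mirdb", "targetscan"),
        "D2-6": ("pita", "targetscan"),
    }
    return {name: SubsetKey(name, preds) for name, preds in combos.items()}


#: name -> SubsetKey for the eleven meta-predictable availability patterns.
SUBSETS: dict[str, SubsetKey] = _subset_table()

_MASK_TO_SUBSET: dict[frozenset, SubsetKey] = {
    frozenset(k.predictors): k for k in SUBSETS.values()
}


@dataclass
class ScoreRecord:
    """A single miRNA:mRNA pair with per-predictor scores.

    ``raw_scores`` / ``scaled_scores`` map predictor id -> float for the
    predictors that scored the pair; absent predictors are simply not in
    the dict (the mask is the key set).
    """

    mirna_id: str
    gene_id: str
    raw_scores: dict[str, float] = field(default_factory=dict)
    scaled_scores: dict[str, float] = field(default_factory=dict)
    label: str = "unknown"

    @property
    def mask(self) -> frozenset:
        return frozenset(self.raw_scores)

    def scale(self) -> "ScoreRecord":
        self.scaled_scores = {
            p: scale_score(p, v) for p, v in self.raw_scores.items()
        }
        return self

    @classmethod
    def from_row(cls, row: pd.Series) -> "ScoreRecord":
        raw = {
            p: float(row[p])
            for p in PREDICTOR_ORDER
            if p in row.index and pd.notna(row[p])
        }
        scaled = {
            p: float(row[f"scaled_{p}"])
            for p in raw
            if f"scaled_{p}" in row.index and pd.notna(row[f"scaled_{p}"])
        }
        label = row.get("label", "unknown")
        return cls(str(row["mirna_id"]), str(row["gene_id"]), raw, scaled,
                   label if isinstance(label, str) else "unknown")


# ---------------------------------------------------------------------------
# IO


def load_score_table(path) -> pd.DataFrame:
    """Parse a TSV score dump into the canonical DataFrame.

    Expected header: ``mirna_id``, ``gene_id`` and one column per base
    predictor.  Empty cells and the markers "NA", "-", "null" denote an
    unscored prediction.  Malformed numeric cells raise a ValueError
    naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mirna_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing id columns {required - set(df.columns)}")
    aux = {"label", "subset"} | {f"scaled_{p}" for p in PREDICTOR_ORDER}
    score_cols = [c for c in df.columns if c not in required | aux]
    unknown = set(score_cols) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"{path}: unknown predictor column(s) {sorted(unknown)}")

    out = df[["mirna_id", "gene_id"]].copy()
    for col in score_cols:
        cells = df[col].str.strip()
        missing = cells.isin(MISSING_MARKERS)
        values = pd.to_numeric(cells.mask(missing), errors="coerce")
        bad = values.isna() & ~missing
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: malformed numeric cell {cells[bad].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )
        out[col] = values.astype(float)
    for p in PREDICTOR_ORDER:
        if p not in out.columns:
            out[p] = np.nan
    if "label" in df.columns:
        out["label"] = df["label"]
    return out


def load_positive_pairs(path) -> set[tuple[str, str]]:
    """Read a TSV of validated (mirna_id, gene_id) interactions."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mirna_id, gene_id")
    return set(zip(df["mirna_id"], df["gene_id"]))


def write_score_table(df: pd.DataFrame, path) -> None:
    """Write the canonical DataFrame as TSV ("NA" for missing scores)."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Preparation


def scale_records(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``scaled_<predictor>`` columns on the common [-1, 1] axis."""
    out = df.copy()
    for p in PREDICTOR_ORDER:
        spec = PREDICTORS[p]
        low, high = spec.native_range
        x = out[p].astype(float)
        if spec.invert:
            x = -x
            low, high = -high, -low
        out[f"scaled_{p}"] = (2.0 * (x - low) / (high - low) - 1.0).clip(-1, 1)
    return out


def label_records(
    df: pd.DataFrame, positive_pairs: set[tuple[str, str]]
) -> pd.DataFrame:
    """Label each pair positive iff it appears in the validated-pair set.

    The caller unions the validated-interaction sources beforehand;
    membership in any one of them suffices.
    """
    out = df.copy()
    keys = list(zip(out["mirna_id"], out["gene_id"]))
    out["label"] = ["positive" if k in positive_pairs else "negative" for k in keys]
    return out


def assign_subset(mask) -> SubsetKey | None:
    """Map an availability mask to its subset, or None for <2 predictors."""
    key = frozenset(mask)
    return _MASK_TO_SUBSET.get(key)


def assign_subsets(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``subset`` column from the non-NaN pattern of raw scores."""
    out = df.copy()
    names = []
    for _, row in out[list(PREDICTOR_ORDER)].notna().iterrows():
        key = assign_subset(tuple(p for p in PREDICTOR_ORDER if row[p]))
        names.append(key.name if key else None)
    out["subset"] = names
    return out


def deduplicate(
    df: pd.DataFrame,
    tolerance: float = DEFAULT_DEDUP_TOLERANCE,
    seed: int = 0,
) -> pd.DataFrame:
    """Remove near-duplicate pairs within each availability pattern.

    Two records with identical masks are duplicates when every shared
    scaled score differs by less than ``tolerance`` (default 0.04, i.e.
    2% of the scaled range width).  One member of each duplicate pair is
    removed; which one survives is random under ``seed``.  The result
    contains no duplicate pair, and the operation is idempotent.
    """
    scaled_cols = [f"scaled_{p}" for p in PREDICTOR_ORDER]
    if not set(scaled_cols) <= set(df.columns):
        raise ValueError("deduplicate requires scaled score columns; call scale_records first")
    rng = np.random.default_rng(seed)
    keep_index: list = []
    mask_key = df[list(PREDICTOR_ORDER)].notna().apply(
        lambda r: tuple(r.to_numpy()), axis=1
    ) if len(df) else pd.Series(dtype=object)
    for _, group in df.groupby(mask_key, sort=False):
        present = [
            f"scaled_{p}"
            for p, has in zip(PREDICTOR_ORDER, group[list(PREDICTOR_ORDER)].notna().iloc[0])
            if has
        ]
        scores = group[present].to_numpy(float)
        order = rng.permutation(len(group))
        kept_rows: list[int] = []
        # greedy pass in random order: keep a record unless it collides
        # with an already-kept one (all shared scores within tolerance)
        sort_col = scores[:, 0] if scores.shape[1] else np.zeros(len(group))
        for i in order:
            collide = False
            for j in kept_rows:
                if abs(sort_col[i] - sort_col[j]) >= tolerance:
                    continue
                if np.all(np.abs(scores[i] - scores[j]) < tolerance):
                    collide = True
                    break
            if not collide:
                kept_rows.append(i)
        keep_index.extend(group.index[sorted(kept_rows)])
    keep = set(keep_index)
    return df.loc[[ix in keep for ix in df.index]]


# ---------------------------------------------------------------------------
# Splits


def split_train_test(
    df: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label random partition into (train, test)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = df["label"]
    stratify = y
    if y.value_counts().min() < 2:
        warnings.warn("a class has <2 members; falling back to unstratified split")
        stratify = None
    train, test = train_test_split(
        df, test_size=test_fraction, random_state=seed, stratify=stratify
    )
    return train, test


def make_cv_folds(
    train: pd.DataFrame,
    seed: int = 0,
    size_threshold: int = DEFAULT_CV_SIZE_THRESHOLD,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified CV folds: 5-fold for large sets, 3-fold for small.

    Returns a list of (train_positions, validation_positions); the
    validation folds partition the input.
    """
    k = 5 if len(train) >= size_threshold else 3
    if len(train) < k:
        raise ValueError(f"cannot make {k} folds from {len(train)} records")
    y = train["label"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(train)), y)]
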