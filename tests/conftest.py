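import numpy as np
import pandas as pd
import pytest

from mirmeta import data
from mirmeta.simulate import SimConfig, generate
from mirmeta.tree import ThresholdSet, d4_thresholds


@pytest.fixture(scope="session")
def d4_ts() -> ThresholdSet:
    return d4_thresholds()


@pytest.fixture(scope="session")
def pair_ts(d4_ts) -> ThresholdSet:
    """Two-predictor (miranda, mirdb) restriction of the packaged thresholds."""
    d = d4_ts.to_dict()
    return ThresholdSet.from_dict({p: d[p] for p in ("miranda", "mirdb")})


@pytest.fixture(scope="session")
def prepared_dataset() -> pd.DataFrame:
    """A scaled, labeled, deduplicated, subset-assigned synthetic table."""
    table, positives = generate(SimConfig(n_samples=1500, seed=3))
    df = data.scale_records(table)
    df = data.label_records(df, positives)
    df = data.deduplicate(df, seed=3)
    return data.assign_subsets(df)


def make_scaled_frame(scaled_rows: list[dict], labels: list[str] | None = None) -> pd.DataFrame:
    """Build a canonical frame directly from scaled scores (raw = scaled)."""
    from mirmeta.predictors import PREDICTOR_ORDER

    rows = []
    for i, scores in enumerate(scaled_rows):
        rec = {"mirna_id": f"m{i}", "gene_id": f"g{i}"}
        for p in PREDICTOR_ORDER:
            rec[p] = scores.get(p, np.nan)
            rec[f"scaled_{p}"] = scores.get(p, np.nan)
        if labels is not None:
            rec["label"] = labels[i]
        rows.append(rec)
    return pd.DataFrame(rows)
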