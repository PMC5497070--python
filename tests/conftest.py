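import numpy as np
import pandas as pd
import pytest

from crowdrasch.data import ABNORMAL, NORMAL


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def small_grades():
    """Nine grades over three workers and four items, with one duplicate pair."""
    rows = [
        ("w1", "i1", ABNORMAL, "a", 0),
        ("w1", "i2", NORMAL, "a", 1),
        ("w1", "i2", ABNORMAL, "a", 5),  # duplicate, later view
        ("w2", "i1", ABNORMAL, "a", 0),
        ("w2", "i3", NORMAL, "a", 1),
        ("w2", "i4", NORMAL, "a", 2),
        ("w3", "i2", ABNORMAL, "a", 0),
        ("w3", "i3", ABNORMAL, "a", 1),
        ("w3", "i4", NORMAL, "a", 2),
    ]
    return pd.DataFrame(
        rows, columns=["worker_id", "item_id", "classification", "batch", "order_index"]
    )


@pytest.fixture
def small_truth():
    return pd.DataFrame(
        {
            "item_id": ["i1", "i2", "i3", "i4"],
            "source_grade": [3, 0, 2, 1],
            "gold": [ABNORMAL, NORMAL, ABNORMAL, NORMAL],
        }
    )


def random_grade_frame(rng, n_workers=6, n_items=8, n_records=40, dup_fraction=0.2):
    """Random grade records with some duplicate (worker, item) pairs."""
    workers = [f"w{k}" for k in range(n_workers)]
    items = [f"i{k}" for k in range(n_items)]
    rows = []
    for r in range(n_records):
        rows.append(
            (
                workers[rng.integers(n_workers)],
                items[rng.integers(n_items)],
                ABNORMAL if rng.random() < 0.5 else NORMAL,
                "b",
                int(rng.integers(0, 50)),
            )
        )
    df = pd.DataFrame(
        rows, columns=["worker_id", "item_id", "classification", "batch", "order_index"]
    )
    if dup_fraction > 0:
        extra = df.sample(frac=dup_fraction, random_state=int(rng.integers(2**31)))
        extra = extra.assign(order_index=extra["order_index"] + 100)
        df = pd.concat([df, extra], ignore_index=True)
    return df


def nonextreme_binary_matrix(rng, n_workers, n_items, p=0.6, max_tries=200):
    """A complete 0/1 matrix whose rows and columns are all mixed."""
    for _ in range(max_tries):
        X = (rng.random((n_workers, n_items)) < p).astype(float)
        rows_ok = ((X.sum(axis=1) > 0) & (X.sum(axis=1) < n_items)).all()
        cols_ok = ((X.sum(axis=0) > 0) & (X.sum(axis=0) < n_workers)).all()
        if rows_ok and cols_ok:
            return X
    raise RuntimeError("failed to draw a non-extreme matrix")
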