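"""Grade-record handling: cleaning rules, dichotomization, partitioning, I/O.

Crowdsourced grading data arrive as a long table of *grade records* — one
worker's binary classification (``normal`` / ``abnormal``) of one item — plus
a *truth table* mapping each item to a gold label, possibly via an ordinal
source grade (the Messidor 0-3 retinopathy scale).  This module owns the
cleaning rules applied before ability estimation: duplicate-grade removal,
exclusion of workers with too few grades in the training set, conversion of
grades into the sparse worker x item correctness matrix, and the random
train/test split of items.

Grade records are plain :class:`pandas.DataFrame` objects with the columns in
:data:`GRADE_COLUMNS`; truth tables use :data:`TRUTH_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

NORMAL = "normal"
ABNORMAL = "abnormal"
LABELS = (NORMAL, ABNORMAL)

GRADE_COLUMNS = ("worker_id", "item_id", "classification", "batch", "order_index")
TRUTH_COLUMNS = ("item_id", "source_grade", "gold")


def dichotomize(source_grade: int) -> str:
    """Map an ordinal Messidor-style grade (0-3) to a binary label.

    Grades 0 and 1 (no or clinically insignificant microaneurysms) are
    ``normal``; grades 2 and 3 are ``abnormal``.

    Raises
    ------
    ValueError
        If ``source_grade`` is not one of 0, 1, 2, 3.
    """
    if source_grade not in (0, 1, 2, 3):
        raise ValueError(f"invalid source grade {source_grade!r}; expected 0-3")
    return NORMAL if source_grade <= 1 else ABNORMAL


def _check_grades(records: pd.DataFrame) -> pd.DataFrame:
    missing = {"worker_id", "item_id", "classification"} - set(records.columns)
    if missing:
        raise ValueError(f"grade table missing columns: {sorted(missing)}")
    bad = set(records["classification"].unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown classification labels: {sorted(bad)}")
    return records


@dataclass(frozen=True)
class DedupeReport:
    n_input: int
    n_kept: int

    @property
    def n_deleted(self) -> int:
        return self.n_input - self.n_kept


def dedupe_grades(records: pd.DataFrame) -> tuple[pd.DataFrame, DedupeReport]:
    """Keep one grade per (worker, item) pair.

    The retained record is the one with the smallest ``order_index`` (the
    worker's first look at the item; later views are contaminated by prior
    exposure).  Records without an ``order_index`` tie at +inf and fall back
    to input order.  Returns the deduplicated table (original row order
    preserved) and a report with the deletion count.
    """
    _check_grades(records)
    df = records.reset_index(drop=True)
    if "order_index" in df.columns:
        order = pd.to_numeric(df["order_index"], errors="coerce").fillna(np.inf)
    else:
        order = pd.Series(np.inf, index=df.index)
    pos = np.argsort(order.to_numpy(), kind="stable")
    kept = df.iloc[pos].drop_duplicates(subset=["worker_id", "item_id"], keep="first")
    kept = kept.sort_index()  # restore input order
    report = DedupeReport(n_input=len(df), n_kept=len(kept))
    return kept.reset_index(drop=True), report


@dataclass(frozen=True)
class FilterReport:
    n_workers_removed: int
    n_grades_removed: int


def filter_sparse_workers(
    records: pd.DataFrame,
    item_subset: Iterable,
    min_grades: int = 10,
    remove_all_records: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop grades by workers with fewer than ``min_grades`` items in a subset.

    Counting is restricted to ``item_subset`` (typically the training items):
    a worker whose number of distinct graded items *within the subset* is
    below ``min_grades`` is excluded.  By default only that worker's records
    within the subset are removed — their test-set grades survive, matching a
    workflow that retains every worker's votes at scoring time.  With
    ``remove_all_records=True`` the worker's records outside the subset are
    removed as well.

    Raises
    ------
    ValueError
        If ``item_subset`` is empty or ``min_grades < 1``.
    """
    _check_grades(records)
    subset = set(item_subset)
    if not subset:
        raise ValueError("item_subset must be non-empty")
    if min_grades < 1:
        raise ValueError("min_grades must be >= 1")
    in_subset = records["item_id"].isin(subset)
    counts = records.loc[in_subset].groupby("worker_id")["item_id"].nunique()
    bad_workers = set(counts.index[counts < min_grades])
    # workers with zero subset grades never hit the threshold: nothing of
    # theirs lies inside the subset, and whole-worker removal is keyed to
    # subset participation
    is_bad = records["worker_id"].isin(bad_workers)
    drop = is_bad if remove_all_records else (is_bad & in_subset)
    out = records.loc[~drop].reset_index(drop=True)
    report = FilterReport(
        n_workers_removed=len(bad_workers), n_grades_removed=int(drop.sum())
    )
    return out, report


@dataclass
class CorrectnessMatrix:
    """Sparse worker x item matrix of grade correctness.

    ``values[w, i]`` is 1.0 where worker ``workers[w]`` graded item
    ``items[i]`` correctly, 0.0 where incorrectly, and NaN where that worker
    did not grade that item.
    """

    workers: list
    items: list
    values: np.ndarray  # shape (n_workers, n_items), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.workers), len(self.items)):
            raise ValueError("values shape does not match index lengths")
        obs = ~np.isnan(self.values)
        if not obs.any(axis=1).all():
            raise ValueError("every worker must have at least one observed cell")
        if not obs.any(axis=0).all():
            raise ValueError("every item must have at least one observed cell")

    @property
    def n_observed(self) -> int:
        return int((~np.isnan(self.values)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.workers, columns=self.items)


def build_correctness_matrix(
    records: pd.DataFrame, truth: pd.DataFrame
) -> CorrectnessMatrix:
    """Score deduplicated grades against gold labels.

    Each retained grade becomes one observed cell: 1 if the classification
    equals the item's gold label, else 0.  Every item graded must appear in
    ``truth``; duplicate (worker, item) pairs are rejected.
    """
    _check_grades(records)
    if records.duplicated(subset=["worker_id", "item_id"]).any():
        raise ValueError("records contain duplicate (worker, item) pairs; dedupe first")
    gold = truth.set_index("item_id")["gold"]
    unknown = set(records["item_id"]) - set(gold.index)
    if unknown:
        raise KeyError(f"items without truth labels: {sorted(map(str, unknown))[:5]}")
    workers = sorted(records["worker_id"].unique())
    items = sorted(records["item_id"].unique())
    widx = {w: k for k, w in enumerate(workers)}
    iidx = {i: k for k, i in enumerate(items)}
    values = np.full((len(workers), len(items)), np.nan)
    correct = (
        records["classification"].to_numpy()
        == gold.loc[records["item_id"]].to_numpy()
    )
    rows = records["worker_id"].map(widx).to_numpy()
    cols = records["item_id"].map(iidx).to_numpy()
    values[rows, cols] = correct.astype(float)
    return CorrectnessMatrix(workers=workers, items=items, values=values)


@dataclass(frozen=True)
class SplitAssignment:
    """A reproducible train/test partition of items."""

    train_items: frozenset
    test_items: frozenset
    seed: int

    def partition_frame(self) -> pd.DataFrame:
        rows = [(i, "train") for i in sorted(self.train_items)] + [
            (i, "test") for i in sorted(self.test_items)
        ]
        return pd.DataFrame(rows, columns=["item_id", "partition"])


def split_items(
    items: Sequence,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_by: pd.Series | dict | None = None,
) -> SplitAssignment:
    """Randomly partition items into train and test sets.

    ``fraction`` is the training share.  With ``stratify_by`` (a mapping from
    item to an ordinal stratum, e.g. the source grade) a largest-remainder
    allocation keeps each stratum's training share within two percentage
    points of the overall fraction while preserving the overall train size.
    Deterministic for a fixed seed.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction * len(items)))
    n_train = min(max(n_train, 1), len(items) - 1)
    if stratify_by is None:
        order = rng.permutation(len(items))
        train = {items[k] for k in order[:n_train]}
    else:
        strata = pd.Series({i: stratify_by[i] for i in items})
        groups = {s: list(g.index) for s, g in strata.groupby(strata)}
        # largest-remainder: floor each stratum's quota, hand out leftovers
        quotas = {s: fraction * len(g) for s, g in groups.items()}
        take = {s: int(np.floor(q)) for s, q in quotas.items()}
        leftover = n_train - sum(take.values())
        by_rem = sorted(groups, key=lambda s: quotas[s] - take[s], reverse=True)
        for s in by_rem[:leftover]:
            take[s] += 1
        train = set()
        for s, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
            order = rng.permutation(len(members))
            train.update(members[k] for k in order[: take[s]])
    test = set(items) - train
    return SplitAssignment(
        train_items=frozenset(train), test_items=frozenset(test), seed=seed
    )


# ---------------------------------------------------------------------------
# File I/O

def load_grades(path: str | Path) -> pd.DataFrame:
    """Read a grades CSV (worker_id,item_id,classification,batch,order_index)."""
    df = pd.read_csv(path, dtype={"worker_id": str, "item_id": str})
    df["classification"] = df["classification"].str.strip().str.lower()
    return _check_grades(df)


def save_grades(records: pd.DataFrame, path: str | Path) -> None:
    _check_grades(records).to_csv(path, index=False)


def load_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth CSV (item_id,source_grade,gold).

    A blank ``gold`` is filled by dichotomizing ``source_grade``; when both
    are present they must agree.
    """
    df = pd.read_csv(path, dtype={"item_id": str})
    return prepare_truth(df)


def prepare_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a truth table and fill gold labels from source grades."""
    df = df.copy()
    if "item_id" not in df.columns:
        raise ValueError("truth table missing item_id column")
    if df["item_id"].duplicated().any():
        raise ValueError("truth table has duplicate item_ids")
    if "gold" not in df.columns:
        df["gold"] = np.nan
    df["gold"] = df["gold"].astype(object)
    if "source_grade" not in df.columns:
        df["source_grade"] = np.nan
    has_grade = df["source_grade"].notna()
    derived = df.loc[has_grade, "source_grade"].map(lambda g: dichotomize(int(g)))
    blank = df["gold"].isna()
    df.loc[has_grade & blank, "gold"] = derived[blank[has_grade]]
    if df["gold"].isna().any():
        raise ValueError("items with neither gold label nor source grade")
    df["gold"] = df["gold"].str.strip().str.lower()
    bad = set(df["gold"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown gold labels: {sorted(bad)}")
    both = has_grade & ~blank
    if both.any():
        mismatch = df.loc[both, "gold"] != df.loc[both, "source_grade"].map(
            lambda g: dichotomize(int(g))
        )
        if mismatch.any():
            raise ValueError("gold labels disagree with dichotomized source grades")
    return df


def save_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def save_split(split: SplitAssignment, path: str | Path) -> None:
    split.partition_frame().to_csv(path, index=False)


def write_manifest(path: str | Path, entries: dict) -> None:
    """Record run provenance (seeds, configs) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=True)
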