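"""Synthetic crowdsourced grading data with Rasch structure.

The generator emulates the statistical setting the weighting method assumes:
a population of workers with heterogeneous ability D ~ Normal(0, ability_sd²),
items with heterogeneous difficulty B ~ Normal(0, difficulty_sd²), gold labels
drawn Bernoulli(prevalence), and sparse assignment of a fixed number of
graders per item.  Each assigned response is *correct* with probability
expit(B_n - D_i); a correct response reproduces the item's gold label, an
incorrect one flips it (a symmetric error model — real graders need not err
symmetrically across classes).

The default configuration mirrors a screening-study geometry: 1200 items,
300 workers, 10 grades per item, abnormal prevalence 0.42.

:func:`benchmark_aggregators` is the end-to-end harness: simulate, split the
items 50/50, fit Rasch weights on the training half, and compare the weighted
consensus AUROC on the test half against the unweighted vote margin and
against an oracle that weights by the true abilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consensus import MajorityVoteConsensus, RaschWeightedConsensus, vote_matrix
from .data import ABNORMAL, NORMAL, split_items
from .evaluation import auroc
from .rasch import rasch_probability

ASSIGNMENT_MODES = ("uniform_random", "heavy_tail")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic crowd.

    ability_sd / difficulty_sd are in logits.  ``heavy_tail`` assignment
    draws worker participation from a truncated Zipf-like law so that a few
    workers do many tasks and many do a handful, mimicking real marketplace
    skew; ``uniform_random`` gives every worker equal selection probability.
    """

    n_items: int = 1200
    n_workers: int = 300
    grades_per_item: int = 10
    prevalence: float = 0.42
    ability_sd: float = 1.0
    difficulty_sd: float = 1.5
    assignment: str = "uniform_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grades_per_item > self.n_workers:
            raise ValueError("grades_per_item cannot exceed n_workers")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.ability_sd < 0 or self.difficulty_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.assignment not in ASSIGNMENT_MODES:
            raise ValueError(f"assignment must be one of {ASSIGNMENT_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("simulation config must specify a seed")
        return cls(**raw)


@dataclass
class SimTruthBundle:
    """A simulated dataset plus the latent parameters that generated it."""

    records: pd.DataFrame
    truth: pd.DataFrame
    true_D: pd.Series  # worker ability, logits (lower = more skilled)
    true_B: pd.Series  # item difficulty, logits (lower = harder)
    config: SimConfig


def _worker_ids(n: int) -> list[str]:
    return [f"w{k:04d}" for k in range(n)]


def _item_ids(n: int) -> list[str]:
    return [f"img{k:05d}" for k in range(n)]


def simulate_crowd(config: SimConfig) -> SimTruthBundle:
    """Draw one synthetic grading dataset; byte-reproducible for a seed.

    Every item receives exactly ``grades_per_item`` grades from distinct
    workers; no worker grades an item twice.
    """
    rng = np.random.default_rng(config.seed)
    workers = _worker_ids(config.n_workers)
    items = _item_ids(config.n_items)

    gold01 = rng.random(config.n_items) < config.prevalence
    D = rng.normal(0.0, config.ability_sd, config.n_workers)
    B = rng.normal(0.0, config.difficulty_sd, config.n_items)

    if config.assignment == "heavy_tail":
        # Zipf-like participation: p(rank r) ~ 1/r, ranks shuffled over ids
        weights = 1.0 / np.arange(1, config.n_workers + 1)
        rng.shuffle(weights)
        probs = weights / weights.sum()
    else:
        probs = None

    rows = []
    for i in range(config.n_items):
        chosen = rng.choice(
            config.n_workers, size=config.grades_per_item, replace=False, p=probs
        )
        p_correct = rasch_probability(B[i], D[chosen])
        correct = rng.random(config.grades_per_item) < p_correct
        gold_label = ABNORMAL if gold01[i] else NORMAL
        flip = NORMAL if gold01[i] else ABNORMAL
        for w, c in zip(chosen, correct):
            rows.append((workers[w], items[i], gold_label if c else flip))
    records = pd.DataFrame(rows, columns=["worker_id", "item_id", "classification"])
    records["batch"] = "sim"
    records["order_index"] = records.groupby("worker_id").cumcount()

    truth = pd.DataFrame(
        {
            "item_id": items,
            "source_grade": pd.array([None] * config.n_items, dtype="Int64"),
            "gold": np.where(gold01, ABNORMAL, NORMAL),
        }
    )
    return SimTruthBundle(
        records=records,
        truth=truth,
        true_D=pd.Series(D, index=workers),
        true_B=pd.Series(B, index=items),
        config=config,
    )


def benchmark_aggregators(
    config: SimConfig,
    n_replicates: int = 1,
    min_grades: int = 1,
    truncation_centiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Compare consensus rules over simulated replicates.

    Per replicate: simulate a crowd, split items 50/50 into train/test, fit
    Rasch worker weights on the training half (workers with fewer than
    ``min_grades`` training grades are excluded from the fit and fall back to
    the neutral weight), then compute the test-set AUROC of (a) the unweighted
    vote margin, (b) the Rasch-weighted score with estimated weights, and (c)
    an oracle weighted score using the true abilities exp(-D).

    Returns a table with one row per replicate: ``replicate, mv_auroc,
    weighted_auroc, oracle_weighted_auroc, converged``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * n_replicates)
    rows = []
    for rep in range(n_replicates):
        sim_seed = int(seeds[2 * rep] % (2**31))
        split_seed = int(seeds[2 * rep + 1] % (2**31))
        bundle = simulate_crowd(replace(config, seed=sim_seed))
        result = run_weighting_pipeline(
            bundle,
            split_seed=split_seed,
            min_grades=min_grades,
            truncation_centiles=truncation_centiles,
        )
        rows.append(
            (
                rep,
                result["mv_auroc"],
                result["weighted_auroc"],
                result["oracle_auroc"],
                result["converged"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "mv_auroc",
            "weighted_auroc",
            "oracle_weighted_auroc",
            "converged",
        ],
    )


def run_weighting_pipeline(
    bundle: SimTruthBundle,
    split_seed: int,
    min_grades: int = 1,
    truncation_centiles: tuple[float, float] = (1.0, 99.0),
) -> dict:
    """One train/test pass over a simulated bundle; returns summary dict."""
    from .data import filter_sparse_workers

    gold = bundle.truth.set_index("item_id")["gold"]
    split = split_items(
        list(gold.index), fraction=0.5, seed=split_seed
    )
    train_items = sorted(split.train_items)
    test_items = sorted(split.test_items)

    train_records = bundle.records[bundle.records["item_id"].isin(split.train_items)]
    if min_grades > 1:
        train_records, _ = filter_sparse_workers(
            train_records, split.train_items, min_grades=min_grades
        )
    test_records = bundle.records[bundle.records["item_id"].isin(split.test_items)]

    X_train = vote_matrix(train_records, items=train_items)
    X_test = vote_matrix(test_records, items=test_items)
    y_train = gold.loc[train_items].to_numpy()
    y_test = gold.loc[test_items]

    low, high = truncation_centiles
    model = RaschWeightedConsensus(
        truncation_centiles=(low, high), missing_weight="neutral"
    ).fit(X_train, y_train)
    weighted_scores = pd.Series(model.decision_function(X_test), index=test_items)

    mv_scores = pd.Series(
        MajorityVoteConsensus().fit(X_test).decision_function(X_test),
        index=test_items,
    )

    oracle_w = np.exp(-bundle.true_D.reindex(X_test.columns).to_numpy())
    oracle_scores = pd.Series(X_test.to_numpy() @ oracle_w, index=test_items)

    return {
        "mv_auroc": auroc(mv_scores, y_test).auroc,
        "weighted_auroc": auroc(weighted_scores, y_test).auroc,
        "oracle_auroc": auroc(oracle_scores, y_test).auroc,
        "converged": bool(model.rasch_.converged_),
        "weighted_scores": weighted_scores,
        "mv_scores": mv_scores,
        "test_gold": y_test,
        "model": model,
    }
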