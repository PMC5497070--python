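"""Vote weighting and consensus aggregation.

Two consensus rules over per-item binary votes:

* **Majority vote (MV)** — an item is ``abnormal`` when half or more of its
  graders said so.
* **Rasch-weighted consensus** — each worker's vote, recoded ``abnormal`` = +1
  / ``normal`` = -1, is multiplied by the worker's weight ``exp(-D_i)`` (the
  odds they classify an average-difficulty item correctly, from a Rasch fit on
  training items); the weighted votes are summed into a score ``S`` and the
  item is called ``abnormal`` when ``S >= 0`` (ties to abnormal — conservative
  for screening).

Weights are truncated at the 1st/99th centiles of their empirical
distribution before use, to damp outlying ability estimates.

Both rules are exposed as scikit-learn style estimators over an item x worker
signed vote matrix (see :func:`vote_matrix`), plus the spec-level functions
(:func:`mv_consensus`, :func:`weighted_score`, ...) they are built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import ABNORMAL, LABELS, NORMAL
from .rasch import RaschJMLE

VOTE_CODES = {ABNORMAL: 1.0, NORMAL: -1.0}


def ability_to_weight(d):
    """Vote weight exp(-D): odds of correctly grading an average item."""
    return np.exp(-np.asarray(d, dtype=float))


@dataclass
class WeightVector:
    """Per-worker vote weights on the odds scale, after centile truncation."""

    weights: dict
    truncation_bounds: tuple[float, float]
    source_fit_id: str | None = None

    def __getitem__(self, worker):
        return self.weights[worker]

    def __contains__(self, worker) -> bool:
        return worker in self.weights


def truncate_weights(
    weights, low_centile: float = 1.0, high_centile: float = 99.0
) -> WeightVector:
    """Clamp weights to their empirical low/high centile values.

    Uses the linear-interpolation percentile over the retained workers;
    interior weights keep their order.  ``(0, 100)`` centiles are the
    identity.
    """
    if not 0.0 <= low_centile < high_centile <= 100.0:
        raise ValueError("need 0 <= low_centile < high_centile <= 100")
    series = pd.Series(dict(weights), dtype=float)
    if len(series) < 2:
        raise ValueError("need at least 2 workers to compute centiles")
    if (series <= 0).any():
        raise ValueError("weights must be positive")
    low, high = np.percentile(series.to_numpy(), [low_centile, high_centile])
    clamped = series.clip(lower=low, upper=high)
    return WeightVector(
        weights=clamped.to_dict(), truncation_bounds=(float(low), float(high))
    )


def mv_consensus(votes) -> str:
    """Majority-vote label: abnormal iff half or more votes are abnormal."""
    votes = list(votes)
    if not votes:
        raise ValueError("cannot take a majority of zero votes")
    bad = set(votes) - set(LABELS)
    if bad:
        raise ValueError(f"unknown vote labels: {sorted(bad)}")
    n_abnormal = sum(v == ABNORMAL for v in votes)
    return ABNORMAL if n_abnormal >= len(votes) / 2 else NORMAL


def weighted_score(votes, weights, missing_weight: str = "error") -> float:
    """Signed weighted vote sum S = sum_i w_i * c_i, with c_i = +/-1.

    ``votes`` maps worker -> label; ``weights`` is a :class:`WeightVector` or
    mapping.  A voter without a weight raises by default; with
    ``missing_weight='neutral'`` they count as an average worker (weight 1).
    """
    if missing_weight not in ("error", "neutral"):
        raise ValueError("missing_weight must be 'error' or 'neutral'")
    # accumulate the two vote directions separately and subtract once, so an
    # exact tie (e.g. equal weights, equal counts) yields exactly 0.0 and the
    # tie-to-abnormal convention is not at the mercy of float associativity
    pro, contra = 0.0, 0.0
    for worker, label in votes.items():
        if label not in VOTE_CODES:
            raise ValueError(f"unknown vote label {label!r}")
        if worker in weights:
            w = weights[worker]
        elif missing_weight == "neutral":
            w = 1.0
        else:
            raise KeyError(f"no weight for voting worker {worker!r}")
        if label == ABNORMAL:
            pro += w
        else:
            contra += w
    return pro - contra


def threshold_label(s: float, cutoff: float = 0.0) -> str:
    """Abnormal iff the consensus score is at or above the cut-off."""
    return ABNORMAL if s >= cutoff else NORMAL


def vote_matrix(records: pd.DataFrame, workers=None, items=None) -> pd.DataFrame:
    """Pivot deduplicated grade records into an item x worker signed matrix.

    Entries are +1 (abnormal vote), -1 (normal vote) or 0 (worker did not
    grade the item) — the estimator input convention.
    """
    if records.duplicated(subset=["worker_id", "item_id"]).any():
        raise ValueError("duplicate (worker, item) grades; dedupe first")
    coded = records["classification"].map(VOTE_CODES)
    if coded.isna().any():
        raise ValueError("unknown classification labels in records")
    wide = (
        records.assign(_code=coded)
        .pivot(index="item_id", columns="worker_id", values="_code")
        .fillna(0.0)
    )
    if items is not None:
        wide = wide.reindex(index=list(items), fill_value=0.0)
    if workers is not None:
        wide = wide.reindex(columns=list(workers), fill_value=0.0)
    return wide.fillna(0.0)


def _as_signed_array(X) -> tuple[np.ndarray, list, list | None]:
    """Coerce an item x worker vote matrix to ndarray; return (V, items, workers)."""
    if isinstance(X, pd.DataFrame):
        items = list(X.index)
        workers = list(X.columns)
        V = X.to_numpy(dtype=float)
    else:
        V = np.asarray(X, dtype=float)
        items = list(range(V.shape[0]))
        workers = list(range(V.shape[1])) if V.ndim == 2 else None
    if V.ndim != 2:
        raise ValueError("vote matrix must be 2-D (items x workers)")
    V = np.where(np.isnan(V), 0.0, V)
    if not np.isin(V, (-1.0, 0.0, 1.0)).all():
        raise ValueError("votes must be coded +1 (abnormal), -1 (normal), 0/NaN (none)")
    return V, items, workers


def _encode_gold(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        bad = set(np.unique(y)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown gold labels: {sorted(bad)}")
        return np.where(y == ABNORMAL, 1.0, -1.0)
    g = y.astype(float)
    if not np.isin(g, (-1.0, 1.0)).all():
        raise ValueError("numeric gold labels must be +/-1")
    return g


class MajorityVoteConsensus(BaseEstimator, ClassifierMixin):
    """Unweighted majority-vote baseline over a signed vote matrix.

    ``decision_function`` is the raw vote margin (count abnormal minus count
    normal); ``predict`` calls ``abnormal`` when the margin is >= 0, so a tie
    goes to abnormal.
    """

    def fit(self, X, y=None):
        _as_signed_array(X)
        self.classes_ = np.array(sorted(LABELS))
        return self

    def decision_function(self, X) -> np.ndarray:
        V, _, _ = _as_signed_array(X)
        return V.sum(axis=1)

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        return np.where(margin >= 0, ABNORMAL, NORMAL)


class RaschWeightedConsensus(BaseEstimator, ClassifierMixin):
    """Consensus classifier weighting each worker's vote by Rasch ability.

    ``fit(X, y)`` scores the training votes against gold labels, estimates
    worker ability measures by Rasch JMLE on the resulting correctness
    matrix, and converts them to truncated ``exp(-D)`` weights.
    ``decision_function(X)`` returns the weighted consensus score S per item;
    ``predict`` thresholds S at ``cutoff`` (default 0, ties to abnormal).

    Parameters
    ----------
    truncation_centiles : pair of floats, default (1, 99)
        Centile bounds for weight truncation, on the odds scale.
    cutoff : float, default 0.0
        Decision threshold on S.
    missing_weight : {'error', 'neutral'}, default 'error'
        Policy for test-set workers absent from the training fit; 'neutral'
        assigns weight 1.0 and counts the imputations in
        ``n_imputed_weights_``.
    tol, max_iter, extreme_score_adjust, centering
        Passed to :class:`~crowdrasch.rasch.RaschJMLE`.
    """

    def __init__(
        self,
        truncation_centiles: tuple[float, float] = (1.0, 99.0),
        cutoff: float = 0.0,
        missing_weight: str = "error",
        tol: float = 0.005,
        max_iter: int = 200,
        extreme_score_adjust: float = 0.3,
        centering: str = "worker_mean_zero",
    ) -> None:
        self.truncation_centiles = truncation_centiles
        self.cutoff = cutoff
        self.missing_weight = missing_weight
        self.tol = tol
        self.max_iter = max_iter
        self.extreme_score_adjust = extreme_score_adjust
        self.centering = centering

    def fit(self, X, y):
        V, items, workers = _as_signed_array(X)
        g = _encode_gold(y)
        if g.shape[0] != V.shape[0]:
            raise ValueError("X and y disagree on the number of items")
        # correctness matrix, workers x items: 1 where vote matches gold
        observed = V != 0
        correct = np.where(observed, (V * g[:, None] > 0).astype(float), np.nan).T
        keep_w = ~np.isnan(correct).all(axis=1)
        keep_i = ~np.isnan(correct[keep_w]).all(axis=0)
        self.rasch_ = RaschJMLE(
            tol=self.tol,
            max_iter=self.max_iter,
            extreme_score_adjust=self.extreme_score_adjust,
            centering=self.centering,
        ).fit(correct[np.ix_(keep_w, keep_i)])
        fitted_workers = [w for w, k in zip(workers, keep_w) if k]
        raw = ability_to_weight(self.rasch_.worker_measures_)
        low, high = self.truncation_centiles
        wv = truncate_weights(dict(zip(fitted_workers, raw)), low, high)
        self.weights_ = pd.Series(wv.weights, dtype=float)
        self.truncation_bounds_ = wv.truncation_bounds
        self.raw_weights_ = pd.Series(dict(zip(fitted_workers, raw)), dtype=float)
        self.classes_ = np.array(sorted(LABELS))
        self.n_imputed_weights_ = 0
        return self

    def _weight_row(self, workers) -> np.ndarray:
        w = self.weights_.reindex(workers)
        self.n_imputed_weights_ = int(w.isna().sum())
        if w.isna().any():
            if self.missing_weight == "neutral":
                w = w.fillna(1.0)
            else:
                missing = [wk for wk, nan in zip(workers, w.isna()) if nan]
                raise KeyError(
                    f"{len(missing)} voting workers have no fitted weight "
                    f"(e.g. {missing[:3]}); refit or set missing_weight='neutral'"
                )
        return w.to_numpy()

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        V, items, workers = _as_signed_array(X)
        if workers is None:
            raise ValueError("vote matrix must carry worker identities")
        voting = (V != 0).any(axis=0)
        w = np.zeros(V.shape[1])
        w[voting] = self._weight_row([wk for wk, v in zip(workers, voting) if v])
        return V @ w

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.where(s >= self.cutoff, ABNORMAL, NORMAL)

    def weight_vector(self) -> WeightVector:
        check_is_fitted(self, "weights_")
        return WeightVector(
            weights=self.weights_.to_dict(), truncation_bounds=self.truncation_bounds_
        )


def aggregate_votes(
    records: pd.DataFrame,
    weights: WeightVector | None = None,
    cutoff: float = 0.0,
    missing_weight: str = "error",
) -> pd.DataFrame:
    """Per-item consensus table from deduplicated grade records.

    Columns: ``item_id, n_votes, n_abnormal_votes, mv_label, weighted_score,
    thresholded_label``.  Without weights every vote counts 1.0, so the
    weighted score is the plain vote margin.
    """
    if records.duplicated(subset=["worker_id", "item_id"]).any():
        raise ValueError("duplicate (worker, item) grades; dedupe first")
    rows = []
    for item, grp in records.groupby("item_id", sort=True):
        votes = dict(zip(grp["worker_id"], grp["classification"]))
        n_abn = sum(v == ABNORMAL for v in votes.values())
        s = weighted_score(
            votes,
            weights if weights is not None else {},
            missing_weight="neutral" if weights is None else missing_weight,
        )
        rows.append(
            (
                item,
                len(votes),
                n_abn,
                mv_consensus(votes.values()),
                s,
                threshold_label(s, cutoff),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "item_id",
            "n_votes",
            "n_abnormal_votes",
            "mv_label",
            "weighted_score",
            "thresholded_label",
        ],
    )


def weights_frame(raw: pd.Series, truncated: WeightVector) -> pd.DataFrame:
    """Tabulate raw vs truncated weights for the weights CSV."""
    low, high = truncated.truncation_bounds
    trunc = pd.Series(truncated.weights)
    return pd.DataFrame(
        {
            "worker_id": raw.index,
            "raw_weight": raw.to_numpy(),
            "truncated_weight": trunc.reindex(raw.index).to_numpy(),
            "clamped": ((raw < low) | (raw > high)).to_numpy(),
        }
    )
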