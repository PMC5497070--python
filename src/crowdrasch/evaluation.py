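"""Diagnostic-accuracy evaluation of consensus rules against gold labels.

Everything here treats ``abnormal`` as the positive class and reports rates as
percents (a sensitivity of 90.3 means 90.3%).  Prevalence always comes from
the gold labels.

The ROC machinery is empirical: the AUROC is the Mann-Whitney probability
that a random positive scores above a random negative (ties counted one
half), its confidence interval and the paired comparison of two correlated
ROC curves use DeLong's placement-based variance estimator, and cut-points
are chosen by exhaustive sweep over the midpoints between adjacent distinct
scores (plus the two infinite extremes), so every reported operating point is
actually attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .consensus import WeightVector, ability_to_weight, truncate_weights, vote_matrix
from .data import ABNORMAL, NORMAL, build_correctness_matrix, prepare_truth
from .rasch import FitConfig, RaschJMLE


def _align(pred, gold) -> tuple[pd.Series, pd.Series]:
    p = pd.Series(dict(pred) if not isinstance(pred, pd.Series) else pred)
    g = pd.Series(dict(gold) if not isinstance(gold, pd.Series) else gold)
    if set(p.index) != set(g.index):
        raise ValueError("prediction and gold item sets differ")
    g = g.loc[p.index]
    return p, g


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts and percent rates of a binary classifier (positive = abnormal)."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    percent_correct: float
    sensitivity: float  # percent; NaN when gold has no abnormal items
    specificity: float  # percent; NaN when gold has no normal items


def confusion(pred, gold) -> ConfusionSummary:
    """Confusion counts and rates for label predictions against gold labels.

    When one gold class is absent the corresponding rate (sensitivity or
    specificity) is NaN, not zero.
    """
    p, g = _align(pred, gold)
    pos = g == ABNORMAL
    tp = int(((p == ABNORMAL) & pos).sum())
    fn = int(((p == NORMAL) & pos).sum())
    tn = int(((p == NORMAL) & ~pos).sum())
    fp = int(((p == ABNORMAL) & ~pos).sum())
    n = len(g)
    n_pos, n_neg = tp + fn, tn + fp
    return ConfusionSummary(
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        percent_correct=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / n_pos if n_pos else float("nan"),
        specificity=100.0 * tn / n_neg if n_neg else float("nan"),
    )


# ---------------------------------------------------------------------------
# DeLong machinery

def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of x (average rank over ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_placements(scores: np.ndarray, labels01: np.ndarray):
    """Per-sample placement values and AUROC for each score row.

    ``scores`` has shape (k, n); returns (aucs, v_pos (k, m), v_neg (k, n-m)).
    """
    pos = labels01 == 1
    m, n_neg = int(pos.sum()), int((~pos).sum())
    aucs = np.empty(scores.shape[0])
    v_pos = np.empty((scores.shape[0], m))
    v_neg = np.empty((scores.shape[0], n_neg))
    for k, s in enumerate(scores):
        x, y = s[pos], s[~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[k] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n_neg)
        v_pos[k] = (tz[:m] - tx) / n_neg
        v_neg[k] = 1.0 - (tz[m:] - ty) / m
    return aucs, v_pos, v_neg


def _delong_cov(v_pos: np.ndarray, v_neg: np.ndarray) -> np.ndarray:
    def _cov(v: np.ndarray) -> np.ndarray:
        k = v.shape[0]
        if v.shape[1] < 2:  # a single positive/negative: variance undefined
            return np.full((k, k), np.nan)
        return np.atleast_2d(np.cov(v))

    return _cov(v_pos) / v_pos.shape[1] + _cov(v_neg) / v_neg.shape[1]


@dataclass
class RocResult:
    """Empirical ROC curve with a DeLong 95% interval for the AUROC."""

    points: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    auroc: float
    ci_low: float
    ci_high: float
    method: str = "empirical"


def _scores_gold(scores, gold) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    s, g = _align(scores, gold)
    y01 = (g == ABNORMAL).to_numpy().astype(int)
    if y01.sum() == 0 or y01.sum() == len(y01):
        raise ValueError("both gold classes must be present for ROC analysis")
    return s.to_numpy(dtype=float), y01, s.index


def auroc(scores, gold, alpha: float = 0.05) -> RocResult:
    """Empirical ROC and AUROC with a DeLong confidence interval.

    ``scores`` maps item -> continuous score (higher = more abnormal); gold
    maps item -> label.  AUROC is the tie-corrected Mann-Whitney statistic.
    """
    from sklearn.metrics import roc_curve

    s, y01, _ = _scores_gold(scores, gold)
    fpr, tpr, _ = roc_curve(y01, s)
    aucs, v_pos, v_neg = _delong_placements(s[None, :], y01)
    var = float(_delong_cov(v_pos, v_neg)[0, 0])
    auc = float(aucs[0])
    if np.isfinite(var):
        half = norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    else:  # a single case in one class: no variance information
        lo, hi = 0.0, 1.0
    return RocResult(
        points=np.column_stack([fpr, tpr]), auroc=auc, ci_low=lo, ci_high=hi
    )


@dataclass(frozen=True)
class DeLongComparison:
    """Paired test of two correlated AUROCs (chi-square, 1 df)."""

    chi_square: float
    p_value: float
    auroc_a: float
    auroc_b: float
    applicable: bool = True


def compare_auroc(scores_a, scores_b, gold) -> DeLongComparison:
    """DeLong paired chi-square test for two score sets on the same items.

    Symmetric in its arguments.  Identical score vectors give chi-square 0
    and p = 1; a degenerate variance with unequal AUROCs is reported as
    not applicable (NaN statistic) rather than a spurious infinity.
    """
    a, g = _align(scores_a, gold)
    b, _ = _align(scores_b, gold)
    b = b.loc[a.index]
    y01 = (g == ABNORMAL).to_numpy().astype(int)
    if y01.sum() in (0, len(y01)):
        raise ValueError("both gold classes must be present")
    s = np.vstack([a.to_numpy(dtype=float), b.to_numpy(dtype=float)])
    aucs, v_pos, v_neg = _delong_placements(s, y01)
    cov = _delong_cov(v_pos, v_neg)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if not np.isfinite(var_diff):
        return DeLongComparison(
            float("nan"), float("nan"), float(aucs[0]), float(aucs[1]), applicable=False
        )
    if var_diff <= 1e-14:
        if abs(delta) <= 1e-12:
            return DeLongComparison(0.0, 1.0, float(aucs[0]), float(aucs[1]))
        return DeLongComparison(
            float("nan"), float("nan"), float(aucs[0]), float(aucs[1]), applicable=False
        )
    stat = delta**2 / var_diff
    return DeLongComparison(
        float(stat), float(chi2.sf(stat, df=1)), float(aucs[0]), float(aucs[1])
    )


# ---------------------------------------------------------------------------
# Logistic calibration

@dataclass
class CalibrationResult:
    """Univariate logistic mapping from consensus score to P(abnormal)."""

    intercept: float
    slope: float
    probabilities: pd.Series | None
    separated: bool = False
    converged: bool = True


def fit_logistic_calibration(scores, gold) -> CalibrationResult:
    """Maximum-likelihood logistic regression of gold on the consensus score.

    The fitted probabilities are a monotone transform of the score whenever
    the slope is positive, so their ROC coincides with the raw-score ROC; the
    value added is a probability scale and a continuous dial for cut-off
    selection.  Complete separation (scores perfectly split the classes) is
    flagged instead of fitted — the raw-score ROC remains valid.
    """
    import statsmodels.api as sm

    s, y01, index = _scores_gold(scores, gold)
    if s[y01 == 1].min() > s[y01 == 0].max() or s[y01 == 1].max() < s[y01 == 0].min():
        return CalibrationResult(
            intercept=float("nan"), slope=float("nan"), probabilities=None,
            separated=True, converged=False,
        )
    X = sm.add_constant(s)
    model = sm.Logit(y01, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception:
        return CalibrationResult(
            intercept=float("nan"), slope=float("nan"), probabilities=None,
            separated=True, converged=False,
        )
    probs = pd.Series(res.predict(X), index=index)
    return CalibrationResult(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        probabilities=probs,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


# ---------------------------------------------------------------------------
# Cut-point selection

CUTPOINT_CRITERIA = ("max_correct", "min_sensitivity", "min_specificity")


@dataclass(frozen=True)
class CutpointReport:
    """A chosen operating point on the consensus-score scale.

    ``auroc_at_cutpoint`` is the AUROC of the dichotomized classifier,
    (sensitivity + specificity) / 2, on the 0-1 scale.
    """

    criterion: str
    target: float | None
    chosen_cutoff: float
    summary: ConfusionSummary
    auroc_at_cutpoint: float


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf and +inf."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def select_cutpoint(
    scores, gold, criterion: str, target: float | None = None
) -> CutpointReport:
    """Pick a decision threshold on the score by exhaustive candidate sweep.

    ``max_correct`` maximizes percent correctly classified (ties broken
    toward higher sensitivity, then the lower cutoff).  ``min_sensitivity``
    requires sensitivity >= ``target`` (a percent) and maximizes specificity
    among qualifying cutoffs; ``min_specificity`` is the mirror image.  The
    prediction rule is abnormal iff score >= cutoff.

    Raises
    ------
    ValueError
        If the target is unattainable; the message names the best achievable
        value.
    """
    if criterion not in CUTPOINT_CRITERIA:
        raise ValueError(f"criterion must be one of {CUTPOINT_CRITERIA}")
    if criterion != "max_correct" and target is None:
        raise ValueError(f"criterion {criterion!r} needs a target percent")
    s, y01, _ = _scores_gold(scores, gold)
    n_pos, n_neg = int(y01.sum()), int(len(y01) - y01.sum())
    cands = candidate_cutoffs(s)
    sens = np.array([100.0 * ((s >= c) & (y01 == 1)).sum() / n_pos for c in cands])
    spec = np.array([100.0 * ((s < c) & (y01 == 0)).sum() / n_neg for c in cands])
    correct = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)

    if criterion == "max_correct":
        # lexicographic: percent correct, then sensitivity, then lower cutoff
        order = np.lexsort((cands, -sens, -correct))
        best = order[0]
    elif criterion == "min_sensitivity":
        ok = sens >= target
        if not ok.any():
            raise ValueError(
                f"no cutoff reaches sensitivity {target}%; "
                f"best achievable is {sens.max():.1f}%"
            )
        order = np.lexsort((cands, -sens, -np.where(ok, spec, -np.inf)))
        best = order[0]
    else:
        ok = spec >= target
        if not ok.any():
            raise ValueError(
                f"no cutoff reaches specificity {target}%; "
                f"best achievable is {spec.max():.1f}%"
            )
        order = np.lexsort((cands, -spec, -np.where(ok, sens, -np.inf)))
        best = order[0]

    c = cands[best]
    pred = pd.Series(
        np.where(s >= c, ABNORMAL, NORMAL), index=_align(scores, gold)[0].index
    )
    summary = confusion(pred, gold)
    return CutpointReport(
        criterion=criterion,
        target=target,
        chosen_cutoff=float(c),
        summary=summary,
        auroc_at_cutpoint=(summary.sensitivity + summary.specificity) / 200.0,
    )


# ---------------------------------------------------------------------------
# Jackknife cross-validation

@dataclass(frozen=True)
class JackknifeConfig:
    """Controls for leave-one-item-out scoring.

    ``weight_mode='rasch'`` refits worker weights with each item excluded
    (warm-started from the full-data fit); ``'uniform'`` gives every worker
    weight 1, in which case the jackknife reduces to the naive vote margin.
    """

    weight_mode: str = "rasch"
    truncation_centiles: tuple[float, float] = (1.0, 99.0)
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.weight_mode not in ("rasch", "uniform"):
            raise ValueError("weight_mode must be 'rasch' or 'uniform'")


@dataclass
class JackknifeResult:
    roc: RocResult
    scores: pd.Series
    n_replicates: int
    n_nonconverged: int


def jackknife_auroc(
    records: pd.DataFrame, truth: pd.DataFrame, config: JackknifeConfig | None = None
) -> JackknifeResult:
    """Leave-one-item-out weighted-consensus AUROC.

    For each item, worker weights come from a Rasch fit on the correctness
    matrix with that item's column removed, and the item's weighted score is
    computed from those weights; the AUROC is taken over the held-out scores.
    A replicate that fails to converge is flagged and that item falls back to
    full-data weights.
    """
    cfg = config or JackknifeConfig()
    truth = prepare_truth(truth)
    gold = truth.set_index("item_id")["gold"]
    cm = build_correctness_matrix(records, truth)
    items = cm.items
    if len(items) < 3:
        raise ValueError("jackknife needs at least 3 items")
    V = vote_matrix(records, workers=cm.workers, items=items).to_numpy()
    low, high = cfg.truncation_centiles

    if cfg.weight_mode == "uniform":
        scores = pd.Series(V.sum(axis=1), index=items, dtype=float)
        return JackknifeResult(
            roc=auroc(scores, gold.loc[items]),
            scores=scores,
            n_replicates=len(items),
            n_nonconverged=0,
        )

    def _make(tol):
        return RaschJMLE(
            tol=tol,
            max_iter=cfg.fit.max_iter,
            extreme_score_adjust=cfg.fit.extreme_score_adjust,
            centering=cfg.fit.centering,
        )

    full = _make(cfg.fit.tol).fit(cm)
    full_weights = _full_weight_array(full.worker_measures_, low, high)

    n_w = len(cm.workers)
    scores = np.empty(len(items))
    n_bad = 0
    for j in range(len(items)):
        sub = np.delete(cm.values, j, axis=1)
        keep_w = ~np.isnan(sub).all(axis=1)
        est = _make(cfg.fit.tol)
        try:
            est.fit(
                sub[keep_w],
                warm_start_measures=(
                    full.worker_measures_[keep_w],
                    np.delete(full.item_measures_, j),
                ),
            )
            ok = est.converged_
        except ValueError:
            ok = False
        if ok:
            w = np.ones(n_w)  # neutral for workers dropped from the refit
            w[keep_w] = _full_weight_array(est.worker_measures_, low, high)
        else:
            n_bad += 1
            w = full_weights
        scores[j] = V[j] @ w
    score_series = pd.Series(scores, index=items)
    return JackknifeResult(
        roc=auroc(score_series, gold.loc[items]),
        scores=score_series,
        n_replicates=len(items),
        n_nonconverged=n_bad,
    )


def _full_weight_array(measures: np.ndarray, low: float, high: float) -> np.ndarray:
    raw = ability_to_weight(measures)
    wv = truncate_weights(dict(enumerate(raw)), low, high)
    return np.array([wv.weights[k] for k in range(len(raw))])


def evaluation_frame(rows: list[tuple]) -> pd.DataFrame:
    """Assemble a metric,value,ci_low,ci_high report table."""
    return pd.DataFrame(rows, columns=["metric", "value", "ci_low", "ci_high"])


def roc_points_frame(roc: RocResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "false_positive_rate": roc.points[:, 0],
            "sensitivity": roc.points[:, 1],
        }
    )
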