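"""Joint maximum-likelihood estimation of the dichotomous Rasch model.

The model: the probability that worker ``i`` (ability measure ``D_i``, in
logits) grades item ``n`` (difficulty measure ``B_n``, in logits) correctly is

    P_ni = exp(B_n - D_i) / (1 + exp(B_n - D_i))

Sign conventions follow the screening application: a *higher* ``B_n`` means an
easier item, a *lower* ``D_i`` a more skilled worker (the most skilled graders
sit at strongly negative measures).  ``exp(-D_i)`` is then the odds that the
worker classifies an item of average difficulty (``B_n = 0``) correctly, which
is what downstream vote weighting uses.

Estimation is plain JMLE: alternating per-parameter Newton-Raphson on the
marginal-score estimating equations (observed marginal = expected marginal),
the algorithm of the Winsteps/Facets family.  Missing cells contribute nothing
to the likelihood (missing-at-random by task assignment).  Perfect and zero
marginal scores, which have no finite MLE, are pulled in by a fractional-score
adjustment before estimation.  JMLE's known small-sample bias (order 1/L for L
responses) is documented, not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import expit
from sklearn.base import BaseEstimator

from .data import CorrectnessMatrix

CENTERING_MODES = ("worker_mean_zero", "worker_median_zero", "item_mean_zero")


def rasch_probability(b, d):
    """Probability of a correct response: expit(B_n - D_i).

    Accepts scalars or broadcastable arrays; saturates smoothly at extreme
    arguments.
    """
    return expit(np.asarray(b, dtype=float) - np.asarray(d, dtype=float))


@dataclass(frozen=True)
class FitConfig:
    """Estimation controls for :func:`fit_rasch`.

    tol: convergence tolerance, applied to both the largest measure update
        and the largest marginal residual (logits / score points).
    max_iter: iteration cap for the alternating Newton sweeps.
    extreme_score_adjust: fractional score pulled in from perfect/zero
        marginals (0.3 score points is the convention of the Winsteps family).
    centering: which facet is anchored and how; a pure location shift that
        cancels in weight ratios but not raw weights, so record it.
    """

    tol: float = 0.005
    max_iter: int = 200
    extreme_score_adjust: float = 0.3
    centering: str = "worker_mean_zero"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.extreme_score_adjust < 0.5:
            raise ValueError("extreme_score_adjust must be in (0, 0.5)")
        if self.centering not in CENTERING_MODES:
            raise ValueError(f"centering must be one of {CENTERING_MODES}")


@dataclass
class RaschFit:
    """Fitted worker and item measures, in logits, with diagnostics."""

    worker_measures: dict
    item_measures: dict
    worker_se: dict
    item_se: dict
    n_iterations: int
    converged: bool
    max_residual: float
    extreme_adjusted_workers: frozenset = frozenset()
    extreme_adjusted_items: frozenset = frozenset()
    n_connected_components: int = 1
    worker_n_observed: dict = field(default_factory=dict)
    item_n_observed: dict = field(default_factory=dict)
    config: FitConfig = field(default_factory=FitConfig)


class RaschJMLE(BaseEstimator):
    """Dichotomous Rasch model fitted by joint maximum likelihood.

    Parameters mirror :class:`FitConfig`.  ``fit`` takes a worker x item
    response array with entries 1 (correct), 0 (incorrect) or NaN (not
    graded), or a :class:`~crowdrasch.data.CorrectnessMatrix`.

    Attributes
    ----------
    worker_measures_ : ndarray of shape (n_workers,)
        Ability measures D_i in logits (lower = more skilled).
    item_measures_ : ndarray of shape (n_items,)
        Difficulty measures B_n in logits (lower = harder).
    worker_se_, item_se_ : ndarray
        Asymptotic standard errors, 1/sqrt(information).
    n_iter_ : int
    converged_ : bool
    max_residual_ : float
        Largest |expected - observed| marginal score at exit.
    """

    def __init__(
        self,
        tol: float = 0.005,
        max_iter: int = 200,
        extreme_score_adjust: float = 0.3,
        centering: str = "worker_mean_zero",
    ) -> None:
        self.tol = tol
        self.max_iter = max_iter
        self.extreme_score_adjust = extreme_score_adjust
        self.centering = centering

    def _config(self) -> FitConfig:
        return FitConfig(
            tol=self.tol,
            max_iter=self.max_iter,
            extreme_score_adjust=self.extreme_score_adjust,
            centering=self.centering,
        )

    def fit(self, X, y=None, warm_start_measures=None):
        """Estimate worker and item measures from a correctness matrix.

        ``warm_start_measures``, if given, is a ``(worker_measures,
        item_measures)`` pair used to initialize the sweeps — useful for
        jackknife refits.
        """
        cfg = self._config()
        if isinstance(X, CorrectnessMatrix):
            self.worker_ids_ = list(X.workers)
            self.item_ids_ = list(X.items)
            X = X.values
        else:
            X = np.asarray(X, dtype=float)
            self.worker_ids_ = list(range(X.shape[0]))
            self.item_ids_ = list(range(X.shape[1]))
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >=2 workers and >=2 items")
        obs = ~np.isnan(X)
        if not (obs.any(axis=1).all() and obs.any(axis=0).all()):
            raise ValueError("every worker and item needs >=1 observed cell")
        vals = np.where(obs, X, 0.0)
        if not np.isin(vals[obs], (0.0, 1.0)).all():
            raise ValueError("observed cells must be 0 or 1")

        n_w, n_i = X.shape
        w_count = obs.sum(axis=1).astype(float)
        i_count = obs.sum(axis=0).astype(float)
        w_score = vals.sum(axis=1)
        i_score = vals.sum(axis=0)

        adj = cfg.extreme_score_adjust
        w_extreme = (w_score == 0) | (w_score == w_count)
        i_extreme = (i_score == 0) | (i_score == i_count)
        # Pull extreme marginals in by `adj` score points, spreading the change
        # over the row's (then column's) observed cells, so that worker and
        # item targets remain marginals of one adjusted matrix — otherwise the
        # two estimating-equation sets disagree on the total score and JMLE
        # cannot drive both residual sets to zero.
        frac = obs.astype(float)
        delta_w = np.clip(w_score, adj, w_count - adj) - w_score
        adj_vals = vals + frac * (delta_w / w_count)[:, None]
        col_sum = adj_vals.sum(axis=0)
        delta_i = np.clip(col_sum, adj, i_count - adj) - col_sum
        adj_vals = adj_vals + frac * (delta_i / i_count)[None, :]
        w_target = adj_vals.sum(axis=1)
        i_target = adj_vals.sum(axis=0)

        # measures are only relatively identified within a connected component
        # of the worker-item bipartite graph
        rows, cols = np.nonzero(obs)
        graph = csr_matrix(
            (np.ones(rows.size), (rows, cols + n_w)), shape=(n_w + n_i, n_w + n_i)
        )
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp > 1:
            warnings.warn(
                f"correctness matrix splits into {n_comp} disconnected blocks; "
                "measures are comparable only within a block",
                UserWarning,
                stacklevel=2,
            )

        if warm_start_measures is not None:
            D = np.asarray(warm_start_measures[0], dtype=float).copy()
            B = np.asarray(warm_start_measures[1], dtype=float).copy()
        else:
            # logit of the (adjusted) proportion correct as a starting point
            D = -np.log(w_target / (w_count - w_target))
            B = np.log(i_target / (i_count - i_target))

        converged = False
        max_resid = np.inf
        for it in range(1, cfg.max_iter + 1):
            P = expit(B[None, :] - D[:, None])
            PQ = P * (1.0 - P)
            exp_w = np.where(obs, P, 0.0).sum(axis=1)
            info_w = np.where(obs, PQ, 0.0).sum(axis=1)
            step_w = np.clip((exp_w - w_target) / info_w, -1.0, 1.0)
            D = D + step_w

            P = expit(B[None, :] - D[:, None])
            PQ = P * (1.0 - P)
            exp_i = np.where(obs, P, 0.0).sum(axis=0)
            info_i = np.where(obs, PQ, 0.0).sum(axis=0)
            step_i = np.clip(-(exp_i - i_target) / info_i, -1.0, 1.0)
            B = B + step_i

            if cfg.centering == "worker_mean_zero":
                shift = D.mean()
            elif cfg.centering == "worker_median_zero":
                shift = np.median(D)
            else:
                shift = B.mean()
            D -= shift
            B -= shift

            P = expit(B[None, :] - D[:, None])
            resid_w = np.abs(np.where(obs, P, 0.0).sum(axis=1) - w_target).max()
            resid_i = np.abs(np.where(obs, P, 0.0).sum(axis=0) - i_target).max()
            max_resid = max(resid_w, resid_i)
            max_step = max(np.abs(step_w).max(), np.abs(step_i).max())
            if max_step < cfg.tol and max_resid < cfg.tol:
                converged = True
                break

        P = expit(B[None, :] - D[:, None])
        PQ = np.where(obs, P * (1.0 - P), 0.0)
        self.worker_measures_ = D
        self.item_measures_ = B
        self.worker_se_ = 1.0 / np.sqrt(PQ.sum(axis=1))
        self.item_se_ = 1.0 / np.sqrt(PQ.sum(axis=0))
        self.n_iter_ = it
        self.converged_ = converged
        self.max_residual_ = float(max_resid)
        self.extreme_workers_ = w_extreme
        self.extreme_items_ = i_extreme
        self.n_connected_components_ = int(n_comp)
        self.n_observed_worker_ = w_count.astype(int)
        self.n_observed_item_ = i_count.astype(int)
        if not converged:
            warnings.warn(
                f"JMLE did not converge in {cfg.max_iter} iterations "
                f"(max residual {max_resid:.4g})",
                UserWarning,
                stacklevel=2,
            )
        return self

    def to_fit(self) -> RaschFit:
        """Package fitted attributes as a :class:`RaschFit`."""
        return RaschFit(
            worker_measures=dict(zip(self.worker_ids_, self.worker_measures_)),
            item_measures=dict(zip(self.item_ids_, self.item_measures_)),
            worker_se=dict(zip(self.worker_ids_, self.worker_se_)),
            item_se=dict(zip(self.item_ids_, self.item_se_)),
            n_iterations=self.n_iter_,
            converged=self.converged_,
            max_residual=self.max_residual_,
            extreme_adjusted_workers=frozenset(
                w for w, e in zip(self.worker_ids_, self.extreme_workers_) if e
            ),
            extreme_adjusted_items=frozenset(
                i for i, e in zip(self.item_ids_, self.extreme_items_) if e
            ),
            n_connected_components=self.n_connected_components_,
            worker_n_observed=dict(zip(self.worker_ids_, self.n_observed_worker_)),
            item_n_observed=dict(zip(self.item_ids_, self.n_observed_item_)),
            config=self._config(),
        )


def fit_rasch(matrix: CorrectnessMatrix, config: FitConfig | None = None) -> RaschFit:
    """Fit the Rasch model on a correctness matrix; thin estimator wrapper."""
    cfg = config or FitConfig()
    est = RaschJMLE(
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        extreme_score_adjust=cfg.extreme_score_adjust,
        centering=cfg.centering,
    )
    est.fit(matrix)
    return est.to_fit()


def worker_measure_quartiles(fit: RaschFit) -> tuple[float, float, float]:
    """Empirical quartiles (Q1, median, Q3) of the worker ability measures."""
    values = np.fromiter(fit.worker_measures.values(), dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def rank_items_by_difficulty(fit: RaschFit) -> list[tuple]:
    """Items sorted hardest first (ascending measure), ties broken by id."""
    return sorted(fit.item_measures.items(), key=lambda kv: (kv[1], str(kv[0])))


def fit_results_frame(fit: RaschFit):
    """Tabulate measures for the fit-results CSV."""
    import pandas as pd

    rows = []
    for wid, m in fit.worker_measures.items():
        rows.append(
            (
                "worker",
                wid,
                m,
                fit.worker_se[wid],
                fit.worker_n_observed.get(wid),
                wid in fit.extreme_adjusted_workers,
            )
        )
    for iid, m in fit.item_measures.items():
        rows.append(
            (
                "item",
                iid,
                m,
                fit.item_se[iid],
                fit.item_n_observed.get(iid),
                iid in fit.extreme_adjusted_items,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "entity_type",
            "id",
            "measure_logits",
            "se_logits",
            "n_observed",
            "extreme_adjusted",
        ],
    )
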