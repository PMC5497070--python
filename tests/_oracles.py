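"""Independent oracles for the test suite.

These deliberately avoid the code paths they check: the Rasch oracle is a
coarse-to-fine coordinate *grid search* over the joint log-likelihood (no
Newton steps, no marginal-matching), the AUROC oracle is the O(n^2)
concordant-pair count, and the cut-point oracle is a plain loop over every
candidate threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def rasch_loglik(D: np.ndarray, B: np.ndarray, X: np.ndarray) -> float:
    """Joint Bernoulli log-likelihood of a (possibly incomplete) 0/1 matrix."""
    P = expit(B[None, :] - D[:, None])
    obs = ~np.isnan(X)
    with np.errstate(divide="ignore"):
        ll = np.where(X == 1, np.log(P), np.log1p(-P))
    return float(np.where(obs, ll, 0.0).sum())


def grid_search_rasch(
    X: np.ndarray, coarse_step: float = 0.5, final_step: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the joint log-likelihood by coordinate-wise grid refinement.

    Each parameter in turn is moved to the best point on a local lattice of
    the current step size; when a full sweep changes nothing, the lattice is
    refined.  Returns worker-mean-centered (D, B).
    """
    n_w, n_i = X.shape
    D = np.zeros(n_w)
    B = np.zeros(n_i)
    step = coarse_step
    offsets = np.arange(-4, 5)  # +/- 4 lattice points around the current value
    while step >= final_step:
        for _ in range(200):
            moved = False
            for w in range(n_w):
                cand = D[w] + step * offsets
                lls = []
                for c in cand:
                    Dt = D.copy()
                    Dt[w] = c
                    lls.append(rasch_loglik(Dt, B, X))
                best = cand[int(np.argmax(lls))]
                if best != D[w]:
                    D[w] = best
                    moved = True
            for i in range(n_i):
                cand = B[i] + step * offsets
                lls = []
                for c in cand:
                    Bt = B.copy()
                    Bt[i] = c
                    lls.append(rasch_loglik(D, Bt, X))
                best = cand[int(np.argmax(lls))]
                if best != B[i]:
                    B[i] = best
                    moved = True
            if not moved:
                break
        step /= 5.0
    shift = D.mean()
    return D - shift, B - shift


def auroc_pair_count(scores: np.ndarray, gold01: np.ndarray) -> float:
    """Mann-Whitney AUROC by exhaustive pair enumeration (ties count 1/2)."""
    pos = scores[gold01 == 1]
    neg = scores[gold01 == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def sweep_cutoffs(scores: np.ndarray, gold01: np.ndarray):
    """Evaluate every candidate cutoff (midpoints plus infinities).

    Returns a list of (cutoff, sensitivity%, specificity%, percent_correct)
    with the rule: predict abnormal iff score >= cutoff.
    """
    u = np.unique(scores)
    cands = [-np.inf] + list((u[:-1] + u[1:]) / 2.0) + [np.inf]
    n_pos = int(gold01.sum())
    n_neg = len(gold01) - n_pos
    rows = []
    for c in cands:
        pred = scores >= c
        tp = int((pred & (gold01 == 1)).sum())
        tn = int((~pred & (gold01 == 0)).sum())
        rows.append(
            (
                c,
                100.0 * tp / n_pos,
                100.0 * tn / n_neg,
                100.0 * (tp + tn) / len(gold01),
            )
        )
    return rows
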