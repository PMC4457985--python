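"""Regression association of combined genotype scores with group membership.

Binary and baseline-category multinomial logistic regression with the score
as a single numeric predictor, fitted by Newton-Raphson on the full
likelihood with step-halving. Significance is assessed by the likelihood-
ratio test against the intercept-only model (chi-square with one degree of
freedom per tested slope), which behaves better than Wald tests at the
n ~ 30-per-group scale these cohorts have.

The multinomial fit also emits pairwise contrasts — each non-reference level
against the reference, as binary fits on the corresponding sample subsets —
mirroring the group-vs-group score comparisons reported in this kind of
study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .combo_score import ComboScore

__all__ = [
    "ScoreAssociationResult",
    "fit_binary_logistic",
    "fit_multinomial_logistic",
]

_MAX_ITER = 100
_LL_TOL = 1e-12
_STEP_TOL = 1e-10
_SEPARATION_BOUND = 10.0  # |slope| beyond this ~ perfect separation


@dataclass
class ScoreAssociationResult:
    """Fitted score-group association.

    ``coefficients`` maps each non-reference outcome label to its
    (intercept, slope) pair in log-odds units relative to the reference
    level. ``p_value`` is the omnibus likelihood-ratio p against the
    intercept-only model.
    """

    model: str
    outcome_labels: list[str]
    reference: str
    coefficients: dict[str, tuple[float, float]]
    log_likelihood: float
    null_log_likelihood: float
    lrt_stat: float
    df: int
    p_value: float
    converged: bool
    n: int
    contrasts: dict[str, "ScoreAssociationResult"] = field(default_factory=dict)


def _align(scores: Sequence[ComboScore] | Sequence[float], outcome) -> tuple[np.ndarray, list]:
    """Pair scores with outcome labels; drops unscored samples."""
    if len(scores) and isinstance(scores[0], ComboScore):
        if isinstance(outcome, Mapping) or hasattr(outcome, "get"):
            pairs = [
                (cs.score, outcome.get(cs.sample_id))
                for cs in scores
                if cs.score is not None and outcome.get(cs.sample_id) is not None
            ]
        else:
            pairs = [
                (cs.score, lab)
                for cs, lab in zip(scores, outcome)
                if cs.score is not None and lab is not None
            ]
    else:
        pairs = [(s, lab) for s, lab in zip(scores, outcome) if lab is not None]
    if not pairs:
        raise ValueError("no scored samples with outcome labels")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = [p[1] for p in pairs]
    return x, y


def _softmax_fit(x: np.ndarray, codes: np.ndarray, n_levels: int):
    """Newton-Raphson MLE of the baseline-category logit model.

    Parameters are (intercept, slope) per non-reference level; the reference
    level's linear predictor is fixed at zero. Returns (beta, ll, converged).
    """
    n = len(x)
    X = np.column_stack([np.ones(n), x])  # n x 2
    L = n_levels
    P_DIM = 2 * (L - 1)
    # one-hot for non-reference levels (reference coded 0)
    Y = np.zeros((n, L - 1))
    for l in range(1, L):
        Y[:, l - 1] = codes == l
    beta = np.zeros((L - 1, 2))
    # start intercepts at the empirical log-odds vs reference
    counts = np.bincount(codes, minlength=L).astype(float)
    beta[:, 0] = np.log(np.maximum(counts[1:], 0.5) / np.maximum(counts[0], 0.5))

    def loglik_and_probs(b):
        eta = X @ b.T  # n x (L-1)
        denom = 1.0 + np.exp(eta).sum(axis=1)
        ll = (Y * eta).sum() - np.log(denom).sum()
        P = np.exp(eta) / denom[:, None]  # n x (L-1)
        return ll, P

    ll, P = loglik_and_probs(beta)
    converged = False
    for _ in range(_MAX_ITER):
        grad = (X.T @ (Y - P)).T.ravel()  # (L-1, 2) row-major
        H = np.zeros((P_DIM, P_DIM))
        for l in range(L - 1):
            for m in range(L - 1):
                w = P[:, l] * ((l == m) - P[:, m])
                H[2 * l : 2 * l + 2, 2 * m : 2 * m + 2] = -(X.T * w) @ X
        try:
            step = np.linalg.solve(H, -grad).reshape(L - 1, 2)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, P_new = loglik_and_probs(cand)
            if ll_new >= ll - 1e-13:
                break
            scale /= 2.0
        beta, delta_ll, ll, P = cand, ll_new - ll, ll_new, P_new
        if abs(delta_ll) < _LL_TOL or np.max(np.abs(scale * step)) < _STEP_TOL:
            converged = True
            break
    return beta, ll, converged


def _null_loglik(codes: np.ndarray, n_levels: int) -> float:
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    n = counts.sum()
    nz = counts[counts > 0]
    return float((nz * np.log(nz / n)).sum())


def _fit(
    x: np.ndarray, labels: list, reference, model_name: str, with_contrasts: bool = False
) -> ScoreAssociationResult:
    levels = sorted(set(labels), key=str)
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among outcomes {levels}")
    ordered = [reference] + [l for l in levels if l != reference]
    L = len(ordered)
    if L < 2:
        raise ValueError("outcome has a single class; association is undefined")
    code_of = {lab: i for i, lab in enumerate(ordered)}
    codes = np.array([code_of[l] for l in labels])
    counts = np.bincount(codes, minlength=L)
    if (counts == 0).any():
        empty = [ordered[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"outcome level(s) with no samples: {empty}")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")

    ll0 = _null_loglik(codes, L)
    if np.ptp(x) == 0:
        # constant predictor: slopes are not identified, model equals the null
        coeffs = {
            lab: (float(np.log(counts[code_of[lab]] / counts[0])), 0.0) for lab in ordered[1:]
        }
        result = ScoreAssociationResult(
            model=model_name,
            outcome_labels=ordered,
            reference=reference,
            coefficients=coeffs,
            log_likelihood=ll0,
            null_log_likelihood=ll0,
            lrt_stat=0.0,
            df=L - 1,
            p_value=1.0,
            converged=True,
            n=len(x),
        )
    else:
        beta, ll, converged = _softmax_fit(x, codes, L)
        if np.max(np.abs(beta[:, 1])) > _SEPARATION_BOUND:
            warnings.warn(
                "outcome (quasi-)separated by score; slope estimate diverges, "
                "likelihood-ratio p reported at the boundary"
            )
            converged = False
        lrt = max(0.0, 2.0 * (ll - ll0))
        df = L - 1
        p = max(float(chi2.sf(lrt, df)), np.finfo(float).tiny)
        coeffs = {lab: (float(beta[code_of[lab] - 1, 0]), float(beta[code_of[lab] - 1, 1]))
                  for lab in ordered[1:]}
        result = ScoreAssociationResult(
            model=model_name,
            outcome_labels=ordered,
            reference=reference,
            coefficients=coeffs,
            log_likelihood=float(ll),
            null_log_likelihood=ll0,
            lrt_stat=float(lrt),
            df=df,
            p_value=p,
            converged=converged,
            n=len(x),
        )

    if with_contrasts and L > 2:
        for lab in ordered[1:]:
            mask = np.array([l in (reference, lab) for l in labels])
            sub_labels = [l for l in labels if l in (reference, lab)]
            result.contrasts[lab] = _fit(x[mask], sub_labels, reference, "binary")
    return result


def fit_binary_logistic(
    scores: Sequence[ComboScore] | Sequence[float], outcome
) -> ScoreAssociationResult:
    """Binary logistic regression of a two-level outcome on the score.

    ``outcome`` is a mapping sample_id -> label (when ``scores`` are
    ComboScore records) or a label sequence aligned with ``scores``. The
    p-value is the likelihood-ratio test of the slope (df = 1).
    """
    x, labels = _align(scores, outcome)
    if len(set(labels)) != 2:
        raise ValueError(f"binary outcome must have exactly 2 classes, got {sorted(set(labels), key=str)}")
    return _fit(x, labels, None, "binary")


def fit_multinomial_logistic(
    scores: Sequence[ComboScore] | Sequence[float], outcome, reference=None
) -> ScoreAssociationResult:
    """Baseline-category multinomial logistic regression on the score.

    Emits the omnibus likelihood-ratio p (df = levels - 1) plus per-level
    binary contrasts against the reference. With a two-level outcome this
    reduces exactly to :func:`fit_binary_logistic`.
    """
    x, labels = _align(scores, outcome)
    return _fit(x, labels, reference, "multinomial", with_contrasts=True)
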