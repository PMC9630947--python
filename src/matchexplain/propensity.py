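"""Propensity-score estimators: logistic, single tree, bagged trees, external.

The propensity score e(Z) = P(T=1 | Z) is the probability of treatment given
confounders.  The logistic fit is maximum likelihood via iteratively
reweighted least squares with step-halving; the tree estimator scores each
subject by the treated fraction of its pruned terminal node; the forest-style
estimator averages leaf fractions over bootstrap trees with per-split feature
subsampling.  Scores from estimators this package does not implement (CBPS,
SVM, gradient-boosted weighting, ...) enter through :func:`external_scores`.

All emitted scores are clipped to [1e-6, 1 - 1e-6] so logit transforms are
always defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from matchexplain.cart_engine import (
    FittedTree,
    TreeControl,
    cross_validated_error,
    grow_tree,
    predict,
    prune,
)

__all__ = [
    "PropensityFit",
    "SCORE_EPS",
    "fit_logistic",
    "fit_tree_propensity",
    "fit_bagged_trees",
    "external_scores",
]

SCORE_EPS = 1e-6


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation detected during a logistic fit."""


@dataclass
class PropensityFit:
    method: str  # logistic | tree | forest | external
    scores: np.ndarray
    parameters: object = None  # coefficient array, FittedTree, list of trees
    converged: bool = True
    iterations: int = 0
    column_names: tuple[str, ...] = field(default_factory=tuple)


def _clip(scores: np.ndarray) -> np.ndarray:
    return np.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _check_groups(T: np.ndarray) -> None:
    if T.min() == T.max():
        raise ValueError("both treatment groups must be non-empty")


def fit_logistic(
    design: np.ndarray | pd.DataFrame,
    T: Sequence[int],
    max_iter: int = 50,
    tol: float = 1e-8,
    column_names: Sequence[str] | None = None,
) -> PropensityFit:
    """Maximum-likelihood logistic regression via IRLS with step-halving.

    An intercept column is prepended automatically.  Convergence is declared
    when every component of the score equation X'(T - p) is below ``tol`` in
    magnitude.  Diverging coefficients (perfect separation) produce a
    :class:`SeparationWarning` and clipped scores rather than an error;
    a rank-deficient design raises, naming the collinear columns.
    """
    if isinstance(design, pd.DataFrame):
        column_names = column_names or list(design.columns)
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    T = np.asarray(T, dtype=float)
    if design.ndim != 2 or design.shape[0] != T.size:
        raise ValueError("design rows must equal length of T")
    _check_groups(T)
    n, p = design.shape
    names = list(column_names) if column_names else [f"x{j}" for j in range(p)]
    X = np.column_stack([np.ones(n), design])

    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        # identify offending columns by greedy rank growth
        bad: list[str] = []
        kept = [0]
        for j in range(1, p + 1):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j - 1])
        raise ValueError(
            f"design matrix is rank-deficient; collinear column(s): {bad}"
        )

    beta = np.zeros(p + 1)
    eta = X @ beta
    mu = _expit(eta)
    loglik = float(T @ np.log(mu) + (1 - T) @ np.log(1 - mu))
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (T - mu) / w
        WX = X * w[:, None]
        try:
            step_beta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by rank check
            separated = True
            break
        # step-halving on likelihood decrease
        new_beta = step_beta
        for _ in range(25):
            new_eta = X @ new_beta
            new_mu = _expit(new_eta)
            with np.errstate(divide="ignore"):
                ll = float(
                    np.sum(np.where(T == 1, np.log(new_mu), np.log(1 - new_mu)))
                )
            if np.isfinite(ll) and ll >= loglik - 1e-12:
                break
            new_beta = 0.5 * (beta + new_beta)
        beta, eta, mu, loglik = new_beta, new_eta, new_mu, ll
        score = X.T @ (T - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        if np.linalg.norm(beta) > 1e4:
            separated = True
            break
    # quasi-perfect separation can "converge" with fitted probabilities
    # pinned to 0/1; linear predictors beyond +-20 are past any plausible
    # propensity and past the clipping bounds
    if np.max(np.abs(eta)) > 20:
        separated = True
    if separated or (not converged and np.linalg.norm(beta) > 1e3):
        warnings.warn(
            "perfect separation suspected: coefficients diverging; "
            "scores returned clipped",
            SeparationWarning,
            stacklevel=2,
        )
    return PropensityFit(
        method="logistic",
        scores=_clip(_expit(X @ beta)),
        parameters=beta,
        converged=converged,
        iterations=it,
        column_names=("(intercept)", *names),
    )


def fit_tree_propensity(
    cohort: pd.DataFrame,
    T: Sequence[int],
    control: TreeControl | None = None,
    covariate_columns: Sequence[str] | None = None,
) -> PropensityFit:
    """Classification-tree propensity scores, pruned at minimum CV error.

    Each subject's score is the treated fraction of its terminal node.  When
    no covariate separates treatment the tree is a root stump and every
    subject receives the overall treated fraction — the degenerate one-score
    outcome a diagnostic consumer should watch for.
    """
    control = control or TreeControl()
    T = np.asarray(T, dtype=np.int64)
    _check_groups(T)
    X = cohort[list(covariate_columns)] if covariate_columns else cohort
    full = grow_tree(X, T, control)
    if full.root.is_leaf:
        tree = full
    else:
        curve = cross_validated_error(X, T, control)
        tree = prune(full, curve.cp_at_min())
    probs, _, _ = predict(tree, X)
    return PropensityFit(
        method="tree",
        scores=_clip(probs),
        parameters=tree,
        converged=True,
        iterations=1,
        column_names=tuple(X.columns),
    )


def fit_bagged_trees(
    cohort: pd.DataFrame,
    T: Sequence[int],
    n_trees: int = 100,
    mtry: int | None = None,
    control: TreeControl | None = None,
    seed: int = 0,
    bootstrap: bool = True,
    covariate_columns: Sequence[str] | None = None,
) -> PropensityFit:
    """Bagged-tree (forest-style) propensity scores.

    Each tree is grown on a bootstrap resample considering a random
    ``mtry``-subset of covariates at every split; a subject's score is the
    mean over trees of its leaf's treated fraction.  Deterministic given
    ``seed``.  With ``n_trees=1``, ``mtry`` = all covariates and
    ``bootstrap=False`` this reduces to a single unpruned tree.
    """
    control = control or TreeControl()
    T = np.asarray(T, dtype=np.int64)
    _check_groups(T)
    X = cohort[list(covariate_columns)] if covariate_columns else cohort
    p = X.shape[1]
    mtry = p if mtry is None else mtry
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(X)
    total = np.zeros(n)
    trees: list[FittedTree] = []
    for _ in range(n_trees):
        rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        Xb = X.iloc[rows].reset_index(drop=True)
        yb = T[rows]
        if yb.min() == yb.max():  # degenerate resample: contributes the pool rate
            total += yb.mean()
            continue
        tree = grow_tree(Xb, yb, control, mtry=mtry, rng=rng)
        trees.append(tree)
        probs, _, _ = predict(tree, X)
        total += probs
    return PropensityFit(
        method="forest",
        scores=_clip(total / n_trees),
        parameters=trees,
        converged=True,
        iterations=n_trees,
        column_names=tuple(X.columns),
    )


def external_scores(
    path_or_frame, n: int, subject_ids: Sequence[int] | None = None
) -> PropensityFit:
    """Adopt externally computed scores from a (subject_id, score) CSV.

    The file must cover every subject exactly once; scores are clipped to
    the open unit interval.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    if not {"subject_id", "score"} <= set(df.columns):
        raise ValueError("external scores need columns subject_id, score")
    ids = np.asarray(subject_ids) if subject_ids is not None else np.arange(n)
    got = df["subject_id"].to_numpy()
    if len(df) != n or set(got.tolist()) != set(ids.tolist()):
        raise ValueError(
            f"external scores must cover every subject exactly once "
            f"({len(df)} rows for {n} subjects)"
        )
    ordered = df.set_index("subject_id").loc[ids, "score"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ordered)):
        raise ValueError("external scores contain non-finite values")
    return PropensityFit(method="external", scores=_clip(ordered))
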