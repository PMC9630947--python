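"""Binary classification trees with rpart-style cost-complexity pruning.

This engine backs two distinct uses: a propensity estimator (tree leaves as
score strata) and the population-level inclusion explainer.  It grows a
binary tree by exhaustive Gini-impurity search — midpoint cutpoints for
continuous covariates, level-subset bipartitions for categoricals — then
prunes by weakest-link cost-complexity: repeatedly collapse the internal
node whose per-leaf risk increase

    alpha = (R(node) - R(branch)) / (|branch leaves| - 1)

is smallest, with R the training misclassification risk as a fraction of all
training subjects.  The resulting (alpha, subtree) ladder is nested and the
alphas strictly increase; a complexity parameter cp selects the subtree
whose alpha-interval contains it.  cp is chosen at the minimum of a
stratified cross-validated misclassification curve.

The positive class is the inclusion label "in" throughout; inputs may use
"in"/"out" strings or 1/0.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeControl",
    "Split",
    "TreeNode",
    "FittedTree",
    "PruneSequence",
    "CVCurve",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "cost_complexity_sequence",
    "cross_validated_error",
    "prune",
    "predict_probability",
    "predict",
    "export_dot",
    "tree_to_json",
    "tree_from_json",
]

IN, OUT = "in", "out"


@dataclass(frozen=True)
class TreeControl:
    """Growth and pruning controls (defaults mirror rpart)."""

    minsplit: int = 20
    minbucket: int = 7
    cp_grow: float = 0.01
    maxdepth: int = 30
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if self.minsplit < 2 * self.minbucket:
            raise ValueError("minsplit must be >= 2 * minbucket")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.maxdepth < 0:
            raise ValueError("maxdepth must be >= 0")


@dataclass(frozen=True)
class Split:
    """One binary split: rows go left when the condition holds.

    Continuous: ``value < threshold``.  Categorical: ``value in left_levels``.
    """

    feature: str
    kind: str  # "continuous" | "categorical"
    threshold: float | None = None
    left_levels: tuple[str, ...] | None = None

    def describe(self) -> str:
        if self.kind == "continuous":
            return f"{self.feature} < {self.threshold:g}"
        return f"{self.feature} in {{{', '.join(self.left_levels)}}}"


@dataclass
class TreeNode:
    n_in: int
    n_out: int
    depth: int
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def n(self) -> int:
        return self.n_in + self.n_out

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def probability(self) -> float:
        return self.n_in / self.n

    @property
    def label(self) -> str:
        # ties go to "in": a subject we cannot separate is treated as matched
        return IN if self.n_in >= self.n_out else OUT

    @property
    def misclassified(self) -> int:
        return min(self.n_in, self.n_out)


@dataclass
class FittedTree:
    """A grown (or pruned) tree plus the training schema needed to predict."""

    root: TreeNode
    feature_names: tuple[str, ...]
    feature_kinds: dict[str, str]
    n_total: int
    degenerate: bool = False  # set when training labels had a single class
    feature_categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def risk(self) -> float:
        """Training misclassification risk, fraction of all training subjects."""
        return sum(leaf.misclassified for leaf in self.leaves()) / self.n_total


@dataclass
class PruneSequence:
    """Weakest-link ladder: ascending (alpha, subtree), ending in the stump."""

    alphas: list[float]
    subtrees: list[FittedTree]

    def subtree_for(self, cp: float) -> FittedTree:
        if cp < 0:
            raise ValueError("cp must be >= 0")
        k = 0
        for i, a in enumerate(self.alphas):
            if a <= cp:
                k = i
        return self.subtrees[k]


@dataclass
class CVCurve:
    """Cross-validated misclassification error along the cp ladder."""

    cps: np.ndarray
    errors: np.ndarray
    std_errors: np.ndarray
    alphas: np.ndarray

    def cp_at_min(self, one_se: bool = False) -> float:
        """cp minimizing CV error; ties -> largest cp (smallest tree).

        ``one_se=True`` returns the largest cp whose error is within one
        standard error of the minimum.
        """
        i_min = int(np.argmin(self.errors))
        best = self.errors[i_min]
        if one_se:
            cutoff = best + self.std_errors[i_min]
        else:
            cutoff = best
        admissible = np.flatnonzero(self.errors <= cutoff + 1e-12)
        return float(self.cps[admissible[-1]])


# --- label handling --------------------------------------------------------

def _as_binary(y: Sequence[Any]) -> np.ndarray:
    """Map labels to {1 = "in", 0 = "out"}; accepts strings or 0/1."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OU":
        vals = set(np.unique(arr).tolist())
        if not vals <= {IN, OUT}:
            raise ValueError(f"labels must be 'in'/'out', got {sorted(vals)!r}")
        return (arr == IN).astype(np.int64)
    out = arr.astype(np.int64)
    if not set(np.unique(out).tolist()) <= {0, 1}:
        raise ValueError("numeric labels must be 0/1")
    return out


# --- impurity --------------------------------------------------------------

def gini_impurity(counts: tuple[int, int]) -> float:
    """Gini impurity 1 - p^2 - (1-p)^2 of an (n_in, n_out) node."""
    n_in, n_out = counts
    if n_in < 0 or n_out < 0:
        raise ValueError("counts must be non-negative")
    n = n_in + n_out
    if n == 0:
        raise ValueError("empty node has no impurity")
    p = n_in / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


# --- split search ----------------------------------------------------------

# Exhaustive bipartition search is exact up to this many observed levels;
# beyond, levels are ordered by in-proportion and only prefix splits are
# scanned (the CART shortcut, exact for a binary outcome).
_EXHAUSTIVE_LEVEL_CAP = 12


@dataclass
class _Column:
    name: str
    kind: str
    values: np.ndarray           # float for continuous, int codes for categorical
    categories: tuple[str, ...] = ()


def _prepare_columns(X: pd.DataFrame) -> list[_Column]:
    cols: list[_Column] = []
    for name in X.columns:
        s = X[name]
        if isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(
                _Column(name, "categorical", np.asarray(s.cat.codes, dtype=np.int64),
                        tuple(str(c) for c in s.cat.categories))
            )
        elif s.dtype.kind in "OUb":
            cat = s.astype("category")
            cols.append(
                _Column(name, "categorical", np.asarray(cat.cat.codes, dtype=np.int64),
                        tuple(str(c) for c in cat.cat.categories))
            )
        else:
            cols.append(_Column(name, "continuous", np.asarray(s, dtype=float)))
    return cols


def _gini_from_counts(n_in: np.ndarray, n: np.ndarray) -> np.ndarray:
    p = n_in / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _search_continuous(
    v: np.ndarray, y: np.ndarray, minbucket: int
) -> tuple[float, float] | None:
    """Best (impurity decrease, cutpoint) for one continuous column, or None."""
    n = v.size
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    cum_in = np.cumsum(ys)
    total_in = int(cum_in[-1])
    # candidate boundaries between distinct adjacent values
    i = np.flatnonzero(vs[:-1] != vs[1:])
    if i.size == 0:
        return None
    n_left = i + 1
    ok = (n_left >= minbucket) & (n - n_left >= minbucket)
    i, n_left = i[ok], n_left[ok]
    if i.size == 0:
        return None
    in_left = cum_in[i]
    g_left = _gini_from_counts(in_left, n_left)
    g_right = _gini_from_counts(total_in - in_left, n - n_left)
    g_node = gini_impurity((total_in, n - total_in))
    decrease = g_node - (n_left * g_left + (n - n_left) * g_right) / n
    j = int(np.argmax(decrease))  # first max: smaller cutpoint wins ties
    return float(decrease[j]), float(0.5 * (vs[i[j]] + vs[i[j] + 1]))


def _search_categorical(
    codes: np.ndarray, y: np.ndarray, minbucket: int, n_categories: int
) -> tuple[float, np.ndarray] | None:
    """Best (impurity decrease, left-code boolean mask over all categories)."""
    n = codes.size
    cnt = np.bincount(codes, minlength=n_categories)
    cnt_in = np.bincount(codes, weights=y, minlength=n_categories)
    present = np.flatnonzero(cnt)
    L = present.size
    if L < 2:
        return None
    total_in = float(cnt_in.sum())
    g_node = gini_impurity((int(total_in), n - int(total_in)))
    if L <= _EXHAUSTIVE_LEVEL_CAP:
        # enumerate subsets of present[1:]; present[0] stays right, so each
        # bipartition appears exactly once, in deterministic mask order
        masks = np.arange(1, 1 << (L - 1), dtype=np.uint32)
        member = (masks[:, None] >> np.arange(L - 1, dtype=np.uint32)) & 1
        sub_cnt = member @ cnt[present[1:]]
        sub_in = member @ cnt_in[present[1:]]
    else:
        prop = cnt_in[present] / cnt[present]
        order = present[np.lexsort((present, prop))]
        sub_cnt = np.cumsum(cnt[order])[:-1]
        sub_in = np.cumsum(cnt_in[order])[:-1]
        member = None
    ok = (sub_cnt >= minbucket) & (n - sub_cnt >= minbucket)
    if not ok.any():
        return None
    g_left = _gini_from_counts(sub_in, np.maximum(sub_cnt, 1))
    g_right = _gini_from_counts(total_in - sub_in, np.maximum(n - sub_cnt, 1))
    decrease = np.where(
        ok, g_node - (sub_cnt * g_left + (n - sub_cnt) * g_right) / n, -np.inf
    )
    j = int(np.argmax(decrease))
    left_mask = np.zeros(n_categories, dtype=bool)
    if member is not None:
        left_mask[present[1:][member[j].astype(bool)]] = True
    else:
        left_mask[order[: j + 1]] = True
    return float(decrease[j]), left_mask


def _best_split_prepared(
    cols: list[_Column],
    idx: np.ndarray,
    y: np.ndarray,
    control: TreeControl,
    n_root: int,
    root_gini: float,
    feature_subset: np.ndarray | None = None,
) -> tuple[Split, np.ndarray] | None:
    """Best admissible split on the rows ``idx``; returns (split, left row mask)."""
    n = idx.size
    if n < control.minsplit or root_gini <= 0:
        return None
    y_node = y[idx]
    n_in = int(y_node.sum())
    if n_in == 0 or n_in == n:
        return None
    active = range(len(cols)) if feature_subset is None else feature_subset
    best: tuple[float, int, Split] | None = None
    for j in active:
        col = cols[j]
        v = col.values[idx]
        if col.kind == "continuous":
            found = _search_continuous(v, y_node, control.minbucket)
            if found is None:
                continue
            decrease, cut = found
            cand = Split(col.name, "continuous", threshold=cut)
        else:
            found = _search_categorical(
                v, y_node, control.minbucket, len(col.categories)
            )
            if found is None:
                continue
            decrease, left_mask = found
            cand = Split(
                col.name,
                "categorical",
                left_levels=tuple(
                    c for k, c in enumerate(col.categories) if left_mask[k]
                ),
            )
        if best is None or decrease > best[0] + 1e-15:
            best = (decrease, j, cand)
    if best is None:
        return None
    decrease, j, split = best
    rel_improvement = (n / n_root) * decrease / root_gini
    if rel_improvement < control.cp_grow:
        return None
    col = cols[j]
    v = col.values[idx]
    if split.kind == "continuous":
        left = v < split.threshold
    else:
        left_codes = {
            k for k, c in enumerate(col.categories) if c in split.left_levels
        }
        left = np.isin(v, list(left_codes))
    return split, left


def best_split(
    X: pd.DataFrame, y: Sequence[Any], control: TreeControl | None = None
) -> Split | None:
    """The admissible split maximizing weighted Gini decrease, or None.

    None when the node is pure, too small (< minsplit), no cutpoint
    respects minbucket, or the best relative improvement falls below
    ``cp_grow`` (improvement scaled by this node's own impurity).
    """
    control = control or TreeControl()
    yb = _as_binary(y)
    cols = _prepare_columns(X)
    idx = np.arange(len(X))
    n_in = int(yb.sum())
    if n_in == 0 or n_in == yb.size:
        return None
    root_gini = gini_impurity((n_in, yb.size - n_in))
    found = _best_split_prepared(cols, idx, yb, control, yb.size, root_gini)
    return None if found is None else found[0]


def grow_tree(
    X: pd.DataFrame,
    y: Sequence[Any],
    control: TreeControl | None = None,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> FittedTree:
    """Recursively grow a tree; depth <= maxdepth, all leaves >= minbucket.

    ``mtry`` restricts every split search to a random subset of that many
    covariates (forest-style growth); it requires ``rng``.
    """
    control = control or TreeControl()
    if mtry is not None and rng is None:
        raise ValueError("mtry requires an rng")
    yb = _as_binary(y)
    n = yb.size
    if n < control.minbucket:
        raise ValueError(
            f"cannot grow a tree on {n} rows with minbucket={control.minbucket}"
        )
    cols = _prepare_columns(X)
    n_in_root = int(yb.sum())
    degenerate = n_in_root == 0 or n_in_root == n
    root_gini = 0.0 if degenerate else gini_impurity((n_in_root, n - n_in_root))

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        n_in = int(yb[idx].sum())
        node = TreeNode(n_in=n_in, n_out=idx.size - n_in, depth=depth)
        if depth >= control.maxdepth:
            return node
        subset = None
        if mtry is not None and mtry < len(cols):
            subset = np.sort(rng.choice(len(cols), size=mtry, replace=False))
        found = _best_split_prepared(cols, idx, yb, control, n, root_gini, subset)
        if found is None:
            return node
        split, left = found
        node.split = split
        node.left = build(idx[left], depth + 1)
        node.right = build(idx[~left], depth + 1)
        return node

    root = build(np.arange(n), 0)
    return FittedTree(
        root=root,
        feature_names=tuple(X.columns),
        feature_kinds={c.name: c.kind for c in cols},
        n_total=n,
        degenerate=degenerate,
        feature_categories={
            c.name: c.categories for c in cols if c.kind == "categorical"
        },
    )


# --- pruning ---------------------------------------------------------------

def _branch_stats(node: TreeNode, n_total: int) -> tuple[float, int]:
    """(branch risk, leaf count) of the subtree rooted at ``node``."""
    if node.is_leaf:
        return node.misclassified / n_total, 1
    rl, ll = _branch_stats(node.left, n_total)
    rr, lr = _branch_stats(node.right, n_total)
    return rl + rr, ll + lr


def _weakest_alpha(node: TreeNode, n_total: int) -> float:
    r_branch, leaves = _branch_stats(node, n_total)
    return (node.misclassified / n_total - r_branch) / (leaves - 1)


_ALPHA_TOL = 1e-12


def _collapse_while(tree: FittedTree, threshold: float) -> None:
    """Collapse weakest links as long as their alpha is <= threshold."""
    while not tree.root.is_leaf:
        internal = [n for n in tree.nodes() if not n.is_leaf]
        gs = [_weakest_alpha(n, tree.n_total) for n in internal]
        hit = [n for n, g in zip(internal, gs) if g <= threshold + _ALPHA_TOL]
        if not hit:
            return
        for node in hit:
            if not node.is_leaf:
                node.split = None
                node.left = None
                node.right = None


def cost_complexity_sequence(tree: FittedTree) -> PruneSequence:
    """Weakest-link prune ladder from the full tree down to the root stump.

    The rung at alpha = 0 is the smallest subtree whose training risk equals
    the full tree's (splits that never change a majority label are already
    collapsed — they are cost-equivalent at cp = 0 and strictly worse for
    any cp > 0).  Each later rung collapses every internal node attaining
    the current minimal alpha; alphas strictly increase and subtrees nest.
    """
    current = copy.deepcopy(tree)
    _collapse_while(current, 0.0)
    alphas = [0.0]
    subtrees = [copy.deepcopy(current)]
    while not current.root.is_leaf:
        internal = [n for n in current.nodes() if not n.is_leaf]
        gs = [_weakest_alpha(n, current.n_total) for n in internal]
        g_min = min(gs)
        _collapse_while(current, g_min)
        if g_min <= alphas[-1] + _ALPHA_TOL:
            # cost-equivalent at the previous rung's alpha: keep the smaller
            subtrees[-1] = copy.deepcopy(current)
        else:
            alphas.append(g_min)
            subtrees.append(copy.deepcopy(current))
    return PruneSequence(alphas=alphas, subtrees=subtrees)


def prune(tree: FittedTree, cp: float) -> FittedTree:
    """Subtree of the weakest-link ladder whose alpha-interval contains cp."""
    return cost_complexity_sequence(tree).subtree_for(cp)


def cross_validated_error(
    X: pd.DataFrame, y: Sequence[Any], control: TreeControl | None = None
) -> CVCurve:
    """Stratified K-fold misclassification curve over the cp ladder.

    Candidate cps are the geometric midpoints of adjacent ladder alphas
    (0 below the first rung, the top alpha itself at the end), the rpart
    convention; errors are pooled over held-out folds with a binomial
    standard error.  Deterministic given ``control.seed``.
    """
    control = control or TreeControl()
    yb = _as_binary(y)
    n = yb.size
    if control.n_folds > n:
        raise ValueError("n_folds exceeds the number of subjects")
    full = grow_tree(X, y, control)
    ladder = cost_complexity_sequence(full)
    alphas = np.asarray(ladder.alphas)
    if alphas.size == 1:
        cps = np.array([0.0])
    else:
        mids = np.sqrt(alphas[1:-1] * alphas[2:]) if alphas.size > 2 else np.empty(0)
        cps = np.concatenate([[0.0], mids, [alphas[-1]]])

    rng = np.random.default_rng(control.seed)
    fold = np.empty(n, dtype=np.int64)
    for cls in (0, 1):
        members = np.flatnonzero(yb == cls)
        rng.shuffle(members)
        fold[members] = np.arange(members.size) % control.n_folds

    miscls = np.zeros(cps.size)
    for k in range(control.n_folds):
        test = fold == k
        train = ~test
        y_train = yb[train]
        if y_train.min() == y_train.max():
            raise ValueError(
                f"fold {k}: training data lost one class; too few subjects "
                "in the minority class for stratified CV"
            )
        sub = grow_tree(
            X.iloc[np.flatnonzero(train)].reset_index(drop=True), y_train, control
        )
        sub_ladder = cost_complexity_sequence(sub)
        X_test = X.iloc[np.flatnonzero(test)].reset_index(drop=True)
        y_test = yb[test]
        for i, cp in enumerate(cps):
            pruned = sub_ladder.subtree_for(cp)
            _, labels, _ = predict(pruned, X_test)
            miscls[i] += int(((labels == IN) != (y_test == 1)).sum())
    errors = miscls / n
    ses = np.sqrt(np.maximum(errors * (1 - errors), 0.0) / n)
    return CVCurve(cps=cps, errors=errors, std_errors=ses, alphas=alphas)


# --- prediction ------------------------------------------------------------

def _route(tree: FittedTree, x) -> tuple[TreeNode, bool]:
    """Walk one row down; returns (leaf, unseen-level flag).

    An unseen categorical level cannot be routed by the split rule; it is
    sent to the child holding more training subjects (ties left) and the
    row is flagged.
    """
    node = tree.root
    flagged = False
    while not node.is_leaf:
        split = node.split
        v = x[split.feature]
        if split.kind == "continuous":
            go_left = float(v) < split.threshold
        else:
            sv = str(v)
            if sv not in tree.feature_categories.get(split.feature, ()):
                flagged = True
                go_left = node.left.n >= node.right.n  # majority child
            else:
                go_left = sv in split.left_levels
        node = node.left if go_left else node.right
    return node, flagged


def predict_probability(
    tree: FittedTree, x: pd.Series | dict
) -> tuple[float, str]:
    """(probability of "in", majority label) for a single covariate row."""
    leaf, _ = _route(tree, x)
    return leaf.probability, leaf.label


def predict(
    tree: FittedTree, X: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized prediction: (probabilities, labels, unseen-level flags)."""
    n = len(X)
    probs = np.empty(n)
    labels = np.empty(n, dtype=object)
    flags = np.zeros(n, dtype=bool)
    cols: dict[str, np.ndarray] = {}
    for name in X.columns:
        if tree.feature_kinds.get(name) == "categorical":
            cols[name] = np.asarray(X[name].astype(str))
        else:
            cols[name] = np.asarray(X[name], dtype=float)

    def fill(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            probs[idx] = node.probability
            labels[idx] = node.label
            return
        split = node.split
        v = cols[split.feature][idx]
        if split.kind == "continuous":
            go_left = v < split.threshold
        else:
            known = np.isin(v, tree.feature_categories.get(split.feature, ()))
            flags[idx[~known]] = True
            majority_left = node.left.n >= node.right.n
            go_left = np.where(known, np.isin(v, split.left_levels), majority_left)
        fill(node.left, idx[go_left])
        fill(node.right, idx[~go_left])

    fill(tree.root, np.arange(n))
    return probs, labels, flags


# --- export ----------------------------------------------------------------

def export_dot(tree: FittedTree, title: str = "inclusion explainer") -> str:
    """Graphviz DOT text; each node shows its majority label, the probability
    of "in" (2 decimals) and the percentage of training subjects it holds."""
    lines = [
        "digraph tree {",
        f'  label="{title}";',
        '  node [shape=box, style="rounded"];',
    ]
    counter = [0]

    def emit(node: TreeNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        pct = round(100.0 * node.n / tree.n_total)
        head = "" if node.is_leaf else f"{node.split.describe()}\\n"
        lines.append(
            f'  n{my_id} [label="{head}{node.label}\\n'
            f'{node.probability:.2f}\\n{pct}%"];'
        )
        if not node.is_leaf:
            lid = emit(node.left)
            rid = emit(node.right)
            lines.append(f'  n{my_id} -> n{lid} [label="yes"];')
            lines.append(f'  n{my_id} -> n{rid} [label="no"];')
        return my_id

    emit(tree.root)
    lines.append("}")
    return "\n".join(lines) + "\n"


def tree_to_json(tree: FittedTree) -> str:
    def node_dict(node: TreeNode) -> dict:
        d: dict[str, Any] = {
            "n_in": node.n_in,
            "n_out": node.n_out,
            "probability": node.probability,
            "label": node.label,
        }
        if not node.is_leaf:
            d["split"] = {
                "feature": node.split.feature,
                "kind": node.split.kind,
                "threshold": node.split.threshold,
                "left_levels": list(node.split.left_levels or []) or None,
            }
            d["left"] = node_dict(node.left)
            d["right"] = node_dict(node.right)
        return d

    return json.dumps(
        {
            "n_total": tree.n_total,
            "feature_names": list(tree.feature_names),
            "feature_kinds": tree.feature_kinds,
            "feature_categories": {
                k: list(v) for k, v in tree.feature_categories.items()
            },
            "degenerate": tree.degenerate,
            "root": node_dict(tree.root),
        },
        indent=2,
    )


def tree_from_json(text: str) -> FittedTree:
    raw = json.loads(text)

    def build(d: dict, depth: int) -> TreeNode:
        node = TreeNode(n_in=d["n_in"], n_out=d["n_out"], depth=depth)
        if "split" in d:
            s = d["split"]
            node.split = Split(
                feature=s["feature"],
                kind=s["kind"],
                threshold=s["threshold"],
                left_levels=tuple(s["left_levels"]) if s["left_levels"] else None,
            )
            node.left = build(d["left"], depth + 1)
            node.right = build(d["right"], depth + 1)
        return node

    return FittedTree(
        root=build(raw["root"], 0),
        feature_names=tuple(raw["feature_names"]),
        feature_kinds=dict(raw["feature_kinds"]),
        n_total=raw["n_total"],
        degenerate=raw["degenerate"],
        feature_categories={
            k: tuple(v) for k, v in raw.get("feature_categories", {}).items()
        },
    )
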