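"""Independent brute-force references the test suite checks the package
against.  Everything here is written with naive loops, deliberately sharing
no code with the implementation."""

from __future__ import annotations

import itertools
import math


def brute_force_match(
    scores,
    T,
    K=1,
    with_replacement=True,
    caliper=None,
    scale="logit",
    strict_k=False,
):
    """Literal replay of greedy nearest-neighbor caliper matching.

    Treated subjects in descending score order (data order on ties); for
    each, the K closest in-caliper controls (ties to the lower id), removed
    from the pool when matching without replacement.
    """
    n = len(scores)
    if scale == "logit":
        d = [math.log(s / (1 - s)) for s in scores]
    else:
        d = list(scores)
    treated = [i for i in range(n) if T[i] == 1]
    controls = [i for i in range(n) if T[i] == 0]
    order = sorted(treated, key=lambda i: -scores[i])  # stable: data order ties
    pool = set(controls)
    pairs = []
    for t in order:
        cands = []
        for c in controls:
            if not with_replacement and c not in pool:
                continue
            dist = abs(d[t] - d[c])
            if dist <= caliper:
                cands.append((dist, c))
        cands.sort()
        if strict_k and len(cands) < K:
            continue
        for dist, c in cands[:K]:
            pairs.append((t, c, dist))
            if not with_replacement:
                pool.discard(c)
    labels = ["out"] * n
    for t, c, _ in pairs:
        labels[t] = "in"
        labels[c] = "in"
    return pairs, labels


def exhaustive_best_split(X_cols, y, minbucket):
    """Max weighted Gini decrease over every cutpoint and level bipartition.

    ``X_cols``: list of (name, kind, values); y: list of 0/1.
    Returns (best decrease, descriptor) or None.
    """
    n = len(y)

    def gini(labels):
        if not labels:
            return 0.0
        p = sum(labels) / len(labels)
        return 1 - p * p - (1 - p) * (1 - p)

    g0 = gini(y)
    best = None
    for name, kind, vals in X_cols:
        if kind == "continuous":
            cuts = sorted(set(vals))
            for a, b in zip(cuts, cuts[1:]):
                cut = (a + b) / 2
                left = [y[i] for i in range(n) if vals[i] < cut]
                right = [y[i] for i in range(n) if vals[i] >= cut]
                if len(left) < minbucket or len(right) < minbucket:
                    continue
                dec = g0 - (len(left) * gini(left) + len(right) * gini(right)) / n
                if best is None or dec > best[0] + 1e-12:
                    best = (dec, (name, "continuous", cut))
        else:
            levels = sorted(set(vals))
            for r in range(1, len(levels)):
                for subset in itertools.combinations(levels, r):
                    left = [y[i] for i in range(n) if vals[i] in subset]
                    right = [y[i] for i in range(n) if vals[i] not in subset]
                    if len(left) < minbucket or len(right) < minbucket:
                        continue
                    dec = g0 - (
                        len(left) * gini(left) + len(right) * gini(right)
                    ) / n
                    if best is None or dec > best[0] + 1e-12:
                        best = (dec, (name, "categorical", frozenset(subset)))
    return best


def enumerate_pruned_subtrees(node):
    """All pruned subtrees of a TreeNode as (risk_count, n_leaves) pairs.

    A pruned subtree either collapses the node to a leaf or keeps its split
    and prunes each child independently.
    """
    options = [(min(node.n_in, node.n_out), 1)]
    if node.split is not None:
        for (rl, ll) in enumerate_pruned_subtrees(node.left):
            for (rr, lr) in enumerate_pruned_subtrees(node.right):
                options.append((rl + rr, ll + lr))
    return options
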