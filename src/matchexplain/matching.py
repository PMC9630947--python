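"""Greedy K:1 nearest-neighbor propensity matching with a caliper.

Treated subjects are processed one at a time (by default in descending order
of score); each takes its K nearest controls by absolute score distance,
raw or logit scale, subject to the caliper.  Without replacement a control
is removed from the pool once used; with replacement controls may serve
several treated subjects.  A treated subject finding no in-caliper control
is dropped from the matched sample.  Every subject then receives an
inclusion label: "in" when it appears in at least one pair, otherwise
"out" — the binary outcome both explainers model.

The default caliper is 0.2 sample standard deviations of the logit score,
the classical Rosenbaum-Rubin recommendation; the matching literature this
implements describes 1:1 matching without replacement, while K:1 matching
with replacement is the variant commonly reported — both are supported and
``with_replacement`` defaults to True.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MatchSpec",
    "MatchResult",
    "auto_caliper",
    "nearest_neighbor_match",
    "label_inclusion",
]

IN, OUT = "in", "out"


@dataclass(frozen=True)
class MatchSpec:
    """Matching recipe.

    ``caliper`` is a positive width on the chosen ``distance_scale`` or the
    token "auto" (0.2 SD of the logit/raw scores).  ``strict_k`` demands all
    K controls or none; the permissive default keeps partial matches.
    """

    K: int = 1
    with_replacement: bool = True
    caliper: float | str = "auto"
    distance_scale: str = "logit"  # or "raw"
    order_policy: str = "descending_score"  # data_order | random
    strict_k: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if isinstance(self.caliper, str):
            if self.caliper != "auto":
                raise ValueError("caliper must be a positive number or 'auto'")
        elif self.caliper <= 0:
            raise ValueError("caliper must be > 0")
        if self.distance_scale not in ("logit", "raw"):
            raise ValueError("distance_scale must be 'logit' or 'raw'")
        if self.order_policy not in ("descending_score", "data_order", "random"):
            raise ValueError(
                "order_policy must be descending_score, data_order or random"
            )


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (treated_id, control_id, distance)
    inclusion: np.ndarray                # per-subject "in"/"out"
    caliper: float
    n_matched_treated: int = 0
    n_unmatched_treated: int = 0
    n_distinct_controls_used: int = 0

    def __post_init__(self) -> None:
        treated = {t for t, _, _ in self.pairs}
        self.n_matched_treated = len(treated)
        self.n_distinct_controls_used = len({c for _, c, _ in self.pairs})


def _logit(scores: np.ndarray) -> np.ndarray:
    return np.log(scores / (1.0 - scores))


def _on_scale(scores: np.ndarray, scale: str) -> np.ndarray:
    return _logit(scores) if scale == "logit" else scores


def auto_caliper(scores: Sequence[float], scale: str = "logit") -> float:
    """0.2 x sample SD (n-1 denominator) of the scores on the given scale."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("auto caliper needs at least 2 subjects")
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("scores must lie strictly in (0, 1)")
    sd = float(np.std(_on_scale(s, scale), ddof=1))
    if sd == 0:
        raise ValueError("all scores equal: zero-width caliper is degenerate")
    return 0.2 * sd


def nearest_neighbor_match(
    scores: Sequence[float], T: Sequence[int], spec: MatchSpec | None = None
) -> MatchResult:
    """Greedy K:1 caliper matching; see the module docstring for semantics.

    Deterministic given ``spec`` (ties in distance go to the lower control
    id; random processing order uses ``spec.seed``).  An empty pair list is
    a valid outcome.
    """
    spec = spec or MatchSpec()
    s = np.asarray(scores, dtype=float)
    T = np.asarray(T, dtype=np.int64)
    if s.size != T.size:
        raise ValueError("scores and T must have equal length")
    treated_ids = np.flatnonzero(T == 1)
    control_ids = np.flatnonzero(T == 0)
    if treated_ids.size == 0 or control_ids.size == 0:
        raise ValueError("both treatment groups must be non-empty")
    d = _on_scale(s, spec.distance_scale)
    caliper = (
        auto_caliper(s, spec.distance_scale)
        if spec.caliper == "auto"
        else float(spec.caliper)
    )

    if spec.order_policy == "descending_score":
        # stable sort on -score keeps data order among tied scores
        order = treated_ids[np.argsort(-s[treated_ids], kind="stable")]
    elif spec.order_policy == "random":
        order = treated_ids.copy()
        np.random.default_rng(spec.seed).shuffle(order)
    else:
        order = treated_ids

    available = np.ones(control_ids.size, dtype=bool)  # pool for no-replacement
    ctrl_d = d[control_ids]
    pairs: list[tuple[int, int, float]] = []
    for t in order:
        dist = np.abs(ctrl_d - d[t])
        ok = dist <= caliper
        if not spec.with_replacement:
            ok &= available
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            continue
        if spec.strict_k and cand.size < spec.K:
            continue
        # K nearest, ties to the lower control id: lexsort is stable with
        # the last key primary
        take = cand[np.lexsort((control_ids[cand], dist[cand]))][: spec.K]
        for j in take:
            pairs.append((int(t), int(control_ids[j]), float(dist[j])))
            if not spec.with_replacement:
                available[j] = False
    result = MatchResult(
        pairs=pairs,
        inclusion=label_inclusion_from_pairs(pairs, s.size),
        caliper=caliper,
    )
    result.n_unmatched_treated = treated_ids.size - result.n_matched_treated
    return result


def label_inclusion_from_pairs(
    pairs: Sequence[tuple[int, int, float]], n: int
) -> np.ndarray:
    labels = np.full(n, OUT, dtype=object)
    for t, c, _ in pairs:
        if t >= n or c >= n:
            raise ValueError(f"pair ({t}, {c}) references a subject >= n={n}")
        labels[t] = IN
        labels[c] = IN
    return labels


def label_inclusion(match_result: MatchResult, n: int) -> np.ndarray:
    """Per-subject "in"/"out": "in" iff the subject appears in any pair."""
    return label_inclusion_from_pairs(match_result.pairs, n)
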