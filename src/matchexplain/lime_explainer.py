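"""Individual-level inclusion explanations via local linear surrogates.

For one subject, the black box (here: the pruned population explainer tree,
but any probability function works) is probed with ``n_permutations``
perturbed copies of the subject's covariate row: each feature is resampled
from the training marginal of its level (categoricals) or quartile bin
(continuous).  Perturbations are weighted by an exponential kernel on their
distance from the original row in indicator space, and a sparse weighted
linear model is fit to the black-box probabilities.  The signed coefficients
say which of the subject's own feature values push its inclusion probability
up (support the predicted label) or down (contradict it), and the weighted
R-squared of the surrogate — the "explanation fit" — says how well a local
linear story captures the black box around this subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LimeConfig",
    "Explanation",
    "TrainingSummary",
    "build_training_summary",
    "discretize",
    "perturb",
    "similarity",
    "explain_instance",
    "summarize_explanations",
]

IN, OUT = "in", "out"


@dataclass(frozen=True)
class LimeConfig:
    n_permutations: int = 5000
    kernel_width: float | str = "default"  # "default" = 0.75 * sqrt(p)
    n_features: int = 5
    discretizer: str = "quartile"  # or "none"
    ridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.discretizer not in ("quartile", "none"):
            raise ValueError("discretizer must be 'quartile' or 'none'")
        if isinstance(self.kernel_width, str) and self.kernel_width != "default":
            raise ValueError("kernel_width must be positive or 'default'")


@dataclass
class Explanation:
    subject_id: int
    predicted_label: str
    probability: float
    features: list[dict]  # {feature, description, weight, direction}
    intercept: float
    explanation_fit: float

    def top_weight(self) -> float:
        return max((abs(f["weight"]) for f in self.features), default=0.0)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "predicted_label": self.predicted_label,
            "probability": self.probability,
            "features": self.features,
            "intercept": self.intercept,
            "explanation_fit": self.explanation_fit,
        }


# --- discretization --------------------------------------------------------

def discretize(values: Sequence[float]) -> tuple[np.ndarray, Callable]:
    """Quartile bin edges and encoder for one continuous training column.

    Edges sit at the 25/50/75th percentiles (linear-interpolation
    quantiles); the encoder maps a value to bin 1..4, upper-inclusive
    (v <= q25 -> 1, q25 < v <= q50 -> 2, ...), hence monotone.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 4:
        raise ValueError("quartile discretization needs >= 4 distinct values")
    edges = np.quantile(v, [0.25, 0.5, 0.75])

    def encoder(x):
        return np.searchsorted(edges, np.asarray(x, dtype=float), side="left") + 1

    return edges, encoder


def _bin_description(name: str, edges: np.ndarray, b: int) -> str:
    if b == 1:
        return f"{name} <= {edges[0]:g}"
    if b == len(edges) + 1:
        return f"{edges[-1]:g} < {name}"
    return f"{edges[b - 2]:g} < {name} <= {edges[b - 1]:g}"


@dataclass
class _Feature:
    name: str
    kind: str  # categorical | binned | standardized
    levels: tuple[str, ...] = ()
    frequencies: np.ndarray | None = None
    edges: np.ndarray | None = None
    bin_values: list[np.ndarray] | None = None  # training values per bin
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class TrainingSummary:
    features: list[_Feature]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]


def build_training_summary(
    X: pd.DataFrame,
    config: LimeConfig | None = None,
    categorical_columns: Sequence[str] | None = None,
) -> TrainingSummary:
    """Per-feature training marginals used by the perturbation sampler."""
    config = config or LimeConfig()
    categorical = set(categorical_columns or [])
    feats: list[_Feature] = []
    for name in X.columns:
        col = X[name]
        is_cat = (
            name in categorical
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype.kind in "OUb"
        )
        if not is_cat and config.discretizer == "quartile":
            # too few distinct values for quartile bins: treat as levels
            is_cat = np.unique(np.asarray(col, dtype=float)).size < 4
        if is_cat:
            vals = col.astype(str)
            counts = vals.value_counts().sort_index()
            feats.append(
                _Feature(
                    name=name,
                    kind="categorical",
                    levels=tuple(counts.index),
                    frequencies=(counts / counts.sum()).to_numpy(),
                )
            )
        elif config.discretizer == "quartile":
            v = np.asarray(col, dtype=float)
            edges, encoder = discretize(v)
            bins = encoder(v)
            feats.append(
                _Feature(
                    name=name,
                    kind="binned",
                    edges=edges,
                    frequencies=np.array(
                        [(bins == b).mean() for b in (1, 2, 3, 4)]
                    ),
                    bin_values=[np.sort(v[bins == b]) for b in (1, 2, 3, 4)],
                )
            )
        else:
            v = np.asarray(col, dtype=float)
            sd = float(np.std(v, ddof=0))
            feats.append(
                _Feature(
                    name=name,
                    kind="standardized",
                    mean=float(np.mean(v)),
                    sd=sd if sd > 0 else 1.0,
                )
            )
    return TrainingSummary(features=feats)


# --- perturbation ----------------------------------------------------------

def perturb(
    instance: pd.Series,
    summary: TrainingSummary,
    config: LimeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Perturbed raw rows, surrogate design matrix, and distances.

    Row 0 is the unperturbed instance.  Categorical and binned features
    contribute a same-as-instance indicator column (row 0 all ones);
    standardized features contribute their z-score.  Distance is the
    Euclidean distance of each design row from row 0.
    """
    config = config or LimeConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.n_permutations
    raw: dict[str, np.ndarray] = {}
    design_cols: list[np.ndarray] = []
    for f in summary.features:
        if f.kind == "categorical":
            own = str(instance[f.name])
            if own not in f.levels:
                raise ValueError(
                    f"level {own!r} of {f.name!r} unseen in training"
                )
            idx = rng.choice(len(f.levels), size=m, p=f.frequencies)
            idx[0] = f.levels.index(own)
            vals = np.asarray(f.levels, dtype=object)[idx]
            raw[f.name] = vals
            design_cols.append((vals == own).astype(float))
        elif f.kind == "binned":
            own_bin = int(
                np.searchsorted(f.edges, float(instance[f.name]), side="left") + 1
            )
            bins = rng.choice(4, size=m, p=f.frequencies) + 1
            bins[0] = own_bin
            # raw value resampled from the training values of the drawn bin
            vals = np.empty(m)
            u = rng.random(m)
            for b in (1, 2, 3, 4):
                members = f.bin_values[b - 1]
                sel = bins == b
                if members.size == 0:  # empty training bin: fall back to edge
                    vals[sel] = f.edges[min(b - 1, len(f.edges) - 1)]
                else:
                    vals[sel] = members[
                        (u[sel] * members.size).astype(int).clip(0, members.size - 1)
                    ]
            vals[0] = float(instance[f.name])
            raw[f.name] = vals
            design_cols.append((bins == own_bin).astype(float))
        else:
            vals = rng.normal(f.mean, f.sd, size=m)
            vals[0] = float(instance[f.name])
            raw[f.name] = vals
            design_cols.append((vals - f.mean) / f.sd)
    design = np.column_stack(design_cols)
    dist = np.sqrt(((design - design[0]) ** 2).sum(axis=1))
    return pd.DataFrame(raw), design, dist


def similarity(
    distances: np.ndarray, kernel_width: float | str, n_features: int | None = None
) -> np.ndarray:
    """Exponential kernel exp(-d^2 / width^2).

    ``kernel_width="default"`` uses 0.75 * sqrt(feature count).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if isinstance(kernel_width, str):
        if n_features is None:
            raise ValueError("default kernel width needs the feature count")
        width = 0.75 * np.sqrt(n_features)
    else:
        width = float(kernel_width)
    if width <= 0:
        raise ValueError("kernel width must be positive")
    return np.exp(-(d ** 2) / width ** 2)


# --- local surrogate -------------------------------------------------------

def _wls(
    design: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float
) -> tuple[np.ndarray, float]:
    """Weighted least squares with intercept; returns (coefs, intercept)."""
    sw = np.sqrt(w)
    Xw = np.column_stack([np.ones(design.shape[0]), design]) * sw[:, None]
    yw = y * sw
    if ridge > 0:
        p = Xw.shape[1]
        pen = np.sqrt(ridge) * np.eye(p)
        pen[0, 0] = 0.0  # never penalize the intercept
        Xw = np.vstack([Xw, pen])
        yw = np.concatenate([yw, np.zeros(p)])
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return beta[1:], float(beta[0])


def _weighted_r2(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    ybar = float(np.average(y, weights=w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot <= 1e-300:
        return 0.0  # zero-variance weighted response convention
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _feature_description(f: _Feature, instance: pd.Series) -> str:
    if f.kind == "categorical":
        return f"{f.name} = {instance[f.name]}"
    if f.kind == "binned":
        b = int(np.searchsorted(f.edges, float(instance[f.name]), side="left") + 1)
        return _bin_description(f.name, f.edges, b)
    return f.name


def explain_instance(
    black_box: Callable[[pd.DataFrame], np.ndarray],
    instance: pd.Series,
    summary: TrainingSummary,
    config: LimeConfig | None = None,
    subject_id: int | None = None,
) -> Explanation:
    """Local surrogate explanation of ``black_box``'s in-probability.

    Perturbs the instance, weights perturbations by kernel similarity,
    selects the ``n_features`` indicators with the largest |coefficient| of
    a full weighted fit, refits on those, and reports signed weights, the
    intercept, and the weighted R-squared ("explanation fit").
    Deterministic given ``config.seed``.
    """
    config = config or LimeConfig()
    raw, design, dist = perturb(instance, summary, config)
    try:
        y = np.asarray(black_box(raw), dtype=float)
        keep = np.isfinite(y)
    except Exception:
        y = np.full(len(raw), np.nan)
        for i in range(len(raw)):
            try:
                y[i] = float(black_box(raw.iloc[[i]])[0])
            except Exception:
                pass
        keep = np.isfinite(y)
    if keep.mean() < 0.5:
        raise RuntimeError(
            "black box failed on more than half of the perturbed rows"
        )
    if not keep.all():
        warnings.warn(
            f"black box failed on {int((~keep).sum())} perturbed rows; dropped",
            stacklevel=2,
        )
    y, design, dist = y[keep], design[keep], dist[keep]
    p = design.shape[1]
    w = similarity(dist, config.kernel_width, n_features=p)
    coefs, _ = _wls(design, y, w, config.ridge)
    order = np.argsort(-np.abs(coefs), kind="stable")
    selected = np.sort(order[: config.n_features])
    sel_coefs, intercept = _wls(design[:, selected], y, w, config.ridge)
    yhat = intercept + design[:, selected] @ sel_coefs
    fit = _weighted_r2(y, yhat, w)
    prob0 = float(y[0])
    label = IN if prob0 >= 0.5 else OUT
    feats = []
    for j, c in zip(selected, sel_coefs):
        f = summary.features[j]
        agrees = (c >= 0) == (label == IN)
        feats.append(
            {
                "feature": f.name,
                "description": _feature_description(f, instance),
                "weight": float(c),
                "direction": "supports" if agrees else "contradicts",
            }
        )
    feats.sort(key=lambda d: -abs(d["weight"]))
    sid = subject_id
    if sid is None:
        sid = int(instance.get("subject_id", -1)) if hasattr(instance, "get") else -1
    return Explanation(
        subject_id=sid,
        predicted_label=label,
        probability=prob0,
        features=feats,
        intercept=intercept,
        explanation_fit=fit,
    )


def summarize_explanations(
    explanations: Sequence[Explanation],
    inclusion: dict[int, str] | Sequence[str],
) -> dict:
    """Per-group (in/out) mean explanation fit and mean |top-feature weight|.

    ``inclusion`` maps subject_id to label (dict) or is indexable by
    subject_id (sequence).  Empty groups are reported as None.
    """
    groups: dict[str, list[Explanation]] = {IN: [], OUT: []}
    for e in explanations:
        if isinstance(inclusion, dict):
            label = inclusion[e.subject_id]
        else:
            label = inclusion[e.subject_id]
        if label not in groups:
            raise ValueError(f"label {label!r} is not 'in'/'out'")
        groups[label].append(e)
    out: dict[str, dict | None] = {}
    for g, members in groups.items():
        if not members:
            out[g] = None
            continue
        out[g] = {
            "n": len(members),
            "mean_explanation_fit": float(
                np.mean([e.explanation_fit for e in members])
            ),
            "mean_top_weight": float(np.mean([e.top_weight() for e in members])),
        }
    return out
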