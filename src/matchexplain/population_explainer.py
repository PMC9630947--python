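"""Population-level inclusion explainer and characteristics-by-match-status
tables.

Once matching has labeled every subject "in" (matched) or "out" (discarded),
the question "who is this analysis actually about?" becomes a supervised
problem: model P(in | Z) with a classification tree, prune it at the
complexity parameter minimizing cross-validated misclassification, and read
the splits.  Alongside the tree, a balance table summarizes each covariate
by inclusion status — mean (SD) with a Welch t-test for continuous
covariates, level counts/percentages with a Pearson chi-square (no
continuity correction) for categoricals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from matchexplain.cart_engine import (
    FittedTree,
    TreeControl,
    cross_validated_error,
    grow_tree,
    prune,
)

__all__ = [
    "fit_population_explainer",
    "BalanceRow",
    "BalanceTable",
    "characteristics_table",
]

IN, OUT = "in", "out"


def fit_population_explainer(
    cohort: pd.DataFrame,
    inclusion: Sequence[str],
    control: TreeControl | None = None,
    covariate_columns: Sequence[str] | None = None,
):
    """Pruned classification tree for P(in | covariates).

    Returns (tree, selected cp, CV curve or None).  Single-class labels
    yield a root-only tree flagged ``degenerate`` rather than an error;
    "no tree grew" is a legitimate, informative outcome (inclusion
    unexplainable from Z).
    """
    control = control or TreeControl()
    X = cohort[list(covariate_columns)] if covariate_columns else cohort
    y = np.asarray(inclusion)
    full = grow_tree(X, y, control)
    if full.root.is_leaf:
        return full, 0.0, None
    curve = cross_validated_error(X, y, control)
    cp = curve.cp_at_min()
    return prune(full, cp), cp, curve


@dataclass
class BalanceRow:
    covariate: str
    kind: str                       # continuous | categorical
    summary_in: dict
    summary_out: dict
    statistic: float
    p_value: float
    test: str
    notes: list[str] = field(default_factory=list)


@dataclass
class BalanceTable:
    n_in: int
    n_out: int
    rows: list[BalanceRow]

    def to_frame(self) -> pd.DataFrame:
        """Report-style long layout: one block per covariate."""
        records = []
        for row in self.rows:
            if row.kind == "continuous":
                records.append(
                    {
                        "covariate": row.covariate,
                        "level": "",
                        "out": f"{row.summary_out['mean']:.0f} "
                               f"({row.summary_out['sd']:.0f})",
                        "in": f"{row.summary_in['mean']:.0f} "
                              f"({row.summary_in['sd']:.0f})",
                        "p": _fmt_p(row.p_value),
                    }
                )
            else:
                first = True
                for level in row.summary_in["counts"]:
                    records.append(
                        {
                            "covariate": row.covariate if first else "",
                            "level": level,
                            "out": _fmt_cat(row.summary_out, level),
                            "in": _fmt_cat(row.summary_in, level),
                            "p": _fmt_p(row.p_value) if first else "",
                        }
                    )
                    first = False
        return pd.DataFrame.from_records(
            records, columns=["covariate", "level", "out", "in", "p"]
        )

    def to_dict(self) -> dict:
        """Machine-readable form with full precision."""
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "covariates": [
                {
                    "covariate": r.covariate,
                    "kind": r.kind,
                    "in": r.summary_in,
                    "out": r.summary_out,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "test": r.test,
                    "notes": r.notes,
                }
                for r in self.rows
            ],
        }


def _fmt_p(p: float) -> str:
    return "< .001" if p < 0.001 else f"{p:.3f}".lstrip("0")


def _fmt_cat(summary: dict, level: str) -> str:
    n = summary["counts"][level]
    pct = summary["percentages"][level]
    return f"{n} ({pct:.1f})"


def characteristics_table(
    cohort: pd.DataFrame,
    inclusion: Sequence[str],
    covariate_columns: Sequence[str] | None = None,
    categorical_columns: Sequence[str] | None = None,
) -> BalanceTable:
    """Covariate summaries by inclusion status with two-sided group tests.

    Continuous: Welch two-sample t.  Categorical: Pearson chi-square,
    df = levels - 1, no continuity correction; a level absent from both
    groups is dropped from the test with a note.
    """
    y = np.asarray(inclusion)
    classes = set(np.unique(y).tolist())
    if not classes <= {IN, OUT}:
        raise ValueError(f"inclusion labels must be 'in'/'out', got {classes}")
    mask_in = y == IN
    n_in, n_out = int(mask_in.sum()), int((~mask_in).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("both inclusion groups must be non-empty")
    columns = list(covariate_columns) if covariate_columns else [
        c for c in cohort.columns
        if c not in ("subject_id", "T", "true_score")
    ]
    categorical = set(categorical_columns or [])
    rows: list[BalanceRow] = []
    for name in columns:
        col = cohort[name]
        is_cat = (
            name in categorical
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype.kind in "OUb"
        )
        if not is_cat:
            a = np.asarray(col, dtype=float)[mask_in]
            b = np.asarray(col, dtype=float)[~mask_in]
            if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
                t, p = 0.0, 1.0  # identical degenerate distributions
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                BalanceRow(
                    covariate=name,
                    kind="continuous",
                    summary_in={
                        "mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1)),
                    },
                    summary_out={
                        "mean": float(np.mean(b)), "sd": float(np.std(b, ddof=1)),
                    },
                    statistic=float(t),
                    p_value=float(p),
                    test="welch_t",
                )
            )
            continue
        vals = col.astype(str)
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [str(l) for l in col.cat.categories]
        else:
            levels = sorted(vals.unique())
        counts_in = vals[mask_in].value_counts()
        counts_out = vals[~mask_in].value_counts()
        notes = []
        used = []
        for level in levels:
            if counts_in.get(level, 0) + counts_out.get(level, 0) == 0:
                notes.append(f"level {level!r} absent from both groups; dropped")
            else:
                used.append(level)
        table = np.array(
            [[counts_in.get(l, 0) for l in used],
             [counts_out.get(l, 0) for l in used]],
            dtype=float,
        )
        if len(used) < 2:
            chi2, p = float("nan"), float("nan")
            notes.append("fewer than 2 observed levels; test undefined")
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            BalanceRow(
                covariate=name,
                kind="categorical",
                summary_in={
                    "counts": {l: int(counts_in.get(l, 0)) for l in used},
                    "percentages": {
                        l: 100.0 * counts_in.get(l, 0) / n_in for l in used
                    },
                },
                summary_out={
                    "counts": {l: int(counts_out.get(l, 0)) for l in used},
                    "percentages": {
                        l: 100.0 * counts_out.get(l, 0) / n_out for l in used
                    },
                },
                statistic=float(chi2),
                p_value=float(p),
                test="pearson_chi2",
                notes=notes,
            )
        )
    return BalanceTable(n_in=n_in, n_out=n_out, rows=rows)
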