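"""End-to-end orchestration: simulate/load -> estimate -> match -> explain.

One :func:`run_pipeline` call produces a reproducible artifact bundle in the
output directory:

    cohort.csv           (when simulated from a preset)
    scores.csv           subject_id, propensity score
    pairs.csv            treated_id, control_id, distance
    labels.csv           subject_id, in/out inclusion label
    balance_table.csv    characteristics by match status (report layout)
    balance_table.json   same, machine-readable at full precision
    explainer_tree.json  pruned population explainer
    explainer_tree.dot   Graphviz rendering source
    explanations.json    per-subject local surrogate explanations
    summary.json         counts, selected cp, CV curve, group fit means
    run.log              stage-by-stage log (no timestamps, so a rerun with
                         the same config and seed is byte-identical)

Every random stage draws its seed from the global seed through a fixed
counter scheme (SeedSequence([seed, stage]); stages: 0 simulate, 1 estimate,
2 match, 3 population explainer, 4 individual explainer), so stages can be
re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from matchexplain import synthetic_cohort as sc
from matchexplain.cart_engine import (
    TreeControl,
    export_dot,
    predict,
    tree_to_json,
)
from matchexplain.lime_explainer import (
    LimeConfig,
    build_training_summary,
    explain_instance,
    summarize_explanations,
)
from matchexplain.matching import MatchSpec, nearest_neighbor_match
from matchexplain.population_explainer import (
    characteristics_table,
    fit_population_explainer,
)
from matchexplain.propensity import (
    external_scores,
    fit_bagged_trees,
    fit_logistic,
    fit_tree_propensity,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_STAGES = {
    "simulate": 0,
    "estimate": 1,
    "match": 2,
    "population": 3,
    "individual": 4,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    preset: str | None = None
    input_path: str | None = None
    n: int | None = None  # preset size override
    treatment: str = "T"
    method: str = "logistic"  # logistic | tree | forest | external
    scores_path: str | None = None  # for method="external"
    match: MatchSpec = dc_field(default_factory=MatchSpec)
    tree: TreeControl = dc_field(default_factory=TreeControl)
    lime: LimeConfig = dc_field(default_factory=LimeConfig)
    explain_subject_ids: Sequence[int] | str = "auto"
    n_trees: int = 100
    mtry: int | None = None
    out_dir: str = "matchexplain_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.preset is None) == (self.input_path is None):
            raise ValueError("exactly one of preset / input_path is required")
        if self.method not in ("logistic", "tree", "forest", "external"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "external" and not self.scores_path:
            raise ValueError("method 'external' needs scores_path")


def _infer_schema(cohort: pd.DataFrame, covariate_cols: list[str]):
    """Covariate descriptors for a cohort loaded from CSV.

    Numeric columns with at most 5 distinct values are treated as
    categorical codes (comorbidity scores and the like survive a CSV
    round trip that way).
    """
    covs = []
    for name in covariate_cols:
        col = cohort[name]
        few_numeric_codes = (
            col.dtype.kind in "iuf" and col.nunique() <= 5
        )
        if few_numeric_codes:
            col = col.astype(str)
            cohort[name] = col
        if (
            few_numeric_codes
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype.kind in "OUb"
        ):
            levels = tuple(sorted(col.astype(str).unique()))
            n = len(col)
            probs = tuple(
                float((col.astype(str) == l).sum()) / n for l in levels
            )
            covs.append(
                sc.CategoricalCovariate(name=name, levels=levels, probabilities=probs)
            )
        else:
            v = np.asarray(col, dtype=float)
            lo, hi = float(v.min()), float(v.max())
            if lo == hi:
                hi = lo + 1.0
            covs.append(sc.ContinuousCovariate(name=name, lo=lo, hi=hi))
    return covs


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    def fail(stage: str, exc: Exception) -> None:
        say(f"FAILED at stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    summary: dict = {"seed": config.seed, "method": config.method}

    # --- stage 0: cohort ---------------------------------------------------
    try:
        if config.preset:
            gen = sc.load_preset(
                config.preset, n=config.n, seed=stage_seed(config.seed, "simulate")
            )
            cohort = sc.generate_cohort(gen)
            covariates = list(gen.covariates)
            sc.write_cohort_csv(cohort, out / "cohort.csv")
            say(f"simulate: preset {config.preset!r}, n={len(cohort)}")
        else:
            cohort = pd.read_csv(config.input_path)
            if config.treatment not in cohort.columns:
                raise ValueError(
                    f"treatment column {config.treatment!r} not in input"
                )
            if "subject_id" not in cohort.columns:
                cohort.insert(0, "subject_id", np.arange(len(cohort)))
            cov_cols = [
                c
                for c in cohort.columns
                if c not in ("subject_id", config.treatment, "true_score")
            ]
            covariates = _infer_schema(cohort, cov_cols)
            say(f"load: {config.input_path} n={len(cohort)}")
        T = np.asarray(cohort[config.treatment], dtype=np.int64)
        cov_names = [c.name for c in covariates]
        categorical_names = [c.name for c in covariates if c.kind == "categorical"]
        X = cohort[cov_names]
    except Exception as exc:
        fail("simulate/load", exc)
        raise

    # --- stage 1: propensity ----------------------------------------------
    try:
        est_seed = stage_seed(config.seed, "estimate")
        if config.method == "logistic":
            design, names = sc.encode_design(cohort, covariates)
            fit = fit_logistic(design, T, column_names=names)
        elif config.method == "tree":
            fit = fit_tree_propensity(
                X, T, TreeControl(
                    minsplit=config.tree.minsplit,
                    minbucket=config.tree.minbucket,
                    cp_grow=config.tree.cp_grow,
                    maxdepth=config.tree.maxdepth,
                    n_folds=config.tree.n_folds,
                    seed=est_seed,
                ),
            )
        elif config.method == "forest":
            fit = fit_bagged_trees(
                X, T, n_trees=config.n_trees, mtry=config.mtry,
                control=config.tree, seed=est_seed,
            )
        else:
            fit = external_scores(
                config.scores_path, len(cohort),
                subject_ids=cohort["subject_id"].to_numpy(),
            )
        _write_csv(
            pd.DataFrame(
                {"subject_id": cohort["subject_id"], "score": fit.scores}
            ),
            out / "scores.csv",
        )
        say(
            f"estimate: method={config.method} converged={fit.converged} "
            f"iterations={fit.iterations}"
        )
        summary["converged"] = bool(fit.converged)
    except Exception as exc:
        fail("estimate", exc)
        raise

    # --- stage 2: matching -------------------------------------------------
    try:
        spec = config.match
        if spec.order_policy == "random":
            spec = MatchSpec(
                K=spec.K, with_replacement=spec.with_replacement,
                caliper=spec.caliper, distance_scale=spec.distance_scale,
                order_policy="random", strict_k=spec.strict_k,
                seed=stage_seed(config.seed, "match"),
            )
        result = nearest_neighbor_match(fit.scores, T, spec)
        inclusion = result.inclusion
        _write_csv(
            pd.DataFrame(
                result.pairs, columns=["treated_id", "control_id", "distance"]
            ),
            out / "pairs.csv",
        )
        _write_csv(
            pd.DataFrame(
                {"subject_id": cohort["subject_id"], "label": inclusion}
            ),
            out / "labels.csv",
        )
        n_in = int((inclusion == "in").sum())
        n_out = len(cohort) - n_in
        say(
            f"match: K={spec.K} replacement={spec.with_replacement} "
            f"caliper={result.caliper:.6g} pairs={len(result.pairs)} "
            f"n_in={n_in} n_out={n_out} "
            f"unmatched_treated={result.n_unmatched_treated}"
        )
        summary.update(
            n=len(cohort),
            n_in=n_in,
            n_out=n_out,
            n_pairs=len(result.pairs),
            caliper=result.caliper,
            n_matched_treated=result.n_matched_treated,
            n_unmatched_treated=result.n_unmatched_treated,
            n_distinct_controls_used=result.n_distinct_controls_used,
        )
    except Exception as exc:
        fail("match", exc)
        raise

    # --- stage 3: population explainer --------------------------------------
    try:
        notes: list[str] = []
        if n_in == 0 or n_out == 0:
            notes.append("single-class inclusion labels: balance table skipped")
            balance = None
        else:
            balance = characteristics_table(
                cohort, inclusion,
                covariate_columns=cov_names,
                categorical_columns=categorical_names,
            )
            balance.to_frame().to_csv(
                out / "balance_table.csv", index=False, lineterminator="\n"
            )
            (out / "balance_table.json").write_text(
                json.dumps(balance.to_dict(), indent=2) + "\n", encoding="utf-8"
            )
        pop_control = TreeControl(
            minsplit=config.tree.minsplit,
            minbucket=config.tree.minbucket,
            cp_grow=config.tree.cp_grow,
            maxdepth=config.tree.maxdepth,
            n_folds=config.tree.n_folds,
            seed=stage_seed(config.seed, "population"),
        )
        tree, cp, curve = fit_population_explainer(
            cohort, inclusion, pop_control, covariate_columns=cov_names
        )
        (out / "explainer_tree.json").write_text(
            tree_to_json(tree) + "\n", encoding="utf-8"
        )
        (out / "explainer_tree.dot").write_text(
            export_dot(tree), encoding="utf-8"
        )
        say(
            f"population explainer: leaves={tree.n_leaves} cp={cp:.6g} "
            f"degenerate={tree.degenerate}"
        )
        summary["selected_cp"] = cp
        if curve is not None:
            summary["cv_curve"] = {
                "cp": [float(c) for c in curve.cps],
                "error": [float(e) for e in curve.errors],
                "std_error": [float(s) for s in curve.std_errors],
            }
        summary["explainer_leaves"] = tree.n_leaves
        summary["explainer_degenerate"] = bool(tree.degenerate)
        if not tree.root.is_leaf:
            summary["explainer_root_split"] = tree.root.split.describe()
    except Exception as exc:
        fail("population explainer", exc)
        raise

    # --- stage 4: individual explainer --------------------------------------
    try:
        lime_cfg = LimeConfig(
            n_permutations=config.lime.n_permutations,
            kernel_width=config.lime.kernel_width,
            n_features=config.lime.n_features,
            discretizer=config.lime.discretizer,
            ridge=config.lime.ridge,
            seed=stage_seed(config.seed, "individual"),
        )
        probs, labels, _ = predict(tree, X)

        def black_box(rows: pd.DataFrame) -> np.ndarray:
            p, _, _ = predict(tree, rows[cov_names])
            return p

        if config.explain_subject_ids == "auto":
            chosen: list[int] = []
            for group in ("in", "out"):
                correct = np.flatnonzero((labels == group) & (inclusion == group))
                if correct.size:
                    chosen.append(int(cohort["subject_id"].iloc[correct[0]]))
                else:
                    notes.append(
                        f"no correctly classified {group!r} subject to explain"
                    )
        else:
            chosen = [int(i) for i in config.explain_subject_ids]
        train_summary = build_training_summary(
            X, lime_cfg, categorical_columns=categorical_names
        )
        explanations = []
        by_id = cohort.set_index("subject_id")
        for sid in chosen:
            row = by_id.loc[sid, cov_names]
            explanations.append(
                explain_instance(
                    black_box, row, train_summary, lime_cfg, subject_id=sid
                )
            )
        (out / "explanations.json").write_text(
            json.dumps([e.to_dict() for e in explanations], indent=2) + "\n",
            encoding="utf-8",
        )
        label_map = {
            int(s): l for s, l in zip(cohort["subject_id"], inclusion)
        }
        if explanations:
            groups = summarize_explanations(explanations, label_map)
        else:
            groups = {"in": None, "out": None}
        say(
            "individual explainer: "
            + ", ".join(
                f"{e.subject_id}:{e.predicted_label} fit={e.explanation_fit:.3f}"
                for e in explanations
            )
        )
        summary["explanation_groups"] = groups
        summary["notes"] = notes
    except Exception as exc:
        fail("individual explainer", exc)
        raise

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    say("done")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return summary
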