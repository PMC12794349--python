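"""Nested group cross-validation.

The outer loop estimates generalisation: either leave-one-protein-out
(every outer fold holds out all spectra of one protein) or repeated random
group splits holding out ~20% of proteins.  The inner loop — a 5-fold
group CV grid search — tunes hyperparameters on the training rows of each
outer fold only, so the scaler statistics and the selected features are
functions of the training proteins alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, LeaveOneGroupOut

from .errors import ConfigurationError
from .formatting import FeatureFrame
from .labels import CLASS_ORDER, HELIX_LONG, HELIX_SHORT
from .metrics import EvalReport, classification_metrics, cohens_kappa, confusion_from_labels, loo_report
from .pipelines import AnovaSVRChain, PipelineSpec, build_pipeline, inner_tune

__all__ = ["CVPlan", "outer_splits", "run_nested_cv"]

_TASK_LABEL = {"class": "class", "helix_length": "helix_length_class"}
_TASK_TARGETS = {
    "fractions": ("frac_beta_pct", "frac_alpha_pct"),
    "helix_count": ("frac_alpha_pct", "n_helices"),
    "sheet_registry": ("frac_antiparallel_pct", "frac_parallel_pct"),
}


@dataclass(frozen=True)
class CVPlan:
    """Outer-loop design: ``loo_by_group`` or ``random_group_splits``."""

    outer: str = "loo_by_group"
    n_splits: int = 3
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer not in ("loo_by_group", "random_group_splits"):
            raise ConfigurationError(f"unknown outer CV scheme {self.outer!r}")
        if not 0 < self.test_frac < 1 or self.n_splits < 1:
            raise ConfigurationError("invalid split configuration")


def outer_splits(plan: CVPlan, X, groups):
    """Yield (train_idx, test_idx) pairs; groups never straddle a split."""
    groups = np.asarray(groups)
    if plan.outer == "loo_by_group":
        splitter = LeaveOneGroupOut()
    else:
        splitter = GroupShuffleSplit(
            n_splits=plan.n_splits, test_size=plan.test_frac, random_state=plan.seed
        )
    yield from splitter.split(X, groups=groups)


def _classification_cv(frame: FeatureFrame, spec: PipelineSpec, plan: CVPlan, task: str) -> EvalReport:
    label = _TASK_LABEL[task]
    if label not in frame.meta.columns:
        raise KeyError(f"frame lacks the {label!r} label column; run label_frame first")
    y = frame.meta[label].to_numpy()
    groups = frame.groups
    classes = [c for c in (CLASS_ORDER if task == "class" else (HELIX_SHORT, HELIX_LONG))
               if c in set(y)]

    fold_tables: dict[str, pd.DataFrame] = {}
    split_rows = []
    chosen = []
    selected_coords: list = []
    for fold, (tr, te) in enumerate(outer_splits(plan, frame.X, groups)):
        search = inner_tune(
            frame.X[tr], y[tr], groups[tr], *build_pipeline(spec),
            inner_folds=spec.inner_folds, scoring="accuracy",
        )
        pred = search.best_estimator_.predict(frame.X[te])
        chosen.append(search.best_params_)
        selector = search.best_estimator_.named_steps["select"]
        if hasattr(selector, "selected_idx_"):
            selected_coords.append(
                [[float(a), float(b)] for a, b in frame.feature_coords[selector.selected_idx_]]
            )
        tbl = pd.DataFrame({"truth": y[te], "pred": pred, "protein_id": groups[te]})
        split_rows.append(
            {"fold": fold, "test_accuracy": float((tbl.truth == tbl.pred).mean()),
             "test_proteins": sorted(set(groups[te]))}
        )
        for pid, sub in tbl.groupby("protein_id"):
            fold_tables.setdefault(pid, []).append(sub)

    merged = {pid: pd.concat(parts, ignore_index=True) for pid, parts in fold_tables.items()}
    report = loo_report(merged, task, classes=classes,
                        selected_features=selected_coords[-1] if selected_coords else [])
    if plan.outer == "random_group_splits":
        accs = [r["test_accuracy"] for r in split_rows]
        report.aggregate["split_accuracies"] = accs
        report.aggregate["mean_split_accuracy"] = float(np.mean(accs))
    report.details = {"splits": split_rows, "chosen_params": chosen, "outer": plan.outer}
    return report


def _chain_cv(frame: FeatureFrame, spec: PipelineSpec, plan: CVPlan, task: str) -> EvalReport:
    targets = _TASK_TARGETS[task]
    missing = [t for t in targets if t not in frame.meta.columns]
    if missing:
        raise KeyError(f"frame lacks target columns {missing}; run label_frame first")
    Y = frame.meta[list(targets)].to_numpy(float)
    groups = frame.groups

    grid = spec.grid or {}
    chain_kw = dict(
        k_grid=grid.get("k_grid", None) or AnovaSVRChain().k_grid,
        inner_folds=spec.inner_folds,
        target_names=targets,
    )
    fold_tables: dict[str, pd.DataFrame] = {}
    chosen = []
    feature_coords: list = []
    for tr, te in outer_splits(plan, frame.X, groups):
        chain = AnovaSVRChain(**chain_kw)
        chain.fit(frame.X[tr], Y[tr], groups=groups[tr])
        pred = chain.predict(frame.X[te])
        chosen.append({"k": chain.k_, "n_features": int(chain.feature_indices_.size)})
        feature_coords = [
            [float(a), float(b)] for a, b in frame.feature_coords[chain.feature_indices_]
        ]
        tbl = pd.DataFrame({"protein_id": groups[te]})
        for j, t in enumerate(targets):
            tbl[f"truth_{t}"] = Y[te, j]
            tbl[f"pred_{t}"] = pred[:, j]
        for pid, sub in tbl.groupby("protein_id"):
            fold_tables.setdefault(pid, []).append(sub)

    merged = {pid: pd.concat(parts, ignore_index=True) for pid, parts in fold_tables.items()}
    report = loo_report(merged, task, targets=targets, selected_features=feature_coords)
    report.details = {"chosen_params": chosen, "outer": plan.outer}
    return report


def run_nested_cv(frame: FeatureFrame, spec: PipelineSpec, plan: CVPlan, task: str = "class") -> EvalReport:
    """Run the nested group CV for one task and assemble its report.

    Classification tasks (``class``, ``helix_length``) tune a
    scaler/selector/predictor pipeline per outer fold; regression tasks
    (``fractions``, ``helix_count``, ``sheet_registry``) fit the SVR
    regression chain.  In every fold all transformers are fitted on the
    training rows only.
    """
    if task in _TASK_LABEL:
        return _classification_cv(frame, spec, plan, task)
    if task in _TASK_TARGETS:
        return _chain_cv(frame, spec, plan, task)
    raise ConfigurationError(f"unknown task {task!r}")
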