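"""Assessment metrics and evaluation-report assembly.

Classification runs are summarised by accuracy, Cohen's kappa and
per-class precision/recall/F1 from the pooled confusion matrix; regression
runs by the RMSE against the ground-truth percentages and the pooled
standard deviation (S_pooled) of the predictions across each protein's
repeated spectra, which measures tolerance to acquisition variability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formatting import FeatureFrame

__all__ = [
    "cohens_kappa",
    "classification_metrics",
    "rmse",
    "s_pooled",
    "confusion_from_labels",
    "EvalReport",
    "loo_report",
    "class_amplitude_summary",
    "plot_loo_report",
]


def confusion_from_labels(y_true, y_pred, classes: Sequence) -> np.ndarray:
    """Confusion matrix with rows = truth, columns = prediction."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    Returns 0 by convention when expected agreement p_e equals 1.
    """
    c = np.asarray(confusion, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("confusion matrix must contain counts")
    total = c.sum()
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def classification_metrics(confusion) -> dict:
    """Accuracy plus per-class precision/recall/F1 and macro averages.

    Classes never predicted get precision 0; classes absent from the truth
    get recall 0 and are listed under ``undefined_recall``.
    """
    c = np.asarray(confusion, dtype=float)
    if c.sum() <= 0:
        raise ValueError("confusion matrix must contain counts")
    tp = np.diag(c)
    pred = c.sum(axis=0)
    truth = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / np.maximum(pred, 1e-300), 0.0)
        recall = np.where(truth > 0, tp / np.maximum(truth, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return {
        "accuracy": float(np.trace(c) / c.sum()),
        "precision": precision.tolist(),
        "recall": recall.tolist(),
        "f1": f1.tolist(),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "undefined_recall": [int(i) for i in np.flatnonzero(truth == 0)],
    }


def rmse(predicted, truth) -> float:
    """Root mean squared error; percentage points when inputs are percent."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and truth must have equal non-zero length")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def s_pooled(groups: Sequence[Sequence[float]]) -> float:
    """Pooled standard deviation across replicate groups.

    sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) ) with s_i the sample SD
    of group i.  Groups of fewer than two values are excluded with a
    warning; if none remain the input is invalid.
    """
    num = 0.0
    den = 0
    skipped = 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            skipped += 1
            continue
        num += (g.size - 1) * float(np.var(g, ddof=1))
        den += g.size - 1
    if skipped:
        warnings.warn(f"{skipped} group(s) of size < 2 excluded from S_pooled", stacklevel=2)
    if den == 0:
        raise ValueError("no group with at least two values")
    return float(np.sqrt(num / den))


@dataclass
class EvalReport:
    """Per-protein and aggregate metrics from one cross-validation run."""

    task: str
    per_protein: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    confusion: list | None = None
    classes: list | None = None
    selected_features: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_protein": self.per_protein,
            "aggregate": self.aggregate,
            "confusion": self.confusion,
            "classes": self.classes,
            "selected_features": self.selected_features,
            "details": self.details,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)


def loo_report(
    fold_results: Mapping[str, pd.DataFrame],
    task: str,
    *,
    classes: Sequence | None = None,
    targets: Sequence[str] = (),
    selected_features: Sequence = (),
) -> EvalReport:
    """Assemble the leave-one-protein-out report.

    ``fold_results`` maps each held-out protein to a table of its spectra
    with columns ``truth``/``pred`` (classification) or ``truth_<t>`` /
    ``pred_<t>`` per regression target.  Classification reports per-protein
    accuracy plus pooled confusion metrics, with the unweighted average of
    per-protein accuracies kept separate; regression reports per-protein
    mean prediction and SD, pooled RMSE and S_pooled per target.
    """
    if not fold_results:
        raise ValueError("no folds supplied")
    per_protein: dict = {}
    report = EvalReport(task=task, selected_features=list(selected_features))

    if task in ("class", "helix_length"):
        if classes is None:
            raise ValueError("classification reports require the class list")
        pooled_t: list = []
        pooled_p: list = []
        for pid, tbl in fold_results.items():
            correct = (tbl["truth"] == tbl["pred"]).mean()
            per_protein[pid] = {"accuracy": float(correct), "n_spectra": int(len(tbl))}
            pooled_t.extend(tbl["truth"])
            pooled_p.extend(tbl["pred"])
        confusion = confusion_from_labels(pooled_t, pooled_p, classes)
        report.confusion = confusion.tolist()
        report.classes = list(classes)
        report.aggregate = classification_metrics(confusion)
        report.aggregate["kappa"] = cohens_kappa(confusion)
        report.aggregate["mean_protein_accuracy"] = float(
            np.mean([v["accuracy"] for v in per_protein.values()])
        )
    else:
        if not targets:
            raise ValueError("regression reports require target names")
        for pid, tbl in fold_results.items():
            entry = {}
            for t in targets:
                p = tbl[f"pred_{t}"].to_numpy(float)
                entry[t] = {
                    "mean_prediction": float(p.mean()),
                    "prediction_sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
                    "truth": float(tbl[f"truth_{t}"].iloc[0]),
                }
            entry["n_spectra"] = int(len(tbl))
            per_protein[pid] = entry
        report.aggregate = {"rmse": {}, "rmse_protein_mean": {}, "s_pooled": {}}
        for t in targets:
            preds = np.concatenate([tbl[f"pred_{t}"].to_numpy(float) for tbl in fold_results.values()])
            truths = np.concatenate([tbl[f"truth_{t}"].to_numpy(float) for tbl in fold_results.values()])
            report.aggregate["rmse"][t] = rmse(preds, truths)
            # Headline LOO error: each protein contributes the average
            # prediction over its repeated spectra (the per-protein marker
            # of a predicted-vs-true plot), not one term per spectrum.
            report.aggregate["rmse_protein_mean"][t] = rmse(
                [per_protein[pid][t]["mean_prediction"] for pid in fold_results],
                [per_protein[pid][t]["truth"] for pid in fold_results],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    report.aggregate["s_pooled"][t] = s_pooled(
                        [tbl[f"pred_{t}"].to_numpy(float) for tbl in fold_results.values()]
                    )
                except ValueError:
                    report.aggregate["s_pooled"][t] = float("nan")
    report.per_protein = per_protein
    return report


def class_amplitude_summary(
    frame: FeatureFrame, selected: Sequence[int], class_column: str = "class"
) -> pd.DataFrame:
    """Mean spectral amplitude per class at each selected feature.

    Rows are classes, columns selected feature indices; an empty class
    yields a row of NaN (flagged rather than dropped).  Used to examine the
    positive -> near-zero -> negative amplitude trend from helix-enriched
    through mixed to sheet-enriched spectra at the selected pixels.
    """
    selected = np.asarray(list(selected), dtype=int)
    if selected.size and (selected.min() < 0 or selected.max() >= frame.n_features):
        raise ValueError("selected feature indices out of range")
    out = {}
    for cls, idx in frame.meta.groupby(class_column, sort=True).groups.items():
        rows = frame.X[np.asarray(idx, dtype=int)][:, selected]
        out[cls] = rows.mean(axis=0) if rows.size else np.full(selected.size, np.nan)
    return pd.DataFrame.from_dict(out, orient="index", columns=[int(i) for i in selected])


def plot_loo_report(report: EvalReport, path) -> None:
    """Save a summary figure for a leave-one-protein-out report.

    Classification: per-protein test accuracies sorted ascending.
    Regression: predicted-vs-true per protein with SD error bars, one
    panel per target, plus the identity line.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.confusion is not None:  # classification
        items = sorted(report.per_protein.items(), key=lambda kv: kv[1]["accuracy"])
        fig, ax = plt.subplots(figsize=(8, 3.2))
        ax.plot([v["accuracy"] for _, v in items], "ks", ms=4)
        ax.set_xticks(range(len(items)))
        ax.set_xticklabels([k for k, _ in items], rotation=90, fontsize=5)
        ax.set_ylabel("test accuracy")
        mean = report.aggregate.get("mean_protein_accuracy")
        if mean is not None:
            ax.set_title(f"mean per-protein accuracy {mean:.3f}", fontsize=9)
    else:  # regression
        targets = sorted(report.aggregate["rmse"])
        fig, axes = plt.subplots(1, len(targets), figsize=(4 * len(targets), 3.5), squeeze=False)
        for ax, target in zip(axes[0], targets):
            truth = [v[target]["truth"] for v in report.per_protein.values()]
            mean = [v[target]["mean_prediction"] for v in report.per_protein.values()]
            sd = [v[target]["prediction_sd"] for v in report.per_protein.values()]
            ax.errorbar(truth, mean, yerr=sd, fmt="ks", ms=4, lw=0.8, capsize=2)
            lim = (min(truth + mean) - 2, max(truth + mean) + 2)
            ax.plot(lim, lim, "g-", lw=1)
            ax.set_xlabel(f"true {target}")
            ax.set_ylabel(f"predicted {target}")
            ax.set_title(f"RMSE {report.aggregate['rmse_protein_mean'][target]:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
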