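"""Target labels for the machine-learning tasks.

Structural class is assigned from the helix/sheet fraction difference:
``alpha - beta >= threshold`` is helix-enriched, ``alpha - beta <=
-threshold`` sheet-enriched, everything else mixed (boundary cases fall in
the enriched classes).  The sign convention on the sheet-enriched rule is
the only reading that leaves the mixed class non-empty; the threshold is
exposed so alternative splits can be explored.

Regression targets (secondary-structure and sheet-registry fractions) are
expressed in percent, matching the units in which prediction errors are
reported.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .formatting import FeatureFrame
from .structures import StructureSpec

__all__ = [
    "CLASS_ALPHA",
    "CLASS_MIXED",
    "CLASS_BETA",
    "assign_class",
    "assign_helix_length_class",
    "label_frame",
    "label_table",
]

CLASS_ALPHA = "alpha_enriched"
CLASS_MIXED = "mixed"
CLASS_BETA = "beta_enriched"
CLASS_ORDER = (CLASS_ALPHA, CLASS_MIXED, CLASS_BETA)

HELIX_SHORT = "short_helices"
HELIX_LONG = "long_helices"

#: Default class threshold on the helix/sheet fraction difference.
CLASS_THRESHOLD = 0.2

#: Helix-length class cutoff (residues).
HELIX_LENGTH_CUTOFF = 15

TASKS = ("class", "fractions", "helix_length", "helix_count", "sheet_registry")


def assign_class(frac_alpha: float, frac_beta: float, threshold: float = CLASS_THRESHOLD) -> str:
    """Structural class from the helix/sheet fraction difference."""
    for name, v in (("frac_alpha", frac_alpha), ("frac_beta", frac_beta)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v!r} outside [0, 1]")
    diff = frac_alpha - frac_beta
    if diff >= threshold:
        return CLASS_ALPHA
    if diff <= -threshold:
        return CLASS_BETA
    return CLASS_MIXED


def assign_helix_length_class(
    helix_lengths: Sequence[int], cutoff: int = HELIX_LENGTH_CUTOFF
) -> str:
    """'long_helices' iff any helix is strictly longer than ``cutoff`` residues."""
    if any(l < 0 for l in helix_lengths):
        raise ValueError("helix lengths must be non-negative")
    return HELIX_LONG if max(helix_lengths, default=0) > cutoff else HELIX_SHORT


def _label_columns(spec: StructureSpec, task: str, threshold: float) -> dict:
    if task == "class":
        return {"class": assign_class(spec.frac_alpha, spec.frac_beta, threshold)}
    if task == "fractions":
        return {
            "frac_alpha_pct": 100.0 * spec.frac_alpha,
            "frac_beta_pct": 100.0 * spec.frac_beta,
        }
    if task == "helix_length":
        return {"helix_length_class": assign_helix_length_class(spec.helix_lengths)}
    if task == "helix_count":
        return {"n_helices": spec.n_helices}
    if task == "sheet_registry":
        return {
            "frac_parallel_pct": 100.0 * spec.frac_parallel,
            "frac_antiparallel_pct": 100.0 * spec.frac_antiparallel,
        }
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def label_frame(
    frame: FeatureFrame,
    structures: Mapping[str, StructureSpec],
    task: str,
    threshold: float = CLASS_THRESHOLD,
) -> FeatureFrame:
    """Return a copy of ``frame`` with the task's label columns appended.

    Every row's protein must have a structure record; labels are constant
    within each protein group by construction.
    """
    missing = set(frame.meta["protein_id"]) - set(structures)
    if missing:
        raise KeyError(f"no structure record for proteins: {sorted(missing)}")
    labels = pd.DataFrame(
        [_label_columns(structures[pid], task, threshold) for pid in frame.meta["protein_id"]]
    )
    meta = pd.concat([frame.meta.reset_index(drop=True), labels], axis=1)
    return frame.with_meta(meta)


def label_table(structures: Mapping[str, StructureSpec], threshold: float = CLASS_THRESHOLD) -> pd.DataFrame:
    """Per-protein label summary (one row per protein, all tasks)."""
    rows = []
    for pid, s in structures.items():
        rows.append(
            {
                "protein_id": pid,
                "class": assign_class(s.frac_alpha, s.frac_beta, threshold),
                "frac_alpha_pct": 100.0 * s.frac_alpha,
                "frac_beta_pct": 100.0 * s.frac_beta,
                "n_helices": s.n_helices,
                "max_helix_len": s.max_helix_length,
                "helix_length_class": assign_helix_length_class(s.helix_lengths),
                "frac_parallel_pct": 100.0 * s.frac_parallel,
                "frac_antiparallel_pct": 100.0 * s.frac_antiparallel,
            }
        )
    return pd.DataFrame(rows)
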