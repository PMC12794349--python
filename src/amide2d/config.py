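"""Study orchestration: simulate -> format -> label -> nested CV -> reports.

A :class:`StudyConfig` (optionally read from YAML) fully determines a run;
every artifact on disk is regenerable from the config plus its seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cv import CVPlan, run_nested_cv
from .errors import ConfigurationError
from .formatting import assemble_frame, bin_probe_axes
from .io import save_frame, write_library
from .labels import TASKS, label_frame, label_table
from .pipelines import PipelineSpec
from .simulate import AcquisitionPlan, SpectralLibrary, build_library
from .structures import sample_structures

__all__ = ["StudyConfig", "run_study", "make_fixture"]

log = logging.getLogger("amide2d")

#: Reduced acquisition plan used for fast fixtures: one cycle, three
#: waiting times, one detector.
_TINY_PLAN = dict(
    n_cycles=1, waiting_times=(250.0, 275.0, 300.0), n_detectors=1,
    n_replicates_default=2, replicate_overrides={},
)


def reduced_reference_plan() -> AcquisitionPlan:
    """Desk-scale analysis plan: one cycle, three waiting times, one
    detector, replicate accounting as in the full campaign.  The full
    6732-spectrum plan (``AcquisitionPlan.reference()``) is reserved for the
    accounting fixture; ML runs on it take hours on one CPU."""
    return AcquisitionPlan.reference(
        n_cycles=1, waiting_times=(250.0, 275.0, 300.0), n_detectors=1
    )


@dataclass
class StudyConfig:
    """Everything needed to reproduce a synthetic study end to end."""

    n_proteins: int = 35
    seed: int = 7
    plan: AcquisitionPlan = field(default_factory=reduced_reference_plan)
    tasks: tuple[str, ...] = ("class", "fractions")
    pipeline: dict[str, PipelineSpec] = field(default_factory=dict)
    cv: dict[str, CVPlan] = field(default_factory=dict)
    out_dir: str | None = None
    write_library: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ConfigurationError(f"unknown tasks: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("study config must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "plan" in raw:
            plan = dict(raw["plan"])
            use_reference = plan.pop("reference", False)
            if "waiting_times" in plan:
                plan["waiting_times"] = tuple(float(t) for t in plan["waiting_times"])
            raw["plan"] = AcquisitionPlan.reference(**plan) if use_reference else AcquisitionPlan(**plan)
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        if "pipeline" in raw:
            raw["pipeline"] = {k: PipelineSpec(**v) for k, v in raw["pipeline"].items()}
        if "cv" in raw:
            raw["cv"] = {k: CVPlan(**v) for k, v in raw["cv"].items()}
        return cls(**raw)


def _default_pipeline(task: str, seed: int) -> PipelineSpec:
    predictor = "svr_rbf" if task in ("fractions", "helix_count", "sheet_registry") else (
        "adaboost" if task == "helix_length" else "svc_rbf"
    )
    return PipelineSpec(selector="anova_f", predictor=predictor, seed=seed)


def _default_cv(task: str, seed: int) -> CVPlan:
    if task in ("class", "helix_length"):
        return CVPlan(outer="random_group_splits", n_splits=3, test_frac=0.2, seed=seed)
    return CVPlan(outer="loo_by_group")


def run_study(config: StudyConfig) -> dict:
    """Run the configured study; returns (and optionally writes) the summary.

    The output directory gains ``library/`` (optional), ``frames/`` and
    ``reports/`` plus a top-level ``summary.json`` holding every aggregate
    metric; identical configs produce identical summaries.
    """
    t0 = time.time()
    specs = sample_structures(config.n_proteins, config.seed)
    library = build_library(specs, config.plan, seed=config.seed)
    log.info("simulated %d spectra of %d proteins", len(library), len(specs))
    library = bin_probe_axes(library)
    frame = assemble_frame(library, mode="full")
    log.info("frame: %d rows x %d features", frame.n_spectra, frame.n_features)

    out = Path(config.out_dir) if config.out_dir else None
    if out:
        (out / "frames").mkdir(parents=True, exist_ok=True)
        (out / "reports").mkdir(parents=True, exist_ok=True)
        if config.write_library:
            write_library(library, out / "library")
        label_table(library.structures).to_csv(out / "labels.csv", index=False)

    summary: dict = {
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "n_spectra": len(library),
        "n_features": frame.n_features,
        "tasks": {},
    }
    for task in config.tasks:
        stage_t0 = time.time()
        labelled = label_frame(frame, library.structures, task)
        spec = config.pipeline.get(task, _default_pipeline(task, config.seed))
        plan = config.cv.get(task, _default_cv(task, config.seed))
        report = run_nested_cv(labelled, spec, plan, task=task)
        summary["tasks"][task] = report.aggregate
        log.info("task %s finished in %.1f s", task, time.time() - stage_t0)
        if out:
            report.save(out / "reports" / f"{task}.json")
            save_frame(labelled, out / "frames" / f"{task}.npz")
    summary["wall_time_s"] = round(time.time() - t0, 2)
    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def make_fixture(name: str, seed: int, out_dir=None) -> SpectralLibrary:
    """Build a named fixture library.

    ``tiny``: 6 proteins under the reduced plan (36 spectra, builds in
    seconds).  ``paper_scale``: the 35-protein panel under the full
    acquisition accounting (6732 spectra).
    """
    if name == "tiny":
        specs = sample_structures(6, seed)
        plan = AcquisitionPlan(**_TINY_PLAN)
    elif name == "paper_scale":
        specs = sample_structures(35, seed)
        plan = AcquisitionPlan.reference()
    else:
        raise ConfigurationError(f"unknown fixture {name!r} (expected 'tiny' or 'paper_scale')")
    library = build_library(specs, plan, seed=seed)
    if out_dir is not None:
        write_library(library, out_dir)
        label_table(library.structures).to_csv(Path(out_dir) / "labels.csv", index=False)
    return library
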