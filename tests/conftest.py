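"""Shared fixtures: seeded synthetic panels, libraries and frames.

Heavy objects (the 35-protein reduced-plan libraries and their frames) are
session-scoped so the evaluation tests share one build.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from amide2d import (
    AcquisitionPlan,
    StructureSpec,
    assemble_frame,
    bin_probe_axes,
    build_library,
    label_frame,
    make_fixture,
    sample_structures,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")

#: The canonical study seed used by every stage of the reference run.
STUDY_SEED = 7

#: Reduced acquisition plan for desk-scale runs: one cycle, three waiting
#: times, one detector, replicates as in the full campaign.
def reduced_plan(**kw) -> AcquisitionPlan:
    kw.setdefault("n_cycles", 1)
    kw.setdefault("waiting_times", (250.0, 275.0, 300.0))
    kw.setdefault("n_detectors", 1)
    return AcquisitionPlan.reference(**kw)


def _spec(pid, fa, fb, lengths, n_res=200, fp=0.0, strands=4.0):
    return StructureSpec(
        protein_id=pid,
        frac_alpha=sum(lengths) / n_res,
        frac_beta=fb,
        frac_parallel=fp,
        frac_antiparallel=fb - fp,
        helix_lengths=tuple(lengths),
        n_residues=n_res,
        mean_sheet_strands=strands,
    )


def archetype_specs() -> list[StructureSpec]:
    """Widely separated class archetypes (noise-free separability panel)."""
    return [
        _spec("arch_a1", 0.60, 0.02, (24, 24, 24, 24, 24)),
        _spec("arch_a2", 0.65, 0.05, (26, 26, 26, 26, 26), strands=3.0),
        _spec("arch_a3", 0.55, 0.00, (22, 22, 22, 22, 22)),
        _spec("arch_m1", 0.25, 0.28, (25, 25), strands=4.0),
        _spec("arch_m2", 0.30, 0.24, (30, 30), strands=5.0),
        _spec("arch_m3", 0.20, 0.30, (20, 20), strands=3.5),
        _spec("arch_b1", 0.04, 0.45, (8,), strands=6.0),
        _spec("arch_b2", 0.02, 0.40, (4,), strands=5.0),
        _spec("arch_b3", 0.06, 0.42, (12,), strands=7.0),
    ]


@pytest.fixture(scope="session")
def panel35():
    return sample_structures(35, STUDY_SEED)


@pytest.fixture(scope="session")
def tiny_library():
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_frame(tiny_library):
    return assemble_frame(bin_probe_axes(tiny_library), mode="full")


@pytest.fixture(scope="session")
def reference_reduced_library(panel35):
    """35-protein library under the reduced plan, default 2% noise."""
    return bin_probe_axes(build_library(panel35, reduced_plan(), seed=STUDY_SEED))


@pytest.fixture(scope="session")
def reference_reduced_frame(reference_reduced_library):
    return assemble_frame(reference_reduced_library, mode="full")


@pytest.fixture(scope="session")
def reference_noiseless_frame(panel35):
    lib = bin_probe_axes(
        build_library(panel35, reduced_plan(noise_sigma_rel=0.0), seed=STUDY_SEED)
    )
    return assemble_frame(lib, mode="full")


@pytest.fixture(scope="session")
def archetype_frame():
    """Noiseless, widely separated three-class panel (9 proteins)."""
    specs = archetype_specs()
    plan = AcquisitionPlan(
        n_cycles=1, waiting_times=(250.0, 275.0, 300.0), n_detectors=1,
        n_replicates_default=3, noise_sigma_rel=0.0,
    )
    lib = bin_probe_axes(build_library(specs, plan, seed=STUDY_SEED))
    frame = assemble_frame(lib, mode="full")
    return label_frame(frame, lib.structures, "class")
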