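"""Rendering of 2D-IR spectra and assembly of spectral libraries.

A spectrum is a pump x probe amplitude matrix on a wavenumber grid covering
the amide I region.  Each diagonal band contributes a negative (ground-state
bleach) 2D Gaussian at (pump = centre, probe = centre) elongated along the
spectrum diagonal and a positive (excited-state absorption) Gaussian at
(pump = centre, probe = centre - anharmonicity); cross peaks contribute the
same pair at an off-diagonal pump position.

The acquisition plan reproduces the accounting of the experimental
measurement campaign: replicates x cycles x waiting times x detectors
spectra per protein, a per-replicate probe-calibration offset, a small
waiting-time signal decay and per-detector gain factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bands import BandComponent, BandModelParams, DEFAULT_BAND_PARAMS, bands_from_structure
from .errors import ConfigurationError, IntegrityError
from .structures import PEROXIDASE_LIKE, PREALBUMIN_LIKE, StructureSpec

__all__ = [
    "Spectrum2DIR",
    "AcquisitionPlan",
    "SpectralLibrary",
    "default_pump_axis",
    "default_probe_axis",
    "render_spectrum",
    "build_library",
]

#: Amide I region bounds (cm-1) used for the default grids.
WNUM_LO = 1550.0
WNUM_HI = 1737.0
N_PUMP = 35
N_PROBE = 85


def default_pump_axis() -> np.ndarray:
    return np.linspace(WNUM_LO, WNUM_HI, N_PUMP)


def default_probe_axis() -> np.ndarray:
    """Probe grid: ~2.2 cm-1 spacing, finer than the pump axis, consistent
    with the ~3 cm-1 probe resolution of a dual-array detector."""
    return np.linspace(WNUM_LO, WNUM_HI, N_PROBE)


@dataclass
class Spectrum2DIR:
    """One gridded 2D-IR spectrum.

    ``amplitude[i, j]`` is the signal at pump ``pump_axis[i]`` and probe
    ``probe_axis[j]``; negative values are bleaches, positive values
    excited-state absorption.
    """

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump_axis = np.asarray(self.pump_axis, dtype=float)
        self.probe_axis = np.asarray(self.probe_axis, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.pump_axis.ndim != 1 or self.probe_axis.ndim != 1:
            raise ValueError("axes must be one-dimensional")
        if np.any(np.diff(self.pump_axis) <= 0) or np.any(np.diff(self.probe_axis) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.amplitude.shape != (self.pump_axis.size, self.probe_axis.size):
            raise ValueError("amplitude shape must match (pump, probe) axes")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def _default_waiting_times() -> tuple[float, ...]:
    return tuple(float(t) for t in range(250, 301, 5))


def _reference_overrides() -> dict[str, int]:
    return {PEROXIDASE_LIKE: 2, PREALBUMIN_LIKE: 1}


@dataclass(frozen=True)
class AcquisitionPlan:
    """Acquisition structure of a spectral library.

    Defaults reproduce the reference campaign: 3 measurement cycles, eleven
    waiting times from 250 to 300 fs in 5 fs steps, two detectors and
    triplicate samples, with a +-1.5 cm-1 per-replicate probe calibration
    offset and 2% relative noise.  ``replicate_overrides`` (empty by
    default) reduces the replicate count of named supply-limited proteins;
    :meth:`reference` supplies the canonical duplicate/single pair.
    """

    n_cycles: int = 3
    waiting_times: tuple[float, ...] = field(default_factory=_default_waiting_times)
    n_detectors: int = 2
    n_replicates_default: int = 3
    replicate_overrides: Mapping[str, int] = field(default_factory=dict)
    noise_sigma_rel: float = 0.02
    calib_jitter: float = 1.5
    t1_lifetime: float = 1000.0
    detector_gains: tuple[float, ...] = (1.0, 0.97)

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_detectors < 1 or self.n_replicates_default < 1:
            raise ConfigurationError("cycle, detector and replicate counts must be >= 1")
        if not self.waiting_times:
            raise ConfigurationError("at least one waiting time is required")
        if self.noise_sigma_rel < 0 or self.calib_jitter < 0 or self.t1_lifetime <= 0:
            raise ConfigurationError("noise, jitter and lifetime must be non-negative/positive")
        if len(self.detector_gains) < self.n_detectors:
            raise ConfigurationError("one gain factor per detector is required")

    @classmethod
    def reference(cls, **overrides) -> "AcquisitionPlan":
        """The full reference accounting (6732 spectra for the 35-protein
        panel): triplicate by default, duplicate peroxidase-like, single
        prealbumin-like."""
        overrides.setdefault("replicate_overrides", _reference_overrides())
        return cls(**overrides)

    @property
    def spectra_per_replicate(self) -> int:
        return self.n_cycles * len(self.waiting_times) * self.n_detectors

    def n_replicates(self, protein_id: str) -> int:
        return int(self.replicate_overrides.get(protein_id, self.n_replicates_default))

    def n_spectra(self, protein_ids: Sequence[str]) -> int:
        return sum(self.n_replicates(p) * self.spectra_per_replicate for p in protein_ids)


def _gauss2d(
    pump: np.ndarray, probe: np.ndarray, pump_c: float, probe_c: float,
    width_diag: float, width_antidiag: float,
) -> np.ndarray:
    """2D Gaussian elongated along the spectrum diagonal."""
    u = pump[:, None] - pump_c
    v = probe[None, :] - probe_c
    a = (u + v) / math.sqrt(2.0)
    b = (v - u) / math.sqrt(2.0)
    return np.exp(-0.5 * (a / width_diag) ** 2 - 0.5 * (b / width_antidiag) ** 2)


def render_spectrum(
    bands: Sequence[BandComponent],
    pump_axis: np.ndarray | None = None,
    probe_axis: np.ndarray | None = None,
    *,
    noise_sigma_rel: float = 0.0,
    tw: float = 250.0,
    detector: int = 0,
    detector_gains: Sequence[float] = (1.0, 0.97),
    day_offset: float = 0.0,
    t1_lifetime: float = 1000.0,
    seed: int = 0,
    meta: dict | None = None,
) -> Spectrum2DIR:
    """Render a band list onto a pump x probe grid.

    The probe axis is shifted by ``day_offset`` before gridding (the signal
    is evaluated on the shifted axis, mimicking a day-to-day calibration
    offset); the total signal decays as ``exp(-(tw - 250)/t1_lifetime)`` and
    is scaled by the per-detector gain.  Zero-mean Gaussian noise with a
    standard deviation of ``noise_sigma_rel`` times the signal maximum is
    added with seeded determinism.
    """
    pump = default_pump_axis() if pump_axis is None else np.asarray(pump_axis, dtype=float)
    probe = default_probe_axis() if probe_axis is None else np.asarray(probe_axis, dtype=float)
    scalars = (noise_sigma_rel, tw, day_offset, t1_lifetime)
    if not all(np.isfinite(scalars)):
        raise ValueError("rendering parameters must be finite")
    if noise_sigma_rel < 0:
        raise ValueError("noise_sigma_rel must be non-negative")
    if not 0 <= detector < len(detector_gains):
        raise ValueError("detector index outside the gain table")

    probe_shifted = probe + day_offset
    signal = np.zeros((pump.size, probe.size))
    for band in bands:
        pump_c = band.cross_pump if band.cross_pump is not None else band.center
        shape = (band.width_diag, band.width_antidiag)
        signal -= band.amplitude * _gauss2d(pump, probe_shifted, pump_c, band.center, *shape)
        signal += band.amplitude * _gauss2d(
            pump, probe_shifted, pump_c, band.partner_center, *shape
        )
    signal *= math.exp(-(tw - 250.0) / t1_lifetime) * detector_gains[detector]

    if noise_sigma_rel > 0:
        sigma = noise_sigma_rel * float(np.max(np.abs(signal), initial=0.0))
        if sigma > 0:
            rng = np.random.default_rng(seed)
            signal = signal + rng.normal(0.0, sigma, signal.shape)
    return Spectrum2DIR(pump, probe_shifted, signal, dict(meta or {}))


@dataclass
class SpectralLibrary:
    """A collection of spectra plus the per-protein ground truth.

    ``groups`` maps each protein id to the indices of its spectra in
    ``spectra``; the index sets partition the library.
    """

    spectra: list[Spectrum2DIR]
    structures: dict[str, StructureSpec]
    groups: dict[str, list[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pid, idx in self.groups.items():
            if pid not in self.structures:
                raise IntegrityError(f"group {pid!r} has no structure record")
            if seen & set(idx):
                raise IntegrityError("group index sets must be disjoint")
            seen.update(idx)
        if seen != set(range(len(self.spectra))):
            raise IntegrityError("group index sets must partition the spectra")
        for sp in self.spectra:
            if sp.meta.get("protein_id") not in self.structures:
                raise IntegrityError("every spectrum must reference a known protein")

    def __len__(self) -> int:
        return len(self.spectra)


def build_library(
    specs: Sequence[StructureSpec],
    plan: AcquisitionPlan,
    seed: int = 0,
    band_params: BandModelParams = DEFAULT_BAND_PARAMS,
) -> SpectralLibrary:
    """Simulate a full spectral library under an acquisition plan.

    Per protein, ``n_replicates x n_cycles x n_waiting_times x n_detectors``
    spectra are emitted; each replicate draws one probe calibration offset
    uniform in +-``calib_jitter``.  Identical inputs yield bit-identical
    libraries.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ids = [s.protein_id for s in specs]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate protein ids in specs")
    unknown = set(plan.replicate_overrides) - set(ids)
    if unknown:
        raise ConfigurationError(f"replicate_overrides name unknown proteins: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    spectra: list[Spectrum2DIR] = []
    groups: dict[str, list[int]] = {pid: [] for pid in ids}
    for spec in specs:
        bands = bands_from_structure(spec, band_params)
        for rep in range(plan.n_replicates(spec.protein_id)):
            day_offset = float(rng.uniform(-plan.calib_jitter, plan.calib_jitter))
            for cycle in range(plan.n_cycles):
                for tw in plan.waiting_times:
                    for det in range(plan.n_detectors):
                        spectrum_seed = int(rng.integers(0, 2**31 - 1))
                        sp = render_spectrum(
                            bands,
                            noise_sigma_rel=plan.noise_sigma_rel,
                            tw=tw,
                            detector=det,
                            detector_gains=plan.detector_gains,
                            day_offset=day_offset,
                            t1_lifetime=plan.t1_lifetime,
                            seed=spectrum_seed,
                            meta={
                                "protein_id": spec.protein_id,
                                "replicate": rep,
                                "cycle": cycle,
                                "detector": det,
                                "waiting_time": float(tw),
                                "day_offset": day_offset,
                            },
                        )
                        groups[spec.protein_id].append(len(spectra))
                        spectra.append(sp)
    return SpectralLibrary(spectra, {s.protein_id: s for s in specs}, groups)
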