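"""Formatting of a spectral library into an N x M analysis frame.

The amide I region (1550-1737 cm-1, inclusive) of each spectrum is
extracted, probe axes are binned to their per-pixel mean across the library
(absorbing the day-to-day calibration offsets), and each spectrum is
vectorised by concatenating its probe-direction slices in ascending pump
order.  The default grid yields 35 x 85 = 2975 features per spectrum; the
diagonal mode instead keeps the 35 pixels nearest the pump = probe line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, IntegrityError
from .simulate import SpectralLibrary, Spectrum2DIR

__all__ = [
    "FeatureFrame",
    "extract_amide_region",
    "bin_probe_axes",
    "vectorize",
    "extract_diagonal",
    "assemble_frame",
]

#: Amide I extraction window (cm-1), inclusive at both ends.
REGION_LO = 1550.0
REGION_HI = 1737.0

#: Probe calibration spread (cm-1) above which binning emits a warning
#: (the stated probe resolution).
MAX_PROBE_SPREAD = 3.0

_ROW_ORDER = ["protein_id", "replicate", "cycle", "waiting_time", "detector"]


@dataclass
class FeatureFrame:
    """N spectra x M features, plus per-row metadata.

    ``feature_coords[j] = (pump, probe)`` gives the spectral position of
    column ``j``; rows are ordered by (protein, replicate, cycle,
    waiting time, detector) regardless of library storage order.
    """

    X: np.ndarray
    feature_coords: np.ndarray
    meta: pd.DataFrame
    mode: str = "full"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_coords = np.asarray(self.feature_coords, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.feature_coords.shape != (self.X.shape[1], 2):
            raise ValueError("feature_coords must have one (pump, probe) pair per column")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix must be finite")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def groups(self) -> np.ndarray:
        """Per-row protein id (the CV group key)."""
        return self.meta["protein_id"].to_numpy()

    def with_meta(self, meta: pd.DataFrame) -> "FeatureFrame":
        return FeatureFrame(self.X, self.feature_coords, meta, self.mode)


def extract_amide_region(
    spectrum: Spectrum2DIR, lo: float = REGION_LO, hi: float = REGION_HI, tol: float = 1.0
) -> Spectrum2DIR:
    """Crop both axes to [lo, hi], inclusive at both ends.

    ``tol`` (cm-1) widens the window by a guard band smaller than one probe
    pixel so that a point nominally at a window edge is retained despite the
    sub-pixel calibration offset remaining after probe binning.
    """
    if lo > hi:
        raise ValueError(f"inverted bounds: lo={lo} > hi={hi}")
    pm = (spectrum.pump_axis >= lo - tol) & (spectrum.pump_axis <= hi + tol)
    rm = (spectrum.probe_axis >= lo - tol) & (spectrum.probe_axis <= hi + tol)
    if not pm.any() or not rm.any():
        raise ValueError("requested region does not intersect the spectrum axes")
    return Spectrum2DIR(
        spectrum.pump_axis[pm],
        spectrum.probe_axis[rm],
        spectrum.amplitude[np.ix_(pm, rm)],
        dict(spectrum.meta),
    )


def bin_probe_axes(library: SpectralLibrary) -> SpectralLibrary:
    """Replace every probe axis by the per-pixel-index mean across the library.

    Amplitudes are untouched; the operation is idempotent.  A warning is
    emitted (and binning still applied) if the per-pixel wavenumber spread
    exceeds the probe resolution.
    """
    shapes = {sp.shape for sp in library.spectra}
    if len(shapes) > 1:
        raise AlignmentError(f"spectra disagree in pixel counts: {sorted(shapes)}")
    axes = np.stack([sp.probe_axis for sp in library.spectra])
    spread = float(np.max(axes.max(axis=0) - axes.min(axis=0)))
    if spread > MAX_PROBE_SPREAD:
        warnings.warn(
            f"probe calibration spread {spread:.2f} cm-1 exceeds the "
            f"{MAX_PROBE_SPREAD} cm-1 resolution; binning applied anyway",
            stacklevel=2,
        )
    # Identical axes are kept bit-exact (also makes binning idempotent).
    mean_axis = axes[0] if spread == 0.0 else axes.mean(axis=0)
    spectra = [
        Spectrum2DIR(sp.pump_axis, mean_axis.copy(), sp.amplitude, dict(sp.meta))
        for sp in library.spectra
    ]
    return SpectralLibrary(spectra, dict(library.structures), {k: list(v) for k, v in library.groups.items()})


def vectorize(spectrum: Spectrum2DIR) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate probe-direction slices in ascending pump order.

    Returns the feature row (length ``n_pump * n_probe``) and the matching
    (pump, probe) coordinate array; feature ``i * n_probe + j`` is pixel
    (pump i, probe j).
    """
    n_pump, n_probe = spectrum.shape
    row = spectrum.amplitude.reshape(n_pump * n_probe)
    coords = np.column_stack(
        [np.repeat(spectrum.pump_axis, n_probe), np.tile(spectrum.probe_axis, n_pump)]
    )
    return row, coords


def extract_diagonal(spectrum: Spectrum2DIR) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude at the probe pixel nearest each pump frequency.

    The pump and probe grids differ in spacing, so the diagonal is defined
    by nearest-probe-pixel matching.
    """
    idx = np.abs(spectrum.probe_axis[None, :] - spectrum.pump_axis[:, None]).argmin(axis=1)
    row = spectrum.amplitude[np.arange(spectrum.pump_axis.size), idx]
    coords = np.column_stack([spectrum.pump_axis, spectrum.probe_axis[idx]])
    return row, coords


def assemble_frame(
    library: SpectralLibrary,
    mode: str = "full",
    lo: float = REGION_LO,
    hi: float = REGION_HI,
) -> FeatureFrame:
    """Build the N x M analysis frame from a (binned) library.

    Rows follow the stable (protein, replicate, cycle, waiting time,
    detector) order; duplicate metadata tuples raise an integrity error and
    spectra whose cropped axes disagree raise an alignment error (bin the
    library first).
    """
    if mode not in ("full", "diagonal"):
        raise ValueError("mode must be 'full' or 'diagonal'")
    if not library.spectra:
        raise ValueError("library is empty")

    meta = pd.DataFrame([sp.meta for sp in library.spectra])
    if meta.duplicated(subset=_ROW_ORDER).any():
        raise IntegrityError("duplicate (protein, replicate, cycle, waiting_time, detector) rows")
    order = meta.sort_values(_ROW_ORDER, kind="mergesort").index.to_numpy()

    rows, coords_ref = [], None
    for i in order:
        region = extract_amide_region(library.spectra[i], lo, hi)
        row, coords = (vectorize if mode == "full" else extract_diagonal)(region)
        if coords_ref is None:
            coords_ref = coords
        elif coords.shape != coords_ref.shape or not np.allclose(coords, coords_ref, atol=1e-9):
            raise AlignmentError("spectra disagree in feature coordinates; bin_probe_axes first")
        rows.append(row)
    return FeatureFrame(np.vstack(rows), coords_ref, meta.iloc[order].reset_index(drop=True), mode)
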