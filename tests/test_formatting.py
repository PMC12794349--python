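"""Region extraction, probe binning, vectorisation and frame assembly."""

import numpy as np
import pytest

from amide2d import (
    Spectrum2DIR,
    assemble_frame,
    bin_probe_axes,
    extract_amide_region,
    extract_diagonal,
    vectorize,
)
from amide2d.errors import AlignmentError, IntegrityError
from amide2d.simulate import (
    SpectralLibrary,
    default_probe_axis,
    default_pump_axis,
    render_spectrum,
)
from amide2d.bands import BandComponent, KIND_COIL


BAND = BandComponent(1650.0, 1634.0, 1.0, 10.0, 7.0, KIND_COIL)


class TestExtractAmideRegion:
    def test_identity_on_exact_default_grid(self):
        sp = render_spectrum([BAND], noise_sigma_rel=0.0)
        out = extract_amide_region(sp)
        assert out.shape == (35, 85)
        assert np.array_equal(out.amplitude, sp.amplitude)

    def test_padded_grid_crops_to_the_unpadded_result(self):
        pump = np.concatenate([[1500.0], default_pump_axis(), [1800.0]])
        probe = np.concatenate([[1500.0], default_probe_axis(), [1800.0]])
        padded = render_spectrum([BAND], pump, probe, noise_sigma_rel=0.0)
        plain = render_spectrum([BAND], noise_sigma_rel=0.0)
        out = extract_amide_region(padded)
        assert out.shape == (35, 85)
        np.testing.assert_allclose(out.amplitude, plain.amplitude, atol=1e-12)

    def test_inverted_bounds_raise(self):
        sp = render_spectrum([], noise_sigma_rel=0.0)
        with pytest.raises(ValueError):
            extract_amide_region(sp, lo=1737.0, hi=1550.0)

    def test_disjoint_window_raises(self):
        sp = render_spectrum([], noise_sigma_rel=0.0)
        with pytest.raises(ValueError):
            extract_amide_region(sp, lo=2000.0, hi=2100.0, tol=0.0)


class TestBinProbeAxes:
    def test_zero_jitter_axes_unchanged(self, specs=None):
        sp = [render_spectrum([BAND], noise_sigma_rel=0.0, meta={"protein_id": "p"}) for _ in range(3)]
        lib = SpectralLibrary(sp, {"p": _dummy_structure()}, {"p": [0, 1, 2]})
        out = bin_probe_axes(lib)
        np.testing.assert_array_equal(out.spectra[0].probe_axis, sp[0].probe_axis)

    def test_two_point_mean(self):
        a = render_spectrum([BAND], day_offset=-0.5, noise_sigma_rel=0.0, meta={"protein_id": "p"})
        b = render_spectrum([BAND], day_offset=+0.5, noise_sigma_rel=0.0, meta={"protein_id": "p"})
        lib = SpectralLibrary([a, b], {"p": _dummy_structure()}, {"p": [0, 1]})
        out = bin_probe_axes(lib)
        np.testing.assert_allclose(out.spectra[0].probe_axis, default_probe_axis(), atol=1e-12)
        np.testing.assert_array_equal(out.spectra[0].amplitude, a.amplitude)

    def test_jittered_library_shares_one_axis_and_is_idempotent(self, tiny_library):
        once = bin_probe_axes(tiny_library)
        ref = once.spectra[0].probe_axis
        for sp in once.spectra:
            np.testing.assert_array_equal(sp.probe_axis, ref)
        twice = bin_probe_axes(once)
        np.testing.assert_array_equal(twice.spectra[0].probe_axis, ref)

    def test_excess_spread_warns_but_bins(self):
        a = render_spectrum([BAND], day_offset=-2.5, noise_sigma_rel=0.0, meta={"protein_id": "p"})
        b = render_spectrum([BAND], day_offset=+2.5, noise_sigma_rel=0.0, meta={"protein_id": "p"})
        lib = SpectralLibrary([a, b], {"p": _dummy_structure()}, {"p": [0, 1]})
        with pytest.warns(UserWarning, match="spread"):
            out = bin_probe_axes(lib)
        np.testing.assert_allclose(out.spectra[0].probe_axis, default_probe_axis(), atol=1e-12)


class TestVectorize:
    def test_full_grid_yields_2975_features(self):
        sp = render_spectrum([BAND], noise_sigma_rel=0.0)
        row, coords = vectorize(sp)
        assert row.shape == (2975,)
        assert coords.shape == (2975, 2)

    def test_indexing_law_single_nonzero_pixel(self):
        amp = np.zeros((35, 85))
        amp[4, 17] = 3.5
        sp = Spectrum2DIR(default_pump_axis(), default_probe_axis(), amp)
        row, coords = vectorize(sp)
        assert np.flatnonzero(row).tolist() == [4 * 85 + 17]
        assert coords[4 * 85 + 17, 0] == pytest.approx(sp.pump_axis[4])
        assert coords[4 * 85 + 17, 1] == pytest.approx(sp.probe_axis[17])

    def test_round_trip_reshape(self):
        sp = render_spectrum([BAND], noise_sigma_rel=0.02, seed=1)
        row, _ = vectorize(sp)
        np.testing.assert_array_equal(row.reshape(35, 85), sp.amplitude)

    def test_column_count_law_on_non_default_grids(self):
        pump = np.linspace(1550, 1737, 10)
        probe = np.linspace(1550, 1737, 12)
        sp = render_spectrum([BAND], pump, probe, noise_sigma_rel=0.0)
        row, coords = vectorize(sp)
        assert row.shape == (120,)
        diag, _ = extract_diagonal(sp)
        assert diag.shape == (10,)


class TestExtractDiagonal:
    def test_length_is_pump_count(self):
        sp = render_spectrum([BAND], noise_sigma_rel=0.0)
        row, coords = extract_diagonal(sp)
        assert row.shape == (35,)
        # nearest-probe matching keeps the coordinate pairs close
        assert np.max(np.abs(coords[:, 0] - coords[:, 1])) <= 1.2

    def test_diagonal_peak_shows_as_row_minimum(self):
        sp = render_spectrum([BAND], noise_sigma_rel=0.0)
        row, _ = extract_diagonal(sp)
        assert row.argmin() == np.abs(sp.pump_axis - 1650.0).argmin()

    def test_zero_spectrum_gives_zero_row(self):
        sp = render_spectrum([], noise_sigma_rel=0.0)
        row, _ = extract_diagonal(sp)
        assert np.all(row == 0.0)


class TestAssembleFrame:
    def test_shapes_full_and_diagonal(self, tiny_library):
        binned = bin_probe_axes(tiny_library)
        full = assemble_frame(binned, mode="full")
        assert full.X.shape == (len(tiny_library), 2975)
        diag = assemble_frame(binned, mode="diagonal")
        assert diag.X.shape == (len(tiny_library), 35)

    def test_row_order_independent_of_storage_order(self, tiny_library):
        binned = bin_probe_axes(tiny_library)
        ref = assemble_frame(binned, mode="full")
        perm = np.random.default_rng(0).permutation(len(binned.spectra))
        inv = {int(old): new for new, old in enumerate(perm)}
        shuffled = SpectralLibrary(
            [binned.spectra[i] for i in perm],
            dict(binned.structures),
            {pid: [inv[i] for i in idx] for pid, idx in binned.groups.items()},
        )
        out = assemble_frame(shuffled, mode="full")
        np.testing.assert_array_equal(out.X, ref.X)
        assert out.meta["protein_id"].tolist() == ref.meta["protein_id"].tolist()

    def test_duplicate_meta_tuples_rejected(self, tiny_library):
        binned = bin_probe_axes(tiny_library)
        dup = SpectralLibrary(
            binned.spectra + [binned.spectra[0]],
            dict(binned.structures),
            {**{pid: list(idx) for pid, idx in binned.groups.items()},
             binned.spectra[0].meta["protein_id"]:
                 binned.groups[binned.spectra[0].meta["protein_id"]] + [len(binned.spectra)]},
        )
        with pytest.raises(IntegrityError):
            assemble_frame(dup, mode="full")

    def test_unbinned_jittered_library_is_refused(self, tiny_library):
        with pytest.raises(AlignmentError):
            assemble_frame(tiny_library, mode="full")


def _dummy_structure():
    from amide2d import StructureSpec

    return StructureSpec("p", 0.1, 0.0, 0.0, 0.0, (20,), 200, 2.0)
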