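"""Band model and spectrum rendering: positions, monotone maps, sign
structure and seeded determinism."""

import numpy as np
import pytest

from amide2d import StructureSpec, bands_from_structure, render_spectrum
from amide2d.bands import (
    BandComponent,
    KIND_COIL,
    KIND_CROSS,
    KIND_HELIX_A,
    KIND_SHEET_PARA,
    KIND_SHEET_PERP,
)


def spec(fa=0.0, fb=0.0, fp=0.0, lengths=(), n_res=200, strands=4.0, pid="p"):
    return StructureSpec(pid, sum(lengths) / n_res, fb, fp, fb - fp,
                         tuple(lengths), n_res, strands)


def kinds(bands):
    return {b.kind for b in bands}


class TestBandsFromStructure:
    def test_pure_long_helix_has_a_mode_near_1660_and_no_sheet(self):
        s = spec(lengths=(25, 25, 25, 25, 25, 25, 25, 25), n_res=200)
        bands = bands_from_structure(s)
        a = [b for b in bands if b.kind == KIND_HELIX_A]
        assert len(a) == 1 and 1650.0 <= a[0].center <= 1660.0
        assert KIND_SHEET_PERP not in kinds(bands)

    def test_all_coil_structure_gives_only_coil_band(self):
        bands = bands_from_structure(spec())
        assert kinds(bands) == {KIND_COIL}

    def test_anharmonic_partner_offset_on_every_band(self):
        s = spec(fb=0.3, lengths=(20, 10, 4), strands=5.0)
        for b in bands_from_structure(s):
            assert b.partner_center == pytest.approx(b.center - 16.0)

    def test_sheet_mode_monotone_in_strand_count(self):
        b2 = bands_from_structure(spec(fb=0.3, strands=2.0))
        b6 = bands_from_structure(spec(fb=0.3, strands=6.0))
        p2 = next(b for b in b2 if b.kind == KIND_SHEET_PERP)
        p6 = next(b for b in b6 if b.kind == KIND_SHEET_PERP)
        assert p6.center < p2.center
        assert p6.amplitude > p2.amplitude

    def test_helix_a_mode_center_non_increasing_in_max_length(self):
        centers = []
        for L in (8, 12, 20, 40):
            bands = bands_from_structure(spec(lengths=(L,), n_res=100))
            centers.append(next(b for b in bands if b.kind == KIND_HELIX_A).center)
        assert all(c1 >= c2 for c1, c2 in zip(centers, centers[1:]))

    def test_very_short_helices_scatter_into_weak_bands(self):
        bands = bands_from_structure(spec(lengths=(4, 5, 4), n_res=100))
        assert KIND_HELIX_A not in kinds(bands)
        scattered = [b for b in bands if b.kind != KIND_COIL]
        assert len(scattered) == 3

    def test_parallel_sheet_is_single_band_without_partner_modes(self):
        bands = bands_from_structure(spec(fb=0.3, fp=0.3, strands=4.0))
        assert KIND_SHEET_PARA not in kinds(bands)
        assert KIND_CROSS not in kinds(bands)
        sheet = [b for b in bands if b.kind == KIND_SHEET_PERP]
        assert len(sheet) == 1 and sheet[0].center == pytest.approx(1638.0)

    def test_antiparallel_sheet_carries_cross_peaks(self):
        bands = bands_from_structure(spec(fb=0.3, strands=4.0))
        crosses = [b for b in bands if b.kind == KIND_CROSS]
        assert len(crosses) == 2
        assert all(b.cross_pump is not None for b in crosses)


class TestRenderSpectrum:
    def test_empty_band_list_renders_zero_matrix(self):
        sp = render_spectrum([], noise_sigma_rel=0.0)
        assert np.all(sp.amplitude == 0.0)

    def test_single_band_extrema_at_bleach_and_partner_pixels(self):
        # The overlapping bleach/ESA pair pulls each extremum slightly away
        # from the other lobe, so allow one probe pixel of displacement.
        band = BandComponent(1650.0, 1634.0, 1.0, 10.0, 7.0, KIND_COIL)
        sp = render_spectrum([band], noise_sigma_rel=0.0)
        spacing = sp.probe_axis[1] - sp.probe_axis[0]
        i_min, j_min = np.unravel_index(sp.amplitude.argmin(), sp.shape)
        i_max, j_max = np.unravel_index(sp.amplitude.argmax(), sp.shape)
        assert i_min == i_max == np.abs(sp.pump_axis - 1650.0).argmin()
        assert abs(sp.probe_axis[j_min] - 1650.0) <= 1.5 * spacing
        assert abs(sp.probe_axis[j_max] - 1634.0) <= 1.5 * spacing

    def test_sign_structure_min_on_diagonal_max_below(self, panel35):
        for s in panel35[::11]:
            sp = render_spectrum(bands_from_structure(s), noise_sigma_rel=0.0)
            i_min, j_min = np.unravel_index(sp.amplitude.argmin(), sp.shape)
            i_max, j_max = np.unravel_index(sp.amplitude.argmax(), sp.shape)
            assert abs(sp.pump_axis[i_min] - sp.probe_axis[j_min]) < 3.0
            assert sp.probe_axis[j_max] < sp.pump_axis[i_max]

    def test_seeded_noise_is_bit_reproducible(self):
        band = BandComponent(1650.0, 1634.0, 1.0, 10.0, 7.0, KIND_COIL)
        a = render_spectrum([band], noise_sigma_rel=0.05, seed=3)
        b = render_spectrum([band], noise_sigma_rel=0.05, seed=3)
        assert np.array_equal(a.amplitude, b.amplitude)
        c = render_spectrum([band], noise_sigma_rel=0.05, seed=4)
        assert not np.array_equal(a.amplitude, c.amplitude)

    def test_waiting_time_decay_stays_within_five_percent(self):
        band = BandComponent(1650.0, 1634.0, 1.0, 10.0, 7.0, KIND_COIL)
        a = render_spectrum([band], tw=250.0, noise_sigma_rel=0.0)
        b = render_spectrum([band], tw=300.0, noise_sigma_rel=0.0)
        ratio = np.abs(b.amplitude).max() / np.abs(a.amplitude).max()
        assert ratio == pytest.approx(np.exp(-50.0 / 1000.0))
        assert 0.95 <= ratio < 1.0

    def test_detector_gain_scales_signal(self):
        band = BandComponent(1650.0, 1634.0, 1.0, 10.0, 7.0, KIND_COIL)
        a = render_spectrum([band], detector=0, noise_sigma_rel=0.0)
        b = render_spectrum([band], detector=1, noise_sigma_rel=0.0)
        assert np.allclose(b.amplitude, 0.97 * a.amplitude)

    def test_day_offset_shifts_probe_axis(self):
        sp = render_spectrum([], day_offset=1.2)
        assert sp.probe_axis[0] == pytest.approx(1551.2)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            render_spectrum([], tw=float("nan"))
        with pytest.raises(ValueError):
            render_spectrum([], noise_sigma_rel=-0.1)
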