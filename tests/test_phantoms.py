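"""Phantom generators: geometry, ground-truth values, determinism."""

import numpy as np
import pytest

import qpamark as q
from qpamark.phantoms import (
    BACKGROUND_SPECTRUM,
    MARKER_LABEL,
    N_WAVELENGTHS,
    UNKNOWN_SPECTRUM,
)


class TestNineRegion:
    def test_marker_and_level_span(self):
        optics, labels, marker = q.make_nine_region_phantom()
        assert np.all(optics.mu_a[marker.mask] == 0.2)
        values = [v for _, v in labels.legend.values()]
        assert min(values) == 0.001 and max(values) == 0.2
        assert len(set(values)) == 9  # nine distinct absorption levels

    def test_scored_region_truths(self):
        optics, labels, _ = q.make_nine_region_phantom()
        for label, truth in [(1, 0.020), (2, 0.075), (3, 0.150),
                             (4, 0.075), (5, 0.001)]:
            assert np.all(optics.mu_a[labels.pixels(label)] == truth)

    def test_depth_classes(self):
        # regions 1-3 shallow (< 10 mm from the nearest boundary),
        # region 4 deep below the top surface, region 5 in the marker shadow
        _, labels, marker = q.make_nine_region_phantom()
        grid = q.GridSpec(100, 100, 0.2)
        X, Y = grid.pixel_centers()
        border = np.minimum.reduce([X, Y, 20 - X, 20 - Y])
        for label in (1, 2, 3):
            assert border[labels.pixels(label)].max() < 10.0
        assert Y[labels.pixels(4)].min() > 10.0
        im, jm = np.nonzero(marker.mask)
        i5, j5 = np.nonzero(labels.pixels(5))
        assert i5.min() > im.max()              # strictly below the marker
        assert abs(j5.mean() - jm.mean()) < 2   # directly in its shadow

    def test_legend_matches_map_exactly(self):
        optics, labels, _ = q.make_nine_region_phantom()
        for label, (_, truth) in labels.legend.items():
            region = labels.pixels(label)
            if region.any():
                assert np.all(optics.mu_a[region] == truth)

    def test_uniform_scattering_and_positivity(self):
        optics, _, _ = q.make_nine_region_phantom()
        assert np.all(optics.mu_s_prime == 2.0)
        assert np.all(optics.mu_a >= 0)

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="too small"):
            q.make_nine_region_phantom(q.GridSpec(5, 5, 0.2))

    def test_marker_error_perturbs_prior_only(self):
        optics, _, marker = q.make_nine_region_phantom(marker_error=0.10)
        assert marker.mu_a_marker == pytest.approx(0.22)
        assert np.all(optics.mu_a[marker.mask] == 0.2)

    def test_bit_identical_regeneration(self):
        a = q.make_nine_region_phantom()
        b = q.make_nine_region_phantom()
        assert np.array_equal(a[0].mu_a, b[0].mu_a)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert np.array_equal(a[2].mask, b[2].mask)


class TestSpectral:
    def test_marker_invariant_across_wavelengths(self):
        for w in range(1, N_WAVELENGTHS + 1):
            optics, _, marker = q.make_spectral_phantom(w)
            assert np.all(optics.mu_a[marker.mask] == 0.2)
            assert marker.mu_a_marker == 0.2

    def test_wavelength_dependence(self):
        o1, l1, _ = q.make_spectral_phantom(1)
        o2, _, _ = q.make_spectral_phantom(2)
        bg = l1.labels == 0
        assert o1.mu_a[bg][0] != o2.mu_a[bg][0]

    def test_maps_trace_bundled_spectra(self):
        # the generated maps reproduce the bundled spectrum table exactly,
        # and the unknown chromophore's spectrum is unimodal (peak at w3)
        for w in range(1, N_WAVELENGTHS + 1):
            optics, labels, _ = q.make_spectral_phantom(w)
            annulus = labels.labels == 4
            assert np.all(optics.mu_a[annulus] == UNKNOWN_SPECTRUM[w - 1])
            assert np.all(optics.mu_a[labels.labels == 0] == BACKGROUND_SPECTRUM[w - 1])
        peak = int(np.argmax(UNKNOWN_SPECTRUM))
        assert np.all(np.diff(UNKNOWN_SPECTRUM[: peak + 1]) > 0)
        assert np.all(np.diff(UNKNOWN_SPECTRUM[peak:]) < 0)
        assert np.all(np.diff(BACKGROUND_SPECTRUM) > 0)

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_wavelength(self, bad):
        with pytest.raises(ValueError, match="wavelength_index"):
            q.make_spectral_phantom(bad)

    def test_subregions_lie_in_annulus(self):
        optics, labels, _ = q.make_spectral_phantom(3)
        for label in (1, 2, 3):
            assert labels.pixels(label).any()
            assert np.all(optics.mu_a[labels.pixels(label)] == UNKNOWN_SPECTRUM[2])


class TestCarotid:
    def test_component_truths(self):
        optics, labels, marker = q.make_carotid_phantom()
        assert np.all(optics.mu_a[marker.mask] == 0.650)
        name_of = {v[0]: k for k, v in labels.legend.items()}
        assert np.all(optics.mu_a[labels.pixels(name_of["lipid"])] == 0.013)
        assert np.all(optics.mu_a[labels.pixels(name_of["muscle"])] == 0.050)
        assert np.all(optics.mu_a[labels.pixels(0)] == 0.008)

    def test_marker_error_option(self):
        optics, _, marker = q.make_carotid_phantom(marker_error=0.10)
        assert marker.mu_a_marker == pytest.approx(0.715)
        assert np.all(optics.mu_a[marker.mask] == 0.650)

    def test_default_grid_is_24mm(self):
        optics, _, _ = q.make_carotid_phantom()
        assert optics.grid.extent == (24.0, 24.0)


class TestTwoLayer:
    def test_zero_thickness_ratio(self):
        h_u, h_m = q.make_two_layer_phantom(0.51, 0.44, 0.0)
        assert h_u / h_m == pytest.approx(0.51 / 0.44)

    def test_attenuated_marker_energy(self):
        _, h_m = q.make_two_layer_phantom(0.51, 0.44, 1.0)
        assert h_m == pytest.approx(0.44 * np.exp(-0.51))

    def test_vanishing_absorber(self):
        h_u, _ = q.make_two_layer_phantom(1e-12, 0.44, 2.0)
        assert h_u == pytest.approx(0.0, abs=1e-11)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q.make_two_layer_phantom(0.5, -0.1, 1.0)
        with pytest.raises(ValueError):
            q.make_two_layer_phantom(0.5, 0.4, -1.0)


def test_marker_prior_validation():
    mask = np.zeros((4, 4), bool)
    with pytest.raises(ValueError, match="empty"):
        q.MarkerPrior(mask, 0.2)
    mask[1, 1] = True
    with pytest.raises(ValueError, match="positive"):
        q.MarkerPrior(mask, 0.0)
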