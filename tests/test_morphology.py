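"""Density profiles, FWHM width estimation, and rendered maps."""

import numpy as np
import pytest

from sptpalmsim import (
    DensityProfile,
    Rectangle,
    SpineRegion,
    density_profile,
    fwhm,
    render_map,
)
from sptpalmsim.loc_error import _scatter


def uniform_strip_with_error(n, width, sigma_loc, rng, length=2000.0):
    """n localizations of fixed molecules uniform in a width x length strip."""
    x = rng.uniform(0.0, width, n)
    y = rng.uniform(0.0, length, n)
    err = _scatter((0.0, 0.0), sigma_loc, n, rng)
    return np.column_stack((x, y)) + err


class TestDensityProfile:
    def test_single_point(self):
        prof = density_profile(np.array([[5.0, 5.0]]), bin_width=10.0)
        assert (prof.counts > 0).sum() == 1
        assert prof.counts.sum() == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            density_profile(np.empty((0, 2)))

    def test_mass_conservation_with_region_alignment(self, rng):
        reg = Rectangle(100.0, 1000.0)
        pts = uniform_strip_with_error(5000, 100.0, 8.0, rng, length=1000.0)
        prof = density_profile(pts, axis="x", bin_width=10.0, region=reg)
        assert prof.counts.sum() == 5000  # edges extended so nothing is dropped

    def test_flat_top_profile(self, rng):
        """Uniform strip + small loc error: flat top with soft edges."""
        pts = uniform_strip_with_error(40_000, 100.0, 8.0, rng)
        prof = density_profile(pts, axis="x", bin_width=10.0, region=Rectangle(100.0, 2000.0))
        c = prof.counts.astype(float)
        interior = c[(prof.bin_centers > 20) & (prof.bin_centers < 80)]
        assert interior.std() / interior.mean() < 0.1  # flat within noise
        w = fwhm(prof).fwhm
        assert 100.0 - 10.0 <= w <= 100.0 + 2 * 8.0 + 10.0

    def test_dataframe_input_uses_detected_only(self):
        import pandas as pd

        df = pd.DataFrame(
            {"x_nm": [1.0, 2.0, 100.0], "y_nm": [0.0, 0.0, 0.0], "detected": [True, True, False]}
        )
        prof = density_profile(df, bin_width=10.0)
        assert prof.counts.sum() == 2


class TestFWHM:
    def test_rectangular_profile(self):
        """Exactly flat-top profile of w nm returns ~w."""
        edges = np.arange(-50.0, 160.0, 10.0)
        counts = ((edges[:-1] >= 0) & (edges[:-1] < 100)).astype(float) * 500
        w = fwhm(DensityProfile(edges, counts, "x")).fwhm
        assert w == pytest.approx(100.0, abs=10.0)

    def test_triangular_profile(self):
        """Triangle of base 2w has FWHM w."""
        centers = np.arange(-100.0, 101.0, 5.0)
        counts = np.clip(100.0 - np.abs(centers), 0, None)
        edges = np.arange(-102.5, 104.0, 5.0)
        w = fwhm(DensityProfile(edges, counts, "x")).fwhm
        assert w == pytest.approx(100.0, abs=5.0)

    def test_degenerate_profile_rejected(self):
        edges = np.arange(0.0, 60.0, 10.0)
        with pytest.raises(ValueError):
            fwhm(DensityProfile(edges, np.full(5, 7.0), "x"))

    def test_smoothing_flag(self, rng):
        pts = uniform_strip_with_error(2000, 100.0, 8.0, rng)
        prof = density_profile(pts, axis="x", bin_width=5.0)
        raw = fwhm(prof, smooth=False)
        sm = fwhm(prof, smooth=True)
        assert sm.smoothed and not raw.smoothed
        assert sm.fwhm == pytest.approx(raw.fwhm, abs=15.0)

    def test_bin_width_insensitivity(self, rng):
        """FWHM of the same data agrees within a bin over 5-25 nm bins."""
        pts = uniform_strip_with_error(30_000, 100.0, 8.0, rng)
        reg = Rectangle(100.0, 2000.0)
        widths = {
            bw: fwhm(density_profile(pts, "x", bw, reg)).fwhm for bw in (5.0, 10.0, 25.0)
        }
        ref = widths[10.0]
        for bw, w in widths.items():
            assert w == pytest.approx(ref, abs=bw + 5.0)

    def test_fwhm_matches_convolution_oracle(self, rng):
        """Measured strip FWHM equals the convolution-oracle prediction.

        Oracle: redraw uniform positions + the same empirical error kernel
        and push them through the identical estimator; the two estimates
        must agree within a bin width, and the width never exceeds the true
        width plus twice the kernel scale.
        """
        sigma = 8.0
        reg = Rectangle(100.0, 2000.0)
        w1 = fwhm(density_profile(uniform_strip_with_error(30_000, 100.0, sigma, rng), "x", 10.0, reg)).fwhm
        w2 = fwhm(density_profile(uniform_strip_with_error(30_000, 100.0, sigma, rng), "x", 10.0, reg)).fwhm
        assert w1 == pytest.approx(w2, abs=10.0)
        assert w1 <= 100.0 + 2 * sigma


class TestRenderMap:
    def test_empty_map(self):
        img = render_map(np.empty((0, 2)), 50.0)
        assert img.counts.sum() == 0

    def test_spine_footprint(self, rng):
        """t=0 localizations render the head/neck/dendrite footprint."""
        reg = SpineRegion()
        from sptpalmsim import sample_region_point

        pts = np.array([sample_region_point(reg, rng) for _ in range(8000)])
        pts = pts + _scatter((0.0, 0.0), 8.0, len(pts), rng)
        img = render_map(pts, 50.0, region=reg)
        assert img.counts.sum() + img.overflow == len(pts)
        # occupied pixels cover all three substructures
        ys, xs = np.nonzero(img.counts > 0)
        px, py = xs * 50.0 + 25.0, ys * 50.0 + 25.0
        assert reg.contains(750.0, 250.0)  # dendrite interior sanity
        for probe_x, probe_y in [(750.0, 250.0), (750.0, 1000.0), (750.0, 1750.0)]:
            assert np.any((np.abs(px - probe_x) < 50) & (np.abs(py - probe_y) < 50))

    def test_neck_occupancy_matches_geometry(self, rng):
        """Neck transverse occupancy at t=0 is ~neck width, not thinner."""
        reg = SpineRegion()
        from sptpalmsim import sample_region_point

        pts = np.array([sample_region_point(reg, rng) for _ in range(40_000)])
        pts = pts + _scatter((0.0, 0.0), 8.0, len(pts), rng)
        in_neck_band = (pts[:, 1] > 700) & (pts[:, 1] < 1300)
        prof = density_profile(pts[in_neck_band], axis="x", bin_width=10.0)
        w = fwhm(prof).fwhm
        assert w == pytest.approx(100.0, abs=20.0)

    def test_bad_pixel_size(self):
        with pytest.raises(ValueError):
            render_map(np.array([[0.0, 0.0]]), 0.0)
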