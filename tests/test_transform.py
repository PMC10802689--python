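"""The annulus-strip projection matrix and the 2D-to-3D inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poremap import (
    build_projection_matrix,
    fit_radial_peak,
    invert_projection,
    sample_cylinder_volume,
    sample_route_points,
    apply_localization_noise,
    select_r_binwidth,
    transform_2d_to_3d,
)
from poremap.errors import InsufficientDataError, NoPeakError

from conftest import make_table


class TestProjectionMatrix:
    def test_single_bin_is_whole_disk(self):
        basis = build_projection_matrix(10.0, 1)
        assert basis.A[0, 0] == pytest.approx(np.pi * 100.0)

    @pytest.mark.parametrize("delta,n", [(10.0, 3), (5.0, 7), (2.5, 12)])
    def test_column_sums_are_annulus_areas(self, delta, n):
        basis = build_projection_matrix(delta, n)
        assert np.allclose(basis.A.sum(axis=0), basis.annulus_areas, rtol=1e-12)

    def test_upper_triangular(self):
        basis = build_projection_matrix(10.0, 5)
        assert np.allclose(np.tril(basis.A, -1), 0.0)
        assert (basis.A >= 0).all()

    def test_entries_match_monte_carlo_areas(self):
        # geometric oracle: area fractions estimated from uniform points
        basis = build_projection_matrix(10.0, 3)
        rng = np.random.default_rng(0)
        n = 10**6
        for i in range(3):
            r_lo, r_hi = 10.0 * i, 10.0 * (i + 1)
            r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, n))
            theta = rng.uniform(0, 2 * np.pi, n)
            y = np.abs(r * np.cos(theta))
            counts, _ = np.histogram(y, bins=basis.edges)
            annulus_area = np.pi * (r_hi**2 - r_lo**2)
            mc_areas = counts / n * annulus_area
            assert np.allclose(mc_areas, basis.A[:, i], rtol=0, atol=0.005 * annulus_area)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_projection_matrix(0.0, 3)
        with pytest.raises(ValueError):
            build_projection_matrix(10.0, 0)


class TestInversion:
    def test_axial_point_source_stays_innermost(self):
        basis = build_projection_matrix(10.0, 4)
        h = np.array([120.0, 0.0, 0.0, 0.0])
        res = invert_projection(h, basis)
        assert res.rho[0] > 0
        assert np.allclose(res.rho[1:], 0.0)

    def test_round_trip_identity(self):
        basis = build_projection_matrix(10.0, 6)
        rng = np.random.default_rng(1)
        rho = rng.uniform(0.0, 5.0, 6)
        res = invert_projection(basis.A @ rho, basis)
        assert np.allclose(res.rho, rho, atol=1e-10)
        assert res.clamped_mass == 0.0

    def test_uniform_disk_recovered_flat(self):
        # 1e5 projected points uniform in a disk of radius 3*delta
        tab = sample_cylinder_volume(30.0, (-20, 20), 100_000, seed=3)
        dmap = transform_2d_to_3d(tab, min_per_bin=100_000, dr=10.0)
        profile = dmap.rho[0]
        assert np.all(np.abs(profile / profile.mean() - 1.0) < 0.02)

    def test_poisson_uncertainty_propagation(self):
        basis = build_projection_matrix(10.0, 1)
        res = invert_projection(np.array([400.0]), basis)
        # single bin: rho = h / A, sigma = sqrt(h) / A
        assert res.sigma[0] == pytest.approx(20.0 / basis.A[0, 0])

    def test_length_mismatch_rejected(self):
        basis = build_projection_matrix(10.0, 3)
        with pytest.raises(ValueError):
            invert_projection(np.ones(4), basis)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    rho=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=6),
    delta=st.floats(2.0, 20.0),
)
def test_forward_then_invert_is_identity(rho, delta):
    """Oracle equivalence on any nonnegative density over <= 6 annuli."""
    rho = np.asarray(rho)
    basis = build_projection_matrix(delta, len(rho))
    res = invert_projection(basis.A @ rho, basis)
    assert np.allclose(res.rho, rho, atol=1e-8)


class TestTransform2Dto3D:
    def test_noiseless_shell_peaks_in_true_annulus_every_x_bin(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 2000, seed=2)
        dmap = transform_2d_to_3d(tab, min_per_bin=200, dr=10.0)
        assert len(dmap.bin_counts) == 10
        for b in range(len(dmap.bin_counts)):
            assert np.argmax(dmap.rho[b]) == 2  # annulus [20, 30)

    def test_min_per_bin_floor_enforced(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 150, seed=4)
        with pytest.raises(InsufficientDataError):
            transform_2d_to_3d(tab, min_per_bin=200)

    def test_on_axis_source_concentrates_innermost(self):
        rng = np.random.default_rng(5)
        tab = make_table(rng.uniform(-20, 20, 1000), np.zeros(1000))
        dmap = transform_2d_to_3d(tab, min_per_bin=250, dr=10.0)
        for b in range(len(dmap.bin_counts)):
            assert np.argmax(dmap.rho[b]) == 0

    def test_mass_conservation_per_bin(self):
        tab = sample_route_points(25.0, 5.0, (-20, 20), 2000, seed=6)
        dmap = transform_2d_to_3d(tab, min_per_bin=400, dr=10.0)
        for b in range(len(dmap.bin_counts)):
            if dmap.clamped_mass[b] == 0:
                mass = np.sum(dmap.rho[b] * dmap.annulus_areas)
                assert mass == pytest.approx(dmap.bin_counts[b] / dmap.n_total, rel=1e-9)

    def test_every_bin_reaches_count_floor(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 1234, seed=7)
        dmap = transform_2d_to_3d(tab, min_per_bin=300, dr=10.0)
        assert (dmap.bin_counts >= 300).all()
        assert dmap.bin_counts.sum() == 1234

    def test_folded_histogram_symmetry(self):
        # uniform-angle sampling means +y and -y strips agree within noise
        tab = sample_route_points(25.0, 0.0, (-20, 20), 50_000, seed=8)
        y = tab["y_nm"].to_numpy()
        pos, _ = np.histogram(y[y > 0], bins=[0, 10, 20, 30])
        neg, _ = np.histogram(-y[y < 0], bins=[0, 10, 20, 30])
        assert np.all(np.abs(pos - neg) < 4.0 * np.sqrt((pos + neg) / 2.0))


class TestRadialPeak:
    def test_single_annulus_mass_peaks_at_bin_center(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 500, seed=9)
        dmap = transform_2d_to_3d(tab, min_per_bin=500, dr=10.0)
        peak = fit_radial_peak(dmap, 0)
        assert peak.radius == pytest.approx(25.0, abs=1e-6)

    def test_noisy_shell_peak_within_one_bin(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 500, seed=10)
        noisy = apply_localization_noise(tab, 10.0, seed=11)
        dmap = transform_2d_to_3d(noisy, min_per_bin=500, dr=10.0)
        peak = fit_radial_peak(dmap, 0)
        assert abs(peak.radius - 25.0) <= 10.0

    def test_uniform_disk_flagged_or_rejected(self):
        tab = sample_cylinder_volume(30.0, (-20, 20), 20_000, seed=12)
        dmap = transform_2d_to_3d(tab, min_per_bin=20_000, dr=10.0)
        try:
            peak = fit_radial_peak(dmap, 0)
            assert peak.low_curvature or peak.width > 30.0
        except NoPeakError:
            pass  # degenerate profile is an acceptable outcome


class TestBinWidthSelection:
    def test_dense_shell_chooses_finest_consistent_width(self):
        tab = sample_route_points(25.0, 3.0, (-20, 20), 20_000, seed=13)
        noisy = apply_localization_noise(tab, 5.0, seed=14)
        report = select_r_binwidth(noisy, [5.0, 10.0, 15.0], min_per_bin=20_000)
        assert report.chosen == 5.0
        assert len(report.table) == 3

    def test_sparse_data_falls_back_to_coarser_width(self):
        tab = sample_route_points(25.0, 3.0, (-20, 20), 200, seed=15)
        noisy = apply_localization_noise(tab, 10.0, seed=16)
        report = select_r_binwidth(noisy, [2.0, 10.0], min_per_bin=200)
        assert report.chosen >= 10.0 or report.warning

    def test_single_candidate_returned_unchanged(self):
        tab = sample_route_points(25.0, 0.0, (-20, 20), 400, seed=17)
        report = select_r_binwidth(tab, [10.0], min_per_bin=400)
        assert report.chosen == 10.0
        assert len(report.table) == 1
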