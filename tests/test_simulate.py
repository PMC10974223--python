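"""Simulator: phantoms, polychromatic forward projection, scatter, noise."""

import numpy as np
import pytest

from castct import (
    Spectrum,
    add_poisson_noise,
    default_spectrum,
    flat_field_correct,
    forward_project,
    geometry_for_phantom,
    inject_scatter,
    make_phantom,
    neg_log,
)
from castct.simulate import ENERGIES_KEV, MATERIALS, mu_of


class TestMaterialsAndSpectrum:
    def test_attenuation_nonincreasing_with_energy(self):
        for name, mu in MATERIALS.items():
            assert np.all(np.diff(mu) <= 0), name

    def test_spectrum_normalised(self):
        s = default_spectrum()
        assert s.weights.sum() == pytest.approx(1.0)
        assert np.all(s.weights >= 0)

    def test_mono_spectrum_single_bin(self):
        s = Spectrum.mono(60.0)
        assert s.is_mono
        assert s.effective_mu("water") == pytest.approx(
            mu_of("water", np.array([60.0]))[0]
        )


class TestMakePhantom:
    def test_disk_area_matches_analytic(self):
        ph = make_phantom("disk", size=256, voxel_size=0.25)
        r_mm = 0.40 * 256 * 0.25 / 2
        n_expected = np.pi * r_mm**2 / 0.25**2
        n_actual = int((ph.material_ids == 1).sum())
        assert abs(n_actual - n_expected) / n_expected < 0.015

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("disk", voxel_size=0.0)
        with pytest.raises(ValueError):
            make_phantom("klein_bottle")

    def test_deterministic_for_fixed_seed(self):
        a = make_phantom("dental_arch", size=64, seed=9)
        b = make_phantom("dental_arch", size=64, seed=9)
        assert np.array_equal(a.material_ids, b.material_ids)
        c = make_phantom("dental_arch", size=64, seed=10)
        assert not np.array_equal(a.material_ids, c.material_ids)

    def test_quart_like_has_three_materials(self):
        ph = make_phantom("quart_like", size=64)
        assert set(np.unique(ph.material_ids)) == {0, 1, 2}
        assert ph.materials == ("air", "pmma", "pvc")

    def test_3d_arch_has_solid_base(self):
        ph = make_phantom("dental_arch", size=48, n_slices=12)
        assert ph.is_3d
        # base slices are supersets of crown slices in footprint
        base = ph.material_ids[0] > 0
        assert base.sum() > 0


class TestForwardProject:
    def test_central_ray_beer_lambert(self, mono_disk_scan, mono_spectrum):
        """Mono beam through the disk diameter: I = exp(-mu d) within 1%."""
        mu = mono_spectrum.effective_mu("plaster")
        ph = make_phantom("disk", size=128, voxel_size=0.5)
        n = mono_disk_scan.geometry.det_cols
        # rasterised chord through the central detector rows (the nominal
        # diameter differs from it by up to one voxel of rasterisation)
        d = ph.material_ids[n // 2 - 1 : n // 2 + 1].sum(axis=1).max() * 0.5
        central = mono_disk_scan.intensities[0, 0, n // 2 - 1 : n // 2 + 1].min()
        assert central == pytest.approx(np.exp(-mu * d), rel=0.01)
        assert d == pytest.approx(2 * 0.40 * 128 * 0.5 / 2, rel=0.02)

    def test_empty_phantom_transmits_everything(self):
        ph = make_phantom("disk", size=32)
        ph.material_ids[:] = 0
        geo = geometry_for_phantom(ph, n_views=8)
        stack = forward_project(ph, geo, Spectrum.mono(60))
        assert np.allclose(stack.intensities, 1.0)

    def test_polychromatic_jensen_bound(self, poly_disk_scan, poly_spectrum):
        """I >= exp(-mu_eff d) on every ray (Jensen's inequality)."""
        mu_eff = poly_spectrum.effective_mu("plaster")
        mono_equiv = forward_project(
            make_phantom("disk", size=128, voxel_size=0.5),
            poly_disk_scan.geometry,
            Spectrum(np.array([50.0]), np.array([1.0])),
        )
        # recover the exact path lengths from the mono projection at a
        # reference energy: t = P_mono / mu(50)
        t = -np.log(mono_equiv.intensities) / mu_of("plaster", np.array([50.0]))[0]
        assert np.all(poly_disk_scan.intensities >= np.exp(-mu_eff * t) - 1e-9)

    def test_hardening_makes_log_projection_concave_in_thickness(self, poly_spectrum):
        t = np.linspace(0.5, 40.0, 60)
        mu = mu_of("plaster", poly_spectrum.energies)
        I = np.sum(
            poly_spectrum.weights[:, None] * np.exp(-np.outer(mu, t)), axis=0
        )
        P = -np.log(I)
        assert np.all(np.diff(P, 2) < 0)

    def test_geometry_mismatch_raises(self):
        # 3-D phantom projected with a detector row count that does not
        # match its slice count
        ph = make_phantom("dental_arch", size=32, n_slices=8)
        geo = geometry_for_phantom(make_phantom("dental_arch", size=32, n_slices=10), n_views=8)
        with pytest.raises(ValueError, match="det_rows"):
            forward_project(ph, geo)
        # 2-D phantom needs a single detector row
        ph2 = make_phantom("disk", size=32)
        geo2 = geometry_for_phantom(ph, n_views=8)
        with pytest.raises(ValueError, match="det_rows"):
            forward_project(ph2, geo2)


class TestInjectScatter:
    def test_zero_spr_is_identity(self, mono_disk_scan):
        out = inject_scatter(mono_disk_scan, 0.0, 10.0)
        assert np.array_equal(out.intensities, mono_disk_scan.intensities)

    def test_negative_spr_rejected(self, mono_disk_scan):
        with pytest.raises(ValueError):
            inject_scatter(mono_disk_scan, -0.1, 10.0)

    def test_scatter_fraction_of_deficit(self, mono_disk_scan):
        spr = 0.3
        out = inject_scatter(mono_disk_scan, spr, 12.0)
        S = out.intensities - mono_disk_scan.intensities
        deficit = 1.0 - mono_disk_scan.intensities
        assert S.mean() / deficit.mean() == pytest.approx(spr, rel=0.02)
        assert np.all(S >= 0)

    def test_scatter_is_smooth(self, mono_disk_scan):
        """Per-pixel gradient of S bounded by the Gaussian smoothing bound
        max|d/dx (G*f)| <= max|f| * 2 g(0) = max|f| * sqrt(2/pi)/sigma."""
        spr, sigma = 0.3, 12.0
        out = inject_scatter(mono_disk_scan, spr, sigma)
        S = out.intensities - mono_disk_scan.intensities
        grad = np.abs(np.diff(S, axis=2)).max()
        bound = spr * (1.0 - mono_disk_scan.intensities).max() * np.sqrt(
            2 / np.pi
        ) / sigma
        assert grad <= bound * 1.05


class TestPoissonNoise:
    def test_seed_reproducible(self, mono_disk_scan):
        a = add_poisson_noise(mono_disk_scan, 1e4, seed=5)
        b = add_poisson_noise(mono_disk_scan, 1e4, seed=5)
        assert np.array_equal(a.intensities, b.intensities)
        c = add_poisson_noise(mono_disk_scan, 1e4, seed=6)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_mean_and_variance(self, small_geometry):
        from castct import ProjectionStack

        g = small_geometry
        counts, I = 1e4, 0.5
        n = g.n_views * 32
        stack = ProjectionStack(
            intensities=np.full((g.n_views, 1, 32), I), geometry=g
        )
        # tile many draws by reusing the (independent) pixels of one stack
        draws = np.concatenate(
            [
                add_poisson_noise(stack, counts, seed=s).intensities.ravel()
                for s in range(135)
            ]
        )
        assert draws.size >= 1e5
        se = np.sqrt(I / counts / draws.size)
        assert abs(draws.mean() - I) < 3 * se
        rel_std = draws.std() / I
        assert rel_std == pytest.approx(1 / np.sqrt(counts * I), rel=0.05)

    def test_invalid_counts(self, mono_disk_scan):
        with pytest.raises(ValueError):
            add_poisson_noise(mono_disk_scan, 0.0)


def test_mono_disk_fbp_recovers_mu(mono_disk_scan, mono_spectrum):
    """Simulator + preprocessing + FBP recovers the true attenuation within
    2% away from edges -- the anchor for all downstream stages."""
    from castct import fbp_reconstruct

    geo = mono_disk_scan.geometry
    P = neg_log(flat_field_correct(mono_disk_scan), geo)
    vol = fbp_reconstruct(P)
    mu = mono_spectrum.effective_mu("plaster")
    n = vol.values.shape[0]
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    r_px = 0.40 * n / 2
    roi = (xx - c) ** 2 + (yy - c) ** 2 < (0.5 * r_px) ** 2
    assert vol.values[roi].mean() == pytest.approx(mu, rel=0.02)
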