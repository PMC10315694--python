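"""OSEM reconstruction, update ladder, and postfilter."""

import math

import numpy as np
import pytest

import ra224spect as r
from ra224spect.recon import (
    DEFAULT_LADDER_UPDATES,
    InvalidSettingsError,
    PREFILTER_FOR_POSTFILTER,
)
from ra224spect.simulate import (
    AcquisitionProtocol,
    RotationOperator,
    attenuation_factors,
    forward_project,
    view_angles,
)


def _uniform_fixture(shape=(24, 24, 8), n_views=2, counts_per_bin=40.0):
    """mu = 0, axis-aligned views, uniform projections."""
    mu = r.VoxelVolume(values=np.zeros(shape), spacing=4.8)
    prot = AcquisitionProtocol(n_views=n_views, t_view=1.0, matrix=shape[0],
                               bin_size=4.8)
    y = np.full((n_views, shape[0], shape[2]), counts_per_bin)
    ps = r.ProjectionSet(main=y, lower_scatter=np.zeros_like(y),
                         upper_scatter=np.zeros_like(y), protocol=prot, seed=0)
    return ps, mu


def _noise_free_phantom(shape=(32, 32, 20), spacing=4.8, n_views=8):
    spec = r.PhantomSpec(sphere_concentrations=(30.0,) * 6)
    act, mu = r.voxelize(spec, spacing, r.MU_WATER_PER_CM[240],
                         shape=shape, subsample=2)
    sys_ = r.SystemModel(
        collimator="ME", window_name="240 keV", windows=r.gamma_window_set(),
        sensitivity=0.1, psf_sigma0_mm=0.0, psf_slope=0.0, primary_fraction=1.0,
    )
    prot = AcquisitionProtocol(n_views=n_views, t_view=30.0, matrix=shape[0],
                               bin_size=spacing, windows=sys_.windows)
    primary = forward_project(act, mu, sys_, prot, psf=False)
    ps = r.ProjectionSet(main=primary, lower_scatter=np.zeros_like(primary),
                         upper_scatter=np.zeros_like(primary), protocol=prot,
                         seed=0)
    return act, mu, ps


class TestLadder:
    def test_default_ladder_contents(self):
        ladder = r.build_ladder()
        ups = ladder.updates
        assert len(ups) == 24
        assert ups[0] == 5 and ups[-1] == 900
        assert all(b > a for a, b in zip(ups, ups[1:]))
        # every optimum reported for the study is reachable
        reported = {5, 12, 16, 20, 24, 30, 34, 42, 48, 60, 75, 90, 120, 150,
                    180, 240, 300, 360, 480, 600, 720, 900}
        assert reported <= set(ups)

    @pytest.mark.parametrize(
        "updates,expected",
        [(60, (30, 2)), (5, (5, 1)), (30, (30, 1)), (90, (30, 3)),
         (900, (150, 6))],
    )
    def test_factorization(self, updates, expected):
        assert r.factorize_updates(updates, n_views=60) == expected

    def test_unfactorizable_updates_raise(self):
        with pytest.raises(InvalidSettingsError):
            r.factorize_updates(7, n_views=8, allowed_subsets=(2, 4))

    def test_prefilter_pairing(self):
        assert PREFILTER_FOR_POSTFILTER == {9.0: 9.0, 12.0: 16.0, 16.0: 20.0}
        s = r.ReconSettings.for_protocol(60, 60, scatter_correction=True,
                                         postfilter_fwhm=12.0)
        assert s.scatter_prefilter_fwhm == 16.0
        s2 = r.ReconSettings.for_protocol(60, 60, scatter_correction=False,
                                          postfilter_fwhm=12.0)
        assert s2.scatter_prefilter_fwhm == 0.0

    def test_subsets_must_divide_views(self, me240_projections, desk_volumes):
        _, mu = desk_volumes
        settings = r.ReconSettings(iterations=2, subsets=7)
        with pytest.raises(InvalidSettingsError):
            r.osem(me240_projections, mu, settings)


class TestOsem:
    def test_mlem_count_preservation(self):
        """Uniform projections, mu = 0, 1 it x 1 ss from a uniform start:
        flat image whose total matches the projection counts within 0.5%."""
        ps, mu = _uniform_fixture()
        vol = r.osem(ps, mu, r.ReconSettings(iterations=1, subsets=1))
        vals = vol.values
        assert np.ptp(vals) / vals.mean() < 1e-9  # flat
        assert vals.sum() == pytest.approx(ps.main.sum(), rel=0.005)

    def test_matches_reference_mlem(self):
        """OSEM with 1 subset reproduces an independently coded MLEM loop."""
        act, mu, ps = _noise_free_phantom(shape=(24, 24, 8), n_views=4)
        vol = r.osem(ps, mu, r.ReconSettings(iterations=3, subsets=1))

        # reference MLEM written directly against the operator primitives
        y = ps.main.astype(float)
        nx, ny, nz = mu.values.shape
        V = ps.protocol.n_views
        rots = [RotationOperator.get(nx, ny, -a) for a in view_angles(V)]
        atts = [attenuation_factors(rot.apply(mu.values), mu.spacing)
                for rot in rots]
        sens = sum(rots[v].apply_adjoint(atts[v]) for v in range(V)) / V
        x = np.where(mu.values > 0, max(y.mean(), 1.0), 0.0)
        for _ in range(3):
            back = np.zeros_like(x)
            for v in range(V):
                est = (rots[v].apply(x) * atts[v]).sum(axis=1) / V
                back += rots[v].apply_adjoint(
                    atts[v] * (y[v] / np.maximum(est, 1e-12))[:, None, :]
                )
            x = x * (back / V) / np.maximum(sens, 1e-12)
            x[sens <= 1e-12] = 0.0
        np.testing.assert_allclose(vol.values, x, rtol=1e-8, atol=1e-10)

    def test_rmse_decreases_early(self):
        """Noise-free, scatter-free phantom data: distance to the truth
        shrinks over the first 10 updates."""
        act, mu, ps = _noise_free_phantom()
        truth = act.values / max(act.values.sum(), 1e-12)
        errs = []
        for it in (1, 4, 10):
            vol = r.osem(ps, mu, r.ReconSettings(iterations=it, subsets=1))
            est = vol.values / vol.values.sum()
            errs.append(float(np.sqrt(np.mean((est - truth) ** 2))))
        assert errs[1] < errs[0]
        assert errs[2] < errs[1]

    def test_deterministic(self, me240_projections, desk_volumes):
        _, mu = desk_volumes
        s = r.ReconSettings(iterations=2, subsets=4)
        a = r.osem(me240_projections, mu, s)
        b = r.osem(me240_projections, mu, s)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sc_with_zero_side_windows_equals_ac(self):
        act, mu, ps = _noise_free_phantom(shape=(24, 24, 8), n_views=4)
        ac = r.osem(ps, mu, r.ReconSettings(iterations=2, subsets=2,
                                            scatter_correction=False))
        sc = r.osem(ps, mu, r.ReconSettings(iterations=2, subsets=2,
                                            scatter_correction=True,
                                            scatter_prefilter_fwhm=16.0))
        np.testing.assert_allclose(sc.values, ac.values, rtol=1e-12)

    def test_concentration_ratio_recovery(self):
        """Two equal-size activity spheres with 2:1 concentration: the
        reconstructed mean ratio recovers 2:1 within 10 % at >= 60 updates
        on noise-free data."""
        shape, spacing = (40, 40, 16), 4.8
        xs = (np.arange(s) - (s - 1) / 2 for s in shape)
        X, Y, Z = np.meshgrid(*[v * spacing for v in xs], indexing="ij")
        c1, c2 = (-48.0, 0.0, 0.0), (48.0, 0.0, 0.0)
        rad = 14.0
        m1 = (X - c1[0]) ** 2 + Y**2 + Z**2 <= rad**2
        m2 = (X - c2[0]) ** 2 + Y**2 + Z**2 <= rad**2
        act = r.VoxelVolume(values=60.0 * m1 + 30.0 * m2, spacing=spacing)
        mu = r.VoxelVolume(
            values=0.127 * (X**2 + Y**2 <= 80.0**2), spacing=spacing
        )
        sys_ = r.SystemModel(
            collimator="ME", window_name="240 keV",
            windows=r.gamma_window_set(), sensitivity=0.1,
            psf_sigma0_mm=0.0, psf_slope=0.0, primary_fraction=1.0,
        )
        prot = AcquisitionProtocol(n_views=12, t_view=30.0, matrix=40,
                                   bin_size=spacing, windows=sys_.windows)
        primary = forward_project(act, mu, sys_, prot, psf=False)
        ps = r.ProjectionSet(main=primary, lower_scatter=np.zeros_like(primary),
                             upper_scatter=np.zeros_like(primary),
                             protocol=prot, seed=0)
        vol = r.osem(ps, mu, r.ReconSettings(iterations=30, subsets=2))
        ratio = vol.values[m1].mean() / vol.values[m2].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)


class TestPostfilter:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        vol = r.VoxelVolume(values=rng.random((10, 10, 10)), spacing=2.4)
        out = r.gaussian_postfilter(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_delta_peak_closed_form(self):
        """12-mm FWHM on a centered delta: the peak equals the cube of the
        normalized discrete-Gaussian center weight for sigma = 5.096 mm on
        a 2.4-mm grid."""
        vals = np.zeros((41, 41, 41))
        vals[20, 20, 20] = 1.0
        vol = r.VoxelVolume(values=vals, spacing=2.4)
        out = r.gaussian_postfilter(vol, 12.0)
        sigma_px = 12.0 / (2 * math.sqrt(2 * math.log(2))) / 2.4
        half = int(4 * sigma_px + 0.5)
        k = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * sigma_px**2))
        expected_peak = (k[half] / k.sum()) ** 3
        assert out.values.max() == pytest.approx(expected_peak, rel=1e-6)

    def test_total_preserved_and_max_not_increased(self, me240_projections,
                                                   desk_volumes):
        _, mu = desk_volumes
        vol = r.osem(me240_projections, mu,
                     r.ReconSettings(iterations=2, subsets=4))
        for fwhm in (9.0, 12.0, 16.0):
            out = r.gaussian_postfilter(vol, fwhm)
            assert out.values.sum() == pytest.approx(vol.values.sum(),
                                                     rel=1e-3)
            assert out.values.max() <= vol.values.max() + 1e-9
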