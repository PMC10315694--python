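"""Forward projector, scatter/noise model, and preset calibration."""

import numpy as np
import pytest
from scipy import stats

import ra224spect as r
from ra224spect.simulate import (
    AcquisitionProtocol,
    InvalidInputError,
    RotationOperator,
    forward_project,
)

from conftest import DESK_SHAPE, DESK_SPACING


def _point_source(shape=(32, 32, 20), spacing=4.8, activity_kbq=50.0):
    act = np.zeros(shape)
    act[shape[0] // 2, shape[1] // 2, shape[2] // 2] = activity_kbq / (
        spacing**3 / 1000.0
    )
    vol = r.VoxelVolume(values=act, spacing=spacing)
    mu = r.VoxelVolume(values=np.zeros(shape), spacing=spacing)
    return vol, mu


def _system(**kw):
    base = dict(
        collimator="ME", window_name="240 keV", windows=r.gamma_window_set(),
        sensitivity=0.1, psf_sigma0_mm=2.0, psf_slope=0.02,
        primary_fraction=0.03,
    )
    base.update(kw)
    return r.SystemModel(**base)


class TestRotationOperator:
    def test_adjoint_is_exact_transpose(self):
        rng = np.random.default_rng(1)
        op = RotationOperator.get(16, 16, 0.7)
        a = rng.random((16, 16, 4))
        b = rng.random((16, 16, 4))
        # <R a, b> == <a, R^T b>
        lhs = float((op.apply(a) * b).sum())
        rhs = float((a * op.apply_adjoint(b)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_angle_is_identity(self):
        rng = np.random.default_rng(2)
        op = RotationOperator.get(12, 12, 0.0)
        a = rng.random((12, 12, 3))
        np.testing.assert_allclose(op.apply(a), a, atol=1e-12)


class TestForwardProject:
    def test_zero_activity_zero_projections(self):
        act, mu = _point_source(activity_kbq=0.0)
        prot = AcquisitionProtocol(n_views=8, t_view=10.0, matrix=32,
                                   bin_size=4.8)
        p = forward_project(act, mu, _system(), prot)
        assert p.shape == (8, 32, 20)
        assert np.all(p == 0)

    def test_point_source_total_counts(self):
        """mu = 0: per-view integral equals sensitivity x t_view x activity
        within 1 % (PSF truncation only)."""
        act, mu = _point_source(activity_kbq=50.0)
        prot = AcquisitionProtocol(n_views=8, t_view=10.0, matrix=32,
                                   bin_size=4.8)
        sys_ = _system()
        p = forward_project(act, mu, sys_, prot)
        expected = sys_.sensitivity * prot.t_view * 50.0
        for v in range(8):
            assert p[v].sum() == pytest.approx(expected, rel=0.01)

    def test_linearity_in_time_and_activity(self):
        act, mu = _point_source()
        sys_ = _system()
        p1 = forward_project(
            act, mu, sys_, AcquisitionProtocol(n_views=4, t_view=10.0)
        )
        p2 = forward_project(
            act, mu, sys_, AcquisitionProtocol(n_views=4, t_view=20.0)
        )
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-12)
        act2 = act.like(3.0 * act.values)
        p3 = forward_project(
            act2, mu, sys_, AcquisitionProtocol(n_views=4, t_view=10.0)
        )
        np.testing.assert_allclose(p3, 3 * p1, rtol=1e-12)

    def test_attenuation_reduces_counts(self, desk_volumes):
        act, mu = desk_volumes
        prot = AcquisitionProtocol(n_views=4, t_view=30.0, matrix=64,
                                   bin_size=4.8)
        sys_ = _system()
        p_att = forward_project(act, mu, sys_, prot)
        p_free = forward_project(act, mu.like(np.zeros_like(mu.values)),
                                 sys_, prot)
        assert p_att.sum() < 0.5 * p_free.sum()

    def test_grid_mismatch_rejected(self):
        act, _ = _point_source(shape=(32, 32, 20))
        _, mu = _point_source(shape=(16, 16, 10))
        with pytest.raises(InvalidInputError):
            forward_project(act, mu, _system(), AcquisitionProtocol(n_views=4))


class TestScatterAndNoise:
    def test_pure_primary_when_fraction_one(self):
        act, mu = _point_source()
        sys_ = _system(primary_fraction=1.0, scatter_floor_fraction=0.0)
        prot = AcquisitionProtocol(n_views=4, t_view=10.0)
        primary = forward_project(act, mu, sys_, prot)
        ps = r.add_scatter_and_noise(primary, sys_, prot, seed=1)
        np.testing.assert_allclose(ps.truth["scatter"], 0.0, atol=1e-9)
        assert ps.lower_scatter.sum() == 0
        assert ps.upper_scatter.sum() == 0

    def test_scatter_mixing_closed_form(self):
        """primary_fraction = 0.03 => expected main-window total equals
        primary total / 0.03."""
        act, mu = _point_source()
        sys_ = _system(primary_fraction=0.03)
        prot = AcquisitionProtocol(n_views=4, t_view=10.0)
        primary = forward_project(act, mu, sys_, prot)
        ps = r.add_scatter_and_noise(primary, sys_, prot, seed=1)
        expect_total = ps.truth["primary"].sum() + ps.truth["scatter"].sum()
        assert expect_total == pytest.approx(primary.sum() / 0.03, rel=1e-9)

    def test_same_seed_identical(self, desk_volumes, me240_protocol):
        act, mu = desk_volumes
        sys_ = r.preset_systems()["ME240"]
        a = r.simulate_acquisition(act, mu, sys_, me240_protocol, seed=9)
        b = r.simulate_acquisition(act, mu, sys_, me240_protocol, seed=9)
        np.testing.assert_array_equal(a.main, b.main)
        np.testing.assert_array_equal(a.lower_scatter, b.lower_scatter)

    def test_distinct_seeds_differ_within_poisson(self, desk_volumes,
                                                  me240_protocol):
        """Per-view totals of two seeds are consistent with Poisson
        variation (chi-square on the difference of totals)."""
        act, mu = desk_volumes
        sys_ = r.preset_systems()["ME240"]
        a = r.simulate_acquisition(act, mu, sys_, me240_protocol, seed=5)
        b = r.simulate_acquisition(act, mu, sys_, me240_protocol, seed=6)
        ta = a.main.sum(axis=(1, 2)).astype(float)
        tb = b.main.sum(axis=(1, 2)).astype(float)
        assert np.any(ta != tb)
        z = (ta - tb) / np.sqrt(ta + tb)
        chi2 = float((z**2).sum())
        p = 1 - stats.chi2.cdf(chi2, df=len(ta))
        assert p > 1e-4

    def test_count_linearity_with_exposure(self, me240_protocol):
        """Expected counts scale with concentration x duration: log-log
        regression slope within 2 % of 1."""
        sys_ = r.preset_systems()["ME240"]
        totals, exposures = [], []
        for conc, t_view in ((10.0, 30.0), (30.0, 30.0), (90.0, 30.0)):
            spec = r.PhantomSpec(sphere_concentrations=(conc,) * 6)
            act, mu = r.voxelize(spec, DESK_SPACING, r.MU_WATER_PER_CM[240],
                                 shape=DESK_SHAPE, subsample=2)
            prot = AcquisitionProtocol(n_views=8, t_view=t_view, matrix=64,
                                       bin_size=DESK_SPACING,
                                       windows=sys_.windows)
            primary = forward_project(act, mu, sys_, prot)
            ps = r.add_scatter_and_noise(primary, sys_, prot, seed=3)
            expect = ps.truth["primary"] + ps.truth["scatter"]
            totals.append(expect.sum())
            exposures.append(conc * t_view)
        slope = np.polyfit(np.log(exposures), np.log(totals), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_tew_recovers_simulated_scatter(self, desk_volumes, me240_protocol):
        """With consistently chosen side fractions the TEW estimate
        recovers the true simulated main-window scatter within 20 %."""
        act, mu = desk_volumes
        # consistent fractions: 2 f (w_main/2) / w_side = 1  =>  f = 0.25
        sys_ = r.preset_systems()["ME240"]
        sys_c = r.SystemModel(
            collimator="ME", window_name="240 keV", windows=sys_.windows,
            sensitivity=sys_.sensitivity, psf_sigma0_mm=2.0, psf_slope=0.035,
            primary_fraction=0.03, tew_side_fractions=(0.25, 0.25),
        )
        ps = r.simulate_acquisition(act, mu, sys_c, me240_protocol, seed=2)
        est = r.tew_scatter_estimate(
            ps.lower_scatter.sum(), ps.upper_scatter.sum(), sys_c.windows
        )
        true = ps.truth["scatter"].sum()
        assert est == pytest.approx(true, rel=0.20)


class TestPresets:
    def test_primary_fractions(self):
        p = r.preset_systems()
        assert p["ME80"].primary_fraction == 0.04
        assert p["HE80"].primary_fraction == 0.06
        assert p["ME240"].primary_fraction == 0.03
        assert p["HE240"].primary_fraction == 0.03
        assert p["ME240"].psf_slope < p["HE240"].psf_slope  # ME sharper

    def test_collimator_and_window_count_ratios(self):
        """On the default phantom: ME collects ~1.79x the HE counts and the
        240-keV window ~1.16x the 80-keV counts (expectation level)."""
        spec = r.PhantomSpec(sphere_concentrations=(90.0,) * 6)
        totals = {}
        for name, sysm in r.preset_systems().items():
            mu_e = int(name[2:])
            act, mu = r.voxelize(spec, DESK_SPACING, r.MU_WATER_PER_CM[mu_e],
                                 shape=DESK_SHAPE, subsample=2)
            prot = AcquisitionProtocol(n_views=8, t_view=30.0, matrix=64,
                                       bin_size=DESK_SPACING,
                                       windows=sysm.windows)
            primary = forward_project(act, mu, sysm, prot)
            totals[name] = primary.sum() / sysm.primary_fraction
        assert totals["ME240"] / totals["HE240"] == pytest.approx(1.79, abs=0.1)
        assert totals["ME80"] / totals["HE80"] == pytest.approx(1.79, abs=0.1)
        assert totals["ME240"] / totals["ME80"] == pytest.approx(1.16, abs=0.05)
        assert totals["HE240"] / totals["HE80"] == pytest.approx(1.16, abs=0.05)
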