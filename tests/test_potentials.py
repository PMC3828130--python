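"""Pair-potential correctness: closed-form values, force-energy consistency,
cutoff continuity, and the worm-like-chain formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchybind.potentials import (
    WCA_CUT_FACTOR,
    InteractionKind,
    InteractionSpec,
    LinkerSpec,
    angular_lj,
    steric_cross,
    wca,
    wlc_force,
    wlc_mean_extension,
)

RNG = np.random.default_rng(20260911)


def wca_spec(eps=1.0, sigma=1.0):
    return InteractionSpec(InteractionKind.WCA, eps, sigma)


def ang_spec(eps=5.0, sigma=0.75, n=2.0, theta_cut=math.pi / 2, r_cut=None):
    return InteractionSpec(
        InteractionKind.ANGULAR_LJ, eps, sigma, n_geom=n,
        r_cut=r_cut, theta_cut=theta_cut,
    )


class TestWCA:
    @pytest.mark.parametrize(
        "r,eps,sigma,expected",
        [
            (WCA_CUT_FACTOR, 1.0, 1.0, 0.0),       # zero at the cutoff
            (1.0, 1.0, 1.0, 1.0),                   # V(sigma) = eps
            (1.2 * WCA_CUT_FACTOR, 3.0, 1.0, 0.0),  # beyond the cutoff
            (0.75, 1.0, 0.75, 1.0),                 # scales with sigma
        ],
    )
    def test_energy_values(self, r, eps, sigma, expected):
        e, _ = wca(r, wca_spec(eps, sigma))
        assert e == pytest.approx(expected, abs=1e-12)

    def test_force_zero_at_cutoff_and_minimum(self):
        _, f = wca(WCA_CUT_FACTOR, wca_spec())
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_never_attractive(self):
        for r in np.linspace(0.3, 2.0, 200):
            e, _ = wca(float(r), wca_spec())
            assert e >= 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wca(0.0, wca_spec())
        with pytest.raises(ValueError):
            wca(-1.0, wca_spec())

    def test_force_is_negative_derivative(self):
        spec = wca_spec(2.5, 0.8)
        h = 1e-7
        for r in RNG.uniform(0.5, 0.95, 50):
            e_plus, _ = wca(r + h, spec)
            e_minus, _ = wca(r - h, spec)
            _, f = wca(float(r), spec)
            assert f == pytest.approx(-(e_plus - e_minus) / (2 * h), rel=1e-5)


class TestStericCross:
    def test_reduces_to_wca_for_equal_sigmas(self):
        for r in (0.8, 1.0, 1.1):
            assert steric_cross(r, 1.0, 1.0) == wca(r, wca_spec())

    def test_cutoff_uses_mixed_sigma(self):
        sij = 0.5 * (0.5 + 1.0)
        e, f = steric_cross(WCA_CUT_FACTOR * sij, 0.5, 1.0)
        assert e == 0.0 and f == 0.0

    def test_contact_energy(self):
        # at r = sigma_ij the energy equals eps0 exactly
        e, _ = steric_cross(0.75, 0.5, 1.0)
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_never_attractive(self):
        for r in np.linspace(0.4, 1.5, 100):
            e, _ = steric_cross(float(r), 0.5, 1.0)
            assert e >= 0.0


class TestAngularLJ:
    def test_on_axis_minimum_energy(self):
        # at the LJ minimum with full angular weight the well depth is
        # -eps up to the (small) cutoff shift
        spec = ang_spec(eps=5.0)
        rmin = WCA_CUT_FACTOR * spec.sigma_pair
        e, f = angular_lj(np.array([0.0, 0.0, rmin]), [0, 0, 1.0], spec)
        shift = 4 * 5.0 * ((spec.sigma_pair / spec.r_cut) ** 6
                           - (spec.sigma_pair / spec.r_cut) ** 12)
        assert e == pytest.approx(-5.0 + shift, rel=1e-12)
        assert np.linalg.norm(f) == pytest.approx(0.0, abs=1e-9)

    def test_zero_at_cutoff_all_angles(self):
        # the energy is continuous (zero) at the radial cutoff at every
        # angle; beyond it both energy and force vanish identically
        spec = ang_spec()
        for theta in np.linspace(0, math.pi * 0.95, 17):
            direction = np.array([math.sin(theta), 0.0, math.cos(theta)])
            e, _ = angular_lj(spec.r_cut * direction, [0, 0, 1.0], spec)
            assert e == pytest.approx(0.0, abs=1e-12)
            e, f = angular_lj(1.0001 * spec.r_cut * direction, [0, 0, 1.0], spec)
            assert e == 0.0
            assert np.all(f == 0.0)

    def test_repulsive_outside_cone(self):
        # beyond the cone half-width only the repulsive branch survives
        spec = ang_spec(theta_cut=math.pi / 4)
        theta = math.pi / 4 + 0.1
        for r in np.linspace(0.6, 0.99 * spec.r_cut, 30):
            v = r * np.array([math.sin(theta), 0.0, math.cos(theta)])
            e, _ = angular_lj(v, [0, 0, 1.0], spec)
            assert e >= 0.0

    def test_sharper_patch_is_less_attractive_off_axis(self):
        theta = math.pi / 4  # half the default cone width
        r = WCA_CUT_FACTOR * 0.75
        v = r * np.array([math.sin(theta), 0.0, math.cos(theta)])
        e1, _ = angular_lj(v, [0, 0, 1.0], ang_spec(n=2.0))
        e2, _ = angular_lj(v, [0, 0, 1.0], ang_spec(n=4.0))
        assert e2 > e1  # doubling n strictly reduces the attraction

    def test_monotone_decreasing_weight_in_theta(self):
        spec = ang_spec(n=3.0)
        r = WCA_CUT_FACTOR * spec.sigma_pair
        energies = []
        for theta in np.linspace(0, spec.theta_cut * 0.999, 40):
            v = r * np.array([math.sin(theta), 0.0, math.cos(theta)])
            e, _ = angular_lj(v, [0, 0, 1.0], spec)
            energies.append(e)
        assert np.all(np.diff(energies) > 0)  # less attractive as theta grows

    def test_isotropic_limit_matches_shifted_lj(self):
        # n = 0 with the default cone reduces to the plain shifted LJ
        spec = ang_spec(n=0.0)
        eps, sig, rc = spec.epsilon, spec.sigma_pair, spec.r_cut
        for r in np.linspace(0.7, 0.99 * rc, 25):
            theta = RNG.uniform(0, 0.45 * math.pi)
            v = r * np.array([math.sin(theta), 0.0, math.cos(theta)])
            e, _ = angular_lj(v, [0, 0, 1.0], spec)
            sr6 = (sig / r) ** 6
            src6 = (sig / rc) ** 6
            lj = 4 * eps * (sr6**2 - sr6) - 4 * eps * (src6**2 - src6)
            assert e == pytest.approx(lj, rel=1e-12)

    def test_force_is_negative_gradient(self):
        # central differences in all three Cartesian directions
        spec = ang_spec(n=3.0, theta_cut=1.2)
        h = 1e-6
        checked = 0
        while checked < 100:
            v = RNG.uniform(-1.5, 1.5, 3)
            r = np.linalg.norm(v)
            if not 0.6 < r < 0.98 * spec.r_cut:
                continue
            theta = math.acos(v[2] / r)
            if abs(theta - spec.theta_cut) < 0.05 or theta < 0.05:
                continue  # avoid the C1 seam and the polar axis
            _, f = angular_lj(v, [0, 0, 1.0], spec)
            for k in range(3):
                dv = np.zeros(3)
                dv[k] = h
                e_p, _ = angular_lj(v + dv, [0, 0, 1.0], spec)
                e_m, _ = angular_lj(v - dv, [0, 0, 1.0], spec)
                num = -(e_p - e_m) / (2 * h)
                assert f[k] == pytest.approx(num, rel=1e-5, abs=1e-7)
            checked += 1

    def test_domain_errors(self):
        spec = ang_spec()
        with pytest.raises(ValueError):
            angular_lj(np.zeros(3), [0, 0, 1.0], spec)
        with pytest.raises(ValueError):
            angular_lj(np.array([0, 0, 1.0]), np.zeros(3), spec)


class TestInteractionSpec:
    def test_wca_cutoff_forced(self):
        spec = wca_spec(1.0, 2.0)
        assert spec.r_cut == WCA_CUT_FACTOR * 2.0

    def test_shift_tracks_parameters(self):
        spec = ang_spec(eps=3.0, sigma=1.0)
        sr6 = (1.0 / spec.r_cut) ** 6
        assert spec.shift_att == pytest.approx(4 * 3.0 * sr6)
        assert spec.shift_rep == pytest.approx(-4 * 3.0 * sr6**2)

    @pytest.mark.parametrize("bad", [-1.0, 0.0, math.pi])
    def test_theta_cut_validated(self, bad):
        with pytest.raises(ValueError):
            ang_spec(theta_cut=bad)


class TestWLC:
    def linker(self, n=10, b=0.5, lp=1.0):
        return LinkerSpec(n_monomers=n, monomer_size=b, persistence_length=lp)

    def test_force_at_zero_and_midpoint(self):
        lk = self.linker()
        assert wlc_force(0.0, lk) == 0.0
        # F(L0/2) = 1.25 kBT/lp
        assert wlc_force(0.5 * lk.contour_length, lk) == pytest.approx(
            1.25 * lk.temperature / lk.persistence_length
        )

    def test_strictly_increasing_and_capped(self):
        lk = self.linker()
        rs = np.linspace(0.0, 0.985 * lk.contour_length, 100)
        fs = [wlc_force(float(r), lk) for r in rs]
        assert np.all(np.diff(fs) > 0)
        assert wlc_force(0.999 * lk.contour_length, lk) == lk.max_force
        assert math.isfinite(wlc_force(2.0 * lk.contour_length, lk))

    def test_overstretch_warns_but_stays_finite(self, caplog):
        import logging

        lk = self.linker()
        with caplog.at_level(logging.WARNING, logger="patchybind.potentials"):
            f = wlc_force(1.5 * lk.contour_length, lk)
        assert f == lk.max_force
        assert any("over-stretch" in r.message for r in caplog.records)

    def test_kratky_porod_limits(self):
        from patchybind.potentials import kratky_porod_extension

        # rigid-rod limit
        stiff = LinkerSpec(10, 0.5, 5000.0)
        assert kratky_porod_extension(stiff) == pytest.approx(
            stiff.contour_length, rel=1e-3
        )
        # flexible limit: sqrt(2 lp L0)
        floppy = LinkerSpec(10000, 0.5, 0.05)
        expected = math.sqrt(2 * 0.05 * floppy.contour_length)
        assert kratky_porod_extension(floppy) == pytest.approx(expected, rel=1e-3)

    def test_kratky_porod_exact_value(self):
        from patchybind.potentials import kratky_porod_extension

        # lp = L0 = 1: sqrt(<r^2>) = sqrt(2/e)
        lk = LinkerSpec(1, 1.0, 1.0)
        assert kratky_porod_extension(lk) == pytest.approx(
            math.sqrt(2.0 / math.e), rel=1e-12
        )

    def test_kratky_porod_against_chain_sampling(self):
        # independent oracle: Monte-Carlo discrete chains with exponentially
        # decorrelating bond directions
        from patchybind.potentials import kratky_porod_extension
        from patchybind.synthetic import sample_wlc_chain

        rng = np.random.default_rng(7)
        n, b, lp = 20, 0.5, 1.5
        samples = sample_wlc_chain(n, b, lp, 2000, rng)
        rms = float(np.sqrt(np.mean(samples**2)))
        lk = LinkerSpec(n, b, lp)
        assert rms == pytest.approx(kratky_porod_extension(lk), rel=0.05)

    def test_spring_energy_is_integral_of_force(self):
        from patchybind.potentials import wlc_spring_energy
        from scipy.integrate import quad

        lk = self.linker()
        for r in (0.5, 2.0, 4.0, 4.97):
            ref = quad(lambda s: wlc_force(s, lk), 0.0, r, limit=200)[0]
            assert wlc_spring_energy(r, lk) == pytest.approx(ref, rel=1e-6)

    def test_mean_extension_matches_independent_quadrature(self):
        # cross-check the trapezoid route with adaptive quadrature of the
        # same Boltzmann weight
        from patchybind.potentials import wlc_spring_energy
        from scipy.integrate import quad

        lk = self.linker()
        num = quad(lambda r: r**3 * math.exp(-wlc_spring_energy(r, lk)),
                   0, lk.contour_length, limit=200)[0]
        den = quad(lambda r: r**2 * math.exp(-wlc_spring_energy(r, lk)),
                   0, lk.contour_length, limit=200)[0]
        assert wlc_mean_extension(lk) == pytest.approx(num / den, rel=1e-4)

    def test_mean_extension_below_ideal_chain_value(self):
        # the two-bead spring under-extends relative to the full chain
        from patchybind.potentials import kratky_porod_extension

        for lp in (0.5, 1.0, 2.0):
            lk = LinkerSpec(10, 0.5, lp)
            assert wlc_mean_extension(lk) < kratky_porod_extension(lk)

    def test_bounded_by_contour_length(self):
        from patchybind.potentials import kratky_porod_extension

        for lp in (0.1, 1.0, 10.0, 100.0):
            lk = LinkerSpec(12, 0.5, lp)
            assert 0 < wlc_mean_extension(lk) < lk.contour_length
            assert 0 < kratky_porod_extension(lk) < lk.contour_length

    def test_bead_steric_raises_mean_extension_when_tight(self):
        # excluded volume between the beads can only push them apart
        lk = LinkerSpec(3, 0.5, 1.0)
        assert wlc_mean_extension(lk, bead_sigma=0.5) > wlc_mean_extension(lk)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    r=st.floats(0.4, 2.0),
    eps=st.floats(0.1, 20.0),
    sigma=st.floats(0.3, 1.5),
)
def test_wca_energy_nonnegative_and_continuous(r, eps, sigma):
    spec = InteractionSpec(InteractionKind.WCA, eps, sigma)
    e, _ = wca(r, spec)
    assert e >= 0.0
    e_cut, f_cut = wca(spec.r_cut * (1 - 1e-12), spec)
    assert abs(e_cut) < 1e-8 and abs(f_cut) < 1e-6
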