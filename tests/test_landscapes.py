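"""Synthetic landscapes, window schemes, samplers and composition bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import ks_1samp

from asymperm.constants import KT_310K
from asymperm.landscapes import (BlendSpec, InvalidParameterError,
                                 MembraneSpec, PeptideSpec, SamplerParams,
                                 SamplerStabilityError, UmbrellaWindow,
                                 blend_landscapes, build_pure_landscape,
                                 lobes_for_tensions, make_stress_profile,
                                 make_window_scheme, membrane_asymmetry,
                                 peptide_net_charge, sample_scheme,
                                 sample_window)


class TestPureLandscape:
    def test_control_points_and_plateau(self, double_well):
        # stated feature values are hit exactly at their control points
        assert double_well.evaluate(2.0) == pytest.approx(-40.0, abs=1e-9)
        assert double_well.evaluate(-2.0) == pytest.approx(-40.0, abs=1e-9)
        assert double_well.evaluate(0.0) == pytest.approx(150.0, abs=1e-9)
        assert double_well.evaluate(4.5) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_by_construction(self, double_well):
        z = np.linspace(-4.5, 4.5, 1801)
        np.testing.assert_allclose(double_well.evaluate(z),
                                   double_well.evaluate(-z), atol=1e-9)

    def test_flat_landscape_is_identically_zero(self, flat_landscape):
        z = np.linspace(-4.5, 4.5, 500)
        np.testing.assert_allclose(flat_landscape.evaluate(z), 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self, double_well):
        z = np.linspace(-4.2, 4.2, 601)
        h = 1e-6
        fd = (double_well.evaluate(z + h) - double_well.evaluate(z - h)) / (2 * h)
        np.testing.assert_allclose(double_well.grad(z), fd, atol=1e-4)

    def test_invalid_widths_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_pure_landscape(widths=-0.1)


class TestBlend:
    def test_identity_blend(self, double_well):
        b = blend_landscapes(double_well, double_well, BlendSpec(0.0, 0.3))
        z = np.linspace(-4.5, 4.5, 901)
        np.testing.assert_allclose(b.evaluate(z), double_well.evaluate(z),
                                   atol=1e-12)

    def test_step_limit(self, demo_trio):
        upper, lower, _ = demo_trio
        b = blend_landscapes(upper, lower, BlendSpec(0.0, 1e-6))
        z_hi = np.linspace(0.2, 4.0, 50)
        z_lo = np.linspace(-4.0, -0.2, 50)
        np.testing.assert_allclose(b.evaluate(z_hi), upper.evaluate(z_hi),
                                   atol=1e-6)
        np.testing.assert_allclose(b.evaluate(z_lo), lower.evaluate(z_lo),
                                   atol=1e-6)

    def test_midpoint_is_mean(self, demo_trio):
        upper, lower, _ = demo_trio
        zc = 0.37
        b = blend_landscapes(upper, lower, BlendSpec(zc, 0.5))
        expected = 0.5 * (upper.evaluate(zc) + lower.evaluate(zc))
        assert b.evaluate(zc) == pytest.approx(float(expected), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(zc=st.floats(-1.5, 1.5), lam=st.floats(0.01, 1.0),
           z=st.floats(-4.5, 4.5))
    def test_blend_is_convex_combination(self, demo_trio, zc, lam, z):
        upper, lower, _ = demo_trio
        b = blend_landscapes(upper, lower, BlendSpec(zc, lam))
        gu, gl = float(upper.evaluate(z)), float(lower.evaluate(z))
        gb = float(b.evaluate(z))
        assert min(gu, gl) - 1e-9 <= gb <= max(gu, gl) + 1e-9

    def test_mismatched_supports_rejected(self, double_well):
        other = build_pure_landscape(support=(-5.0, 5.0))
        with pytest.raises(ValueError, match="support"):
            blend_landscapes(double_well, other, BlendSpec())


class TestWindowScheme:
    def test_spacings_and_transitional_gaps(self):
        ws = make_window_scheme((-2.3, 2.3), (0.5, 2.3), (-0.5, 0.5),
                                0.1, 0.05, (1000.0, 5000.0, 3000.0))
        z0 = np.array([w.z0 for w in ws])
        assert np.all(np.diff(z0) > 0)
        gaps = np.round(np.diff(z0), 9)
        assert set(gaps) <= {0.05, 0.1}

    def test_uniform_band_window_count(self):
        ws = make_window_scheme((0.0, 1.0), (0.0, 1.0), (0.0, 0.0),
                                0.1, 0.05, (1000.0, 5000.0, 3000.0))
        assert len(ws) == 11

    def test_center_band_gets_center_tier(self):
        # stiffest springs (5000 kJ/mol/nm^2) belong to the membrane center
        ws = make_window_scheme((-2.3, 2.3), (1.0, 2.3), (-0.5, 0.5),
                                0.1, 0.05, (1000.0, 5000.0, 3000.0))
        for w in ws:
            if -0.5 <= w.z0 <= 0.5:
                assert w.k == 5000.0
            elif 1.0 < abs(w.z0) <= 2.3:
                assert w.k == 1000.0

    def test_reproducible_bit_exact(self):
        args = ((-3.4, 3.4), (1.4, 3.4), (-0.6, 0.6), 0.1, 0.05,
                (1000.0, 5000.0, 3000.0))
        assert make_window_scheme(*args) == make_window_scheme(*args)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(InvalidParameterError, match="overlap"):
            make_window_scheme((-2.0, 2.0), (0.5, 2.0), (-1.0, 1.0),
                               0.1, 0.05, (1000.0, 5000.0, 3000.0))


class TestSampler:
    def test_harmonic_moments_on_flat_landscape(self, flat_landscape):
        k, z0 = 5000.0, 1.0
        win = UmbrellaWindow(z0=z0, k=k)
        sp = SamplerParams(n_steps=40000, D=0.5 * (2.4 * math.sqrt(KT_310K / k))**2)
        ts = sample_window(flat_landscape, win, sp, seed=7)
        x = ts.production
        var_expected = KT_310K / k  # ~5.15e-4 nm^2
        sem = math.sqrt(var_expected / len(x)) * 4  # autocorrelation slack
        assert abs(x.mean() - z0) < 3 * sem * 3
        assert x.var() == pytest.approx(var_expected, rel=0.1)

    def test_linear_tilt_shifts_mean(self):
        # G = c z completed against the spring: mean -> z0 - c/k
        c, k = 50.0, 2000.0
        tilted = build_pure_landscape(
            adsorption_well_depth=0.0, center_G=0.0, headgroup_barrier=0.0)
        base_eval, base_grad = tilted._eval, tilted._grad
        tilted._eval = lambda z: base_eval(z) + c * np.asarray(z, dtype=float)
        tilted._grad = lambda z: base_grad(z) + c
        win = UmbrellaWindow(z0=0.5, k=k)
        sp = SamplerParams(n_steps=60000,
                           D=0.5 * (2.4 * math.sqrt(KT_310K / k))**2)
        x = sample_window(tilted, win, sp, seed=3).production
        assert x.mean() == pytest.approx(win.z0 - c / k, abs=4e-3)

    def test_bimodal_lobe_masses_match_boltzmann(self):
        # window at the barrier top of a double well: the log-ratio of lobe
        # masses must match the Boltzmann quadrature of the biased potential
        land = build_pure_landscape(
            adsorption_well_depth=6.0, adsorption_well_pos=1.0,
            center_G=8.0, widths=0.35, support=(-3.0, 3.0))
        win = UmbrellaWindow(z0=0.3, k=10.0)  # soft spring, breaks symmetry
        kT = KT_310K

        def boltz(z):
            return np.exp(-(land.evaluate(z) + win.bias(z)) / kT)

        mass_pos = quad(boltz, 0, 3.0, limit=200)[0]
        mass_neg = quad(boltz, -3.0, 0, limit=200)[0]
        expected = math.log(mass_pos / mass_neg)

        sp = SamplerParams(n_steps=400000, D=0.18)  # large hops cross the barrier
        x = sample_window(land, win, sp, seed=21).production
        observed = math.log((x > 0).mean() / (x < 0).mean())
        assert observed == pytest.approx(expected, abs=0.15)

    def test_empirical_distribution_converges_to_boltzmann(self, double_well):
        # KS distance to the quadrature-normalized Boltzmann CDF decreases
        # with chain length, averaged over seeds
        win = UmbrellaWindow(z0=2.0, k=1000.0)
        kT = KT_310K
        zg = np.linspace(1.4, 2.6, 4001)
        dens = np.exp(-(double_well.evaluate(zg) + win.bias(zg)) / kT)
        cdf_grid = np.cumsum(dens)
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, zg, cdf_grid)

        def mean_ks(n):
            ds = []
            for seed in (1, 2, 3, 4):
                sp = SamplerParams(
                    n_steps=n, D=0.5 * (2.4 * math.sqrt(kT / win.k))**2)
                x = sample_window(double_well, win, sp, seed=seed).production
                ds.append(ks_1samp(x, cdf).statistic)
            return np.mean(ds)

        assert mean_ks(20000) < mean_ks(1000)

    def test_langevin_matches_metropolis_distribution(self, double_well):
        win = UmbrellaWindow(z0=2.0, k=1000.0)
        sp = SamplerParams(n_steps=60000, D=0.01, dt=0.02,
                           scheme="overdamped-langevin")
        x = sample_window(double_well, win, sp, seed=5).production
        spm = SamplerParams(n_steps=40000,
                            D=0.5 * (2.4 * math.sqrt(KT_310K / win.k))**2)
        y = sample_window(double_well, win, spm, seed=6).production
        assert x.mean() == pytest.approx(y.mean(), abs=0.01)
        assert x.std() == pytest.approx(y.std(), rel=0.15)

    def test_langevin_stability_error_suggests_dt(self, double_well):
        win = UmbrellaWindow(z0=0.0, k=5000.0)
        sp = SamplerParams(n_steps=100, D=1.0, dt=1.0,
                           scheme="overdamped-langevin")
        with pytest.raises(SamplerStabilityError, match="dt"):
            sample_window(double_well, win, sp, seed=1)

    def test_deterministic_given_seed(self, double_well):
        win = UmbrellaWindow(z0=1.0, k=1000.0)
        sp = SamplerParams(n_steps=500)
        a = sample_window(double_well, win, sp, seed=42).samples
        b = sample_window(double_well, win, sp, seed=42).samples
        np.testing.assert_array_equal(a, b)
        scheme = [UmbrellaWindow(z0=z, k=1000.0) for z in (0.0, 0.5)]
        ts1 = sample_scheme(double_well, scheme, seed=9, n_steps=300)
        ts2 = sample_scheme(double_well, scheme, seed=9, n_steps=300)
        for t1, t2 in zip(ts1, ts2):
            np.testing.assert_array_equal(t1.samples, t2.samples)


class TestStressSynthesis:
    def test_box_integral_metadata(self):
        # approximate a box profile with a narrow Gaussian of equal area:
        # closed-form gamma follows the analytic integral either way
        s = make_stress_profile(lobes=[(0.5, 0.08, 10.0)], midplane=0.0)
        area = 10.0 * 0.08 * math.sqrt(2 * math.pi)
        assert s.metadata["gamma_plus"] == pytest.approx(0.1 * area, rel=1e-6)
        assert s.metadata["gamma_minus"] == pytest.approx(0.0, abs=1e-8)

    def test_mirror_symmetric_shape_gives_equal_tensions(self):
        s = make_stress_profile(lobes=[(1.0, 0.3, 5.0), (-1.0, 0.3, 5.0)],
                                midplane=0.0)
        assert s.metadata["gamma_plus"] == pytest.approx(
            s.metadata["gamma_minus"], rel=1e-9)

    def test_opposite_lobes_for_target_tensions(self):
        s = make_stress_profile(lobes=lobes_for_tensions(4.0, -4.0))
        assert s.metadata["gamma_plus"] == pytest.approx(4.0, rel=1e-3)
        assert s.metadata["gamma_minus"] == pytest.approx(-4.0, rel=1e-3)


class TestComposition:
    @pytest.mark.parametrize("upper,lower,pct,total", [
        ((("POPC", 144),), (("POPC", 106),), 15, 250),
        ((("POPC", 144),), (("POPC", 144),), 0, 288),
        ((("POPE", 484),), (("POPG", 484),), 0, 968),
    ])
    def test_asymmetry_worked_examples(self, upper, lower, pct, total):
        rec = membrane_asymmetry(MembraneSpec(upper=upper, lower=lower))
        assert rec["total_lipids"] == total
        assert rec["asymmetry_percent_rounded"] == pct

    def test_asymmetry_unrounded_value(self):
        rec = membrane_asymmetry(
            MembraneSpec(upper=(("POPC", 144),), lower=(("POPC", 106),)))
        assert rec["asymmetry_percent"] == pytest.approx(15.2, abs=0.05)

    def test_asymmetry_symmetric_under_leaflet_swap(self):
        a = MembraneSpec(upper=(("POPE", 144),), lower=(("POPG", 135),))
        b = MembraneSpec(upper=(("POPG", 135),), lower=(("POPE", 144),))
        assert membrane_asymmetry(a)["asymmetry_percent"] == \
            membrane_asymmetry(b)["asymmetry_percent"]

    def test_empty_leaflet_rejected(self):
        with pytest.raises(ValueError):
            MembraneSpec(upper=(), lower=(("POPC", 10),))

    @pytest.mark.parametrize("seq,n_term,c_term,charge", [
        ("LKKLLKLLKKLLKLLKKLLKL", "charged", "amidated", 10),
        ("LSSLLSLLSSLLSLLSSLLSL", "charged", "amidated", 1),
        ("LLLL", "neutral", "amidated", 0),
        ("DEKR", "neutral", "free", -1),
    ])
    def test_net_charge(self, seq, n_term, c_term, charge):
        spec = PeptideSpec(sequence=seq, n_term=n_term, c_term=c_term)
        assert peptide_net_charge(spec) == charge

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            peptide_net_charge(PeptideSpec(sequence="LKB"))

    @settings(deadline=None, derandomize=True)
    @given(a=st.text("ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           b=st.text("ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_net_charge_additive_with_neutral_termini(self, a, b):
        def q(seq):
            return peptide_net_charge(
                PeptideSpec(sequence=seq, n_term="neutral", c_term="amidated"))

        assert q(a + b) == q(a) + q(b)
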