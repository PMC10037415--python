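"""Unit and property tests for the dipole-emission electrodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from giet import materials
from giet import optics as op
from giet.errors import DispersionRangeError


def airy_reflection(n0, n1, n2, t_nm, wavelength_nm, q, pol):
    """Closed-form two-interface (Airy) film reflection, written independently."""
    k0 = 2 * np.pi / wavelength_nm
    kz = [np.sqrt(complex(n ** 2 - (n0 * q) ** 2)) * k0 for n in (n0, n1, n2)]
    kz = [kk if kk.imag >= 0 else -kk for kk in kz]

    def fresnel(na, nb, kza, kzb):
        if pol == "s":
            return (kza - kzb) / (kza + kzb)
        return (nb ** 2 * kza - na ** 2 * kzb) / (nb ** 2 * kza + na ** 2 * kzb)

    r01 = fresnel(n0, n1, kz[0], kz[1])
    r12 = fresnel(n1, n2, kz[1], kz[2])
    phase = np.exp(2j * kz[1] * t_nm)
    return (r01 + r12 * phase) / (1 + r01 * r12 * phase)


class TestInterfaceReflection:
    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.3])
    def test_identical_media_reflect_nothing(self, pol, q):
        assert op.interface_reflection(1.4, 1.4, q, pol) == 0

    def test_normal_incidence_closed_form(self):
        r = op.interface_reflection(1.0, 1.5, 0.0, "s")
        assert r == pytest.approx((1 - 1.5) / (1 + 1.5))
        # p convention: perfect mirror gives r_p = +1, so at q=0 signs differ
        assert op.interface_reflection(1.0, 1.5, 0.0, "p") == pytest.approx(0.2)

    def test_total_internal_reflection_unit_modulus(self):
        # water -> air beyond the critical angle q > n2/n1
        q = 0.9
        assert q > 1.0 / 1.33
        for pol in "sp":
            r = op.interface_reflection(1.33, 1.0, q, pol)
            assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            op.interface_reflection(1.0, 1.5, -0.1, "s")
        with pytest.raises(ValueError):
            op.interface_reflection(1.0, 1.5, np.nan, "s")
        with pytest.raises(ValueError):
            op.interface_reflection(1.0, 1.5, 0.5, "x")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(n1=st.floats(1.0, 2.0), n2=st.floats(1.0, 2.0), q=st.floats(0.0, 0.999))
    def test_passivity_lossless_interface(self, n1, n2, q):
        for pol in "sp":
            assert abs(op.interface_reflection(n1, n2, q, pol)) <= 1.0 + 1e-12


class TestStackReflection:
    def test_degenerate_stack_is_homogeneous(self):
        stack = op.LayerStack(1.333, (op.Layer(0.0, 1.8), op.Layer(0.0, 2.5)), 1.333)
        for pol in "sp":
            assert op.stack_reflection(stack, 680.0, 0.4, pol) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("q", [0.0, 0.6, 1.4])
    def test_single_film_matches_airy_formula(self, pol, q):
        stack = op.LayerStack(1.52, (op.Layer(120.0, 2.1 + 0.3j),), 1.333)
        r = op.stack_reflection(stack, 650.0, q, pol, side="below")
        expected = airy_reflection(1.333, 2.1 + 0.3j, 1.52, 120.0, 650.0, q, pol)
        assert r == pytest.approx(expected, rel=1e-10)

    def test_graphene_stack_passive(self, stack_spec):
        """|r| <= 1 for real q < 1 between lossless bounding media."""
        stack = stack_spec.stack()
        for wl in (620.0, 680.0, 740.0):
            q = np.linspace(0.0, 0.999, 200)
            for pol in "sp":
                r = op.stack_reflection(stack, wl, q, pol, side="below")
                assert np.all(np.abs(r) <= 1.0 + 1e-10)

    def test_wavelength_outside_dispersion_table(self, stack_spec):
        stack = stack_spec.stack()
        with pytest.raises(DispersionRangeError, match="graphene"):
            op.stack_reflection(stack, 1200.0, 0.3, "s")


class TestRelativeDecayRate:
    def test_free_space_is_unity(self):
        stack = op.LayerStack(1.333, (), 1.333)
        for z in (0.0, 3.0, 50.0):
            assert op.relative_decay_rate(stack, z, 680.0, "horizontal") == pytest.approx(1.0)
            assert op.relative_decay_rate(stack, z, 680.0, "vertical") == pytest.approx(1.0)

    def test_dipole_limits_on_perfect_mirror(self):
        """Image-dipole closed forms: r_s = -1, r_p = +1 at contact.

        The horizontal dipole's image cancels it (S -> 0); the vertical
        dipole's image reinforces it (S -> 2).
        """
        q, dq, w = op._quadrature_nodes(96, 24)
        r_s = -np.ones_like(q, dtype=complex)
        r_p = np.ones_like(q, dtype=complex)
        zero = np.zeros_like(q, dtype=complex)
        S_h = op._rate_from_reflections(q, dq, w, r_s, r_p, zero, zero, 1.0, 1.0,
                                        "horizontal")
        S_v = op._rate_from_reflections(q, dq, w, r_s, r_p, zero, zero, 1.0, 1.0,
                                        "vertical")
        assert S_h == pytest.approx(0.0, abs=1e-10)
        assert S_v == pytest.approx(2.0, abs=1e-10)

    def test_isotropic_is_weighted_mix(self, stack_spec):
        stack = stack_spec.stack()
        S_h = op.relative_decay_rate(stack, 7.0, 680.0, "horizontal")
        S_v = op.relative_decay_rate(stack, 7.0, 680.0, "vertical")
        S_i = op.relative_decay_rate(stack, 7.0, 680.0, "isotropic")
        assert S_i == pytest.approx((2 * S_h + S_v) / 3, rel=1e-12)

    def test_adaptive_matches_brute_force_trapezoid(self, stack_spec):
        """Adaptive panels vs a 10^6-node trapezoid over the same integrand."""
        stack = stack_spec.stack()
        rng = np.random.default_rng(11)
        for _ in range(3):
            z = rng.uniform(0.5, 25.0)
            wl = rng.uniform(655.0, 745.0)
            S_adaptive = op.relative_decay_rate(stack, z, wl, "horizontal", rtol=1e-9)
            S_brute = _trapezoid_rate(stack, z, wl)
            assert S_adaptive == pytest.approx(S_brute, rel=1e-6)

    def test_rate_is_nonnegative(self, stack_spec):
        stack = stack_spec.stack()
        z = np.linspace(0.0, 40.0, 81)
        for ori in ("horizontal", "vertical"):
            S = op.relative_decay_rate(stack, z, 680.0, ori)
            assert np.all(S >= 0.0)

    def test_negative_height_rejected(self, stack_spec):
        with pytest.raises(ValueError):
            op.relative_decay_rate(stack_spec.stack(), -1.0, 680.0)


def _trapezoid_rate(stack, z, wl, n_nodes=1_000_000):
    """Brute-force fixed-grid quadrature oracle for the horizontal dipole rate."""
    n_top = op.resolve_index(stack.top_medium, wl)
    k = 2 * np.pi * n_top.real / wl
    # propagating part in theta (q = sin(theta)) and evanescent part in s
    theta = np.linspace(0.0, np.pi / 2, n_nodes // 2)
    q1 = np.sin(theta)
    w1 = np.cos(theta).astype(complex)
    s = np.linspace(0.0, op.S_MAX, n_nodes // 2)[1:]
    q2 = np.sqrt(1.0 + s ** 2)
    w2 = 1j * s

    def integrand(q, w, dvol):
        rs = op.stack_reflection(stack, wl, q, "s", side="below")
        rp = op.stack_reflection(stack, wl, q, "p", side="below")
        phase = np.exp(2j * w * k * z)
        a_s, a_p = rs * phase, rp * phase
        val = (q / w) * a_s - (q * w) * a_p
        return np.real(val * dvol)

    f1 = integrand(q1, w1, np.cos(theta))          # dq = cos(theta) dtheta
    f2 = integrand(q2, w2, s / q2)                 # dq = (s/q) ds
    total = np.trapezoid(f1, theta) + np.trapezoid(f2, s)
    return 1.0 + 0.75 * total


class TestSpectralAveraging:
    def test_single_line_spectrum_equals_single_wavelength(self, stack_spec):
        stack = stack_spec.stack()
        spectrum = op.EmissionSpectrum(np.array([680.0]), np.array([1.0]))
        em = op.Emitter(spectrum=spectrum)
        S_line = op.spectrally_averaged_rate(stack, em, 5.0)
        S_direct = op.relative_decay_rate(stack, 5.0, 680.0, "horizontal")
        assert S_line == pytest.approx(S_direct, rel=1e-8)

    def test_matches_direct_summation_oracle(self, stack_spec, emitter):
        stack = stack_spec.stack()
        z = 6.0
        S_avg = op.spectrally_averaged_rate(stack, emitter, z)
        spec = emitter.spectrum.resample(2.0)
        weights = spec.weight / spec.weight.sum()
        S_sum = sum(wt * op.relative_decay_rate(stack, z, wl, "horizontal")
                    for wl, wt in zip(spec.wavelength_nm, weights) if wt > 0)
        assert S_avg == pytest.approx(S_sum, rel=1e-7)


class TestLifetimeCurve:
    def test_vanishing_quantum_yield_gives_free_space_lifetime(self, stack_spec, emitter):
        em = op.Emitter(tau0_ns=2.6, phi=1e-9, orientation="horizontal",
                        spectrum=emitter.spectrum)
        _, tau = op.lifetime_curve(stack_spec.stack(), em, np.array([2.0, 10.0, 20.0]))
        assert tau == pytest.approx(2.6, rel=1e-6)

    def test_homogeneous_medium_gives_free_space_lifetime(self, emitter):
        hom = op.LayerStack(1.333, (), 1.333)
        _, tau = op.lifetime_curve(hom, emitter, np.array([1.0, 5.0]))
        assert tau == pytest.approx(emitter.tau0_ns, rel=1e-9)

    def test_far_field_recovery(self, stack_spec, emitter):
        """S-bar returns to 1 within 2% at 100 nm above the substrate."""
        curve, tau = op.lifetime_curve(stack_spec.stack(), emitter,
                                       np.array([100.0, 150.0]))
        assert np.all(np.abs(curve.S - 1.0) < 0.02)
        assert tau[-1] == pytest.approx(emitter.tau0_ns, rel=0.02)

    def test_bad_grid_rejected(self, stack_spec, emitter):
        with pytest.raises(ValueError):
            op.lifetime_curve(stack_spec.stack(), emitter, np.array([3.0, 2.0]))


class TestTables:
    def test_dispersion_table_roundtrip(self, tmp_path):
        table = materials.graphene_dispersion()
        path = tmp_path / "graphene.csv"
        table.to_csv(path)
        back = op.DispersionTable.from_csv(path)
        assert back.index(680.0) == pytest.approx(table.index(680.0), rel=1e-9)

    def test_spectrum_roundtrip_and_resample(self, tmp_path):
        spec = materials.atto655_spectrum()
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        back = op.EmissionSpectrum.from_csv(path)
        res = back.resample(2.0)
        assert res.wavelength_nm[0] == spec.wavelength_nm[0]
        assert np.all(np.diff(res.wavelength_nm) == pytest.approx(2.0))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            op.DispersionTable(np.array([500.0, 400.0]), np.array([1.0, 1.0]),
                               np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            op.EmissionSpectrum(np.array([500.0, 510.0]), np.array([0.0, 0.0]))
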