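"""SLR core: conventions, round trips, energy identity, design contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampulse.slr import (DesignInfeasibleError, PolynomialPair, PulseSpec,
                         RFPulse, design_beta_filter, design_refocusing,
                         forward_slr, inverse_slr, matched_excitation,
                         min_phase_alpha)


def random_pulse(rng, n, am=False, scale=0.1):
    s = rng.normal(0, scale, n)
    if not am:
        s = s * np.exp(1j * rng.uniform(-np.pi, np.pi, n))
    return RFPulse(s.astype(complex), 6.4e-6)


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        dict(tbp=0), dict(tbp=-2), dict(flip_angle=0), dict(flip_angle=4.0),
        dict(n_samples=4), dict(ripple_pass=0.0), dict(ripple_stop=1.5),
        dict(dwell=0),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            PulseSpec(**kw)

    def test_infeasible_ripple_tbp_combination(self):
        # transition wider than the band: must fail loudly, not degrade
        with pytest.raises(DesignInfeasibleError):
            design_beta_filter(PulseSpec(tbp=1.0, ripple_pass=1e-3,
                                         ripple_stop=1e-3))


class TestHardPulseConvention:
    @pytest.mark.parametrize("theta", [np.pi / 6, np.pi / 2, np.pi])
    def test_single_sample_pair(self, theta):
        pair = forward_slr(np.array([theta], dtype=complex))
        assert pair.alpha == pytest.approx(np.cos(theta / 2))
        assert pair.beta == pytest.approx(np.sin(theta / 2))
        back = inverse_slr(pair)
        assert back.samples == pytest.approx([theta])

    def test_hard_90_flat_beta_response(self):
        pair = forward_slr(np.array([np.pi / 2], dtype=complex))
        _, bf = pair.frequency_response()
        assert np.abs(bf) == pytest.approx(np.sin(np.pi / 4))

    def test_zero_pulse_is_identity(self):
        pair = forward_slr(np.zeros(16, dtype=complex))
        assert pair.alpha[0] == pytest.approx(1.0)
        assert np.abs(pair.alpha[1:]).max() < 1e-14
        assert np.abs(pair.beta).max() < 1e-14


class TestRoundTrips:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), am=st.booleans())
    def test_forward_inverse_identity(self, seed, am):
        rng = np.random.default_rng(seed)
        pulse = random_pulse(rng, 32, am=am)
        pair = forward_slr(pulse)
        assert pair.energy_residual() < 1e-9
        back = inverse_slr(pair, pulse.dwell)
        assert np.abs(back.samples - pulse.samples).max() < 1e-6

    def test_roundtrip_on_100_random_pairs(self, rng):
        for _ in range(100):
            pulse = random_pulse(rng, 24)
            pair = forward_slr(pulse)
            pair2 = forward_slr(inverse_slr(pair))
            assert np.abs(pair2.beta - pair.beta).max() < 1e-6
            assert np.abs(pair2.alpha - pair.alpha).max() < 1e-6

    def test_inverse_rejects_invalid_pair(self):
        bad = PolynomialPair(beta=np.full(8, 0.5 + 0j),
                             alpha=np.full(8, 0.5 + 0j))
        with pytest.raises(ValueError, match="energy"):
            inverse_slr(bad)


class TestMinPhaseAlpha:
    def test_zero_beta_gives_unit_impulse(self):
        pair = min_phase_alpha(PolynomialPair(beta=np.zeros(16)))
        assert pair.alpha[0] == pytest.approx(1.0)
        assert np.abs(pair.alpha[1:]).max() < 1e-12

    def test_energy_identity_any_valid_beta(self, rng):
        b = rng.normal(0, 0.05, 32)
        pair = min_phase_alpha(PolynomialPair(beta=b))
        assert pair.energy_residual() < 1e-6

    def test_real_beta_real_alpha(self, base_tbp4):
        _, pair = base_tbp4
        rel = np.abs(pair.alpha.imag).max() / np.abs(pair.alpha).max()
        assert rel < 1e-6

    def test_singular_beta_rejected(self):
        b = np.zeros(16)
        b[0] = 1.0
        with pytest.raises(ValueError, match="singular"):
            min_phase_alpha(PolynomialPair(beta=b))


class TestRefocusingDesign:
    @pytest.mark.parametrize("tbp", [4, 8])
    def test_beta_passband_within_ripple(self, tbp):
        from ampulse.slr import beta_ripples, dinf
        spec = PulseSpec(tbp=tbp)
        pair = design_beta_filter(spec)
        d1, d2 = beta_ripples(spec)
        n = pair.n
        w = dinf(d1, d2) / tbp
        bf = np.fft.fft(pair.beta, 16 * n)
        cyc = np.fft.fftfreq(16 * n) * n
        pb = np.abs(cyc) <= (1 - w) * tbp / 2
        sb = np.abs(cyc) >= (1 + w) * tbp / 2
        assert np.abs(np.abs(bf[pb]) - 1).max() < 2.2 * d1  # unit-circle clamp slack
        assert np.abs(bf[sb]).max() < 1.05 * d2

    def test_realness_propagates_to_pulse(self, base_tbp4):
        pulse, pair = base_tbp4
        assert np.abs(pair.beta.imag).max() < 1e-9
        assert pulse.is_am

    def test_exact_pair_energy(self, base_tbp4):
        _, pair = base_tbp4
        assert pair.energy_residual() < 1e-9

    def test_linear_phase_beta_symmetric(self):
        pair = design_beta_filter(PulseSpec(tbp=6))
        b = pair.beta.real
        assert np.abs(b - b[::-1]).max() < 1e-9 * np.abs(b).max()


class TestMatchedExcitation:
    def test_flip_angle_at_band_centre(self, base_tbp4):
        from ampulse.bloch import simulate_profile
        _, pair = base_tbp4
        exc = matched_excitation(pair, PulseSpec(tbp=4))
        prof = simulate_profile(exc, np.array([0.0]))
        # |Mxy| = sin(flip) ~ 1 at the slice centre, within the ripple budget
        assert abs(np.abs(prof.mxy[0]) - 1.0) < 0.02

    def test_spin_echo_phase_flat_in_band(self, base_tbp4):
        from ampulse.bloch import simulate_profile
        _, pair = base_tbp4
        exc = matched_excitation(pair, PulseSpec(tbp=4))
        n = pair.n
        band = np.linspace(-0.3, 0.3, 31) * 2 * np.pi * 4 / n
        echo = (np.conj(simulate_profile(exc, band).mxy)
                * simulate_profile_refocus(pair, band))
        inb = np.abs(echo) > 0.5
        assert np.ptp(np.angle(echo[inb])) < 0.05


def simulate_profile_refocus(pair, band):
    from ampulse.bloch import simulate_profile
    pulse = inverse_slr(pair)
    return simulate_profile(pulse, band).refocus
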