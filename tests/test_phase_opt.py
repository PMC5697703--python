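"""Phase-optimized multiband modulation: structure, optima, gauge handling."""

import numpy as np
import pytest

from ampulse.phase_opt import (MultibandSpec, apply_modulation, canonicalize,
                               gauge_match, modulated_pulse,
                               modulation_function, optimize_phases,
                               resample_pulse, slice_offsets)
from ampulse.reference import REFERENCE_AM_PHASES_DEG
from ampulse.slr import RFPulse


def am_spec(mb, phi=None, n=256, tbp=4, sep=5):
    h = mb // 2
    if phi is None:
        half = np.linspace(1, 0.2, h)
        phi = np.concatenate([half, [0.0] * (mb % 2), -half[::-1]])
    return MultibandSpec.build(mb, sep, tbp, n, phi=phi, am=True)


class TestSpecValidation:
    def test_antisymmetry_enforced(self):
        with pytest.raises(ValueError, match="antisymmetric"):
            MultibandSpec.build(4, 5, 4, 256, phi=[1, 0, 0, 0], am=True)

    def test_central_phase_pinned_odd(self):
        with pytest.raises(ValueError, match="antisymmetric|central"):
            MultibandSpec(mb=3, slice_sep=5, omega=[-1, 0, 1],
                          phi=[0.0, 0.5, 0.0], tau=[0, 0, 0], am=True)

    def test_omega_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            MultibandSpec(mb=3, slice_sep=5, omega=[1, 0, -1],
                          phi=[0, 0, 0], tau=[0, 0, 0])


class TestModulationFunction:
    @pytest.mark.parametrize("mb", [2, 3, 6, 9])
    def test_in_phase_peak_is_mb(self, mb):
        spec = MultibandSpec.build(mb, 5, 4, 256)
        assert modulation_function(spec, np.array([0.0]))[0] == pytest.approx(mb)

    @pytest.mark.parametrize("mb", [3, 4, 7, 8])
    def test_am_spec_gives_real_modulation(self, mb):
        f = modulation_function(am_spec(mb), np.linspace(-500, 500, 2001))
        assert np.abs(f.imag).max() < 1e-9

    def test_reference_mb3_row_real_peak_at_bound(self):
        # the MB=3 antisymmetric problem is degenerate: every offset choice
        # peaks at exactly MB (the benchmark row is one gauge representative)
        phi = np.radians(REFERENCE_AM_PHASES_DEG[3])
        spec = MultibandSpec.build(3, 5, 4, 256, phi=phi, am=True)
        t = np.linspace(0, 2 * np.pi / spec.omega[2], 4096)
        f = modulation_function(spec, t)
        assert np.abs(f.imag).max() < 1e-9
        assert np.abs(f).max() == pytest.approx(3.0, abs=1e-5)


class TestOptimizePhases:
    def test_mb1_trivial(self):
        phi, peak = optimize_phases(1, am=True)
        assert peak == pytest.approx(1.0)
        assert phi == pytest.approx([0.0])

    @pytest.mark.parametrize("mb", range(3, 17))
    def test_am_never_beats_unconstrained(self, mb):
        _, pk_u = optimize_phases(mb, False, n_starts=12, seed=10 + mb)
        _, pk_a = optimize_phases(mb, True, n_starts=12, seed=20 + mb)
        assert pk_a >= pk_u - 1e-9
        assert pk_a < mb  # strictly better than in-phase for mb >= 3

    def test_mb4_am_below_in_phase_bound(self):
        _, pk = optimize_phases(4, True, n_starts=20, seed=3)
        assert pk < 4.0

    @pytest.mark.parametrize("mb", [4, 5, 7])
    def test_recovers_reference_rows_mod_gauge(self, mb):
        phi, _ = optimize_phases(mb, True, n_starts=40, seed=99)
        ref = np.radians(REFERENCE_AM_PHASES_DEG[mb])
        _, resid = gauge_match(phi, ref, am=True)
        assert np.degrees(resid) < 3.0

    def test_canonicalize_is_gauge_invariant(self):
        phi, _ = optimize_phases(5, True, n_starts=10, seed=4)
        shifted = phi + slice_offsets(5) * 0.713
        a = canonicalize(phi)
        b = canonicalize(shifted)
        assert np.abs(a - b).max() < 0.05  # same orbit, same representative


class TestApplyModulation:
    def test_identity_single_slice(self, base_tbp4):
        base, _ = base_tbp4
        spec = MultibandSpec(mb=1, slice_sep=5, omega=[0.0], phi=[0.0],
                             tau=[0.0])
        out = apply_modulation(base, spec)
        assert np.abs(out.samples - base.samples).max() < 1e-15

    def test_real_base_am_spec_is_am(self, base_tbp4):
        base, _ = base_tbp4
        out = apply_modulation(base, am_spec(4, n=base.n_samples))
        assert out.is_am

    def test_duration_unchanged(self, base_tbp4):
        base, _ = base_tbp4
        out = apply_modulation(base, am_spec(6, n=base.n_samples))
        assert out.duration == pytest.approx(base.duration)

    def test_peak_can_fall_below_product_bound(self, base_tbp4):
        # peak alignment: modulated peak <= max|p| * max|f|, often strictly
        base, _ = base_tbp4
        phi, pk_f = optimize_phases(5, True, n_starts=10, seed=5)
        out = modulated_pulse(base, 5, 13, 4, phi, am=True)
        assert out.peak <= base.peak * pk_f * (1 + 1e-9)

    def test_resample_preserves_teff_and_realness(self, base_tbp4):
        from ampulse.metrics import effective_duration
        base, _ = base_tbp4
        up = resample_pulse(base, 1024)
        assert up.is_am
        assert up.duration == pytest.approx(base.duration)
        assert effective_duration(up) == pytest.approx(
            effective_duration(base), rel=1e-3)


class TestSliceProfileEquivalence:
    def test_am_and_unconstrained_share_magnitude_profile(self, base_tbp4):
        # small-tip Fourier magnitudes agree per slice (phases differ)
        base, _ = base_tbp4
        phi_u, _ = optimize_phases(4, False, n_starts=10, seed=7)
        phi_a, _ = optimize_phases(4, True, n_starts=10, seed=8)
        pu = modulated_pulse(base, 4, 6, 4, phi_u)
        pa = modulated_pulse(base, 4, 6, 4, phi_a, am=True)
        n = pu.n_samples
        m = 8 * n
        Fu = np.abs(np.fft.fft(pu.samples, m))
        Fa = np.abs(np.fft.fft(pa.samples, m))
        # compare within the slice passbands (out-of-band tails are at
        # ripple level and interfere differently between the two designs)
        cyc = np.fft.fftfreq(m) * n
        inband = np.zeros(m, bool)
        for c in (np.arange(1, 5) - 2.5) * 4 * 6:
            inband |= np.abs(cyc - c) <= 0.35 * 4
        assert np.abs(Fu[inband] - Fa[inband]).max() < 0.05 * Fu.max()
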