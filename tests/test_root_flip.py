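"""Root factorization, flipping, symmetry classes, stopband treatment."""

import numpy as np
import pytest

from ampulse.root_flip import (RootSet, am_stopband_treatment,
                               build_multiband_beta, factor_beta, flip,
                               roots_to_beta, symmetrize_stopband)
from ampulse.slr import PolynomialPair, inverse_slr, min_phase_alpha


@pytest.fixture(scope="module")
def mb_beta():
    return build_multiband_beta(4, 4, 4)


@pytest.fixture(scope="module")
def rootset(mb_beta):
    pair, layout = mb_beta
    return factor_beta(pair, layout)


class TestFactor:
    def test_single_root(self):
        c = 0.4
        r = 0.3 + 0.2j
        pair = PolynomialPair(beta=np.array([c, -c * r]))
        rs = factor_beta(pair)
        assert rs.roots[0] == pytest.approx(r)

    def test_reconstruction_roundtrip(self, rootset, mb_beta):
        pair, _ = mb_beta
        b = roots_to_beta(rootset.roots, rootset.target_max, rootset.n)
        m = 8 * rootset.n
        assert np.abs(np.abs(np.fft.fft(b, m))
                      - np.abs(np.fft.fft(pair.beta, m))).max() < 1e-6

    def test_min_phase_roots_inside(self, rootset):
        # homomorphic factor: all roots on or inside the circle
        assert np.abs(rootset.roots).max() < 1.01

    def test_conjugate_closed_real_filter(self, rootset):
        assert rootset.conjugate_closed()

    def test_degenerate_leading_coeff_rejected(self):
        beta = np.zeros(8, complex)
        beta[4] = 0.5
        with pytest.raises(Exception, match="degenerate|factor"):
            factor_beta(PolynomialPair(beta=beta))


class TestFlip:
    def test_real_root_inversion(self):
        rs = RootSet(roots=np.array([0.5 + 0j]), band_labels=np.array([0]),
                     flip_mask=np.array([False]), leading_coeff=1.0,
                     target_max=0.5, n=2)
        out = flip(rs, np.array([True]))
        assert out.roots[0] == pytest.approx(2.0)

    def test_unit_circle_root_fixed_point(self):
        r = np.exp(1j * 0.7)
        rs = RootSet(roots=np.array([r]), band_labels=np.array([0]),
                     flip_mask=np.array([False]), leading_coeff=1.0,
                     target_max=0.5, n=2)
        out = flip(rs, np.array([True]))
        assert out.roots[0] == pytest.approx(r)

    def test_magnitude_profile_invariant_under_any_flip(self, rootset, rng):
        m = 8 * rootset.n
        b0 = roots_to_beta(rootset.roots, rootset.target_max, rootset.n)
        for _ in range(5):
            mask = rng.random(len(rootset.roots)) < 0.3
            b1 = roots_to_beta(flip(rootset, mask).roots, rootset.target_max,
                               rootset.n)
            assert np.abs(np.abs(np.fft.fft(b1, m))
                          - np.abs(np.fft.fft(b0, m))).max() < 1e-6

    def test_origin_root_rejected(self):
        rs = RootSet(roots=np.array([0.0 + 0j]), band_labels=np.array([0]),
                     flip_mask=np.array([False]), leading_coeff=1.0,
                     target_max=0.5, n=2)
        with pytest.raises(ValueError, match="origin"):
            flip(rs, np.array([True]))


class TestStopbandTreatment:
    def test_no_stopband_roots_identity(self):
        rs = RootSet(roots=np.array([0.5 + 0.1j, 0.5 - 0.1j]),
                     band_labels=np.array([0, 0]),
                     flip_mask=np.array([False, False]), leading_coeff=1.0,
                     target_max=0.5, n=3)
        out = am_stopband_treatment(rs)
        assert np.all(out.roots == rs.roots)

    def test_conjugate_closure_preserved(self, rootset):
        assert am_stopband_treatment(rootset).conjugate_closed()

    def test_edge_energy_reduced_vs_one_sided_stopband(self, rootset, mb_beta):
        # one-sided radial arrangements (all stopband roots inside, the
        # minimum-phase start) pile stopband energy into an edge spike;
        # the alternating sub-band pattern spreads it
        pair, _ = mb_beta
        alpha = min_phase_alpha(pair).alpha
        n = rootset.n

        def edge_peak(rs):
            b = roots_to_beta(rs.roots, rs.target_max, n)
            p = inverse_slr(PolynomialPair(beta=b, alpha=alpha))
            k = max(1, n // 20)
            return max(np.abs(p.samples[:k]).max(), np.abs(p.samples[-k:]).max())

        assert edge_peak(am_stopband_treatment(rootset)) < edge_peak(rootset)


class TestSymmetryClasses:
    def test_am_pattern_conjugate_closed(self, rootflip_mb4_am):
        assert rootflip_mb4_am.rootset.conjugate_closed()
        assert rootflip_mb4_am.pulse.is_am

    def test_unconstrained_pattern_not_conjugate_closed(self, rootflip_mb4_unc):
        # anti-flipped conjugate pairs: closure only in the trivial patterns
        pb = rootflip_mb4_unc.rootset.band_labels >= 0
        flipped = rootflip_mb4_unc.rootset.flip_mask & pb
        if 0 < flipped.sum() < pb.sum():
            assert not rootflip_mb4_unc.rootset.conjugate_closed()
        assert not rootflip_mb4_unc.pulse.is_am

    def test_unconstrained_pulse_time_symmetric(self, rootflip_mb4_unc):
        b = rootflip_mb4_unc.pulse.samples
        env = np.abs(b)
        assert np.abs(env - env[::-1]).max() < 0.12 * env.max()

    def test_flip_search_beats_min_phase_start(self, rootflip_mb4_unc, mb_beta):
        pair, _ = mb_beta
        start = inverse_slr(min_phase_alpha(pair))
        assert rootflip_mb4_unc.peak < start.peak

    def test_one_sided_arrangements_put_peak_at_an_edge(self, rootset, mb_beta):
        # all passband roots on one radial side concentrate the main
        # amplitude peak at one end of the pulse; flipping them to the
        # other side moves it to the opposite end
        pair, _ = mb_beta
        alpha = min_phase_alpha(pair).alpha
        n = rootset.n

        def argmax_of(rs):
            b = roots_to_beta(rs.roots, rs.target_max, n)
            p = inverse_slr(PolynomialPair(beta=b, alpha=alpha))
            return int(np.argmax(np.abs(p.samples)))

        assert argmax_of(rootset) > 2 * n // 3          # all inside: end
        outside = flip(rootset, rootset.band_labels >= 0)
        assert argmax_of(outside) < n // 3              # all outside: start


class TestDesignedProfiles:
    def test_refocusing_profile_meets_ripple_spec(self, rootflip_mb4_am):
        from ampulse.bloch import simulate_profile
        layout = rootflip_mb4_am.layout
        n = layout["n"]
        om = np.linspace(-np.pi, np.pi, 4096)
        prof = simulate_profile(rootflip_mb4_am.pulse, om)
        cyc = om * n / (2 * np.pi)
        pb = np.zeros_like(cyc, bool)
        sb = np.ones_like(cyc, bool)
        for c in layout["centres"]:
            pb |= np.abs(cyc - c) <= layout["f1"]
            sb &= np.abs(cyc - c) >= layout["f2"]
        assert np.abs(np.abs(prof.refocus[pb]) - 1).max() < 1.5 * 0.01
        assert np.abs(prof.refocus[sb]).max() < 1.5 * 0.01
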