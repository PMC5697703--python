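"""Shinnar–Le Roux (SLR) core: single-band beta-filter design, minimum-phase
alpha recovery, and the forward / inverse hard-pulse recursions.

The SLR transform maps a sampled RF pulse onto a pair of complex polynomials
``(alpha, beta)`` whose values on the unit circle encode the spin-domain
rotation produced at each off-resonance frequency.  Design proceeds in the
beta domain: a linear-phase FIR filter approximating the desired slice
profile is designed, the matching minimum-phase alpha is recovered from the
energy identity |alpha|^2 + |beta|^2 = 1, and the inverse recursion converts
the pair back into an RF waveform.

Spin-domain convention used throughout this package: a hard rotation by
nutation angle ``phi`` about a transverse axis at phase ``theta`` has
Cayley–Klein parameters ``C = cos(phi/2)`` and ``S = exp(i*theta)*sin(phi/2)``
(no extra factor of i on S), and free precession advances beta by one unit
delay.  Under this convention a single hard pulse of angle ``theta`` has
``beta = [sin(theta/2)]`` (real), and real beta/alpha coefficients yield a
real (amplitude-modulated) RF waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.signal import remez

__all__ = [
    "GAMMA_1H",
    "PulseSpec",
    "PolynomialPair",
    "RFPulse",
    "DesignInfeasibleError",
    "dinf",
    "beta_ripples",
    "design_beta_filter",
    "min_phase_alpha",
    "mag_to_min_phase",
    "forward_slr",
    "inverse_slr",
    "design_refocusing",
    "matched_excitation",
]

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA_1H = 267.522187e6

# Fraction by which max|beta| is kept below 1 when a designed filter
# overshoots the unit circle; the minimum-phase alpha magnitude then dips to
# ~sqrt(2e-8) at the passband centre, which the 16N homomorphic grid resolves.
_BETA_CLAMP_EPS = 1e-8
_MINPHASE_GRID_MULT = 16


class DesignInfeasibleError(ValueError):
    """The requested ripple / TBP / length combination cannot be met."""


def dinf(d1: float, d2: float) -> float:
    """Empirical time-bandwidth of an equiripple transition with passband
    ripple ``d1`` and stopband ripple ``d2`` (the classic polynomial fit
    used in SLR filter design)."""
    a = (5.309e-3, 7.114e-2, -4.761e-1, -2.66e-3, -5.941e-1, -4.278e-1)
    l1, l2 = np.log10(d1), np.log10(d2)
    return (a[0] * l1 * l1 + a[1] * l1 + a[2]) * l2 + (a[3] * l1 * l1 + a[4] * l1 + a[5])


@dataclass(frozen=True)
class PulseSpec:
    """A single-band SLR design request.

    Parameters
    ----------
    flip_angle:
        Nutation angle in radians, in (0, pi].
    tbp:
        Time-bandwidth product of the slice profile.
    n_samples:
        Number of RF samples.  ``None`` selects a default suited to the
        design regime (see :func:`design_beta_filter`).
    dwell:
        Sample duration in seconds.
    ripple_pass, ripple_stop:
        Fractional ripple of the *effective profile* (the crushed spin-echo
        profile for refocusing pulses, the transverse magnetization for
        excitation pulses), in and out of slice.
    pulse_class:
        ``"refocusing"`` or ``"excitation"``; selects the profile-to-beta
        ripple conversion and the beta passband amplitude ``sin(flip/2)``.
    phase_class:
        Only ``"linear"`` beta filters are designed here; root manipulation
        of the linear-phase design produces the other phase classes.
    """

    flip_angle: float = np.pi
    tbp: float = 4.0
    n_samples: Optional[int] = None
    dwell: float = 6.4e-6
    ripple_pass: float = 0.01
    ripple_stop: float = 0.01
    pulse_class: Literal["refocusing", "excitation"] = "refocusing"
    phase_class: Literal["linear", "minimum", "maximum"] = "linear"

    def __post_init__(self):
        if not 0 < self.flip_angle <= np.pi:
            raise ValueError(f"flip_angle must be in (0, pi], got {self.flip_angle}")
        if not self.tbp > 0:
            raise ValueError(f"tbp must be positive, got {self.tbp}")
        if self.n_samples is not None and self.n_samples < 8:
            raise ValueError(f"n_samples must be >= 8, got {self.n_samples}")
        if not 0 < self.ripple_pass < 1 or not 0 < self.ripple_stop < 1:
            raise ValueError("ripples must be fractional, in (0, 1)")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


@dataclass
class RFPulse:
    """A sampled complex RF waveform.

    ``samples`` are in radians of nutation per sample; the physical field is
    ``B1[T] = samples / (GAMMA_1H * dwell)``.
    """

    samples: np.ndarray
    dwell: float
    carrier_offsets_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dwell

    @property
    def peak(self) -> float:
        """Peak nutation per sample, radians."""
        return float(np.abs(self.samples).max())

    @property
    def b1_max_uT(self) -> float:
        """Peak |B1| in microtesla."""
        return self.peak / (GAMMA_1H * self.dwell) * 1e6

    @property
    def is_am(self) -> bool:
        """True when the waveform is purely amplitude modulated (real up to
        a relative imaginary residual of 1e-6)."""
        m = np.abs(self.samples).max()
        if m == 0:
            return True
        return np.abs(self.samples.imag).max() / m < 1e-6

    def amplitude_uT(self) -> np.ndarray:
        """Per-sample |B1| in microtesla."""
        return np.abs(self.samples) / (GAMMA_1H * self.dwell) * 1e6

    def scaled_to_b1max(self, b1max_uT: float) -> "RFPulse":
        """Rescale dwell so the peak equals ``b1max_uT`` (minimum duration at
        the given amplitude cap; flip angle and profile are preserved)."""
        new_dwell = self.peak / (GAMMA_1H * b1max_uT * 1e-6)
        return RFPulse(self.samples.copy(), new_dwell, dict(self.carrier_offsets_meta))


@dataclass
class PolynomialPair:
    """SLR (alpha, beta) coefficient pair.

    Either polynomial may be ``None`` while a design is in flight; a complete
    pair satisfies |alpha|^2 + |beta|^2 = 1 on the unit circle.
    """

    beta: np.ndarray
    alpha: Optional[np.ndarray] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=complex)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=complex)
            if len(self.alpha) != len(self.beta):
                raise ValueError("alpha and beta must have equal length")

    @property
    def n(self) -> int:
        return len(self.beta)

    def frequency_response(self, grid_mult: int = 8):
        """(alpha_tilde, beta_tilde) on a uniform unit-circle grid of size
        ``grid_mult * n`` (alpha part None if alpha unset)."""
        m = grid_mult * self.n
        bf = np.fft.fft(self.beta, m)
        af = np.fft.fft(self.alpha, m) if self.alpha is not None else None
        return af, bf

    def energy_residual(self, grid_mult: int = 8) -> float:
        """max | |alpha|^2 + |beta|^2 - 1 | over the evaluation grid."""
        if self.alpha is None:
            raise ValueError("alpha is unset")
        af, bf = self.frequency_response(grid_mult)
        return float(np.abs(np.abs(af) ** 2 + np.abs(bf) ** 2 - 1).max())


# ---------------------------------------------------------------------------
# beta filter design
# ---------------------------------------------------------------------------

def beta_ripples(spec: PulseSpec) -> tuple[float, float]:
    """Convert effective-profile ripples to beta-polynomial ripples.

    Refocusing (crushed spin echo, profile beta^2): passband d1/4, stopband
    sqrt(d2).  Excitation (profile 2 conj(a) b): passband sqrt(d1/2),
    stopband d2/sqrt(2).  These are the classic SLR conversions.
    """
    if spec.pulse_class == "refocusing":
        return spec.ripple_pass / 4.0, np.sqrt(spec.ripple_stop)
    return np.sqrt(spec.ripple_pass / 2.0), spec.ripple_stop / np.sqrt(2.0)


def _chebyshev_lp(n: int, bands: list[tuple[float, float, float, float]],
                  nyquist: float, cap: Optional[float] = None,
                  n_pass_grid: int = 80, stop_grid_density: float = 8.0):
    """Weighted-Chebyshev linear-phase FIR design by linear programming.

    ``bands`` is a list of (f_lo, f_hi, desired, ripple_weight) in the same
    frequency units as ``nyquist``.  Minimizes the common ripple scale
    ``delta`` such that |A(f) - desired| <= delta * ripple_weight on each
    band.  ``cap`` optionally bounds |A(f)| <= cap on the complement
    (transition) regions.  Returns (h, delta).  Even n -> type II symmetric.
    """
    M = n // 2 if n % 2 == 0 else (n + 1) // 2
    tau = (n - 1) / 2 - np.arange(M)

    def cosmat(f):
        c = np.cos(np.pi * np.outer(f, tau) / nyquist)
        if n % 2 == 0:
            return 2 * c
        c = 2 * c
        c[:, -1] /= 2  # centre tap counted once
        return c

    rows, rhs = [], []
    band_edges = []
    for f_lo, f_hi, des, wt in bands:
        width = f_hi - f_lo
        npts = n_pass_grid if des != 0 else max(64, int(stop_grid_density * width))
        fgrid = np.linspace(f_lo, f_hi, max(npts, 8))
        C = cosmat(fgrid)
        one = np.ones((len(fgrid), 1))
        rows.append(np.hstack([C, -wt * one]))
        rhs.append(np.full(len(fgrid), des))
        rows.append(np.hstack([-C, -wt * one]))
        rhs.append(np.full(len(fgrid), -des))
        band_edges.append((f_lo, f_hi))
    if cap is not None:
        band_edges.sort()
        gaps = []
        prev = 0.0
        for lo, hi in band_edges:
            if lo > prev:
                gaps.append((prev, lo))
            prev = max(prev, hi)
        if prev < nyquist:
            gaps.append((prev, nyquist))
        for lo, hi in gaps:
            ft = np.linspace(lo, hi, 32)[1:-1]
            if len(ft) == 0:
                continue
            C = cosmat(ft)
            z = np.zeros((len(ft), 1))
            rows.append(np.hstack([C, z]))
            rhs.append(np.full(len(ft), cap))
            rows.append(np.hstack([-C, z]))
            rhs.append(np.full(len(ft), cap))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    c = np.zeros(M + 1)
    c[-1] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(None, None)] * M + [(0, None)], method="highs")
    if not res.success:
        raise DesignInfeasibleError(f"LP filter design failed: {res.message}")
    half = res.x[:M]
    delta = float(res.x[-1])
    if n % 2 == 0:
        h = np.concatenate([half, half[::-1]])
    else:
        h = np.concatenate([half, half[-2::-1]])
    return h, delta


def default_n_samples(tbp: float, d1: float = 0.0025, d2: float = 0.1) -> int:
    """Design-length default: compact lengths for narrow fractional
    passbands (low TBP), 256 otherwise.  Over-long equiripple refocusing
    designs are degenerate (the optimal filter spreads energy across unused
    taps and the pulse's effective duration drifts with length), so low-TBP
    designs are kept near their compact length."""
    w = dinf(d1, d2) / tbp
    passband_cycles = (1 - w) * tbp / 2
    return 192 if passband_cycles < 2.0 else 256


def design_beta_filter(spec: PulseSpec) -> PolynomialPair:
    """Design the linear-phase beta polynomial for ``spec``.

    Narrow-passband designs (passband under ~2 cycles across the pulse) use
    a dense-grid weighted-Chebyshev linear program; wider designs use the
    Parks–McClellan exchange (scipy.signal.remez) with an LP fallback.  The
    transition half-width follows the empirical ``dinf`` rule.  The filter is
    scaled by ``sin(flip/2)`` and clamped just below the unit circle if it
    overshoots.
    """
    if spec.phase_class != "linear":
        raise ValueError("design_beta_filter designs linear-phase filters; "
                         "derive other phase classes by root manipulation")
    d1, d2 = beta_ripples(spec)
    w = dinf(d1, d2) / spec.tbp
    if w >= 1.0:
        raise DesignInfeasibleError(
            f"transition width {w:.2f}x the band: TBP {spec.tbp} cannot support "
            f"beta ripples ({d1:.2g}, {d2:.2g})")
    n = spec.n_samples if spec.n_samples is not None else default_n_samples(spec.tbp, d1, d2)
    f1, f2 = (1 - w) * spec.tbp / 2, (1 + w) * spec.tbp / 2
    narrow = f1 < 2.0
    h = None
    if not narrow:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h = remez(n, [0, f1, f2, n / 2], [1, 0],
                          weight=[1, d1 / d2], fs=n, maxiter=250)
            bf = np.abs(np.fft.fft(h, 8 * n))
            if not np.all(np.isfinite(h)) or bf.max() > 1.5:
                h = None
        except Exception:
            h = None
    if h is None:
        bands = [(0.0, f1, 1.0, d1), (f2, n / 2, 0.0, d2)]
        h, delta = _chebyshev_lp(n, bands, n / 2)
        if delta > 1.0 + 1e-6:
            raise DesignInfeasibleError(
                f"achieved ripple {delta:.3f}x the specification "
                f"(TBP={spec.tbp}, n={n})")
    beta = np.asarray(h, float) * np.sin(spec.flip_angle / 2)
    m = np.abs(np.fft.fft(beta, _MINPHASE_GRID_MULT * n)).max()
    if m >= 1.0:
        beta = beta / (m + _BETA_CLAMP_EPS)
    return PolynomialPair(beta=beta)


# ---------------------------------------------------------------------------
# minimum-phase alpha
# ---------------------------------------------------------------------------

def mag_to_min_phase(mag: np.ndarray) -> np.ndarray:
    """Minimum-phase spectrum with the given magnitude samples on a uniform
    unit-circle grid (homomorphic / folded-cepstrum construction; the phase
    is the Hilbert transform of log-magnitude)."""
    m = len(mag)
    cep = np.fft.ifft(np.log(mag))
    fold = np.zeros(m, dtype=complex)
    fold[0] = cep[0]
    fold[1:m // 2] = 2 * cep[1:m // 2]
    if m % 2 == 0:
        fold[m // 2] = cep[m // 2]
    return np.exp(np.fft.fft(fold))


def min_phase_alpha(pair: PolynomialPair, grid_mult: int = _MINPHASE_GRID_MULT) -> PolynomialPair:
    """Fill in the minimum-phase alpha for a beta polynomial.

    |alpha| = sqrt(1 - |beta|^2) pointwise on a ``grid_mult * n`` unit-circle
    grid and the phase of alpha is the Hilbert transform of log|alpha|.  A
    conjugate-symmetric (real) beta yields a real alpha.
    """
    beta = pair.beta
    n = len(beta)
    bf = np.fft.fft(beta, grid_mult * n)
    mag2 = 1.0 - np.abs(bf) ** 2
    if mag2.min() <= 0:
        raise ValueError("max|beta| reaches 1 on the evaluation grid; "
                         "log|alpha| is singular")
    af = mag_to_min_phase(np.sqrt(mag2))
    alpha = np.fft.ifft(af)[:n]
    if np.abs(beta.imag).max() <= 1e-12 * max(np.abs(beta).max(), 1e-300):
        # real beta: discard the numerically-tiny imaginary residue
        alpha = alpha.real.astype(complex)
    return PolynomialPair(beta=beta.copy(), alpha=alpha)


# ---------------------------------------------------------------------------
# forward / inverse recursions
# ---------------------------------------------------------------------------

def forward_slr(pulse: RFPulse | np.ndarray) -> PolynomialPair:
    """Hard-pulse forward recursion: RF samples -> exact (alpha, beta).

    The returned pair satisfies the unit-circle energy identity to machine
    precision by construction.
    """
    rf = pulse.samples if isinstance(pulse, RFPulse) else np.asarray(pulse, complex)
    n = len(rf)
    a = np.array([1.0 + 0j])
    b = np.array([0.0 + 0j])
    for j in range(n):
        phi = np.abs(rf[j])
        theta = np.angle(rf[j]) if phi > 0 else 0.0
        C = np.cos(phi / 2)
        S = np.exp(1j * theta) * np.sin(phi / 2)
        az = np.concatenate([a, [0.0]])
        bz = np.concatenate([[0.0], b])
        a, b = (C * az - np.conj(S) * bz)[: j + 1], (S * az + C * bz)[: j + 1]
    return PolynomialPair(beta=b, alpha=a)


def inverse_slr(pair: PolynomialPair, dwell: float = 6.4e-6,
                energy_tol: float = 0.05) -> RFPulse:
    """Inverse SLR recursion: (alpha, beta) -> RF samples.

    Requires a complete pair approximately satisfying the energy identity
    (residual below ``energy_tol``); exact pairs round-trip through
    :func:`forward_slr` to machine precision.
    """
    if pair.alpha is None:
        raise ValueError("pair.alpha is unset; run min_phase_alpha first")
    res = pair.energy_residual()
    if res > energy_tol:
        raise ValueError(f"energy identity violated (residual {res:.3g} > "
                         f"{energy_tol}); not a valid SLR pair")
    a = np.ascontiguousarray(pair.alpha, dtype=complex).copy()
    b = np.ascontiguousarray(pair.beta, dtype=complex).copy()
    n = len(a)
    from ._kernels import HAVE_NUMBA, inverse_slr_kernel
    if HAVE_NUMBA:
        return RFPulse(inverse_slr_kernel(a, b), dwell)
    rf = np.zeros(n, dtype=complex)
    for j in range(n - 1, -1, -1):
        t = b[0] / a[0]
        phi = 2 * np.arctan(np.abs(t))
        theta = np.angle(t) if np.abs(t) > 0 else 0.0
        rf[j] = phi * np.exp(1j * theta)
        C = np.cos(phi / 2)
        S = np.exp(1j * theta) * np.sin(phi / 2)
        a_new = C * a + np.conj(S) * b
        b_new = -S * a + C * b
        a = a_new[: max(j, 1)]
        b = b_new[1: max(j, 1) + 1]
    return RFPulse(rf, dwell)


# ---------------------------------------------------------------------------
# turnkey designs
# ---------------------------------------------------------------------------

def design_refocusing(spec: PulseSpec) -> tuple[RFPulse, PolynomialPair]:
    """Design a single-band linear-phase refocusing pulse.

    Returns the pulse and its *exact* polynomial pair (recomputed from the
    waveform by the forward recursion, so the energy identity holds to
    machine precision; the beta profile differs from the designed filter by
    less than ~2e-4, far inside the ripple budget).
    """
    pair = design_beta_filter(spec)
    pair = min_phase_alpha(pair)
    pulse = inverse_slr(pair, spec.dwell)
    if np.abs(pair.beta.imag).max() <= 1e-12:
        pulse.samples = pulse.samples.real.astype(complex)
    exact = forward_slr(pulse)
    return pulse, exact


def matched_excitation(ref_pair: PolynomialPair, spec: PulseSpec,
                       grid_mult: int = _MINPHASE_GRID_MULT) -> RFPulse:
    """Design the matched excitation pulse for a refocusing beta (single- or
    multiband).

    The excitation beta magnitude is obtained by halving the local flip
    angle of the refocusing profile, ``|beta_ex| = sin(arcsin(|beta_ref|)/2)``
    (passband sin(pi/4), stopband ~half the refocusing stopband ripple),
    which reproduces the band structure exactly.  Its phase is set to
    ``angle(alpha_ex) + 2*angle(beta_ref)`` so the crushed spin-echo profile
    ``conj(Mxy_ex) * beta_ref^2`` has flat through-slice phase in every
    passband; the minimum-phase alpha depends only on the magnitude, so the
    construction is direct.  The result is the minimum-duration matched
    excitation once rescaled to the shared peak-amplitude cap.
    """
    n = ref_pair.n
    n_ex = 2 * n   # the matched-phase response needs roughly twice the taps
    m = grid_mult * n
    rf = np.fft.fft(ref_pair.beta, m)
    mag_ref = np.minimum(np.abs(rf), 1.0 - _BETA_CLAMP_EPS)
    mag_ex = np.sin(np.arcsin(mag_ref) / 2)
    alpha_ex = np.fft.ifft(mag_to_min_phase(np.sqrt(1 - mag_ex ** 2)))[:n_ex]
    af = np.fft.fft(alpha_ex, m)
    target = mag_ex * np.exp(1j * (np.angle(af) + 2 * np.angle(rf)))
    beta_matched = np.fft.ifft(target)[:n_ex]
    pair = PolynomialPair(beta=beta_matched, alpha=alpha_ex)
    return inverse_slr(pair, spec.dwell)
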