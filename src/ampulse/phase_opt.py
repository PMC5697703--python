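"""Phase-optimized multiband pulses.

A multiband pulse is the product of a single-band pulse ``p(t)`` and a
modulation function ``f(t) = sum_n exp(i*(omega_n*t + phi_n))`` carrying one
frequency offset per slice.  Optimizing the phase offsets ``phi_n``
minimizes the peak of ``|f|``.  Restricting the offsets to be antisymmetric
across the slice group (``phi_i = -phi_j`` for slices equidistant from the
centre; the central slice of an odd group pinned to zero) makes ``f`` real,
so a real single-band pulse yields a purely amplitude-modulated multiband
pulse.

The optimal offsets depend only on the multiband factor: slice separation
and the single-band waveform rescale the time axis of ``f`` but not its
peak.  The peak-minimization problem has exact gauge freedoms — a common
time shift of the modulation (which adds a phase ramp ``omega_n * s``, and
preserves antisymmetry because the offsets are centred), a global sign, and
the slice-order flip — so optimized offsets are only comparable modulo
these; :func:`gauge_match` reduces a solution onto the gauge orbit point
closest to a reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._optim import minimize_peak_phases
from .slr import RFPulse
from scipy.signal import resample as _fourier_resample

__all__ = [
    "MultibandSpec",
    "slice_offsets",
    "modulation_function",
    "optimize_phases",
    "apply_modulation",
    "modulated_pulse",
    "resample_pulse",
    "gauge_match",
    "canonicalize",
]


def slice_offsets(mb: int) -> np.ndarray:
    """Slice index offsets ``n - (mb+1)/2`` for n = 1..mb: unit-spaced,
    strictly increasing, symmetric about zero."""
    return np.arange(1, mb + 1) - (mb + 1) / 2


@dataclass
class MultibandSpec:
    """A multiband modulation request.

    ``omega`` are per-slice angular frequency offsets in radians per sample,
    evenly spaced and centred on zero; ``phi`` phase offsets in radians;
    ``tau`` per-slice time shifts in samples (zero for pure phase
    modulation).  ``am`` asserts the conjugate-symmetry conditions
    (antisymmetric ``phi``, pair-shared ``tau``).
    """

    mb: int
    slice_sep: float
    omega: np.ndarray
    phi: np.ndarray
    tau: np.ndarray
    am: bool = False

    def __post_init__(self):
        self.omega = np.asarray(self.omega, float)
        self.phi = np.asarray(self.phi, float)
        self.tau = np.asarray(self.tau, float)
        if self.mb < 1:
            raise ValueError("mb must be >= 1")
        if self.slice_sep <= 0:
            raise ValueError("slice_sep must be positive")
        if not (len(self.omega) == len(self.phi) == len(self.tau) == self.mb):
            raise ValueError("omega, phi, tau must each have length mb")
        if self.mb > 1:
            d = np.diff(self.omega)
            if not np.all(d > 0):
                raise ValueError("omega must be strictly increasing")
            if np.abs(self.omega + self.omega[::-1]).max() > 1e-9:
                raise ValueError("omega must be symmetric about 0")
        if self.am:
            if np.abs(self.phi + self.phi[::-1]).max() > 1e-9:
                raise ValueError("AM spec requires antisymmetric phase offsets")
            if np.abs(self.tau - self.tau[::-1]).max() > 1e-9:
                raise ValueError("AM spec requires pair-shared time shifts")
            if self.mb % 2 and abs(self.phi[self.mb // 2]) > 1e-9:
                raise ValueError("AM spec requires zero central-slice phase")

    @classmethod
    def build(cls, mb: int, slice_sep: float, tbp: float, n_samples: int,
              phi: Optional[Sequence[float]] = None,
              tau: Optional[Sequence[float]] = None,
              am: bool = False) -> "MultibandSpec":
        """Spec with offsets ``delta_omega = 2*pi*tbp*slice_sep/n`` implied
        by the base pulse's time-bandwidth and the slice separation (in
        slice thicknesses)."""
        dw = 2 * np.pi * tbp * slice_sep / n_samples
        omega = slice_offsets(mb) * dw
        phi = np.zeros(mb) if phi is None else np.asarray(phi, float)
        tau = np.zeros(mb) if tau is None else np.asarray(tau, float)
        return cls(mb=mb, slice_sep=slice_sep, omega=omega, phi=phi, tau=tau, am=am)


def modulation_function(spec: MultibandSpec, tgrid: np.ndarray) -> np.ndarray:
    """f(t) = sum_n exp(i*(omega_n t + phi_n)) on the given sample grid."""
    t = np.asarray(tgrid, float)
    return np.exp(1j * (np.outer(t, spec.omega) + spec.phi)).sum(axis=1)


def optimize_phases(mb: int, am: bool, n_starts: int = 100, seed: int = 1234,
                    grid_per_period: int = 64):
    """Peak-minimizing phase offsets for ``mb`` unit-spaced slices.

    Evaluates the modulation on ``grid_per_period * mb`` points per
    fundamental period and returns ``(phi, peak)``; ``am=True`` restricts to
    the antisymmetric subspace.  The result is canonicalized (peak-centred
    time-shift gauge; see :func:`canonicalize`).
    """
    if mb < 1:
        raise ValueError("mb must be >= 1")
    if mb == 1:
        return np.zeros(1), 1.0
    om = slice_offsets(mb)
    t = np.linspace(0, 2 * np.pi, grid_per_period * mb, endpoint=False)
    C = np.exp(1j * np.outer(t, om))
    phi, peak = minimize_peak_phases(C, mb, am, n_starts=n_starts, seed=seed)
    # refine the peak on a denser grid
    t2 = np.linspace(0, 2 * np.pi, 1024 * mb, endpoint=False)
    peak = float(np.abs(np.exp(1j * (np.outer(t2, om) + phi)).sum(axis=1)).max())
    return canonicalize(phi, am=am), peak


def _wrap(x):
    return (x + np.pi) % (2 * np.pi) - np.pi


def gauge_match(phi: np.ndarray, reference: np.ndarray,
                am: bool = True, n_scan: int = 8192):
    """Reduce ``phi`` onto its gauge orbit point nearest ``reference``.

    Scans the continuous time-shift gauge (phase ramp ``omega_n * s``), the
    sign flip, and — for non-AM solutions — a global phase offset, and
    returns the transformed phases minimizing the maximum circular distance
    to the reference.
    """
    mb = len(phi)
    om = slice_offsets(mb)
    ref = np.asarray(reference, float)
    best = (np.inf, None)
    period = 4 * np.pi  # covers half-integer offsets for even mb
    for sign in (1.0, -1.0):
        base = sign * np.asarray(phi, float)
        for s in np.linspace(0, period, n_scan, endpoint=False):
            cand = base + om * s
            if not am:
                cand = cand - np.mean(_wrap(cand - ref))
            d = np.abs(_wrap(cand - ref)).max()
            if d < best[0]:
                best = (d, _wrap(cand))
    return best[1], float(best[0])


def _peak_centered(phi: np.ndarray, om: np.ndarray) -> np.ndarray:
    """Shift the time-gauge so the modulation magnitude peaks at t = 0."""
    t = np.linspace(0, 2 * np.pi, 16384, endpoint=False)
    f = np.exp(1j * (np.outer(t, om) + phi)).sum(axis=1)
    af = np.abs(f)
    k = int(np.argmax(af))
    dt = t[1] - t[0]
    d = af[k - 1] - 2 * af[k] + af[(k + 1) % len(af)]
    t_star = t[k] + (0.5 * (af[k - 1] - af[(k + 1) % len(af)]) / d * dt
                     if d < 0 else 0.0)
    return phi + om * t_star


def canonicalize(phi: np.ndarray, am: bool = True) -> np.ndarray:
    """Deterministic gauge fixing: the time origin is placed at the peak of
    the modulation magnitude (so the peak aligns with the centre of a
    centred envelope), the residual sign / reflection freedom is resolved
    lexicographically, and — for non-AM solutions — the global phase is
    removed by making f(0) real and positive.  AM antisymmetry is preserved
    exactly."""
    phi = np.asarray(phi, float)
    mb = len(phi)
    om = slice_offsets(mb)
    cands = []
    for sign in (1.0, -1.0):
        cand = _peak_centered(sign * phi, om)
        if not am:
            # rotate so f(0) is real positive (global-phase gauge)
            f0 = np.exp(1j * cand).sum()
            cand = cand - np.angle(f0)
        cand = _wrap(cand)
        if am:
            cand = 0.5 * (cand - cand[::-1])   # exact antisymmetry
        cands.append(cand)
    # lexicographic tie-break on the rounded phases
    key = [tuple(np.round(c, 6)) for c in cands]
    return cands[0] if key[0] >= key[1] else cands[1]


def resample_pulse(pulse: RFPulse, n_new: int) -> RFPulse:
    """Fourier resampling to ``n_new`` samples at constant duration (dwell
    rescaled); preserves the waveform shape, flip angle and realness."""
    if n_new == pulse.n_samples:
        return pulse
    scale = pulse.n_samples / n_new  # radians per sample shrink
    re = _fourier_resample(pulse.samples.real, n_new)
    im = _fourier_resample(pulse.samples.imag, n_new)
    return RFPulse((re + 1j * im) * scale, pulse.dwell * pulse.n_samples / n_new,
                   dict(pulse.carrier_offsets_meta))


def apply_modulation(base: RFPulse, spec: MultibandSpec) -> RFPulse:
    """Samplewise product ``b = p * f`` on the base pulse's grid (time
    centred on the pulse midpoint); duration unchanged."""
    n = base.n_samples
    t = np.arange(n) - (n - 1) / 2
    f = modulation_function(spec, t)
    out = RFPulse(base.samples * f, base.dwell, dict(base.carrier_offsets_meta))
    out.carrier_offsets_meta.update(mb=spec.mb, omega=spec.omega.tolist(),
                                    phi=spec.phi.tolist(), am=spec.am)
    if base.is_am and spec.am:
        out.samples = out.samples.real.astype(complex)
    return out


def modulated_pulse(base: RFPulse, mb: int, slice_sep: float, tbp: float,
                    phi: np.ndarray, am: bool = False,
                    oversample: float = 2.5) -> RFPulse:
    """Build the multiband pulse, resampling the base first whenever the
    modulation would be undersampled on the base grid.

    The fastest modulation component sits at ``delta_omega * (mb-1)/2``; the
    base is Fourier-resampled (power-of-two length) so that at least
    ``oversample`` samples cover each period of that component, keeping the
    sampled peak faithful to the continuous waveform.
    """
    need = int(np.ceil(oversample * tbp * slice_sep * (mb - 1)))
    n = base.n_samples
    if need > n:
        n = 1 << int(np.ceil(np.log2(need)))
    base_r = resample_pulse(base, n)
    spec = MultibandSpec.build(mb, slice_sep, tbp, n, phi=phi, am=am)
    return apply_modulation(base_r, spec)
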