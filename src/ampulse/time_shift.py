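"""Time-shifted multiband pulses.

Instead of multiplying one envelope by a modulation function, each slice's
single-band pulse is delayed by its own time shift before summation:
``b(t) = sum_n p(t - tau_n) * exp(i*(omega_n t + phi_n))``.  Spreading the
copies over an extended window (100%..200% of the single-band duration)
reduces constructive interference and therefore the peak.  The AM variant
shares each shift between the two slices equidistant from the band centre
(and keeps the phase offsets antisymmetric), which by the Fourier shift
theorem gives both slices the same linear spectral phase and preserves
conjugate symmetry — hence a real waveform for a real base pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import minimize_peak_phases
from .phase_opt import MultibandSpec, slice_offsets, resample_pulse
from .slr import RFPulse

__all__ = ["assemble_timeshifted", "optimize_timeshift", "TimeShiftResult"]


def _shift_matrix(base: np.ndarray, spec: MultibandSpec):
    """Columns ``c_n(t) = p(t - tau_n) exp(i*omega_n t)`` on the extended
    grid (time centred on the extended window)."""
    tau = np.round(spec.tau).astype(int)
    if np.abs(tau - spec.tau).max() > 1e-9:
        raise ValueError("time shifts must lie on the sample grid")
    n0 = len(base)
    lo, hi = min(tau.min(), 0), max(tau.max(), 0)
    next_ = n0 + (hi - lo)
    t = np.arange(next_) - (next_ - 1) / 2
    C = np.zeros((next_, spec.mb), dtype=complex)
    for k in range(spec.mb):
        start = tau[k] - lo
        if start < 0 or start + n0 > next_:
            raise ValueError("shift places a pulse copy outside the window")
        C[start:start + n0, k] = base
        C[:, k] *= np.exp(1j * spec.omega[k] * t)
    return C, t


def assemble_timeshifted(base: RFPulse, spec: MultibandSpec) -> RFPulse:
    """Sum the shifted, modulated single-band copies on the extended grid.

    With all shifts zero this reduces exactly to the samplewise product of
    the base pulse and the modulation function.  A real base with an
    AM-valid spec (antisymmetric phases, pair-shared shifts) yields a real
    output.
    """
    C, _ = _shift_matrix(base.samples, spec)
    b = C @ np.exp(1j * spec.phi)
    out = RFPulse(b, base.dwell, dict(base.carrier_offsets_meta))
    out.carrier_offsets_meta.update(mb=spec.mb, omega=spec.omega.tolist(),
                                    phi=spec.phi.tolist(), tau=spec.tau.tolist(),
                                    am=spec.am)
    if base.is_am and spec.am:
        out.samples = out.samples.real.astype(complex)
    return out


def _ramp_shifts(mb: int, extension: int, am: bool) -> np.ndarray:
    """Per-slice integer shifts: a linear ramp over ``extension`` samples.

    Unconstrained: slices 1..mb ramp from 0 to extension.  AM: the
    ``mb // 2`` equidistant pairs ramp over the extension, both members of a
    pair sharing the shift; the middle slice of an odd group sits at the
    central ramp value.
    """
    if mb == 1:
        return np.zeros(1)
    if not am:
        return np.round(np.linspace(0, extension, mb))
    npair = mb // 2
    vals = np.round(np.linspace(0, extension, npair)) if npair > 1 \
        else np.array([round(extension / 2)])
    tau = np.empty(mb)
    tau[:npair] = vals
    tau[-npair:] = vals[::-1]
    if mb % 2:
        tau[mb // 2] = round(extension / 2)
    return tau


@dataclass
class TimeShiftResult:
    spec: MultibandSpec
    pulse: RFPulse
    peak: float
    duration_ratio: float
    product: float  # peak * duration, the selection metric
    candidates: list  # (ratio, peak, product) per candidate


def optimize_timeshift(base: RFPulse, mb: int, slice_sep: float, tbp: float,
                       am: bool = False, n_candidates: int = 50,
                       n_starts: int = 50, seed: int = 1234,
                       oversample: float = 2.5) -> TimeShiftResult:
    """Search candidate extensions and phase offsets for the best
    time-shifted multiband pulse.

    Candidate total durations span 100%..200% of the single-band duration.
    For each candidate the shifts follow the linear ramp (paired in AM mode)
    and the phase offsets are optimized by the multistart smoothed-minimax
    search; the returned candidate minimizes peak amplitude x duration.
    """
    need = int(np.ceil(oversample * tbp * slice_sep * max(mb - 1, 1)))
    n = base.n_samples
    if need > n:
        n = 1 << int(np.ceil(np.log2(need)))
    base_r = resample_pulse(base, n)
    p = base_r.samples
    n0 = len(p)

    rng = np.random.default_rng(seed)
    ratios = np.linspace(1.0, 2.0, n_candidates)
    best = None
    cands = []
    for i, r in enumerate(ratios):
        ext = int(round((r - 1) * n0))
        tau = _ramp_shifts(mb, ext, am)
        spec = MultibandSpec.build(mb, slice_sep, tbp, n0, tau=tau, am=False)
        C, _ = _shift_matrix(p, spec)
        phi, peak = minimize_peak_phases(
            C, mb, am, n_starts=n_starts,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        dur_ratio = len(C) / n0 * 1.0
        prod = peak * dur_ratio
        cands.append((float(r), float(peak), float(prod)))
        if best is None or prod < best[0]:
            best = (prod, phi, tau, peak, dur_ratio)
    prod, phi, tau, peak, dur_ratio = best
    spec = MultibandSpec.build(mb, slice_sep, tbp, n0, phi=phi, tau=tau, am=am)
    pulse = assemble_timeshifted(base_r, spec)
    return TimeShiftResult(spec=spec, pulse=pulse, peak=float(peak),
                           duration_ratio=float(dur_ratio),
                           product=float(prod), candidates=cands)
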