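"""Root-flipped multiband refocusing pulses.

The multiband beta polynomial is designed directly as a minimum-phase FIR
filter with one passband per slice, then expressed in factored form
``beta(z) = beta0 * prod(1 - r_n z^-1)``.  Reflecting a root through the
unit circle (``r -> 1/conj(r)``) leaves |beta| unchanged on the circle but
redistributes the pulse energy in time, so a search over flip patterns can
minimize the peak RF amplitude at fixed duration.

Two mutually exclusive symmetry classes are searched:

* unconstrained ("time-symmetric"): one free bit per positive-frequency
  passband root; the conjugate root is anti-flipped, yielding a complex,
  time-symmetric waveform;
* AM: conjugate root pairs are co-flipped so the flipped multiset stays
  closed under conjugation, beta stays real, and the waveform is purely
  amplitude modulated.  Outer stopband roots are additionally pre-flipped
  in alternating angular sub-bands (six per half circle) to stop stopband
  energy piling up at the pulse edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .slr import (DesignInfeasibleError, PolynomialPair, RFPulse, _BETA_CLAMP_EPS,
                  beta_ripples, dinf, forward_slr, inverse_slr, mag_to_min_phase,
                  min_phase_alpha, PulseSpec)

__all__ = [
    "RootSet", "choose_n_samples", "build_multiband_beta", "factor_beta",
    "flip", "roots_to_beta", "am_stopband_treatment", "symmetrize_stopband",
    "search_flip_pattern",
    "design_root_flipped", "RootFlipResult",
]


# ---------------------------------------------------------------------------
# multiband minimum-phase beta
# ---------------------------------------------------------------------------

def _band_layout(mb: int, tbp: float, slice_sep: float, d1: float, d2: float):
    """Passband/stopband edges in cycles-per-pulse for a length-n design
    (centres at ``(j - (mb+1)/2) * tbp * slice_sep``)."""
    w = dinf(d1, d2) / tbp
    centres = (np.arange(1, mb + 1) - (mb + 1) / 2) * tbp * slice_sep
    f1 = (1 - w) * tbp / 2
    f2 = (1 + w) * tbp / 2
    return centres, f1, f2, w


def choose_n_samples(mb: int, tbp: float, slice_sep: float,
                     d1: float = 0.0025, d2: float = 0.1,
                     margin: float = 0.42) -> int:
    """Smallest multiple of 16 (>=128) placing the outermost stopband edge
    below ``margin`` cycles/sample."""
    centres, _, f2, _ = _band_layout(mb, tbp, slice_sep, d1, d2)
    outer = centres[-1] + f2
    n = int(np.ceil(outer / margin / 16.0)) * 16
    return max(n, 128)


def _amplitude_on_grid(h: np.ndarray, m: int) -> np.ndarray:
    """Real amplitude response of a symmetric (linear-phase) filter on an
    m-point uniform circle grid."""
    k = np.arange(m)
    return (np.fft.fft(h, m) * np.exp(1j * np.pi * k * (len(h) - 1) / m)).real


def build_multiband_beta(mb: int, tbp: float, slice_sep: float,
                         n: int | None = None,
                         ripple_pass: float = 0.01, ripple_stop: float = 0.01,
                         grid_mult: int = 16) -> tuple[PolynomialPair, dict]:
    """Minimum-phase multiband beta with one passband per slice.

    A linear-phase prototype of length ``2n-1`` approximating |beta|^2
    (passband ripple 2*d1, stopband ripple d2^2/2, transition amplitude
    capped) is designed by the dense-grid Chebyshev LP, floored to be
    nonnegative, square-rooted, and converted to its minimum-phase spectral
    factor, whose roots all start inside the unit circle.

    Returns the beta-only pair and a band-layout dict used for root
    classification.
    """
    from .slr import _chebyshev_lp

    spec = PulseSpec(tbp=tbp, ripple_pass=ripple_pass, ripple_stop=ripple_stop,
                     pulse_class="refocusing")
    d1, d2 = beta_ripples(spec)
    centres, f1, f2, w = _band_layout(mb, tbp, slice_sep, d1, d2)
    if n is None:
        n = choose_n_samples(mb, tbp, slice_sep, d1, d2)
    if centres[-1] + f2 >= 0.5 * n:
        raise DesignInfeasibleError(
            f"band layout exceeds Nyquist for n={n} "
            f"(outer edge {centres[-1] + f2:.1f} cycles)")
    d1_sq, d2_sq = 2 * d1, d2 ** 2 / 2
    bands = []
    for c in centres:
        if c + f1 <= 0:          # negative-frequency band: mirrored implicitly
            continue
        lo, hi = max(c - f1, 0.0), c + f1
        bands.append((lo, hi, 1.0, d1_sq))
    # stopband segments between band edges on [0, nyquist]
    pos_edges = sorted((max(c - f2, 0.0), c + f2) for c in centres if c + f2 > 0)
    prev = 0.0
    stop = []
    for lo, hi in pos_edges:
        if lo > prev:
            stop.append((prev, lo, 0.0, d2_sq))
        prev = max(prev, hi)
    if prev < 0.5 * n:
        stop.append((prev, 0.5 * n, 0.0, d2_sq))
    h, delta = _chebyshev_lp(2 * n - 1, bands + stop, n / 2,
                             cap=1.0 + 2 * d1_sq, n_pass_grid=60,
                             stop_grid_density=6.0)
    if delta > 1.0 + 1e-6:
        raise DesignInfeasibleError(
            f"multiband ripple spec not met (achieved {delta:.3f}x)")
    m = grid_mult * n
    H = _amplitude_on_grid(h, m)
    lift = max(-H.min(), 0.0) * (1 + 1e-3) + 1e-12
    mag = np.sqrt(H + lift)
    mmax = mag.max()
    if mmax >= 1.0:
        mag = mag / (mmax + _BETA_CLAMP_EPS)
    beta = np.fft.ifft(mag_to_min_phase(mag))[:n].real
    # truncation to n taps can push |beta~| marginally over the circle
    mmax = np.abs(np.fft.fft(beta, m)).max()
    if mmax >= 1.0:
        beta = beta / (mmax + _BETA_CLAMP_EPS)
    layout = dict(mb=mb, tbp=tbp, slice_sep=slice_sep, n=n,
                  centres=centres, f1=f1, f2=f2, w=w)
    return PolynomialPair(beta=beta.astype(complex)), layout


# ---------------------------------------------------------------------------
# factored form
# ---------------------------------------------------------------------------

@dataclass
class RootSet:
    """Factored-form beta: roots ``r_n`` with per-root band labels
    (slice index 0..mb-1, or -1 for stopband), the cumulative flip mask,
    and the scale needed to reproduce |beta| on the circle."""

    roots: np.ndarray
    band_labels: np.ndarray
    flip_mask: np.ndarray
    leading_coeff: complex
    target_max: float          # max |beta~| to preserve under rescaling
    n: int
    meta: dict = field(default_factory=dict)

    def conjugate_closed(self, tol: float = 1e-8) -> bool:
        """True when the root multiset is closed under conjugation."""
        r = self.roots
        rem = list(range(len(r)))
        for i in range(len(r)):
            if i not in rem:
                continue
            target = np.conj(r[i])
            d = np.abs(r[rem] - target) / max(np.abs(target), 1e-12)
            j = rem[int(np.argmin(d))]
            if d.min() > tol:
                return False
            rem.remove(j)
            if j != i and i in rem:
                rem.remove(i)
        return True


def factor_beta(pair: PolynomialPair, layout: dict | None = None) -> RootSet:
    """Factor beta into Eq-10 form.  Roots are classified as passband
    (within +-tbp/2 cycles of a slice centre, i.e. out to mid-transition)
    or stopband."""
    beta = pair.beta
    n = len(beta)
    if np.abs(beta[0]) < 1e-12 * np.abs(beta).max():
        raise DesignInfeasibleError("beta[0] ~ 0: factored form degenerate")
    x_roots = np.roots(beta[::-1])           # roots in x = z^{-1}
    if len(x_roots) != n - 1 or not np.all(np.isfinite(x_roots)):
        raise DesignInfeasibleError("polynomial factorization failed")
    r = 1.0 / x_roots
    labels = np.full(len(r), -1, dtype=int)
    if layout is not None:
        ang = np.angle(r) * layout["n"] / (2 * np.pi)   # cycles per pulse
        half = layout["tbp"] / 2
        for j, c in enumerate(layout["centres"]):
            inband = np.abs(ang - c) <= half
            labels[inband] = j
    target = float(np.abs(np.fft.fft(beta, 8 * n)).max())
    return RootSet(roots=r, band_labels=labels,
                   flip_mask=np.zeros(len(r), dtype=bool),
                   leading_coeff=complex(beta[0]), target_max=target, n=n,
                   meta=dict(layout or {}))


def _leja_order(roots: np.ndarray) -> np.ndarray:
    """Greedy Leja ordering for numerically stable polynomial expansion."""
    r = np.asarray(roots)
    m = len(r)
    order = np.empty(m, dtype=int)
    order[0] = int(np.argmax(np.abs(r)))
    logd = np.log(np.abs(r - r[order[0]]) + 1e-300)
    used = np.zeros(m, dtype=bool)
    used[order[0]] = True
    for k in range(1, m):
        logd[used] = -np.inf
        nxt = int(np.argmax(logd))
        order[k] = nxt
        used[nxt] = True
        if k < m - 1:
            logd = logd + np.log(np.abs(r - r[nxt]) + 1e-300)
    return order


def roots_to_beta(roots: np.ndarray, target_max: float, n: int,
                  force_real: bool | None = None) -> np.ndarray:
    """Rebuild beta coefficients from roots, rescaled so max|beta~| equals
    ``target_max``.  Conjugate-closed root sets produce real coefficients."""
    order = _leja_order(roots)
    c = np.array([1.0 + 0j])
    for rt in roots[order]:
        c = np.convolve(c, np.array([1.0, -rt]))
        m = np.abs(c).max()
        if m > 1e100:       # re-scale mid-product; absolute scale fixed later
            c = c / m
    beta = c
    cur = np.abs(np.fft.fft(beta, 8 * n)).max()
    beta = beta * (target_max / cur)
    im_ratio = np.abs(beta.imag).max() / max(np.abs(beta).max(), 1e-300)
    if force_real is None:
        force_real = im_ratio < 1e-6
    if force_real:
        beta = beta.real.astype(complex)
    return beta


def flip(rootset: RootSet, mask: np.ndarray) -> RootSet:
    """Reflect the masked roots through the unit circle (r -> 1/conj(r));
    |beta~| is preserved after rescaling."""
    mask = np.asarray(mask, dtype=bool)
    r = rootset.roots.copy()
    if np.any(np.abs(r[mask]) == 0):
        raise ValueError("cannot flip a root at the origin")
    r[mask] = 1.0 / np.conj(r[mask])
    return RootSet(roots=r, band_labels=rootset.band_labels.copy(),
                   flip_mask=rootset.flip_mask ^ mask,
                   leading_coeff=rootset.leading_coeff,
                   target_max=rootset.target_max, n=rootset.n,
                   meta=dict(rootset.meta))


def rootset_to_pair(rootset: RootSet,
                    alpha: np.ndarray | None = None) -> PolynomialPair:
    beta = roots_to_beta(rootset.roots, rootset.target_max, rootset.n)
    return PolynomialPair(beta=beta, alpha=alpha)


# ---------------------------------------------------------------------------
# AM stopband treatment
# ---------------------------------------------------------------------------

def symmetrize_stopband(rootset: RootSet) -> RootSet:
    """Flip the positive-angle stopband roots through the circle.

    The minimum-phase starting filter holds every root inside the unit
    circle; moving the upper-half-plane stopband roots outside makes the
    stopband multiset (off the real axis) closed under ``r -> 1/conj(r)``,
    which together with the anti-flip passband rule yields time-symmetric
    unconstrained pulses — and hence antisymmetric per-slice echo times.
    """
    ang = np.angle(rootset.roots)
    mask = (rootset.band_labels == -1) & (ang > 1e-9)
    return flip(rootset, mask) if mask.any() else rootset


def am_stopband_treatment(rootset: RootSet, n_subbands: int = 6) -> RootSet:
    """Flip alternating angular sub-bands of the stopband roots.

    Each half circle of the stopband is split by angle into ``n_subbands``
    equal sub-bands and every other sub-band is flipped (a square-wave
    pattern), mirrored between the half circles so conjugate closure is
    preserved.  This spreads stopband energy across the pulse instead of
    letting it accumulate at the edges; with all sub-bands on one radial
    side the minimum-phase edge spike survives every passband pattern.
    """
    stop = rootset.band_labels == -1
    if not np.any(stop):
        return rootset
    ang = np.abs(np.angle(rootset.roots))
    mask = np.zeros(len(rootset.roots), dtype=bool)
    width = np.pi / n_subbands
    idx = np.clip((ang / width).astype(int), 0, n_subbands - 1)
    mask[stop] = (idx[stop] % 2 == 0)
    return flip(rootset, mask)


# ---------------------------------------------------------------------------
# flip-pattern search
# ---------------------------------------------------------------------------

def _pattern_groups(rootset: RootSet, am: bool, pair_tol: float = 1e-6):
    """Group passband roots into search variables.

    Returns a list of index groups; toggling a variable flips every index in
    its group (AM: conjugate pairs co-flipped, real-axis roots individually)
    or, for the unconstrained class, flips the positive-angle root and
    anti-flips its conjugate (encoded by (pos_idx, neg_idx) with the
    negative partner pre-flipped).
    """
    pb = np.nonzero(rootset.band_labels >= 0)[0]
    r = rootset.roots
    ang = np.angle(r)
    used = set()
    pairs, reals = [], []
    for i in pb:
        if i in used:
            continue
        if abs(ang[i]) < 1e-9:
            reals.append(i)
            used.add(i)
            continue
        # find conjugate partner among passband roots
        cands = [j for j in pb if j not in used and j != i]
        if cands:
            d = [abs(r[j] - np.conj(r[i])) / max(abs(r[i]), 1e-12) for j in cands]
            k = int(np.argmin(d))
            if d[k] < pair_tol:
                j = cands[k]
                used.update((i, j))
                if ang[i] > 0:
                    pairs.append((i, j))
                else:
                    pairs.append((j, i))
                continue
        warnings.warn("unpaired passband root treated as real-axis root")
        reals.append(i)
        used.add(i)
    return pairs, reals


def _mask_from_bits(bits, pairs, reals, am, nroots):
    mask = np.zeros(nroots, dtype=bool)
    k = 0
    for (ip, ineg) in pairs:
        if am:
            if bits[k]:
                mask[ip] = mask[ineg] = True
        else:
            # anti-symmetric: exactly one of the pair is flipped
            if bits[k]:
                mask[ip] = True
            else:
                mask[ineg] = True
        k += 1
    if am:
        for i in reals:
            if bits[k]:
                mask[i] = True
            k += 1
    return mask


@dataclass
class RootFlipResult:
    rootset: RootSet
    pulse: RFPulse
    pair: PolynomialPair        # exact pair recomputed from the waveform
    peak: float
    layout: dict
    generations_run: int = 0


def search_flip_pattern(rootset: RootSet, alpha: np.ndarray, am: bool,
                        ga_population: int = 50, generations: int = 60,
                        stagnation: int = 40, seed: int = 1234,
                        dwell: float = 6.4e-6) -> RootFlipResult:
    """Genetic search over flip patterns minimizing peak RF amplitude.

    ``alpha`` is the minimum-phase alpha of |beta~| (invariant under flips,
    computed once).  The unconstrained class never co-flips a conjugate
    pair; the AM class always does.
    """
    rng = np.random.default_rng(seed)
    pairs, reals = _pattern_groups(rootset, am)
    L = len(pairs) + (len(reals) if am else 0)
    n = rootset.n

    def evaluate(bits):
        mask = _mask_from_bits(bits, pairs, reals, am, len(rootset.roots))
        rs = flip(rootset, mask)
        beta = roots_to_beta(rs.roots, rs.target_max, n, force_real=am or None)
        pulse = inverse_slr(PolynomialPair(beta=beta, alpha=alpha), dwell)
        return float(np.abs(pulse.samples).max()), rs, pulse

    if L == 0:
        pk, rs, pulse = evaluate(np.zeros(0, dtype=bool))
        return RootFlipResult(rs, pulse, forward_slr(pulse), pk,
                              dict(rootset.meta))

    pop = rng.random((ga_population, L)) < 0.5
    fits = np.array([evaluate(ind)[0] for ind in pop])
    best_bits = pop[np.argmin(fits)].copy()
    best_fit = fits.min()
    stale = 0
    gen = 0
    for gen in range(1, generations + 1):
        new = [best_bits.copy(), pop[np.argmin(fits)].copy()]   # elitism
        while len(new) < ga_population:
            # tournament selection
            i1, i2 = rng.integers(0, ga_population, 2)
            p1 = pop[i1] if fits[i1] < fits[i2] else pop[i2]
            i1, i2 = rng.integers(0, ga_population, 2)
            p2 = pop[i1] if fits[i1] < fits[i2] else pop[i2]
            cross = rng.random(L) < 0.5
            child = np.where(cross, p1, p2)
            mut = rng.random(L) < (1.0 / L)
            child = child ^ mut
            new.append(child)
        pop = np.array(new[:ga_population])
        fits = np.array([evaluate(ind)[0] for ind in pop])
        if fits.min() < best_fit - 1e-12:
            best_fit = fits.min()
            best_bits = pop[np.argmin(fits)].copy()
            stale = 0
        else:
            stale += 1
            if stale >= stagnation:
                break
    pk, rs, pulse = evaluate(best_bits)
    if am:
        pulse.samples = pulse.samples.real.astype(complex)
    return RootFlipResult(rs, pulse, forward_slr(pulse), pk,
                          dict(rootset.meta), generations_run=gen)


def design_root_flipped(mb: int, tbp: float, slice_sep: float, am: bool,
                        n: int | None = None, seed: int = 1234,
                        ga_population: int = 50, generations: int = 60,
                        stagnation: int = 40, dwell: float = 6.4e-6,
                        ripple_pass: float = 0.01, ripple_stop: float = 0.01
                        ) -> RootFlipResult:
    """End-to-end root-flipped multiband refocusing design."""
    pair, layout = build_multiband_beta(mb, tbp, slice_sep, n=n,
                                        ripple_pass=ripple_pass,
                                        ripple_stop=ripple_stop)
    alpha = min_phase_alpha(pair).alpha
    rootset = factor_beta(pair, layout)
    rootset = am_stopband_treatment(rootset) if am else symmetrize_stopband(rootset)
    res = search_flip_pattern(rootset, alpha, am, ga_population=ga_population,
                              generations=generations, stagnation=stagnation,
                              seed=seed, dwell=dwell)
    res.layout = layout
    return res
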