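# Methods

This note records the models, conventions and numerical choices behind
`ampulse`, and what the test suite does and does not establish.

## Problem setting

Simultaneous-multislice (multiband, MB) imaging excites several slices with
one RF pulse. The naive construction — multiply a single-band pulse `p(t)`
by a modulation function `f(t) = Σ_n exp(i ω_n t)` — has peak amplitude
`MB·max|p|`, which quickly exceeds hardware limits. Three established
remedies are implemented: optimizing per-slice phase offsets of `f`
(phase-optimizing), summing temporally staggered copies of `p`
(time-shifting), and redistributing the energy of a directly designed
multiband SLR beta polynomial by reflecting selected roots through the unit
circle (root-flipping).

Each method additionally supports an **amplitude-modulation (AM)
constraint**: the waveform is forced to be real by imposing conjugate
symmetry on its frequency-domain representation (antisymmetric phase
offsets, pair-shared time shifts, or conjugation-closed root-flip
patterns). AM waveforms survive analog AM/FM pulse-generation chains that
corrupt rapidly frequency-modulated pulses; the price is a longer
*effective duration*

```
t_eff = T · γ · B1max / θ
```

the duration relative to a hard pulse of the same peak amplitude and flip
angle θ. `t_eff` is invariant under trading amplitude for duration, so it
is the package's universal efficiency measure.

## SLR core

Spin-domain convention: a hard rotation by nutation φ at RF phase θ has
Cayley–Klein parameters `C = cos(φ/2)`, `S = e^{iθ} sin(φ/2)` (no factor of
i on S), and free precession applies a unit delay to beta *before* each
rotation. Consequences, covered by unit tests: a single hard pulse has
`β = [sin(φ/2)]` real; real `(α, β)` ⇔ real RF; the spinor propagated at
frequency ω equals the polynomial pair evaluated at `z⁻¹ = e^{-iω}`, which
is how the Bloch simulator and the forward recursion cross-validate.

**Profile-to-beta ripples.** Refocusing pulses are specified by crushed
spin-echo profile ripples (1 % in and out of slice by default); the beta
filter then gets passband ripple `δ₁/4` and stopband ripple `√δ₂` (the
classical crushed-spin-echo mapping, since the echo profile is `β²`).

**Beta filter design.** The linear-phase beta is a weighted-Chebyshev
approximation problem with the transition half-width given by the empirical
`dinf(δ₁,δ₂)/TBP` rule. Two solvers are used:

* narrow fractional passbands (passband under ~2 cycles across the pulse,
  i.e. TBP ≲ 5): a dense-grid linear-programming Chebyshev design at a
  compact length n = 192;
* wider passbands: Parks–McClellan (`scipy.signal.remez`) at n = 256, with
  the LP as fallback.

The split exists because over-long equiripple refocusing designs are
degenerate: once the filter is longer than the ripple spec requires, the
optimum over-delivers ripple and the recovered pulse's effective duration
drifts with the length and with solver details. The compact-length LP
regime keeps low-TBP designs stable. The free constants of this rule (the
regime threshold, lengths, and the 1e-8 margin by which `max|β̃|` is kept
below 1 when a design overshoots the unit circle — the RF peak of a 180°
pulse is extremely sensitive to how closely the passband approaches
`|β̃| = 1`) were calibrated once against the published single-band effective
durations (t_eff = 3.637, 8.270, 13.231, 18.156, 23.051 for TBP
2, 4, 6, 8, 10), which the regression test holds to 1 %.

**Minimum-phase alpha.** `|α̃| = √(1-|β̃|²)` on a 16 n grid; the phase is
the Hilbert transform of `log|α̃|`, computed by the folded-cepstrum
(homomorphic) construction. The truncated alpha satisfies the energy
identity only approximately (residual up to ~1e-2 near `|β̃|→1`), so every
*returned* design pair is re-derived exactly by running the waveform back
through the forward recursion; the profile perturbation from this
consistency step is below 2e-4, far inside the ripple budget. All stored
pairs therefore satisfy `|α̃|²+|β̃|² = 1` to machine precision.

**Matched excitation.** For a refocusing beta (single- or multiband) the
excitation magnitude is obtained by halving the local flip angle,
`|β̃_ex| = sin(asin|β̃_ref|/2)`, which reproduces the band structure
exactly; the phase is set to `∠α̃_ex + 2∠β̃_ref` so the crushed echo
`conj(Mxy_ex)·β̃_ref²` has flat through-slice phase. The matched response
needs about twice the refocusing pulse's taps, so the excitation is
designed at 2 n samples and becomes minimum-duration when rescaled to the
shared B1 cap.

## Phase optimization

`max_t |Σ exp(i(ω_n t + φ_n))|` is minimized over one fundamental period on
a 64·MB grid through a staged sequence of p-norm surrogates
(p = 8…2048, renormalized per stage) with analytic gradients and L-BFGS,
from 100 uniform random restarts (best-of-restarts). This reproduces the
best known antisymmetric offset tables to within 0.1 % in peak value.

The problem has exact gauge freedoms: a common time shift of the modulation
(a phase ramp `ω_n·s`, which preserves antisymmetry because the offsets are
centred), a global phase (non-AM only), a sign flip, and the slice-order
reversal. Optimized offsets are therefore only defined modulo gauge; two
consequences shape the API:

* `canonicalize` fixes the gauge deterministically by placing the time
  origin at the modulation-magnitude peak (so the peak aligns with the
  centre of a centred envelope), making sweep results independent of the
  optimizer's arbitrary landing point on the orbit;
* `gauge_match` reduces a solution onto the orbit point nearest a reference
  set, which is how recovered offsets are compared against the benchmark
  table (for MB = 3 the antisymmetric problem is fully degenerate — every
  offset choice peaks at exactly MB — so only orbit membership is
  meaningful).

When a multiband pulse is assembled, the base pulse is Fourier-resampled to
a power-of-two grid providing ≥ 2.5 samples per period of the fastest
modulation component; without this the sampled peak undercounts the
continuous waveform at large `TBP·separation·MB`.

## Time-shifting

`b(t) = Σ p(t-τ_n)·exp(i(ω_n t + φ_n))` on an extended window. Candidate
total durations span 100–200 % of the single-band duration (50 candidates
by default); shifts follow a linear ramp across slices, rounded to the
sample grid and centred in the evaluation window. In AM mode the
`⌊MB/2⌋` equidistant pairs share shifts spaced over the extension, the
middle slice of an odd group taking the central ramp value. Phase offsets
per candidate are optimized by the same multistart smoothed-minimax search
(50 restarts by default, standing in for a population-50 global search with
local polish); the candidate minimizing peak × duration wins.

## Root-flipping

The multiband beta is designed directly: a linear-phase prototype of length
2n-1 approximating `|β̃|²` (passband 2δ₁ᵦ, stopband δ₂ᵦ²/2, transition
amplitude capped) is designed by the Chebyshev LP, floored to be
nonnegative, square-rooted and spectrally factored to minimum phase, so all
roots start inside the unit circle. The design length is the smallest
multiple of 16 placing the outermost stopband edge below 0.42 cycles/sample
(≥ 128). Roots within ±TBP/2 cycles of a slice centre (i.e. out to
mid-transition) are classified as that slice's passband roots; everything
else is stopband.

Flip patterns are searched by a small generational GA (population 50,
uniform crossover, 1/L mutation, tournament selection, elitism, early stop
on stagnation), one bit per conjugate root pair. The two symmetry classes
are mutually exclusive:

* *unconstrained*: the conjugate partner is **anti**-flipped, and the
  positive-angle stopband roots are pre-flipped outside, making the root
  multiset closed under `r → 1/r̄`; the pulses are time-symmetric and their
  per-slice echo times come out antisymmetric about the mean;
* *AM*: conjugate pairs are co-flipped (closure under conjugation ⇒ real
  beta ⇒ real pulse). The stopband is pre-treated with the alternating
  sub-band pattern: each half circle is split into six equal angular
  sub-bands and every other sub-band flipped. One-sided stopband
  arrangements concentrate stopband energy in an edge spike that no
  passband pattern can remove; the alternating pattern spreads it. The
  treatment is applied to the whole stopband arc (not only beyond the
  outermost passband) — this measurably improves AM designs at low TBP and
  is fixed before the GA rather than searched.

Since `|β̃|` is invariant under every flip, the minimum-phase alpha is
computed once per design and reused across all GA evaluations. Polynomials
are rebuilt from roots in Leja order for numerical stability and rescaled
to preserve `max|β̃|`.

## Bloch simulation and echo timing

Hard-pulse spin-domain propagation, no relaxation (norm conserved to
machine precision). The spin-echo simulator models: time-resolved
excitation, free precession over a gap (gradient off, so only the
off-resonance term acts), the refocusing pulse through its crushed pathway
`m → conj(m)·b²` (an ideal-crusher model: only the doubly-refocused
coherence survives), and free readout. Echo envelopes are formed by
averaging complex transverse magnetization over 21 isochromats spanning
±50 Hz; flip-down and echo times are the quadratic-refined argmax of
|Mxy| per slice during excitation and readout. Slice positions are given
as frequencies on the shared design grid (radians/sample), which models
matched slice-select gradient rescaling when the two pulses run at
different dwell times.

## Sweeps and desk-scale defaults

The full study grid is MB 3–16 × TBP {2,4,6,8,10} × separation 3–22 slice
thicknesses (1400 cells per method and mode). Phase-optimization sweeps run
the full grid routinely (the per-MB optimization is shared across cells).
Time-shifting and root-flipping sweeps are GA-driven per cell; the package
runs them on a stratified subsample (every MB contributes its smallest
feasible cells from a fixed canonical list, ≥ 30 cases) with reduced search
budgets (8 candidate durations × 6 restarts; GA population 24 × 20
generations), and labels such runs with their scale. The acceptance tests
hold the subsampled means only to the ballpark (±10 percentage points)
for exactly this reason; full-fidelity means would require the complete
1400-case GA sweeps.

## What the tests show

All data are synthetic by construction (the package designs its own
pulses). Verification closes three independent loops: filter-domain specs
vs Bloch-simulated profiles; polynomial algebra vs spin-domain propagation;
and design symmetry constraints vs measured waveform realness and echo
timing. What is *not* shown: behaviour under B0/B1 inhomogeneity beyond
constant offsets, relaxation during pulses, gradient imperfections, or any
hardware pulse-generation effect — the AM constraint's practical benefit is
motivated by such effects but only the design-side properties are testable
here.

## Known limitations

* The two-regime beta designer is calibrated to the published single-band
  effective durations; other ripple specifications fall back to the same
  rule but without a regression anchor.
* Root-flip designs above roughly n = 512 samples (large
  MB × TBP × separation) become slow (dense polynomial factorization) and
  are outside the default sweep envelope.
* The matched excitation truncates ~0.1 % of its impulse-response energy at
  2 n taps; its profile is correspondingly approximate at the 1e-2 level,
  which is visible as a small plateau shift in echo amplitude but not in
  echo timing.
* `optimize_timeshift` assumes the base pulse envelope peaks centrally
  (true for linear-phase designs) when centring candidate ramps.
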