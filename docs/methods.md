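# Methods

## Signal model and conventions

A 2DJ data set is modelled as *M* two-dimensional exponentially damped
complex sinusoids plus complex white Gaussian noise (per-quadrature standard
deviation σ). Sample indices are zero-based; frequencies are stored in Hz as
offsets from the carrier, with the positive-frequency convention
e^{+2πi f t}; radians appear only inside exponent evaluation. Amplitudes are
kept non-negative by folding sign flips into the phase, phases are wrapped
into (−π, π], and dampings are non-negative (growing signals are rejected or
clamped). Output oscillator lists are always sorted by (f₂, f₁), which makes
every stage deterministic.

The "−45° signal" — the inverse FT of the pure shift spectrum — replaces
each oscillator's direct frequency by f₂ − f₁ and keeps its direct-dimension
damping. Estimated phases are retained when rendering spectra (after phase
correction they are near zero for genuine signals, and retaining them keeps
the spectrum an honest render of the fit); a zero-phase display option
exists and is recorded in each spectrum's processing record.

## Preprocessing

**Phase correction.** The zero/first-order frequency-domain correction
determined on the first slice is applied identically to every slice.
Parameters are user-supplied; an automatic zero-order search (closed form:
the phase of the summed first-slice spectrum) is provided as a documented
heuristic for synthetic or well-behaved data.

**Sub-FID filtering via the virtual echo.** Per-region band-passing uses a
super-Gaussian window `g(f) = exp(−2^{p+1}((f−c)/b)^p)` with default order
p = 40 — near-rectangular with smooth edges, so it does not ring the way a
hard cut would. The window is applied to the *virtual echo* of each slice
(the conjugate-symmetric length-2N₂ extension whose spectrum is purely
absorptive for phased data), and the causal half is returned. This matters:
filtering the raw causal FID leaves the *dispersion* tail of every
out-of-band line — the broadband transient of the t = 0 onset — inside the
band at the percent level, whereas absorption tails fall quadratically. The
surviving amplitude of a line five bandwidths away is below 10⁻⁴. The first
virtual-echo point enters once (not doubled); doubling it would put a flat
y₀/2 baseline across the whole spectrum. The construction assumes phased
data, which is why phase correction precedes filtering in the pipeline.

**Noise fill.** Suppressed out-of-band spectrum is optionally topped up with
synthetic Gaussian noise at the baseline level (a median-absolute-deviation
estimate over far-out-of-band points, robust to peaks elsewhere), weighted
by 1 − g so in-band data are untouched. Without it, the near-zero noise
floor outside the band biases the model-order criterion, which assumes white
noise.

**Band reduction.** Because estimation cost grows quickly with the number of
points, a filtered sub-FID can be truncated or — preferably — frequency
shifted to the region centre and decimated. Decimation preserves the total
acquisition time, hence resolution; truncation does not. After decimation by
a factor d, the part of the reduced band outside the filter support carries
no noise; it is refilled at the in-band spectral density ("matched-density
fill"), so the reduced grid has white noise of per-sample std σ/√d — the
sensitivity gain genuinely bought by discarding out-of-band noise. The
automatic factor keeps the reduced sweep width at least twice the region
bandwidth and at least ~64 direct points (so the singular spectrum remains
informative for order selection).

## Model-order selection

The Wax–Kailath MDL criterion on the singular values of the Hankel matrix of
the first (filtered) direct-dimension slice, with pencil rows L = ⌊N/3⌋ and
the complex-model penalty ½k(2L−k)·ln Ñ, Ñ = N−L+1. The criterion is
scale-invariant and reliable in its intended regime (well-separated lines at
line-amplitude SNR ≳ 30 dB); on crowded or weak data it under-counts — the
1D slice simply carries less information than the full 2D grid — and the
pipeline accepts manual per-region orders instead, which is the recommended
practice for such data. Candidate orders run from 0 to L−1.

## MMEMPM initialization

The enhanced matrix is the L₁ × (N₁−L₁+1) block-Hankel matrix whose (p, q)
block is the L₂ × (N₂−L₂+1) Hankel matrix of slice p+q (pencil sizes
⌊N/3⌋). It is never materialized for large grids: its action on a vector is
a 2D cross-correlation with the data grid, evaluated by FFT convolution, and
the dominant subspace comes from an iterative partial SVD with a fixed
deterministic start vector (dense LAPACK SVD is used for small problems).

Both shift-invariance maps F₁ (advance in n₁: drop last vs first block-row)
and F₂ (advance in n₂: drop last vs first row within blocks) act on the same
M-dimensional subspace. The poles are paired by simultaneous
diagonalization: the eigenvectors of F₁ + μF₂ (fixed complex μ) diagonalize
both maps, so (z₁, z₂) emerge matched even when one dimension carries
duplicated poles — common in 2DJ data, where lines of different multiplets
share J displacements and every multiplet has lines near f₁ = 0. This
removes the need for a duplicate-clustering tolerance. Growing poles are
clamped to the unit circle before refinement; complex amplitudes follow from
a linear least-squares fit of the full grid against the paired
Kronecker-product basis.

## Refinement

The cost is the residual sum-of-squares plus λ times the circular variance
1 − |mean e^{iφ}| of the phases (wrap-safe, zero when all phases agree). The
default λ = 10⁻³ · RSS(initial guess) is scale-matched: large enough to break
the near-degeneracy between a common phase roll and amplitude changes, small
enough not to bias amplitudes; λ = 0 gives plain least squares.

Minimization is damped Gauss–Newton (Levenberg–Marquardt damping relative to
the curvature diagonal) with analytic gradients; only cost-decreasing steps
are accepted, so descent is monotone, and convergence is declared on a small
gradient or a < 10⁻¹⁴ relative cost drop. The model is separable, so the
6M × 6M Gauss–Newton matrix assembles from six M × M Gram matrices per
dimension in O(M²(N₁+N₂)); no Jacobian is ever formed over the data grid.
Amplitude positivity is restored by sign-flip normalization after
optimization; negative dampings and (for sub-FIDs) out-of-band direct
frequencies are softly penalized, the latter confined to the filter
pass-band ± three-quarters of a bandwidth. Oscillators ending below 10⁻³ of
the largest amplitude are purged, logged, and the remainder re-optimized (at
most three purge rounds).

Parameter uncertainties use the observed-information approximation:
covariance = σ̂² (Re JᴴJ)⁻¹ with σ̂² = RSS/(2N₁N₂ − 6M), computed with the
same Gram assembly. A caveat: on a filtered sub-FID the residual noise is
coloured (band-limited), so σ̂² underestimates the in-band density and the
reported errors are optimistic; errors reported by the pipeline therefore
come from the final refit against the raw grid, where the noise is white and
the calibration is verified (empirical spread within ~10% of the mean
reported error at SNR 20 dB).

## Pipeline

Phase correction → per-region filtering (+ shift/decimate) → per-region
order selection → MMEMPM → refinement on the reduced grid → refinement on
the full filtered sub-FID → region merge with deduplication (two oscillators
from different regions within one digital-resolution bin in f₂ and ε in f₁
are one line; the copy from the nearer region centre wins) → a final global
refit of all merged oscillators against the raw phase-corrected grid. The
global refit removes the small lineshape bias that band-pass filtering
leaves in per-region fits (measured zero centre-frequency bias on noiseless
fixtures) and furnishes the calibrated error bars above. It is on by
default (`global_refit: false` disables it).

Then: multiplet grouping, purging, spectrum construction, and a result
record (CSV oscillator table + JSON metadata with full provenance: seeds,
filter settings, λ, ε, software version). Every stochastic step draws its
seed from the single config seed through a spawned `numpy.random.SeedSequence`,
so a config re-run is bit-identical.

## Multiplets

Grouping clusters the pure shift frequencies f₂ − f₁ with single-linkage
closure at threshold ε — the minimal consistent completion of the pairwise
condition; complete linkage is available for cases where chaining
over-merges. ε defaults to the digital resolution of the worse-resolved
dimension and is user-overridable (crowded spectra often need more). The
multiplet centre is the amplitude-weighted mean of members' pure shift
frequencies. A signal is purged only when *both* non-first-order criteria
hold: it is ungrouped *and* |f₁| > ε. A genuine singlet (f₁ ≈ 0) is never
purged.

## Spectra

Processing conventions: exponential line broadening e^{−π·lb·n·τ}, first
point halved, zero-fill ×2 by default, real part shown, axis high-to-low.
The magnitude-mode tilt-projection comparator uses sine-bell apodization in
both dimensions (sin(πn/(N−1))), a 2D FT, an exact shear implemented as an
FT-domain linear phase ramp per indirect frequency (no interpolation), then
magnitude and skyline (or sum) projection. Multiplet spectra are built from
members' direct-dimension parameters only (f₂, η₂), so the sum of all
multiplet spectra plus purged-line spectra reproduces the full
direct-dimension model spectrum by linearity.

## Synthetic data

The generator emulates exactly the structure the model assumes: first-order
multiplets expanded from coupling trees ((J, k) → k+1 lines at displacements
(j − k/2)J with binomial weights; amplitude conserved exactly), optional
unpaired "artifact" lines standing in phenomenologically for
strong-coupling responses, and i.i.d. complex Gaussian noise. SNR convention
throughout: SNR(dB) = 20·log₁₀(max|noiseless grid| / σ). What it does *not*
emulate: genuine strong-coupling quantum dynamics (tilted/partial
multiplets), t₁-noise and other coherent instrument artifacts, baseline
distortions, radiation damping, temperature drift. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to every pathology of real spectrometer data.

The canonical validation fixture is an eight-multiplet proton-like system
(doublets to eight-line patterns, couplings 2.4–11 Hz, amplitudes 0.9–1.5)
on a 64 × 512 grid (sweep widths 50 Hz / 1 kHz) at SNR 25 dB, with three
artifact lines, analysed in eight 50 Hz regions centred on the multiplets
with manual orders (the appropriate practice at this SNR; see
model-order section). Validation studies use scaled-down problem sizes —
100-seed Monte Carlo at 64 × 512 rather than experimental 128 × 8k grids —
chosen so the full validation suite runs in about a minute; the quantitation
study uses a 64 × 4096 grid with a ~1 s direct acquisition, where lines
decay well inside the window as in routine practice.

## Numerical choices and degenerate inputs

All-zero inputs: order selection returns M = 0 with a warning; subspace
estimation raises (rank-deficient). Requesting more components than the
signal rank yields near-zero-amplitude spurious oscillators, which the purge
removes. Duplicate oscillators make the curvature singular; errors for the
affected parameters are reported as NaN with a warning. Ties in sorting are
broken by ascending f₁. ARPACK is started from a fixed vector so repeated
runs are identical.

## Known limitations

- Sub-FID filtering assumes phased data; severely phase-distorted data must
  be corrected first or filtered with generous margins.
- MDL under-counts on crowded or low-SNR regions (by design of the 1D
  criterion); manual orders are the supported fallback.
- Multiplet centre accuracy is information-limited: at the canonical
  fixture's SNR the per-multiplet centre standard deviation is
  ~0.02 Hz, so demands much below ~3σ of that limit will fail in a
  non-negligible fraction of noise realizations even though the estimator is
  calibrated at the Cramér–Rao bound.
- One experimental on-disk dialect (Bruker-style 2D time domain) is
  supported; the group-delay convention of other acquisition pipelines is
  untested.
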