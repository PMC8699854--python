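# Methods

## Symmetry selection rules

An RNₙᵛ sequence packs N net-π rotations into n rotor periods with element
phases alternating ±πν/N (the first element takes +πν/N; rotor phase is
defined as zero at the start of the schedule — γ-encoded observables are
insensitive to both conventions). To first order in average-Hamiltonian
theory a rotational component (l, m, λ, μ) of an interaction survives iff

    R sequences:  m·n − μ·ν = (N/2)·Z,  Z an integer with the parity of λ,
    C sequences:  m·n − μ·ν = N·Z.

`allowed_terms` evaluates the rule directly; the test suite checks it
against an independent brute-force scan over (m, μ, Z). Two amendments are
applied on top of the bare rule:

- **l = 2, m = 0 components are always dropped** — magic-angle spinning
  nulls them regardless of the pulse sequence.
- Only ¹H-involving interactions enter the candidate filter (heteronuclear
  dipolar λ = 1, homonuclear ¹H–¹H λ = 2). ¹⁵N-only terms are refocused by
  the experiment's echo and are not tested.

**γ-encoding** is decided per term set: the recoupled amplitude is
independent of the crystallite γ angle iff no spin component μ is recoupled
through space components m of both signs. **Correlation** (sign(m) =
sign(μ) for every term) vs anticorrelation governs second-order error
terms; see the robustness section.

**Candidate enumeration** scans N (even, for R sequences), n, and
1 ≤ ν ≤ ⌊N/2⌋ (ν and N−ν give mirrored sequences and are not emitted
twice). By default only primitive triples with gcd(N, n, ν) = 1 are
reported: R(kN)₍ₖₙ₎^(kν) prescribes byte-for-byte the same RF waveform as k
back-to-back repeats of RNₙᵛ — identical element duration n·τr/N, identical
phase list — so non-primitive triples are duplicates, not new sequences.
With this deduplication the 100 kHz search (N = 10–42, n = 1–37, γ-encoded,
heteronuclear allowed, homonuclear suppressed, base field < 200 kHz) yields
310 candidates. `dedup_repeats=False` restores the raw scan (373 for the
same window).

## Composite R-elements and timing

Flip angles are stored as exact affine coefficients a + b·θ (degrees), so
the sweep factor k_p = Σ flip/180° and the segment timing fractions
flipᵢ/Σflip are exact rationals for rational θ. The element window is
n·τr/N seconds (N elements span exactly n rotor periods), which makes

    duration · match_field · fractionᵢ = flipᵢ/360

hold identically — the internal consistency check used in the tests. The
θ domain defaults to [0°, 720°]; all catalog elements compose to a net π
rotation for every θ (verified by quaternion composition to < 10⁻⁹ rad),
so θ can be swept continuously without losing the inversion property.
Zero-length segments (e.g. the θ portions of `1a` at θ = 0) are collapsed.
User-defined elements are first-class via `make_element`.

## Two-spin propagation

The spin system is an isolated ¹H–¹⁵N pair. The rotating-frame Hamiltonian
is H/2π = d(t)·2IzSz + ν₁(t)(Ix cos φ + Iy sin φ) + off_I·Iz + off_S·Sz
with the standard rank-2 MAS modulation of the axially symmetric dipolar
tensor,

    d(t) = d·[√2 sinβ cosβ cos(ωr t + γ) + ½ sin²β cos(2ωr t + 2γ)],

where d (Hz) is the splitting-defining dipolar constant — the single free
normalization, pinned by 1.02 Å ↔ 11,477.3 Hz (γ₁H = 2.67522187×10⁸,
γ₁₅N = 2.7126180×10⁷ rad s⁻¹ T⁻¹).

Because RF is applied on ¹H only, [H, Sz] = 0 and the 4×4 propagator
factorizes into two exact 2×2 SU(2) blocks; each integration step is a
closed-form rotation about the piecewise-constant effective field evaluated
at the step midpoint. Steps never exceed τr/points_per_rotor and always
align with RF segment boundaries. Defaults: 720 steps per rotor period for
single-crystal κ extraction (halving the step changes κ by < 10⁻⁵), 360
for powder libraries (per-point trajectory error ≲ 5×10⁻⁴). Time-ordered
products are accumulated by pairwise tree reduction over component arrays,
which is what makes 251-coupling × several-thousand-crystallite library
builds tractable on one core.

Detection starts from transverse ¹⁵N magnetization and samples it
stroboscopically once per symmetry cycle (n·τr), mirroring the experiment's
constant-time dipolar increment.

**Default crystallite** (α=0°, β=90°, γ=0°): the candidate sequences
recouple m = ±2 components, whose orientation factor ½sin²β is maximal at
β = 90°. **Powder sets** are ZCW-style quasi-uniform grids: golden-ratio
spiral in (α, cos β) over the hemisphere crossed with an explicit γ grid
(default 376 × 16, equal weights). Even for γ-encoded sequences the *full
trajectory* (transients, unrecoupled fraction) depends on γ — only the
recoupled frequency does not — so the γ grid is never collapsed.

**κ extraction.** The stroboscopic trajectory oscillates at half the
recoupled doublet splitting. κ is therefore 2·f_peak/d, where f_peak is the
positive-frequency maximum of the magnitude spectrum of a 256-cycle
noiseless trajectory after mean subtraction (the unrecoupled fraction
otherwise dominates as a zero-frequency line), refined by parabolic
interpolation on a 32× zero-filled grid. This splitting-over-static-limit
convention was fixed once against the plain-π tabulated value for R14₈⁵ and
then frozen; with it, all eight tabulated κ values for the four validation
sequences reproduce within 0.0025 (tests assert ±0.02).

**Robustness scans** multiply every segment amplitude by a mis-set factor
(timings fixed — an amplitude error, as from B₁ inhomogeneity) or add a ¹H
carrier offset, and report the recoupled peak shift. Correlated term sets
lack the second-order "pulse" cross term, and their peak moves by tens of
Hz at a 0.9 mis-set where typical anticorrelated sequences move by hundreds
(R14₈⁵ is a known anticorrelated exception at ~40 Hz). Offset shifts scale
quadratically, as expected of a second-order term; in these simulations
they are small (< 15 Hz at 10 kHz offset) for both classes, so the
offset-vs-mis-set trade-off is asserted only on the mis-set side.

## Trajectory fitting

The library holds powder-averaged trajectories on a uniform coupling grid
(default 7,500–12,500 Hz, 20 Hz step, 251 rows; 15 points at the k·n·τr
increment, first point normalized to 1). Each row is expanded by

    model(t) = scale · exp(−π·lb·t) · row(t) + dc

with dc ∈ [−0.2, 0.5], scale ∈ [0.9, 1.1], lb ∈ [0, 2500] Hz. The damping
convention exp(−π·lb·t) makes lb the FWHM of the equivalent Lorentzian —
the conventional "Hz of line broadening". Nuisance grid steps (0.01 / 0.01
/ 50 Hz) are the package's own choice, set so that on-grid round trips are
exact at interactive runtimes.

The fit is an exhaustive grid search minimizing the time-domain residual
sum of squares. One exactness-preserving reduction is applied: for fixed
(coupling, lb, scale) the RSS is a convex parabola in dc, so the grid
minimum over dc is one of the two grid points bracketing the unconstrained
minimizer; both are evaluated and compared. The tests verify bit-level
agreement with brute-force enumeration of the full grid. Ties break toward
lower lb, then lower |dc|. Fits with S² > 1 are flagged, never clipped.

**Monte-Carlo errors** add independent per-point noise drawn uniformly on
±noise_level (default 0.075 — a constant absolute level on the normalized
trajectories, which deliberately overestimates errors for weak peaks and is
honest only for typical intensities) and refit, default 5,000 steps; the
reported σ is the standard deviation of the refit couplings. All randomness
flows through one seeded generator.

**Order parameters**: S² = (d/11,477.3 Hz)²; cone semi-angles invert
S = cosβ(1+cosβ)/2 in closed form (positive root of the quadratic). Note
the inversion gives the *semi*-angle: the difference between S² ≈ 0.9 and
S² ≈ 0.7 is ~12° of semi-angle by this expression.

## Synthetic data

`generate_synthetic_trajectories` emulates the experimental data model:
nearest-library-row trajectory, nuisance transform, bounded uniform noise.
Defaults draw couplings from 9,500–11,500 Hz (spanning the S² ≈ 0.7–0.9
regimes of the measured samples), dc ∈ [−0.05, 0.15] and lb ∈ [0, 600] Hz
(the ranges the real fits returned), scale ∈ [0.95, 1.05], noise ±7.5%.
What the generator does **not** emulate: peak overlap, intensity-dependent
noise, ¹H–¹H residual couplings, B₁ distributions across the coil, or
relaxation during the pulses — so passing recovery tests demonstrate the
correctness and precision of the fitting machinery under the stated noise
model, not immunity to those systematics.

## Problem sizes in the shipped tests

The test suite and the acceptance script use reduced problem sizes chosen
for convergence at interactive runtimes: single-crystal κ at 256 cycles and
720 steps/rotor (identical to 4 decimal places with the defaults), test
libraries at 30–100 orientations × 2–4 γ and 120 steps/rotor (powder error
≲ 2%, irrelevant for self-consistent recovery tests), Monte-Carlo at 500
steps (σ stable to a few Hz versus 5,000). The library defaults themselves
remain the full study conditions.

## Known limitations

- First-order selection rules only; no supercycles, no second-order
  engineering.
- Two-spin system: no ¹H CSA by default, no remote protons, no relaxation
  during pulses, ideal rectangular amplitudes.
- The enumeration window criteria reproduce the published 100 kHz count;
  the corresponding 60 kHz count depends on range choices that are not
  fully specified and is not asserted.
- Fit couplings are reported on the library grid (20 Hz quantization);
  off-grid truths are recovered to half a step in noise-free tests.
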