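# Methods

This note records the models behind each analysis stage, the numerical
choices, what the synthetic generators do and do not emulate, and the known
limitations. Units are fixed throughout: area per molecule A in Å², surface
pressure π in mN/m, compression modulus in mN/m, splittings in gauss,
mobility in instrument units (1 unit = 10⁻⁸ m² V⁻¹ s⁻¹), ζ in mV, energies
in J/mol.

## Isotherm feature extraction

A compression isotherm is stored with strictly decreasing A (input in
expansion order or shuffled is canonicalised by sorting; duplicate
abscissae are rejected, as are series with fewer than 10 points, areas ≤ 0
or pressures below a −0.5 mN/m baseline tolerance).

**Smoothing and differentiation.** Derivatives of noisy trough data are the
dominant error source, so the pipeline uses local-polynomial
(Savitzky–Golay) filtering at two scales:

* a *detection* scale — degree 2, window 11 points — smooths π before
  differencing, and a second degree-2 pass (window 31) smooths the modulus
  curve itself. Differentiation turns pressure noise σ_π into modulus noise
  of order A·σ_π/(h√w) (h the grid step), which is largest in the soft
  low-pressure tail where A is big; the second pass tames exactly that.
* a *stiffness* scale — a single Savitzky–Golay first-derivative of the
  **raw** curve with a wider window (41 points, clipped to half the
  condensed-branch length when a plateau leaves only a short branch) — is
  used for `Cs⁻¹_max` and `A_lim`, where bias and variance of the
  derivative enter the reported numbers directly. With σ_π = 0.1 mN/m on a
  ~0.05 Å² grid this keeps the modulus estimate within a few percent; the
  window trade-off is variance (narrow) against kink smearing (wide).

Endpoints are filled by evaluating the edge-window polynomial fits
(`scipy.signal.savgol_filter(mode="interp")`), so no points are lost. The
filters assume a (nearly) uniform area grid; non-uniform input falls back
to smoothing plus centred differences. `compression_modulus` itself is the
plain centred-difference estimate Cs⁻¹ = −A·Δπ/ΔA, one-sided at the ends —
on a 500-point 2-D ideal-gas curve (π·A = kT) it reproduces the closed form
Cs⁻¹ = π to ≲0.01 %.

**Collapse.** Scanning in compression direction, collapse is the earlier of

1. the first attainment of the global maximum of the smoothed π, provided π
   stops increasing afterwards (the maximum is not the last point) and
   exceeds a floor (default 5 mN/m) that keeps the near-zero tail out of
   consideration; a small walk-back tolerance (0.15 mN/m) moves the index
   to the first point of a noise-flat top. A literal pointwise
   "dπ/dA ≥ 0" test is not used because inside an LE/LC plateau the true
   slope (≈0.05 mN/m per Å²) is below derivative noise; for any curve whose
   post-collapse branch has dπ/dA ≥ 0 the two readings coincide.
2. the first point after the attained modulus maximum where Cs⁻¹ falls
   below 20 % of that maximum (`drop_fraction`, configurable).

The reported π_coll is refined to the maximum of the *raw* pressures within
half a smoothing window of the detected index, which undoes the downward
bias of fitting a polynomial across the collapse kink. A monotonically
rising curve reports the last pressure with `collapse_detected = False`.

**Plateau.** An LE/LC coexistence plateau is an interior run of the
detection-scale modulus below a ceiling (50 mN/m) bounded on *both* sides by
regions exceeding the run's typical level — its median, robust against
single-point noise dips — by a factor 2. The two-sided requirement is what
separates a plateau from collapse: collapse has no condensed branch after
it, so a soft region adjacent to the collapse point is classified as
collapse, not plateau. Two noise guards: runs separated by fewer than 25
above-ceiling points are merged (noise flicker around the ceiling must not
cut the soft tail into spurious "interior" valleys), and the first
smoothing window is folded into the leading boundary region (edge-fit
artifacts). π_plateau is π at the modulus minimum inside the run, with the
smeared run edges (one smoothing window) excluded from the argmin.

**Limiting area.** At the pre-collapse modulus maximum (π*, A*),
`A_lim = A*(1 + π*/Cs⁻¹_max)`, i.e. the tangent in the (A, π) plane
extrapolated to π = 0. This is the dominant convention for the "area of a
maximally packed molecule" and is exact (to floating point) whenever the
condensed branch is affine, because every tangent of a line recovers its
intercept. For mixed films A is interpreted per *all* spread molecules
(lipid + steroid); the package never rescales areas silently, and file
readers refuse units other than Å²/mN/m rather than guessing.

## Excess Gibbs free energy of binary films

Endmember and mixture isotherms are first resampled to A(π) on a uniform
pressure grid (default step 0.1 mN/m) using the strictly increasing
pre-collapse segment and linear interpolation; extrapolation above the
achievable pressure is refused, and a curve that misses π = 0 by at most
1 mN/m is extended linearly from its two lowest-pressure points (a larger
gap is an error). The excess area A₁₂ − x₁A₁ − x₂A₂ is integrated by the
trapezoidal rule from 0 to π₂ and converted via 1 Å²·mN/m = 10⁻²³ J and
Avogadro's number, so ΔG_exc [J/mol] = 6.02214076 × I with I in Å²·mN/m.
Default target pressures are 5, 10, 20 and 25 mN/m, the last being closest
to the packing of a native membrane. Checks: a constant 2 Å² excess over
[0, 25] gives 301.107 J/mol (closed form); an exact mole-fraction-weighted
mixture gives 0 to 10⁻⁹; the trapezoid agrees with a 100×-finer midpoint
Riemann oracle to ≪0.5 % on smooth excess functions; differentiating
ΔG_exc(π₂) numerically recovers N_A × excess area (fundamental-theorem
consistency); the result is invariant under swapping the endmember labels
together with x₁ ↔ x₂. "Component 1/2" are whichever two film systems the
caller designates — the machinery covers both steroid–steroid and
lipid-film–lipid-film mixing designs. No interaction-parameter fitting or
phase-diagram construction is attempted.

## EPR order parameter

S = 0.5407·(A′∥ − A′⊥)/a₀ with a₀ = (A′∥ + 2A′⊥)/3. The 0.5407 prefactor
encodes the anisotropy of the nitroxide hyperfine tensor and is used as a
fixed constant, not recomputed from tensor components. Splittings are
inputs: raw spectrum acquisition and lineshape fitting are out of scope.
Per temperature, S is computed per replicate and summarised as mean ± SE
(sample SD/√n; exactly 0 for n = 1 or identical replicates). S is
scale-invariant in the splittings and monotone in A′∥; |S| > 1.05 is
rejected as unphysical. Temperatures outside 0–60 °C are refused
(instrument range, configurable in the record type).

## Zeta potentials

ζ = ημ/(ε₀ε_r) (Smoluchowski limit — thin double layer; no Henry-function,
relaxation or κa corrections, matching standard instrument practice for
~200 nm liposomes in water). Mobilities use the Zetasizer unit convention,
1 unit = 10⁻⁸ m² V⁻¹ s⁻¹; |μ| ≥ 20 units is rejected as a gross outlier.
Water viscosity/permittivity defaults are CRC-handbook values at
5–30 °C in 5 °C steps with linear interpolation (linear extrapolation
toward the 0–60 °C validity bounds), all overridable per call. Worked
check: μ = −2.0 units in η = 0.8872 mPa·s, ε_r = 78.3 gives −25.59 mV.

## Percent-of-reference normalisation and reports

Each (system, parameter) series is rescaled to its value at a reference
temperature (default 20 °C), whose row becomes exactly 100. Percentages are
computed from the printed/aggregated means, not per-replicate values;
negative inputs are refused rather than silently normalised (all monolayer
parameters here are positive, so no sign convention is needed). The
operation is idempotent. Report bundles are one JSON document plus one CSV
per section with deterministic section and key order; statistical group
letters (multiple-range tests) are deliberately not produced.

## Synthetic generators

Each generator is the exact inverse of its analyzer in the noiseless limit,
which is what makes recovery rates meaningful.

* **Isotherms** are C⁰ piecewise constructions on a uniform area grid:
  an exponential liquid-expanded tail (decay scale auto-chosen so the tail
  join slope is 0.6× the condensed slope — LE films are softer than LC), an
  optional near-flat plateau segment (residual slope 0.05 mN/m per Å² plus
  a small cubic bow that puts the modulus minimum, and hence π_plateau, at
  the segment centre), an affine condensed branch A = A_lim − π/s_c (which
  makes the tangent construction exact), and a post-collapse branch with
  dπ/dA ≥ 0. Gaussian noise is added to π; σ_π = 0.1 mN/m in recovery
  studies, matching a Wilhelmy-plate accuracy of ±0.1 mN/m. Grids default
  to 1000 points, a typical trough sampling density. Presets are
  parameterised from published A_lim/π_coll/π_plateau/Cs⁻¹_max means of
  PC 18:3, PC 16:0 and their 1:1 mixture (pure and steroid-doped, 10–30 °C);
  they emulate the curve *families*, not the experimental curves. LE-type
  systems whose maximal modulus is below their collapse pressure (PC 18:3
  at 10 °C) cannot be represented by an affine branch and have no preset;
  their temperature normalisation uses the printed table directly.
* **Mixtures** compose A₁₂(π) = x₁A₁ + x₂A₂ + f(π) with f zero, constant,
  or a half-sine spanning the common pressure range; ground truth ΔG_exc is
  closed-form for the first two and a fine-grid midpoint sum for the third.
* **EPR series** invert the S formula: d = S·a₀/0.5407, A′∥ = a₀ + 2d/3,
  A′⊥ = a₀ − d/3, plus Gaussian noise per splitting (default studies use
  0.2 G, n = 10). The default a₀ of 15 G is a typical isotropic nitrogen
  splitting for a doxyl probe in a fluid bilayer; the preset S(T) profile
  (0.20 → 0.13 over 5→20 °C, 0.16 at 30 °C) reproduces only the qualitative
  shape of the measured temperature response, since numeric S values are
  not published.
* **Mobilities** apply Gaussian noise in ζ-space (σ = 2 mV, the scale of
  published replicate SEs) and invert the Smoluchowski relation at the
  requested temperature.

All randomness flows from one explicit integer seed; equal seeds give
byte-identical datasets, and a `ground_truth.json` sidecar accompanies every
simulated dataset.

**What passing tests show — and don't.** The generators produce idealised
piecewise curves with white Gaussian noise. Real troughs add correlated
drift, barrier-speed effects, compression–expansion hysteresis and impurity
artifacts; real EPR spectra require lineshape fitting before splittings
exist; real mobility distributions can be skewed. Recovery rates measured
here therefore bound performance under the stated noise model only, and
exact numeric agreement with published table values is not attainable
without the underlying raw curves (the published smoothing and
differentiation scheme is unreported).

## Problem sizes

Default study sizes keep every check cheap while leaving headroom above the
statistical requirements: 100 replicates per preset for isotherm recovery,
20×10 replicates for noisy EPR recovery, 200 seeds for zeta round-trip
coverage, 500-point grids for the ideal-gas oracle and 0.1 mN/m pressure
grids (251 points to 25 mN/m) for the mixing integrals. The full test suite
runs in a few seconds on one CPU.
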