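# Methods

## The TDS measurement model

The package computes the transition-dipole-strength spectrum

    d(ω) = |ΔOD_s(ω,ω)| / OD_s(ω)
         · OD_c(ω_max) / |ΔOD_c(ω_max,ω_max)|
         · I_pump(ω_max) / I_pump(ω)
         · |μ_c|²

from four inputs: the sample's 2D IR spectrum (pump × probe ΔOD), its
baseline-corrected linear OD, the pump intensity spectrum, and a calibrant
measurement (N-methylacetamide, a single uncoupled amide I′ oscillator
with |μ_c|² = 0.12 D²).  Assumptions: the diagonal 2D signal scales as
|μ|⁴ and the linear signal as |μ|², geometry and polarization factors are
common to sample and calibrant (absorbed by the calibrant ratio), and the
pump envelope varies slowly over a band so its value at the band frequency
normalizes the 2D excitation efficiency.

Exact identities that follow from the model (and are tested as such):
running the calibrant as the sample gives d(ω_max) = |μ_c|² to floating
point; joint rescaling of ΔOD and OD (concentration, path length) and
global rescaling of the pump leave d unchanged; doubling ΔOD doubles d.

Conventions: the fundamental (bleach/stimulated-emission) diagonal lobe is
stored negative and the overtone lobe positive; magnitude is taken
explicitly where Eq.-level quantities need it.  All interpolation is
linear; operations restrict to axis intersections and never extrapolate.
The diagonal slice takes the fundamental-lobe magnitude at equal pump and
probe frequency, interpolating along each pump row.  ω_max is located on
the calibrant's corrected linear OD (smoother than the 2D diagonal); an
ω_max on the axis boundary is an error (band not captured).

Because the ratio diverges as OD → 0, points with OD below
`od_floor_frac` (default 0.05) of the OD maximum are dropped from the TDS
spectrum rather than computed.  Per-mode values are read inside assignment
windows; the default read-out is the TDS-spectrum argmax in the window,
with an option to read d at the 2D diagonal maximum instead (`reference`).
For noisy data the reference read-out is preferable: the argmax of a noisy
ratio spectrum preferentially lands on upward noise excursions and is
biased high by several percent at SNR ≈ 50, while the diagonal maximum is
a stable location.

## Baseline estimation

Linear OD spectra are corrected with a penalized-least-squares scheme
built on the Whittaker smoother: minimise Σ w_i (y_i − z_i)² +
λ·Σ(Δ²z)², solved as the banded system (W + λDᵀD)z = Wy.  The airPLS
iteration re-weights residuals — zero weight above the baseline,
exponentially growing weight below — so z settles onto the lower envelope
of the spectrum.

Plain airPLS has two failure modes on amide-I′-like data, and the
implementation addresses both:

* **Noise termination.**  With measurement noise, the negative-residual
  mass cannot fall below the `tol` threshold until the exponential
  weights have concentrated onto the deepest noise minima, at which point
  the baseline sinks far below the data across the zero-weight band
  regions.  The iteration therefore also stops as soon as the
  negative-residual mass increases between iterations (no further
  progress), keeping the previous estimate.  Edge windows (10% of points
  at each end) are pinned to the maximum weight, anchoring the ends of the
  baseline to data.
* **Curvature bias.**  Exponential weighting anchors the fit only on
  points that happen to lie below the current baseline, which biases the
  boundary values and slopes of the spline bridge under each band.  A
  refinement pass therefore uses the converged airPLS estimate only to
  *locate* peak regions (signal above `peak_frac` = 2% of the maximum or
  4× the noise scale, mask dilated by ~10 grid points to clear band
  tails) and re-fits the baseline with uniform unit weights on all
  non-peak points.  Uniform anchoring tracks the centre of the noise band
  instead of its lower envelope, and the under-band bridge then carries
  only the O(f″·gap²) error intrinsic to interpolating an unobservable
  stretch.

Parameters: λ = 5·10⁴ for ~1 cm⁻¹ grids (chosen on synthetic scenes as
the stiffness that neither eats into 25 cm⁻¹-wide bands nor loses broad
background curvature; exposed in `AirPLSConfig`), difference order 2,
`tol` = 10⁻³, `max_iter` = 50.  The configuration and convergence outcome
are recorded in the output metadata.  Baseline correction applies to
linear OD only; the synthetic 2D spectra are generated background-free and
no 2D surface baselining is attempted.

An intrinsic limit worth stating: the baseline *under* a band is
unobservable, so any estimator interpolates it from the flanks with error
of order f″·gap²/8 (background curvature × band-support width²).  A
background component whose own hump sits narrowly under the band region is
mathematically indistinguishable from an unresolved spectral band, and no
baseline algorithm will separate them.  The synthetic backgrounds are
accordingly generated as slowly varying across the analysis window (see
below); against sharply curved backgrounds the 2% recovery figures quoted
by the tests do not transfer.

## CD helicity

Mean residue ellipticity [θ] = θ/(l·C·n) with θ in mdeg, l in mm, C in
mol/L (equal to the usual θ/(10·l_cm·C·n)); theoretical maximum
[θ]_H = −40000·(1 − x/n) + 100·T with T in °C and the end-effect constant
x = 2.5 (appropriate for chains of ~8–23 residues); percent helicity
100·[θ]₂₂₂/[θ]_H, clamped at 0 for disordered line shapes with the raw
ratio kept for diagnostics.  [θ]₂₂₂ is read by linear interpolation at
exactly 222 nm.  Helical residue counts are reported to 0.1 residue;
because reported percentages are themselves rounded, comparisons against
reported (percent, residue) pairs use ±0.15 residue.

## Helix-length calibration

Ordinary least squares of TDS on helical residues through the four model
[EK]_N points — (0, 0.13), (5.9, 0.15), (13.2, 0.21), (20.2, 0.26) —
giving slope 0.00667 D²/residue and intercept 0.1220 D² (r² = 0.981).
Unweighted OLS is the default since the calibration is conventionally an
unweighted trendline; a 1/sd² weighted variant is available because
replicate standard deviations exist.  The intercept is freely fitted, not
forced through the 0.12 D² uncoupled-amide value; the free fit reproduces
all reported predictions within 0.5 residue.  The [EK]₂ abscissa is the
CD-derived 5.9 residues (the integer 5 is sometimes quoted; the ±0.5
residue comparison tolerance covers both).  Chain lengths 8/13/18/23 for
N = 1–4 follow from the 5-residue repeat unit.

Inverse prediction L = (d − b)/m with first-order (delta-method)
uncertainty from the measurement sd, the coefficient standard errors and
their covariance; no bootstrap (four points).  Negative lengths report as
0 with a `below_calibration_range` flag; lengths beyond the calibration
maximum are flagged `extrapolated` but returned — the physics has no
cutoff at the largest calibration peptide.  The frequency-vs-length trend
is fitted by the same machinery but always carries a caveat flag:
amide I′ frequency is unreliable for globular proteins and must not be
inverted for length.  β-sheet TDS values are reported without structural
inversion (no strand-count model).

## Synthetic data

Scenes are sums of unit-area Gaussian/Lorentzian/pseudo-Voigt amide I′
bands (1600–1700 cm⁻¹) on a polynomial-plus-broad-Gaussian baseline, with
a Gaussian pump envelope (default centre 1640 cm⁻¹, FWHM 120 cm⁻¹ —
documented defaults, not measured values) and i.i.d. Gaussian noise; every
generator is a deterministic function of (spec, seed).

The 2D generator inverts the TDS relation: the diagonal magnitude is set
to d(ω)·OD_band(ω)·[I(ω)/I(ω_max)]·[ΔOD_c/OD_c]/|μ_c|², where OD_band is
the band-only OD (the pipeline's baseline correction is expected to
remove the rest) and the ground-truth profile d(ω) is the OD-weighted
mean of band TDS values — how an unresolved multi-mode band presents a
single apparent TDS.  The overtone lobe is red-shifted 16 cm⁻¹ along
probe (typical amide I′ anharmonicity) and orthogonalized to vanish
exactly on the diagonal, so it is cosmetic.  The calibrant measurement is
generated noise-free (a dedicated reference measurement); the
instrument's 2D-to-1D gain ratio is arbitrary and cancels.

CD spectra mix fixed helix/coil basis shapes (helix: positive 192 nm,
negative 208/222 nm bands, normalized to 1 at 222 nm; coil: deep negative
198 nm band with negligible 222 nm contribution) scaled so the noise-free
mean residue ellipticity at 222 nm equals frac_helix·[θ]_H, then converts
to raw millidegrees by inverting the normalization.

Randomized validation scenes draw 1–3 Gaussian bands at 1615–1675 cm⁻¹
(≥15 cm⁻¹ apart, FWHM 18–27 cm⁻¹, peak OD ≈ 0.1–0.4, TDS 0.12–0.35 D²),
a mild linear baseline, a broad background Gaussian (amplitude ≤ 0.06 OD,
FWHM 450–800 cm⁻¹, centre anywhere in 1500–1800 cm⁻¹) that stays slowly
varying across the window — the identifiability constraint above — and a
pump FWHM swept over 60–200 cm⁻¹.  Validation figures computed by the
test suite: noise-free, every band's peak TDS is recovered within 2%; at
SNR 50 on the linear OD (noise also applied to the 2D matrix at the same
ratio), the dominant band's TDS is recovered within 10% in ≥95% of
scenes.  The SNR-50 figure is quoted for the dominant band because a
shoulder band at ~20% of the peak OD has per-point ratio noise above 10%
at that SNR — no estimator can beat the noise floor for such bands.

What the generator does *not* emulate: vibrational coupling and exciton
structure (cross peaks, realistic 2D line shapes), polarization effects,
solvent/temperature drifts, detector nonlinearity, or correlated noise.
Passing recovery tests therefore demonstrate the correctness of the
analysis arithmetic and baseline handling under the stated band/baseline
model, not instrument-level robustness.

## Numerical choices and degenerate inputs

Whittaker systems are solved sparsely (scipy); the smoother is verified
against dense normal-equation solves.  OLS/WLS fits go through
statsmodels; r² is cross-checked against the 1 − SSR/SST definition.
Duplicate axis values are rejected, not averaged; files without the
expected unit header are rejected; descending axes are normalized to
ascending on construction.  Degenerate cases that raise: all-zero
smoother weights, flat calibrant OD (boundary argmax), empty pump/probe
overlap, fewer than 3 unmasked points in a peak window, zero x-variance
in a calibration fit, nonpositive transmission, θ_H at n ≤ x.
Non-convergence of airPLS within `max_iter` is not an error; it is
flagged in metadata.

## Known limitations

Single-calibrant normalization assumes identical beam geometry for sample
and calibrant runs.  The under-band baseline is interpolated, with the
identifiability limit described above.  Helix-length predictions beyond
~20 residues extrapolate the calibration line.  The CD estimate is the
two-point 222 nm method — no spectral deconvolution.  TDS values for
β-sheets are reported but carry no length/strand interpretation.
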