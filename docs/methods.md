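# Methods

This note documents the models implemented in `cenquant`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Integrated-fluorescence counting

The measured quantity is a ratio: the background-, autofluorescence- and
oversampling-corrected signal of one centromeric focus divided by the
corrected total fluorescence of the same cell (or nucleus). Because both
numerator and denominator come from the same image, the fraction is invariant
to illumination intensity, exposure and detector gain (a property tested
explicitly), and converting it to molecules only requires an independent
measurement of the total pool.

Steps and conventions:

- **Flatfield.** Every plane is divided by a unit-mean normalized image of a
  uniform fluorescent slide. Strictly positive reference required.
- **Volume segmentation.** The exclusion stain (bright medium, dark cells)
  is Otsu-thresholded *as a volume* and dark 3D connected components are the
  cells, largest first. A volume-wise threshold with 3D connectivity is used
  rather than per-slice thresholds because z-slices that contain no cell
  cross-section have no bimodal histogram and per-slice Otsu fabricates
  structure there. A guard rejects frames whose two intensity classes are
  separated by < 4 pooled standard deviations ("no cell found"); this
  correctly rejects pure-noise frames, whose Otsu split sits near 2.7.
  The nuclear variant segments the bright phase of a nuclear marker.
- **Total fluorescence.** Per z-slice, the mean per-pixel intensity of 1–3
  user- or automatically-chosen background regions is subtracted from the
  in-mask sum; slices are then summed. Background regions must not overlap
  any cell. Autofluorescence is subtracted as (mean per-voxel intensity of
  label-free cells measured identically) × (positive-cell voxel count),
  floored at zero with a flag.
- **Focus detection.** A maximum-intensity projection is band-passed by a
  difference of Gaussians (sigma 1.0 px vs 6.0 px) to remove the diffuse
  nucleoplasmic pool; local maxima above a robust threshold (median +
  6 × 1.4826 × MAD of the band-passed image) are each segmented at half
  their peak amplitude, and the half-maximum region must pass area
  (4–50 px²), circularity (≥ 0.7) and maximum Feret diameter (≤ 10 px).
  Per-peak segmentation keeps nearby foci separable where a single global
  threshold would merge them. All filter values are configuration, not
  measurements.
- **Focus measurement.** The focus is integrated over pixels whose centres
  lie within 2.5 px of the (sub-pixel) centroid in its focal plane (the
  z-slice maximizing the in-disk sum); local background is the mean
  per-pixel intensity of the 2.5–3.5 px annulus scaled to the disk pixel
  count. The mean (not median) annulus is used: it is linear, so the
  subtraction is exact in expectation for any locally linear background, and
  a test shows it beats a global background on a gradient. Negative
  corrected signals are floored at zero and counted.
- **Axial oversampling.** A z-stack integrates each focus's photons over
  several planes, but the focus is measured in a single plane. Beads imaged
  at the same z-step provide the correction: factor = mean over beads of
  (sum of per-plane signals / maximum plane). The single-plane focus signal
  is *multiplied* by this factor, making it commensurate with the z-summed
  cell total; the equivalent alternative (dividing the cell total) gives the
  identical fraction. Averaged over focus z-phases the correction is
  unbiased up to a Jensen term E[w]·E[1/w] − 1 ≈ 0.6% at the default
  axial sampling (sigma_z 350 nm, step 500 nm).
- **Mitotic spreads.** Spread intensities are normalized to the mean of all
  centromeres of the same cell (per-cell mean 1), removing cell-to-cell
  staining differences before comparing a marked centromere class (e.g. a
  neocentromere) with the bulk.

## Fluctuation counting

For a centromere carrying `N` segregating units of brightness `b` split
Binomial(N, ½) onto sisters, `E[δ²] = b²N` and `Σ ≈ bN`, so
`α = mean(δ²/Σ)` estimates `b` and `Σ/α` estimates `N`. `α` is computed per
experiment-and-cell-line scope; pairs with `Σ = 0` are excluded and counted;
all-zero deltas raise (no fluctuation signal). The estimator's standard
error follows from `Var(δ²/Σ) ≈ 2b²` (the scaled fluctuation is
approximately chi-squared with 1 d.f.), giving a relative error of
`sqrt(2/n_pairs)` — the bound used by the recovery tests.

Additive measurement noise inflates `δ²` and hence `α`, so noisy unit counts
are biased *downward*; together with possible co-segregation of several
nucleosomes per unit this makes `2 × units` a minimum molecule estimate.
Wild-type scaling divides by the measuring line's relative expression level
(a configuration input measured independently).

The random re-pairing control pools all sister intensities of an experiment
and re-pairs them at random (3 rounds), comparing per-pair units with a
two-sided Welch t test. Note that the control differs from the sister result
in *both* dispersion regimes, in opposite directions: with inter-centromere
dispersion the mixture inflates `δ²` (units drop); with none, independent
halves carry half the sister fluctuation (`E[δ²] = b²N/2`, since sisters are
perfectly anti-correlated while random partners are independent), so units
double. The tests assert both directions.

## Absolute calibration and synthesis

The standard curve is ordinary least squares of blot signal on loaded mass
(not forced through the origin); a linearity diagnostic flags the curve when
any point's intercept-corrected signal/mass ratio deviates from the slope by
more than 20% across the fold range of the standards. Sample mass converts
to molecules via Avogadro's number at 16 kDa (untagged) or 43 kDa (tagged),
both overridable; an optional per-lane loading-control scalar divides the
signal first.

`fraction × molecules/cell` is the point estimate; SEMs propagate in
quadrature. The calibrated-standard bound scales the focus/standard signal
ratio by the standard's maximum capacity (204 GFP molecules on the default
LacO array) — an upper bound because the array need not be fully occupied —
and is rounded *up* (a bound must not shrink by rounding); point estimates
round half-up, lower bounds down. The proportionality fit minimizes
`Σ(y − kx)²` with `r² = 1 − SS_res/SS_tot` defined against the mean of `y`;
it can be negative and is reported as-is.

## Inheritance risk

Tail probabilities of Binomial(n, ½) are computed as exact integer sums of
binomial coefficients over 2^n (Python arbitrary-precision integers through
`fractions.Fraction`), converted to correctly rounded doubles. This one code
path gives bit-exact agreement with arbitrary-precision summation at any n
used in practice and full double precision for tails down to 1e-25 and
below — no log-space approximations are needed. Tails are inclusive (≤ c);
`tail_mode="both"` adds the symmetric upper tail `P(X ≥ n − c)` capped at 1.
The default is the lower tail: the inherited-deficit reading, which also
matches the printed order-of-magnitude claims; the two-tailed variant is
exposed for comparison since the verbal model description mentions both
sides. Cell-level risk uses `-expm1(k·log1p(-X))` so tiny `X` survives
floating point. Chromosomes are assumed independent. A Monte-Carlo
simulator provides an independent check where `R` is large enough to sample
(≳ 1e-4 at 1e5 trials).

## Chromatin budget

All constants are explicit parameters (defaults: 9.1e4 molecules/cell, 74%
chromatin-bound, 0.44% of the pool per centromere, 0.73% of the nuclear
pool, 46 centromeres, 2 molecules/nucleosome, 200 bp spacing, 2.5 Mb
centromeres with a 40% CENP-A domain, 6 Gb diploid genome). Centromeric
density counts nucleosomes against the 1 Mb domain's 5000 positions; the
genomic density counts non-centromeric CENP-A nucleosomes against the
positions of the genome excluding the full 2.5 Mb centromeres; their ratio
is the per-unit-length enrichment (~48 at the defaults, conventionally
rounded to ~50). Pool fractions (centromeric, non-centromeric chromatin,
soluble) sum to 1 exactly by construction, and inconsistent inputs (a
centromeric pool exceeding the chromatin-bound fraction) raise.

## Occupancy maps

Positions are called greedily by profile height with a minimum separation
(default 100 bp; ties break to the leftmost coordinate, which also resolves
coverage plateaus deterministically). "Reads overlying a position" is taken
as the per-bp coverage *at* the called position — by definition the number
of reads whose footprint covers that bp — and total reads are total coverage
divided by the 147 bp nucleosomal footprint. This choice (over
footprint-window sums, which remain available) makes the normalization
identity exact: the probabilities sum to `N × (reads on positions / total
reads)`, hence to `N` when every read overlies a called position.
Probabilities above 1 are flagged, never clipped: they indicate an absolute
count inconsistent with the profile. The summary reports the median and
maximum occupancy and the share of all occupancy carried by the top decile
of positions.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analyses rely on,
with exact bookkeeping of every deposited photon or read:

- **Cell stacks** (default 24 × 256 × 320 voxels at 160 nm pixels / 500 nm
  z-step): an ellipsoidal cell with a concentric nucleus, a diffuse labelled
  pool split between nucleoplasm and cytoplasm, 46 diffraction-limited foci
  (separable 3D Gaussian PSF, sigma 100 nm lateral / 350 nm axial) placed in
  the nucleus with a minimum lateral separation, an exclusion-stain channel
  (bright medium), a nuclear-marker channel, an optional label-free
  neighbour cell carrying only autofluorescence, and Poisson (or Gaussian,
  or no) noise. Defaults put 400 molecules on each of 46 centromeres against
  a 91,000-molecule pool (0.44% per centromere; 0.73% of the nuclear pool at
  the default 50/50 nucleoplasm split with 74% total chromatin-bound
  share). Not emulated: EMCCD gain statistics, optical aberrations,
  spherical-aberration depth dependence, cell-cycle dynamics, focus
  brightness heterogeneity between centromeres. Passing recovery tests
  therefore demonstrate correctness of the measurement chain, not robustness
  to every real-microscope artifact.
- **Bead stacks**: isolated point sources on a grid with uniformly random
  axial phase relative to the plane grid — exactly what makes the bead
  sum/max calibration an unbiased estimate of the axial correction.
- **Sister pairs**: per-centromere unit totals drawn lognormal (positive
  support, one dispersion knob — the coefficient of variation, default
  0.25), split Binomial(N, ½), scaled by unit brightness (default 100),
  plus optional truncated Gaussian measurement noise (truncations counted).
  Default mean 75.4 units over 46 × 220 pairs.
- **Blot series**: linear signal = slope × mass + intercept with Gaussian
  noise; standards 0.1–3.2 ng (a 32-fold range), sample mass 0.363 ng — the
  CENP-A content of 150,000 cells at 9.1e4 16-kDa molecules per cell.
- **Read profiles**: 1113 positions over 300 kb; per-position occupancies
  drawn gamma (shape 0.32) and bounded to 0.5%–80% of cells (iterated
  clip-and-renormalize), the observed occupancy range at the emulated
  locus, with the shape set so the median occupancy is ~6%; 5e5 reads of
  147 bp placed multinomially with 20 bp centre jitter. The jitter matters:
  perfectly stacked reads produce flat coverage plateaus with no defined
  peak. Not emulated: mappability gaps, GC bias, duplicate reads,
  input-control structure.

All randomness in a generator flows from a single integer seed; fixed seeds
give bit-identical artifacts.

## Problem sizes and runtime

Defaults are sized so the full test suite runs in well under a minute and
the acceptance script in a few seconds on one CPU: one 2-million-voxel
stack per imaging analysis, 10,120 sister pairs per fluctuation estimate,
5e5 reads per profile, 1e5 Monte-Carlo trials per risk check. These sizes
put every estimator's sampling error comfortably inside the tolerances the
tests assert (e.g. ±10% relative on the recovered fraction, 3 analytic
standard errors on unit recovery).

## Known limitations

- The fluctuation estimator assumes equal unit brightness; brightness
  heterogeneity between units inflates `α` like noise does, pushing the
  (already minimum) estimate further down, never up.
- The oversampling correction applies one mean factor to all foci; per-focus
  axial phases make individual focus totals noisy even though the per-cell
  mean is unbiased.
- Occupancy probabilities at a called position inherit an upward
  argmax-selection bias of order `1/sqrt(reads at position)` (the peak bp is
  the noisiest-high bp of the local plateau); at the default depth this is a
  few percent at the top of the map.
- The budget model treats centromeric nucleosome positions as a uniform
  grid (density only); clustering within the domain is out of scope.
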