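# Methods

## Signal model and scope

A sample is a single 1-D absorbance spectrum on a uniform wavenumber
grid, 4000–650 cm⁻¹ at 2 cm⁻¹ spacing, stored in descending order. The
package covers the analysis chain only: replicate averaging, restriction
to the fingerprint region, wavelet feature extraction, and PNN
classification. Baseline correction, ATR penetration-depth correction,
smoothing and atmospheric compensation are deliberately out of scope —
the chain is designed to work on spectra as acquired, with averaging the
only preprocessing.

## Synthetic data generator

The generator emulates the band structure of pancreatic tissue spectra.
Each class is a sum of band profiles

    A(ν) = Σ_b a_b(class) · exp(−4 ln2 (ν − ν_b)² / w_b²)

(Gaussian by default; a Lorentzian profile of the same FWHM is a config
switch). Band inventory: a broad hydroxyl envelope at 3327 cm⁻¹
(FWHM 200 cm⁻¹, class-invariant), sharp bands (FWHM 20 cm⁻¹) at
2956/2924/2852 (C–H stretches), 1743 (ester carbonyl), 1650/1555
(amide I/II) and 1242/1084 cm⁻¹ (phosphodiesters). Only the *ordering*
of amplitudes across classes is fixed by tissue biochemistry; the
numeric defaults are model choices: weakening bands use 1.0/0.6/0.3 for
normal/early/advanced, the ester carbonyl 1.0/0.5/0.0 (it vanishes in
advanced carcinoma), class-invariant bands 1.0 throughout. These values
make the advanced class strongly separable while normal and early
overlap under noise, which reproduces the qualitative error pattern of
real cohorts (all confusions involve early carcinoma). Whether the
phosphodiester bands change with canceration is not established; the
defaults keep them class-invariant.

Per-sample randomness: each band amplitude is scaled by U[0.9, 1.1]
(`amplitude_jitter = 0.10`), a linear baseline with slope
N(0, 0.005 absorbance / 1000 cm⁻¹) anchored at the grid centre is added,
and i.i.d. Gaussian noise with sd 0.01 absorbance is superimposed. The
default cohort is 220 normal / 120 early / 100 advanced = 440 samples,
all drawn from one seeded stream, so a cohort is a bit-reproducible
function of (config, seed).

What the generator does **not** emulate: real line shapes and band
overlap, scattering and ATR penetration-depth physics, water-vapor and
CO₂ artifacts, instrument drift, or correlated noise. Passing tests on
synthetic cohorts therefore demonstrate the correctness and internal
consistency of the pipeline, not clinical performance on rat or human
tissue.

Note one grid subtlety: with the 2 cm⁻¹ grid anchored at 4000 cm⁻¹, all
grid points are even wavenumbers, so bands centred at odd wavenumbers
(3327, 1743, 1555) peak at the adjacent grid point; the noiseless normal
spectrum's maximum in the 1800–1700 cm⁻¹ window is at 1744 cm⁻¹, one
half-step from the 1743 cm⁻¹ band centre.

## Discrete wavelet transform

The Mallat pyramid with Daubechies filter banks, orders 1–10. Filter
coefficients were derived once by spectral factorization of the
Daubechies polynomial (minimal-phase root selection), frozen as literals
to ≥ 16 significant digits for bit-stability, and are verified in the
test-suite against the published tables carried by PyWavelets. The
analysis high-pass is the quadrature mirror hi[k] = (−1)^k lo[L−1−k];
this sign convention makes detail coefficients the negation of
PyWavelets', which affects no energy and no reconstruction.

Boundary handling:

* `symmetric` (default for spectra, which are not periodic): half-point
  symmetric extension; level output length ⌊(n + L − 1)/2⌋.
* `periodic`: periodized transform, orthogonal for even lengths with
  exact energy conservation (Σ signal² = Σ coeff²); odd lengths are
  padded by repeating the last sample, which preserves perfect
  reconstruction but not exact energy parity. Level output length
  ⌈n/2⌉.

Both modes invert exactly (≤ 1e−8 relative, in practice machine
precision) via stored per-level lengths. Decomposition requires the
running approximation to be at least one filter length at every level;
a too-deep request errors with the maximum feasible depth.

The default wavelet is db4: a common chemometrics default, and the
pipeline's conclusions are insensitive to the order (any of db1–db10 can
be configured). No quantitative criterion for choosing among wavelet
families is implemented; the family/order is configuration, not an
optimized quantity.

## Features

The spectrum restricted to 2000–650 cm⁻¹ (676 points, closed interval so
both named boundaries are kept) is decomposed to 5 levels; details 3 and
4 are each split into two contiguous halves (earlier regions take the
extra coefficient when the length is odd — the exact published region
boundaries are not machine-readable, so a midpoint split is used and the
boundaries are configurable), and each region contributes its energy
Σc². The 4-vector is normalized to unit Euclidean norm, making features
invariant to uniform intensity scaling; min–max scaling is available as
an option. A 9-feature variant (e.g. 3 levels × 3 regions) is expressible
through the same configuration for users who want a larger input layer.
No spectrum-level normalization is applied before the transform.

## Classifier

Exemplar PNN: every training vector is a pattern-layer centre. The
Parzen window is the isotropic Gaussian kernel without its normalizing
constant (the constant is shared by all classes and cancels in the
argmax). Default summation weights w_jk = δ_jk/n_k make each output the
class-average kernel response — the kernel-density Bayes rule with equal
priors; unequal priors can be expressed through the weight matrix. Exact
score ties break toward the lowest class ordinal
(normal < early < advanced). Duplicating the training set leaves
predictions unchanged (the 1/n_k normalization absorbs it).

There is no iterative, error-driven training. The "error goal" is
interpreted as a target leave-one-out misclassification rate for
smoothing selection: σ is the first value of an ascending grid
(default 31 points, geometric from 10⁻³ to 1 — the features live on the
unit sphere, so pairwise distances are ≤ 2) whose LOO rate is ≤ 0.01;
if no value attains the goal, the LOO-minimizing value is returned with
ties toward smaller σ. The procedure is deterministic. As σ → 0 every
training point is dominated by its own kernel, so training recognition
is exactly 100% — the test-suite asserts this at
σ = 10⁻³ × the minimum inter-sample distance.

An optional k-means reduction (scipy `kmeans2`, seeded) replaces each
class's exemplars by a fixed number of prototypes, for users who want a
compact RBF-style pattern layer (e.g. four pattern nodes); it is off by
default because the exemplar form *is* the Parzen density estimate.

## Split and report

The 230/210 train/test split is stratified: per-class counts follow
class frequency with largest-remainder rounding (remainder ties toward
the lower ordinal), within-class assignment by seeded shuffle, train and
test disjoint. For the default cohort this gives 115/63/52 training and
105/57/48 test samples. The report gives the confusion matrix per
partition and the per-class recognition rate 100 · diagonal / row-sum —
the most common reading of "recognition rate" — plus overall accuracy.

## Numerical choices and degenerate inputs

Grid uniformity is checked to 1e−6 relative; non-uniform input is
rejected rather than silently resampled (an explicit `resample` does
linear interpolation). An all-zero feature vector cannot be normalized
and is an error. JCAMP-DX reading supports only the uncompressed
(X++(Y..Y)) AFFN dialect; compressed forms raise "dialect unsupported"
instead of misparsing. CSV writers emit full-precision `repr` values so
write-then-read round trips are exact.

## Problem sizes

The default study (440 spectra × 1676 points, 5-level db4, 31-point LOO
grid over 230 training vectors) runs end to end in about one second on
one CPU; the full test-suite takes a few seconds. These sizes are the
study conditions themselves, not reduced surrogates.

## Known limitations

* Synthetic spectra are far cleaner than real tissue spectra; absolute
  recognition rates on the generator say nothing quantitative about
  instrument data (the early-class rate is generator-noise dependent by
  design).
* The periodized transform loses exact energy parity for odd lengths
  (padding adds energy).
* No wavelet-packet or continuous transform; no statistical comparison
  across wavelet families.
* The PNN stores all exemplars; prediction cost grows linearly with the
  training set (negligible at these sizes).
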