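# Methods

## Scope and model

`drstissue` implements a spectral classification chain for diffuse
reflectance spectroscopy (DRS) of five healthy tissue types, together with
a synthetic data generator that stands in for the (unavailable) measured
spectra. The chain has two feature paths feeding the same classifier
battery: a *characteristics* path built on nine physiologically motivated
spectral landmarks, and a *PCA* path using the leading 40 principal
components of the preprocessed spectra.

## Synthetic spectra

Each noiseless tissue template is

    R(λ) = scatter · B(λ) · exp(−Σ_c w_c A_c(λ))

with `B` a smooth baseline (UV roll-off centred at 260 nm times a
sigmoidal decay of relative depth 0.65 centred near 650 nm, width 50–70 nm
by tissue) and `A_c` Gaussian chromophore bands. Band centres/widths (nm):
protein 280/14, hemoglobin Soret 410/8 and 432/9, hemoglobin β 540/10 and
α 575/8, lipid 934/9, water 968/11. The lipid and water bands sit at their
in-tissue positions (a few nm off the textbook solvent values) so that
every template exhibits three *distinct* derivative zeros in the
lipid/water region — minimum ≈ 934 nm, inter-band maximum ≈ 951 nm,
water valley ≈ 968 nm — inside the landmark search windows; likewise the
secondary Soret band at 432 nm provides the 436 nm derivative zero. This
placement was verified numerically for all five default profiles and then
frozen.

Per-tissue band weights encode the qualitative contrasts of tissue optics
(fat lipid-rich; muscle and bone hemoglobin-rich; water present in every
tissue) and are chosen distinct enough that classes are separable at the
default noise level.

Measurement artifacts follow the hierarchy of the emulated campaign
(5 tissues × 10 specimens × 2 samples/specimen × 16 points/sample ×
4 measurements/point = 6400 spectra):

| effect | level | default | unit |
|---|---|---|---|
| log-normal gain | specimen | σ = 0.08 | relative |
| log-normal gain | sample | σ = 0.06 | relative |
| log-normal gain | point | σ = 0.04 | relative |
| linear trend | sample | σ = 2·10⁻⁴ | intensity/nm |
| integer grid shift | sample | σ = 1.2 (clipped ±8) | 0.5 nm steps |
| white noise | measurement | σ = 0.01 | intensity |

Gains multiply, so nested units share their ancestors' effects; one master
seed spawns one substream per hierarchy unit (`numpy` `SeedSequence`), so
datasets are bit-reproducible. No quantitative noise figures exist for the
emulated campaign; the defaults are set at the low end of typical relative
repeatability for controlled ex vivo reflectance work, under the stated
design requirement that the end-to-end pipeline separates the default
classes (PCA+LDA ≥ 0.95, gradients+kNN ≥ 0.85). They were checked once
against that requirement and not tuned further.

**What the generator does not emulate:** instrument response and
stray-light structure, wavelength-dependent noise (detector noise grows
toward the UV/NIR ends in real CCD spectrometers), intra-class biological
heterogeneity beyond log-normal gains (e.g. variable blood perfusion
changing band *shapes*), specular contamination, and any covariance
between chromophores. Passing tests therefore demonstrate the correctness
and internal consistency of the pipeline, not field performance on real
tissue; the near-perfect synthetic accuracies should be read as an upper
bound that real data will not reach.

## Preprocessing

Order: normalize → detrend → renormalize → Savitzky–Golay → align.

* **Normalization** subtracts the mean and scales to unit *sample* SD
  (n−1 denominator; a convention choice, configurable in spirit via the
  code path). Constant spectra are rejected ("zero variance").
* **Detrend** removes the per-spectrum least-squares straight line in λ;
  because detrending perturbs the SD, the residual is rescaled to unit SD
  (`renormalize_after_detrend`, default on) so downstream stages see
  unit-variance spectra. `detrend_deviation` reports the mean absolute
  deviation from the line, the scalar used to quantify residual trend.
* **Savitzky–Golay** defaults to window 11 (5.5 nm) and polyorder 3 —
  wide enough to suppress white noise, narrow enough to leave the ~8–15 nm
  bands unmoved (peak positions shift < 1 grid step). Edges use a
  polynomial fit to the terminal window, so any global polynomial of
  degree ≤ 3 is reproduced exactly at *all* points; mirror padding was
  rejected because it breaks this fixed-point property at the edges.
* **Alignment** is icoshift-style: the grid is split into contiguous
  segments (default 1), and each spectrum's segment is shifted by the
  integer lag (≤ 10 steps = 5 nm) maximizing the *cosine-normalized*
  correlation with the reference segment (default reference: set mean).
  Plain dot-product scoring was rejected: with edge-replicated shifting it
  can strictly prefer a nonzero lag even for a spectrum identical to the
  reference (replicated large-magnitude edges inflate the score), whereas
  the normalized score is maximal at lag 0 for an in-register spectrum.
  Score ties resolve to the smallest |lag|. Note that alignment to the
  *mean* of a multi-class set shifts each class systematically toward the
  grand mean; this is harmless for classification (shifts are consistent
  within class) but means alignment is not a per-spectrum no-op.

## Landmarks and gradients

The nine landmarks: minima at 410, 540, 575 nm; maxima in 450–540 and
545–570 nm; derivative zeros at 436 nm, in 940–970 nm (anchored at the
970 nm water valley), at 934 nm and at 958 nm. Single-wavelength entries
search nominal ± 10 nm ("vicinity" width, a choice). Minima/maxima are
window argmin/argmax; derivative zeros are sign changes of the
central-difference derivative, position linearly interpolated at the
crossing, candidate closest to the nominal wavelength chosen. Because the
three water-region windows overlap, landmarks claim crossings uniquely:
a later landmark takes the nearest *unclaimed* candidate, and the
no-crossing fallback (window extremum of |derivative|, `found=False`)
avoids claimed grid points. This guarantees nine distinct wavelengths, so
pair slopes are always defined; on noiseless templates the behaviour is
identical to independent per-landmark search.

Gradients are `g[i][j] = (v_j − v_i)/|λ_j − λ_i|`, the full ordered-pair
9×9 matrix flattened row-major to 81 named features — the only
construction from nine points matching that count. The absolute
wavelength difference makes the matrix antisymmetric (`g[i][j] = −g[j][i]`)
with a zero diagonal; diagonal features carry F = 0 and are never
selected. Wavelengths are the *detected* per-spectrum positions, not the
nominal ones.

Feature ranking uses the one-way ANOVA F ratio
`F = [SSB/(K−1)]/[SSW/(N−K)]` across the five classes, computed on the
full dataset (ranking is part of feature construction, as in the emulated
analysis, not refit per split). Zero within-class variance with nonzero
between-class spread yields a +inf sentinel that ranks above all finite
values; ties break toward the smaller feature index. The top 14 features
are retained by default.

## PCA

Components are the leading eigenvectors of the 1/(N−1) sample covariance.
For D ≤ N the symmetric eigendecomposition of the D×D covariance is used
(the LAPACK divide-and-conquer SVD took ~90 s on the rank-degenerate
noiseless 6400×1761 matrix; `eigh` takes ~1 s and is the contract
anyway); for N < D the SVD of the centered matrix is used. Sign
convention: each component's largest-magnitude entry is positive.
`explained_similarity` is the cumulative explained-variance ratio; it is
reported for information (≈ 0.79 for one component, ≈ 0.97 for 40 on
default synthetic data) but is not an acceptance quantity, since the
"similarity" notion it approximates is not precisely defined. Default
M = 40 for the classification path.

## Classifiers

All five are implemented natively (scikit-learn appears only as an
independent cross-check in tests):

* **LDA**: pooled within-class covariance with *MLE* (1/n) normalization —
  chosen so that replicating the training set leaves the model exactly
  unchanged (sufficient statistics); decisions are invariant to the
  overall covariance scale, so this is a pure convention. Ridge
  ε = 10⁻⁶ × mean diagonal (floored) guards near-singular covariances from
  small training fractions of 40-D scores.
* **QDA**: per-class sample covariances (n−1), same ridge; quadratic
  log-discriminants via `slogdet` and explicit Mahalanobis terms.
* **Naive Bayes**: per-feature class-conditional normals, variance floor
  10⁻⁹.
* **kNN**: Euclidean, default k = 5 (no value is prescribed anywhere;
  k = 5 is the common small odd default). Ties break by smaller mean
  neighbor distance within tied classes, then class order.
* **CART**: greedy binary splits minimizing Gini impurity, thresholds at
  midpoints of consecutive distinct values, stopping at depth 20 /
  min-leaf 5 / purity. The described criterion "maximization of the
  p-value of the predictor" is not implementable as stated (a p-value is
  maximized by the *least* informative split); an optional `chi2`
  criterion maximizing the split's chi-square statistic — the sensible
  reading — is provided.

**Protocol**: one fifth of the spectra train, four fifths test, stratified
by class; R = 20 independent splits by default (mean accuracy ± sample
SD). Default stratification unit is the spectrum, reproducing the
emulated protocol; because the four measurements of a point are nearly
identical, spectrum-level splitting leaks sample identity between train
and test, so a `unit="sample"` grouping (no physical sample on both
sides) is offered, and an `aggregate_measurements` option averages the
four measurements per point first. The test-set size implied by the
published confusion matrices (row totals 280+232+280+304+216 = 1312)
matches neither 4/5 of 6400 nor 4/5 of 1600, so the original aggregation
is unknowable; the package takes no position on it.

## Evaluation conventions

Rows of the confusion matrix are true classes, columns predictions, in
fixed order (fat, skin, nerve, bone, muscle). Sensitivity is per-class
recall. The quantity tabulated as "specificity" is per-class *precision*
(diagonal over column sum): this is forced by the published numbers — in
the PCA-path matrix the fat column gives 279/284 = 0.982 → the printed
0.98, whereas the true-negative rate rounds to 1.00. The TNR is available
under its correct name. Averages are support-weighted (weights = row
totals), the unique convention reproducing the published 0.83 average
specificity (unweighted macro precision gives 0.84); it also makes
average sensitivity ≡ accuracy, an identity the tests assert on random
matrices. Table reproduction rounds half-up; a cell passes if the
recomputed value rounds to the published one or differs from it by less
than one unit in the last printed digit — the published accuracies are
means over repeated splits (0.818 ± 0.036 / 0.993 ± 0.005), so the
single-matrix ratios (0.8186, 0.9939) legitimately sit within one
rounding unit rather than rounding exactly.

## Numerical and degenerate-input choices

* Constant spectra: normalization errors out; landmark detection returns
  all `found=False` via the fallback path (an identically zero derivative
  has no sign change and is not treated as a crossing).
* Reflectance wavelengths where |Ref − B| < 10⁻¹² are NaN and flagged.
* Noiseless datasets: every spectrum of a class is identical; ridge floors
  keep LDA/QDA solvable, the ANOVA +inf sentinel keeps ranking total, and
  both paths classify perfectly — asserted as an acceptance property.
* All randomness flows from explicit seeds; derived stream seeds stay
  below 2³¹.

## Problem sizes used in checks

The acceptance script and end-to-end tests run the full default design
(6400 spectra × 1761 wavelengths) for both feature paths, with 5 (script)
or 2–3 (tests) split repetitions — enough for a stable mean at the
observed split-to-split SD (< 0.001). Oracle-equivalence checks run on
small random instances (≤ 60 × 10) where brute-force computation is
exact.
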