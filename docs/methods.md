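# Methods

## Signal model

A multispectral acquisition is L = 4 co-registered 2-D images, one per
excitation:emission filter pair (465:540, 465:580, 535:600, 570:620 nm;
30 nm excitation and 20 nm emission passbands). After dividing channel i by
its excitation-light correction factor fᵢ (NFE correction), the pixel
vector is modeled as a noiseless linear mixture

    y(x) = A(x)·a + D(x)·d,

where a and d are unit-norm endmember spectra (tissue autofluorescence and
the DsRed reporter) and A, D ≥ 0 are their per-pixel abundances. Unmixing
solves the per-pixel unconstrained least-squares problem with the
Moore–Penrose pseudo-inverse of S = [a d]; the pseudo-inverse is computed by
SVD (rank-revealing, stable for near-collinear spectra) while the
normal-equations formula (SᵀS)⁻¹Sᵀ serves as the independent oracle in the
tests. Negative coefficients are retained at this stage; unconstrained
least squares is the primary mode because it is linear (so abundance maps
inherit the linearity of the imaging model) and unbiased, with non-negative
least squares available for comparison (`nonneg=True`).

## Reference spectra

The autofluorescence reference is the ROI-mean spectrum of a pre-injection
(day 0) image, scaled to unit Euclidean norm. Unit-norm columns make
abundances from different sessions comparable and make the library's
condition number meaningful; the convention is ours, as acquisition
protocols leave it unspecified.

The reporter reference comes from a tumor-containing ROI with the
background removed. Two removal modes exist:

- **direct** (default): subtract the *unscaled* day-0 mean spectrum of the
  same ROI. When the autofluorescence field is stable between the two
  acquisitions, the subtraction cancels the background contribution exactly
  and recovers the true reporter spectrum — direction and all.
- **projection**: remove the component parallel to the unit background
  vector, d_raw = m − (m·â)â. The output is orthogonal to â by
  construction. Because real reporter and background spectra overlap, this
  tilts the recovered vector away from the true reporter by 90° − θ (θ the
  a–d angle) and rescales downstream abundances by sin θ. It is therefore
  *not* the default; it remains available for data without a matched
  background ROI, and its orthogonality property is tested in that mode.

A tumor ROI whose residual after background removal is at the numerical
noise floor is rejected as an unusable reference.

## Thresholding and quantification

The published procedure thresholds the DsRed map but states no rule. The
pipeline derives τ from each animal's own tumor-free day-0 DsRed map:
τ = mean + k·sd (sd with denominator n−1, default k = 3). This makes the
threshold self-contained, reproducible, and adaptive to the noise level; a
fixed user τ is also accepted. "Above threshold" is strict (abundance > τ),
so τ = 0 excludes exact-zero background. Tumor burden is the sum of
above-threshold DsRed abundance; negative masked values (impossible with a
positive τ) are clipped to zero with a warning so totals are non-negative.

Longitudinal series are reported relative to day 0 as per-animal ratios
R(t) = T(t)/max(T(0), ε), with ε > 0 guarding a zero pre-treatment baseline
(guard use is flagged with a warning); a difference mode T(t) − T(0) is
configurable. Whether a published "relative to day 0" denominator means the
day-0 post-injection signal or a pre-injection background is generally
ambiguous; the default here is the literal day-0 measurement, and the
simulator provides a separate pre-injection image so that the day-0
denominator is a real (nonzero) inoculum signal. Missing animal-days
(sacrifice rule) are absent measurements, never zeros; group mean ± SEM uses
the animals present that day.

## Statistics

Two independent groups of 5 animals sit deep in exact-test territory, so
the default comparison is the exact Wilcoxon rank-sum test: midranks for
ties, null distribution enumerated over all C(n₁+n₂, n₁) assignments
(cached per rank multiset), two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
Enumeration is the default up to n₁+n₂ = 12 tie-free observations; beyond
that a tie-corrected normal approximation with continuity correction takes
over. The exact signed-rank test (all 2ⁿ sign patterns, n ≤ 15, zeros
dropped by Wilcoxon's rule or kept by Pratt's) covers paired designs, and
the paired t-test covers cell-line replicate experiments. Some reports name
the "signed-rank" test for independent group comparisons; since that test
presumes pairing, the pipeline defaults to rank-sum for groups and keeps
signed-rank available, implementing both conventions.

Per-day p-values are reported without multiple-testing correction (matching
field practice for daily growth monitoring); an AUC mode collapses each
animal's curve to one number and runs a single test instead.

## Synthetic phantoms and cohorts

The generator emulates the measurement chain exactly as modeled:
radiance = (A·a + D·d)·f per channel, so NFE correction inverts synthesis
identically in the noiseless case. Defaults, chosen once as a realistic
stated world:

- Image 128×128; autofluorescence field = base 1.0 plus 6 Gaussian bumps
  (amplitude 0.25–0.75, width 10–40 px) — smooth, strictly positive,
  anatomically fixed per animal across days.
- Tumor: Gaussian inclusion, σ = 8 px, peak abundance 5 at unit burden,
  centered in the upper-middle of the image (interscapular injection site).
- True spectra: autofluorescence decaying across emission channels,
  reporter peaked in the 570:620 channel. These are plausible shapes shipped
  as editable configuration — no measured spectra are published for this
  system, and the defaults are not presented as such. A minimum spectral
  angle (15°) guards against accidentally collinear configurations.
- Noise: Poisson photon counting with gain 10⁵ counts per radiance unit
  (IVIS-class images are high-count; at signal levels of order 1 this gives
  per-channel relative noise of a few tenths of a percent, a deliberately
  clean-instrument regime). The gain was fixed from this SNR argument
  before any acceptance measurement. Additive Gaussian noise and a
  noise-free mode are available.
- Cohort: 5 animals per group, imaging days 0–7, dosing day 2 (or 2/4/6);
  B₀ lognormal (median 1, σ_log 0.3), growth rate lognormal (median ln 2
  per day — a daily doubling, aggressive but plausible for a transplantable
  plasmacytoma — σ_log 0.15); treatment multiplies the rate by ρ ∈ [0, 1]
  from the first dose onward, piecewise-exponentially, without compounding
  across repeat doses. No quantitative growth or effect-size values are
  readable from published growth curves, so these are simulator choices,
  not estimates. An optional burden cap emulates the sacrifice rule by
  truncating later measurements.

What a green phantom test does establish: the pipeline inverts its own
forward model exactly without noise, stays within a few percent of truth
under the stated counting noise, and its exact tests have their nominal
discrete level. What it does not establish: robustness to model violations
real data bring — mouse pose changes between days, spatially varying
excitation, more than two fluorophores, scattering/depth effects, or
misdrawn ROIs. The simulator deliberately omits anatomy, PSF and
pharmacokinetics.

## Numerical choices

- Pixel coordinates are (row, col), 0-based, origin top-left; ROIs are
  explicit coordinate sets (CSV-serializable, rectangle/disk helpers).
- NaN/infinite pixels abort loading rather than being masked: silent
  masking would shift ROI means invisibly.
- Library condition number above 10⁴ warns (noise amplification) but does
  not error; rank deficiency errors.
- Exact-test p-values compare doubled midranks as integers, so tie halves
  never hit floating-point equality issues.
- Type-I calibration of the 5+5 exact test targets its attainable discrete
  level 8/252 ≈ 0.032, not nominal 0.05: the discrete test is conservative
  by construction. In effect-detection checks, rejection-rate monotonicity
  is asserted from the first imaging day the dose can influence (dose day
  + 1); pre-dose days are exact-null by design, so their rates are checked
  for consistency with the null band rather than for sampled monotonicity,
  which would compare pure noise.
- End-to-end determinism: all randomness flows through
  `numpy.random.default_rng(seed)`; manifests record SHA-256 checksums so
  reruns are verifiable byte-for-byte. On-disk stacks are float32 (the
  conventional interchange precision), so disk round trips agree with
  in-memory analysis to ~10⁻⁷ relative rather than exactly.

## Known limitations

- Excitation-light correction is a per-channel scalar; a spatial
  correction field would be a straightforward extension but is not
  implemented.
- No inter-day registration: totals are position-independent, but any
  pose-dependent autofluorescence change between reference and measurement
  days biases the direct background subtraction.
- The two-endmember model is the tested configuration; K > 2 works
  mathematically but has no validated defaults here.
- Thresholds derived from a day-0 control assume the control shares the
  acquisition settings of the measurement images.
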