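# Methods

This note records the models behind `mwfp`, the parameter choices that
matter, and what the synthetic studies do and do not demonstrate.

## Signal model and peak processing

A chromatogram is a detector trace on a strictly increasing uniform time
grid (minutes).  Non-uniform grids are rejected rather than resampled:
fusion and trapezoidal integration both assume a shared grid, and silent
resampling would hide acquisition problems.

**Baseline.**  The baseline is a rolling minimum over a window
(default 1.5 min) smoothed by a moving average of the same window, then
subtracted.  The window must be much wider than a peak (≈ 0.3 min at the
default peak σ of 0.05 min) so peaks are not eaten, and much shorter
than the drift period (default 18 min) so drift is followed.  Corrected
intensities may dip slightly below zero at noise level; that is expected.

**Detection and integration.**  Apexes are local maxima above a height
threshold with topographic prominence above a prominence threshold
(defaults 0.5 and 0.3 response units — several hundred standard
deviations above the default noise floor of 0.02, and far below the
smallest designed peak height of ≈ 15).  Integration is valley-to-valley:
the boundary on each side of an apex is the intensity minimum of the
interval towards the neighbouring apex or trace end.  A literal
"nearest local minimum" rule degenerates under any noise (every noise
dip is a local minimum), so the minimum is taken over the whole
inter-apex interval instead; the search is additionally capped at
`max_halfwidth` (default 0.6 min = 12 σ) from the apex, because
integrating an isolated peak across many minutes of residual baseline
accumulates bias that would otherwise dominate the few-percent level of
everything downstream.

**Matching.**  Detected peaks are pooled over samples, sorted by apex
retention time, and grouped greedily: an apex joins the current group
while it is within `rt_tolerance` (default 0.2 min, ≈ 4 σ) of the
group's running mean *or* of the most recently added apex.  The chaining
clause tolerates gradual retention drift across a batch sequence; the
price is that a dense run of apexes spaced below the tolerance merges
into one group, which is why detection thresholds must stay above the
noise floor.  If one sample contributes several peaks to a group, their
areas are summed, so matching conserves area.  Groups present in every
sample (presence fraction 1.0) form the co-possessing peak matrix on
which everything downstream operates.

## Fusion

The fused profile is the point-wise sum of a sample's single-wavelength
traces (optionally weighted; default weights are all 1 because the
projection of a time × wavelength surface along the wavelength axis is
an unweighted sum).  Fusion happens at the signal level, *before* peak
detection, so a compound invisible at one wavelength still produces a
single coherent fused peak.  Fusion is linear and channel-order
invariant, and for an isolated baseline-free peak the fused area equals
the sum of the single-channel areas up to integration tolerance.

## ALQFM similarity and grading

With sample vector x, reference y (strictly positive) and ratios
r = x/y over n shared peaks:

* Sm = (S_cos + S_prof)/2, where S_cos is the cosine between x and y
  and S_prof = Σ min(pᵢ, qᵢ) over the area fractions — both scale-free,
  so Sm measures agreement of the *profile*;
* Pm = 100·mean(r), a linear overall-content measure in percent;
* α = sd(r)/mean(r) (n−1 denominator, the analytical-chemistry
  convention), the relative dispersion of per-peak content ratios.

Sm and α are invariant to rescaling x; Pm scales linearly.  Sm = 1 and
α = 0 hold exactly when x is proportional to y.

**Grades.**  Each parameter is rated by the smallest grade (1–7) whose
threshold it meets — Sm ≥ {0.95, 0.90, 0.85, 0.80, 0.70, 0.60, 0.50},
Pm ∈ {[95,105], [90,110], [80,120], [75,125], [70,130], [60,140],
[50,150]}, α ≤ {0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50} — grade 8
otherwise; band boundaries are inclusive, and the returned grade is the
worst of the three ratings.  Worst-of-three is the only monotone
combination consistent with the bundled published report, which the rule
reproduces for 26 of its 32 rows; the six exceptions (S4, S8, S9, S13,
S17, S18) are printed one grade worse than any reading of the threshold
table applied to their own printed parameters and are treated as
irreproducible (software internals or typesetting).  The published
grade-8 α cell reads "> 0.05", an evident slip for "> 0.50": otherwise
grades 2–7 would be unreachable for α in (0.05, 0.50].

**References.**  The similarity report scores each sample against the
column-mean reference of its channel (the fingerprint-software
convention).  The *origin-discrimination* stage instead designates a
benchmark sample (default: the batch of median total fused area) and
scores everyone against it.  This distinction is essential, not
cosmetic: against the grand mean of a two-group study, both groups
deviate symmetrically — the Pm bands are symmetric around 100 and α is
scale-free — so grades cannot separate the groups by construction.
Against a single benchmark batch, samples of the benchmark's origin
differ from it only by batch noise (low α), while samples of the other
origin show a heterogeneous ratio pattern (high α) and a shifted Pm;
the grade then separates the origins, which also matches the structure
of the published per-batch report (its sample-size-weighted mean Pm is
≈ 80, not 100, so its reference cannot have been the grand mean).  The
*median*-total batch is used rather than the most concentrated one
because an extreme benchmark pushes every other sample's Pm far from
100 and the quantitative band drowns the grade.

## Chemometrics

* **HCA** — agglomerative clustering where the distance between clusters
  is the mean of all pairwise squared Euclidean distances
  (between-groups/average linkage), updated exactly via Lance–Williams;
  ties break on the smallest node-index pair, so results are
  deterministic.  The pipeline normalises fingerprint rows to relative
  areas (unit total) and autoscales columns before clustering: overall
  batch strength otherwise dominates the distances and the 2-cluster cut
  isolates concentration outliers instead of origins.
* **PCA** — SVD of the centred (optionally autoscaled) matrix;
  orthonormal loadings with a deterministic sign convention
  (largest-magnitude element positive); explained-variance fractions
  against the total variance.
* **OPLS-DA** — classes encoded ±1 and centred.  Per orthogonal round:
  w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, w_orth ∝ p − (wᵀp)w,
  t_orth = X w_orth, and X is deflated by t_orth p_orthᵀ.  The final
  predictive component comes from the deflated X; R²Y is the variance of
  y explained by regressing y on the predictive score.  By construction
  the predictive score is orthogonal to every orthogonal score.  One
  orthogonal component is the default (the number used in practice is
  rarely reported; one is the common choice for a two-class model).
  With zero orthogonal components the model reduces exactly to
  one-component PLS.
* **VIP** — computed from the predictive component only (the usual
  OPLS-DA reporting convention; a "VIP-total" including orthogonal
  variation is deliberately not implemented).  With one predictive
  component VIP_j = √p·|w_j| for unit-norm w, so mean(VIP²) = 1 exactly
  and VIP > 1 marks above-average influence.

Scaling for PCA/OPLS-DA defaults to unit variance (autoscaling), the
chemometrics-package convention; centring-only is available.

## Quantitation

Calibration lines are ordinary least squares with R² and an
LOD = 3.3·σ_resid/slope (ICH convention); non-positive slopes and
degenerate designs are rejected.  Solution concentrations convert to
contents via content = conc × V/m with the 0.500 g / 20 mL extraction
(factor 40).  Summary statistics are the arithmetic mean and
RSD% = 100·sd(n−1)/mean — the n−1 convention reproduces the bundled
panel's printed RSD row to the printed precision.  Origin differences
use Welch's two-sample t-test (unequal group sizes and variances; the
original analysis does not name its test).

## Synthetic studies

The generator emulates the design of the real study: 15 + 17 batches of
two origins, three detection wavelengths, a 0–55 min gradient window on
a 0.01 min grid, and a 33-compound library matching the study's
co-possessing peak count.

* **Peaks** are Gaussians (σ = 0.05 min) with area = content ×
  response factor; retention times are separated by > 6 σ and jittered
  per (sample, compound) with sd 0.02 min, shared across wavelengths as
  a diode-array detector would.  Tailing/fronting asymmetry is
  deliberately omitted.
* **Spectral classes**: saponin-like compounds respond at 203 nm only
  (saponins lack a UV chromophore above the low-UV region), flavonoid-
  like at 270 and 325 nm, amino-acid-like at 270 nm.  The three
  single-wavelength matrices therefore see 23, 10 and 5 of the 33
  peaks — each blind to part of the signal the fused matrix sees whole.
* **Contents** are log-normal: origin mean × a per-batch global strength
  factor (CV 10%, shared by all compounds — extraction efficiency and
  overall plant vigour) × an idiosyncratic per-compound factor (CV 8%).
  For the five named saponins the origin means are computed from the
  bundled content panel; with these dispersions the pooled per-compound
  RSD lands in the panel's printed 19–28% range.
* **Origin effects**: the four named saponins whose panel contents
  differ between origins (G-Rb1, G-Rg1, G-Rd lower in Yunnan, NG-R2
  higher; NG-R1 shows no panel difference and carries none), seven
  unnamed saponin-like compounds at a declared Yunnan/Sichuan factor of
  0.72, and the two flavonoids (factor 1.67) and two amino acids
  (factor 1.45) higher in Yunnan — 15 discriminating compounds in all.
  The unnamed effect sizes are generator configuration, declared once;
  they are not literature values.
* **Noise**: white Gaussian (sd 0.02) plus a positive sinusoidal drift
  (amplitude 0.5, period 18 min, random phase per trace).

Retention times for NG-R1 and NG-R2 (17.2 and 23.2 min) are plausible
synthetic placements — the qualitative analysis of the real study does
not list them; the other named compounds sit at their reported times.

**What passing tests show — and don't.**  The synthetic studies verify
that the pipeline's machinery is correct and that, *under the designed
conditions* (class-separated spectral responses, the declared effect
sizes, well-resolved Gaussian peaks), fusion demonstrably beats any
single channel and VIP recovers the injected discriminators.  They do
not show that real chromatograms — with co-eluting peaks, nonlinear
detector response, inter-run drift and matrix effects — would behave as
cleanly, and the published per-batch similarity parameters themselves
cannot be reproduced without the raw instrument data, which is not
deposited.  The published tables are therefore checked only at the
levels the printed numbers support: summary statistics, the grade rule,
and the grade/origin confusion counts.

## Numerical choices and degenerate inputs

* Grid uniformity tolerance 1e-6 relative; fusion requires grids equal
  to the same tolerance and never resamples.
* Grade-band comparisons use an absolute epsilon of 1e-12 so printed
  boundary values (e.g. Pm = 70.0) rate inclusively.
* sd uses the n−1 denominator throughout.
* Zero-variance columns make autoscaling fail loudly, naming the column.
* Empty peak lists are valid detection output; a matching run in which
  no group satisfies the presence rule raises an error suggesting a
  larger tolerance.
* HCA/OPLS-DA require two groups with ≥ 2 members each; single-channel
  studies skip fusion with a logged warning but are otherwise analysed.

## Problem sizes

Default study: 32 samples × 3 channels × 5 501 grid points; a full
pipeline run (simulation included) takes well under a second, and the
20-seed robustness sweeps in the test suite a few seconds.

## Known limitations

Overlapping-peak deconvolution, retention alignment beyond tolerance
matching (no dynamic time warping), multi-wavelength surfaces beyond
three discrete channels, cross-validated component selection for
OPLS-DA (Q², CV-ANOVA, permutation tests) and figure rendering are out
of scope; the heat-map helper returns the reordered scaled matrix and
leaves plotting to the caller.
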