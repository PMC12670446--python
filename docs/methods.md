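# Methods

## The problem

Quantifying how far an individual's facial shape lies along the spectrum
between an unaffected (normative) population and a dysmorphic phenotype —
and whether a treatment moves it back — requires (i) a shape coordinate
system free of pose, size and bilateral-asymmetry nuisance, (ii) a
direction in that space that encodes the phenotype after removing age and
sex effects, and (iii) statistics appropriate for a very small
longitudinal treated cohort referenced against large cross-sectional
control cohorts. morphoscore implements that pipeline for dense homologous
3D landmark configurations and validates every stage against a synthetic
cohort with known ground truth.

## Shape coordinates

**Centroid size** is the root summed squared distance of a configuration's
landmarks to their centroid; all configurations are scaled to unit size, so
downstream coordinates are dimensionless.

**Symmetrization.** Each scan is averaged with its mirror image (reflection
about x = 0 followed by left/right label swapping) after ordinary
Procrustes superimposition of the mirrored copy onto the original. A
single align-and-average step is not an exact projection onto the
bilaterally symmetric subspace: alignment and averaging do not commute,
leaving a residual that is second order in the asymmetry. The step is
therefore iterated to its fixed point (convergence is quadratic;
tolerance 1e-12 of centroid size, at most 30 rounds, typically 4–5).
The result is exactly idempotent to numerical precision and is itself
symmetric. The pair is aligned to each other, not to a grand consensus;
for the small asymmetries typical of faces the two conventions differ
negligibly, and the pairwise form keeps symmetrization a per-scan
operation.

**Generalized Procrustes analysis.** All scans are centered, scaled to
unit centroid size, and iteratively rotated to the running consensus (the
mean shape, re-centered and rescaled to unit size each round) until the
consensus RMS movement falls below 1e-8 or 100 iterations. Because every
configuration is held at unit size, the per-scan similarity alignment
reduces to a proper rotation; improper rotations (reflections) are never
allowed, so an asymmetric shape cannot silently match its mirror image —
bilateral structure is handled only by the label-aware reflection.
Non-convergence sets a flag rather than raising. No projection to
Procrustes tangent space is applied before PCA; within-species facial
shape variation is small enough that the curvature correction is
numerically minor, and the omission is deliberate and documented rather
than silent.

## Shape space

PCA is fitted to the flattened aligned coordinates of the pooled sample
(normative, affected, and treated scans together), centered on the sample
mean, via SVD; eigenvalues use the n−1 convention. The number of retained
components is chosen by Horn-style **parallel analysis**: components are
kept while their eigenvalue exceeds the 95th percentile (configurable) of
eigenvalues of reference data at the same rank, with 100 reference
draws. The default reference permutes each variable independently across
samples, preserving every marginal distribution; a Gaussian reference
with matched per-variable SDs is also available. Retention is the largest
m such that all of components 1..m pass, and at least one component is
always retained for downstream scoring.

## Phenotype axis and scores

For the control scans only (treated scans are excluded from this fit,
though they participate in the pooled PCA), each retained PC score is
regressed by OLS on an intercept, centered age, age², age³, sex (0/1) and
a group indicator (0 = normative, 1 = affected). Age is centered at the
pooled control mean before powers; raw centered polynomials are used
rather than an orthogonal basis, with centering providing the numerical
guard. The vector **v** of group coefficients across PCs spans the
age/sex-adjusted normative and affected means.

A scan's residual r is its PC score minus the model prediction for a
*normative* individual of the same age and sex. The raw projection is
(r·v)/‖v‖ and the normalized score (r·v)/‖v‖². The double division by
‖v‖ fixes the scale: the normative mean scores 0 and the full
normative-to-affected mean displacement scores exactly 1. Because the
axis is fitted and the controls scored in the same sample, the in-sample
mean scores of the normative and affected control groups are exactly 0
and 1 — a least-squares identity, not an approximation. Scores are
additionally expressed in SDs of the affected-control distribution, and,
when the affected controls show a significant linear score-on-age trend
(OLS, threshold alpha = 0.05), treated scores are residualized with the
control-estimated slope before longitudinal modeling; otherwise they pass
through unchanged and the non-significant test is reported.

**Per-vertex fields.** At landmark j, with d_j the scan's displacement
from the predicted normative shape and v_j the local axis direction, the
vertex score is (d_j·v_j)/‖v_j‖², zeroed where ‖v_j‖ ≤ ε‖v‖/√k
(ε = 1e-3) to avoid division blow-up where the axis has no local signal.
Since the aligned data lie in the span of the PCA basis and v does too,
the ‖v_j‖²-weighted mean of vertex scores equals the global normalized
score exactly — the heatmap is a spatial decomposition of the score, and
the identity is asserted for every scan in the test suite. Change maps
are last-minus-first fields; negative values mean movement toward
normative.

## Inference

**Paired Hotelling's T².** First-vs-last visit differences on the leading
p PC axes give T² = n·d̄ᵀS⁻¹d̄ (S the sample covariance of differences,
n−1 denominator, no shrinkage) and F = (n−p)/(p(n−1))·T² under F(p, n−p).
The caller caps p; with 14 pairs at most 13 axes can be tested, producing
the characteristic F(13, 1) reference. With p = 1 the statistic reduces
exactly to the squared paired t.

**Longitudinal mixed model.** Treated scores are modeled as
score ~ protocol + time + protocol:time with a random intercept per
individual, fitted by maximum likelihood. Protocol is a binary indicator
of the placebo-first regimen; time is years from first dose, retained as
negative for pre-dose placebo scans. The time effect is tested by a
likelihood-ratio χ² (df = 1) against the same ML fit with the time main
effect deleted (single-term deletion; deleting main effect plus
interaction together, df = 2, is available by flag because the printed
χ²/df convention does not disambiguate the two). Per-term LRTs for
protocol and the interaction are reported the same way. The ML fit uses
a profiled likelihood: for a fixed variance ratio θ = σ²_b/σ² the GLS
coefficients and σ² are closed-form (per-subject blocks of I + θZZᵀ
invert analytically), leaving a 1-D bounded optimization over log θ with
the θ = 0 boundary checked explicitly. This costs microseconds per fit,
which the calibration simulations (thousands of replicate fits) rely on;
agreement with statsmodels' MixedLM (ML) is verified in the test suite
to ~1e-6 in coefficients and log-likelihood. A residual quadratic-form
floor of 1e-14·(yᵀy + 1) keeps degenerate zero-residual fits finite.
When no subject has repeated observations the random intercept is
unidentifiable and the model falls back to OLS with a flag.

## Synthetic cohort generator

The generator emulates the statistical structure of the study design —
not facial appearance. The template is a bilaterally symmetric
half-ellipsoid point cloud (semi-axes 0.8/1.0/1.2, 10% radial jitter;
default 25 left/right pairs + 10 midline points = 60 landmarks), with the
sagittal plane fixed at x = 0 and midline landmarks exactly on it.
Homology and bilateral structure are all the analysis needs, and the
geometric template keeps the generator dependency-free and exactly
seed-reproducible.

Scans are built additively in landmark space: template + cubic-age growth
+ sex effect + group displacement (affected and treated) + per-subject
offset + slope × max(years-from-first-dose, 0) × group displacement +
i.i.d. Gaussian landmark noise, then pushed through a random similarity
transform (uniform quaternion rotation, translation in [−10, 10]³, scale
in [0.5, 2]) that the Procrustes stage must undo. Because the treatment
acts along the group axis with a time-linear coefficient, the true score
of a treated scan is exactly 1 + subject term + slope·years, matching the
mixed model's linearity assumption. Pre-dose placebo visits (first dose
one year after the first visit) carry negative time and no treatment
term.

Effect fields are distance-kernel-smoothed Gaussian noise (kernel width
0.5 template units) symmetrized under the bilateral map and normalized to
a target RMS per-landmark displacement. Crucially, the similarity
components of the field — its net translation, rotation and scaling at
the template, an up to 7-dimensional tangent subspace — are projected out
before normalization. A smooth field is otherwise dominated by
near-rigid motion, which superimposition removes by construction; without
the projection the injected "group difference" would be mostly
unrecoverable by any Procrustes-based method, not because the method
fails but because most of the injected energy was never shape change.
The similarity subspace is reflection-invariant, so the projection
preserves bilateral symmetry. Growth is modeled as three fixed smooth
symmetric unit-RMS fields scaled by scalar coefficients per power of
centered age; literal per-axis translation coefficients would be annulled
by alignment and could not represent growth-related shape change.

Default study conditions (dimensionless displacement RMS relative to a
template of ~unit radius): group effect 0.1, landmark noise SD 0.02 (the
5× signal-to-noise regime of the recovery analyses), per-subject offset
SD 0.05, sex effect 0.03, growth coefficients (0.01, 5e-4, 2e-5) per
year^p; 200 normative + 96 affected cross-sectional scans with ages
uniform on 3–20 years; 14 treated subjects × 7 visits at 0.75-year
spacing (~4.5 years of follow-up), 4 of 14 on the placebo-first protocol,
first-visit ages ~N(5, 1) years clipped below at 3; treatment slope
−0.05 score units/year. Inter-visit score variability in real data is
unknown; the landmark noise SD is the corresponding configuration choice,
not a claim about its realistic magnitude.

Because offsets and treatment act along the axis, the landmark model
reduces exactly, in score units, to a random-intercept model with
intercept SD subject_sd/(scale·√k) and residual SD noise_sd/(scale·√k);
`simulate_treated_scores` draws from this reduction so that
slope-recovery and type-I-error studies can run thousands of replicates
without re-running the geometric pipeline. The reduction's SDs are
cross-checked empirically against the landmark generator in the tests.

### What the generator does not emulate

Real registration error is spatially structured and scan-specific, not
i.i.d.; real faces have growth that interacts with sex and diagnosis;
real cohorts have missing visits, variable follow-up length and QC
exclusions; and the affected-group difference in life is not exactly a
single fixed field. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under its stated model, not that
real facial data satisfy that model.

## Validation summary

The test suite asserts, among others: Procrustes invariance (similarity
copies collapse to one shape-space point, < 1e-8), symmetrization fixed
point and idempotence (< 1e-10 / < 1e-8), eigenvalue trace conservation
(< 1e-10 relative), parallel-analysis recovery of a known rank under 5×
SNR (≥ 90% of seeds), exact score calibration (0 / 1 / 0 to 1e-8),
injected-axis recovery through the full pipeline (cosine ≥ 0.95 over 20
seeds), the vertex aggregation identity (< 1e-8, every scan),
Hotelling-vs-paired-t equivalence (< 1e-10) and null rejection in
[0.040, 0.060] over 2000 replicates, mixed-model slope recovery (< 10%
mean bias, 95% CI coverage in [0.91, 0.98] over 200 seeds) and null
type-I error in [0.040, 0.060] over 2000 seeds, and bitwise
reproducibility of the full study under a fixed seed. Problem sizes in
the simulations (e.g., 60-landmark templates, 100–200 scans per group)
are chosen so the whole suite runs in well under a minute while leaving
all statistical bands at their stated widths.

## Known limitations

- No tangent-space projection before PCA (documented above); for large
  shape dispersions this would matter.
- The random-intercept model has no random slopes; between-subject
  heterogeneity in treatment response is absorbed into the residual.
- Wald CIs for the time slope use the normal quantile on ML standard
  errors; with very few subjects and strong intercept variance they can
  undercover slightly (the calibration test tracks this).
- The per-vertex score formula is a local projection; it is one natural
  spatial decomposition of the global score, defined by the aggregation
  identity, not a uniquely determined quantity.
- Missing landmarks, sliding semilandmarks and weighted Procrustes are
  out of scope.
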