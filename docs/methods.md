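# Methods

## Scope and sampling unit

All inference operates on **tree-level values**: replicate measurements
(ten leaves per tree for leaf traits, five readings for soil moisture and
water potentials) are averaged per tree first. Zone contrasts (CVs,
correlation matrices, integration) pool trees from large patches only,
where the moisture gradient is expressed; this mirrors a design of 5
trees × 3 zones × 4 patches with two large patches pooled to n = 10
trees per zone. Water potentials are stored as positive magnitudes of
−ψ (MPa), so larger stored values mean drier trees.

## Hydraulics

Flow is the least-squares slope of cumulative balance mass against time
over a stable window. Window selection: slide a window of at least
`window_s` (default 180 s, matching the practice of reading flow once it
has been approximately constant for ≥ 3 min) across the log; among
windows whose linear fit reaches R² ≥ 0.99, choose the one with the
smallest coefficient of variation of the first differences, breaking
ties toward the latest window (flow settles over time). If no window
reaches the threshold, the globally most stable window is returned with
an `unstable` flag rather than an error, so noisy field logs still yield
a diagnosable number.

Conductivity is K_h = F·L/ΔP — flux divided by the pressure *gradient*
ΔP/L — with units kg m s⁻¹ MPa⁻¹, and K_s = K_h/A (kg m⁻¹ s⁻¹ MPa⁻¹).
Published unit strings for K_h sometimes repeat the K_s units; they are
dimensionally inconsistent with the verbal definition, and this package
follows the definition. Gravity is taken as g = 9.8 m s⁻² so a 1 m head
is exactly 9.8 kPa (0.0098 MPa), the convention used with 1 m reservoir
columns. PLC = (K_max − K_s)/K_max is reported as a fraction; negative
values (native conductivity above the flushed maximum — measurement
noise) are returned with a warning flag, never clamped, so downstream
summaries can decide how to treat them.

## CV comparison

CV = SD/mean with the n−1 divisor, defined only for positive-mean
samples of n ≥ 2. The two-sample test uses T_D = |CV_x − CV_y|,
V_D = the variance of T_D across B replicates resampling both groups
independently with replacement at their original sizes, and
Z_D = T_D/√V_D, with B = 10,000 by default.

**Null construction.** The published description of this statistic does
not fully specify how the null replicates Z*_b are generated. Two
constructions were evaluated by simulation (lognormal samples, equal CV
0.2, n = 10 per group, 1000 simulations, B = 500):

- *Centered single-level bootstrap-t*, Z*_b = |T*_b − T_D|/√V_D from the
  same first-level resamples: rejection rate **0.242** at nominal 0.05.
  The folded statistic T_D is not pivotal near zero (its bootstrap
  distribution is folded-normal shaped), so recentring does not produce
  a null distribution.
- *Pooled studentized bootstrap-t* (the default): both groups are
  resampled from the pooled mean-normalised sample (CV is scale
  invariant, so dividing each sample by its mean aligns the groups
  without changing either CV — under the null of equal shape the pooled
  values are a draw from the common normalised distribution), and each
  replicate recomputes the complete statistic: its own T*_b and its own
  inner bootstrap variance V*_b (B_inner = 50), giving Z*_b = T*_b/√V*_b.
  Rejection rate **0.045** at CV 0.2 and 0.041 at CV 0.5; null p-values
  uniform (KS distance 0.04); power 0.30/0.75 at CV ratios 2/4 with
  n = 10.

p = (1 + #{Z*_b ≥ Z_D})/(B + 1); the add-one convention keeps p > 0
under either reading of the ambiguous printed formula. The centered
variant remains available (`null_method="centered"`) for comparison but
should not be used for inference.

Pairwise zone tests use Bonferroni α/npairs (0.05/3 = 0.017 for three
zones). Compact letters come from the insert-and-absorb algorithm over
the significance graph, processed in canonical zone order
(windward, core, leeward), so two zones share a letter exactly when
their pairwise test is non-significant at the adjusted level.

## Integration

Correlation matrices are pairwise-complete Pearson correlations of
**log-transformed** tree means (minimum 3 complete pairs per trait
pair); log transformation matches the bootstrap CI, which resamples the
log-transformed data, and keeps the estimator consistent with the
generator (below). A raw-scale option exists as a flag.

INT is the sample variance (k−1 divisor) of the matrix's eigenvalues.
Because the eigenvalues of any correlation matrix average exactly 1,
INT = 2·Σ_{i<j} r²ᵢⱼ/(k−1); both routes are computed and asserted to
agree within 1e-10. The k−1 divisor is fixed by consistency with the
reference values this package reproduces (the leeward matrix gives 1.87,
rounding to the published 1.9; the k divisor would give 1.50). The CI is
the 2.5/97.5 percentile interval over B resamples of trees; degenerate
replicates (a constant trait after resampling) are skipped and counted,
with an error if more than 10% are skipped. Percentile rather than BCa:
the reference analysis states only that the CI was obtained by
bootstrapping, and the percentile interval is the assumption-lightest
choice; measured coverage on synthetic data (n = 50, 500 simulations,
B = 500) is 92%.

Matrix similarity is the Pearson correlation between the two vectors of
k(k−1)/2 off-diagonal coefficients — this element-wise index reproduces
the published between-zone values to within one rounding unit, which is
why it was adopted over Mantel-style alternatives. The p-value permutes
the trait labels of one matrix, two-sided on |index|; with k ≤ 7 all k!
relabellings are enumerated (identity included), so for five traits p is
a multiple of 1/120. Larger k falls back to Monte Carlo with the
(1+count)/(n+1) convention.

## Synthetic data

The generator states a world and samples it: per zone, tree-level trait
vectors come from a Gaussian copula with lognormal marginals. On the log
scale, each trait has σ_log = √ln(1+CV²) and the configured correlation
matrix; exponentiating with μ_log = ln(mean) − σ²_log/2 makes the
marginal mean exact. Lognormal marginals guarantee positivity (all
modelled traits are positive magnitudes) and mean that the *log-scale*
correlation equals the target exactly in population; raw-scale Pearson
correlations differ slightly, which is documented and harmless because
the integration stage also works on logs. Replicates scatter around each
tree value with a within-tree CV (default 0.1 — the replicate-level
spread is not reported in the source tables, so this is an explicit
fixture choice, not an estimate).

Seeding: one master seed; each (patch, zone) derives an independent
stream from `SeedSequence([master, crc32(patch_id), zone_index,
purpose])`, so adding a patch never perturbs another patch's draws and
output is bit-identical for a fixed config.

The bundled `fray_jorge_like.yaml` encodes the published large-patch
zone means, per-zone CVs and per-zone correlation matrices as a
realistic default world. Soil-moisture and water-potential CVs are not
published; 0.25 is used as a realistic field-scale value. Small patches
reuse core-like values for the leeward zone, mirroring the weaker
differentiation observed there. These defaults are paper-derived
fixtures, not ground truth: a green test against this world establishes
that the estimators recover the parameters of the stated generating
process (means within 2%, CVs within 10%, log-scale correlations within
±0.05 at n = 2000, INT within ±0.15 at n = 1000), not that any field
claim is true. The generator has no fog-interception physics, no spatial
autocorrelation, no temporal dynamics and no tree mortality.

Non-positive-definite target correlations raise an error naming the
opt-in repair (`repair=True`), which clips eigenvalues at 1e-8 and
renormalises the diagonal.

## Numerical and degenerate-input choices

- CV of a constant sample is 0; a CV test where both samples are
  constant raises a degenerate-test error (V_D = 0).
- R² of a perfect or constant-mass fit is defined as 1, so noiseless
  logs select cleanly.
- Correlation of a constant trait raises an error naming the trait.
- Zero-CV traits are drawn as exact constants and excluded from the
  copula (their log-scale variance is 0).
- All bootstrap/permutation seeds are recorded in result objects and the
  run manifest; identical seeds reproduce identical p-values and CIs.

## Known limitations

- The CV test's pooled null assumes the two groups share a distribution
  shape up to scale under H0; strong shape differences with equal CVs
  are outside its calibration.
- Integration CIs at n = 10 per zone are wide and percentile coverage
  degrades below n ≈ 20; the reference design's per-zone CIs should be
  read qualitatively.
- The similarity permutation test conditions on the observed matrices;
  it does not propagate the sampling error of the correlations
  themselves.
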