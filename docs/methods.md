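# Methods

## Model and procedure

The package validates a correlation-matrix PCA. The input is an n×p matrix
`X` of n objects on p variables (n ≥ 3, p ≥ 2, no missing values; the
intended regime is n of a few dozen, p ~ 10, n > p). Columns are
standardized to mean 0 and sample SD 1 (n−1 denominator throughout, so that
`Σ = D²/(n−1)` is exactly the correlation-matrix spectrum). The SVD
`X = U D Vᵀ` yields loadings `V` (p×p, orthonormal columns), scores
`Z = X V = U D`, and eigenvalues `σ_j² = λ_j²/(n−1)` that sum to p.

Explained variance is computed on the eigenvalues,
`100·Σ_{j≤m} σ_j² / Σ_j σ_j²`. (A formulation summing the singular values
themselves is sometimes written; only the eigenvalue form is consistent
with a trace-10 correlation spectrum whose leading pair 8.42/0.74 explains
91.6% in two dimensions, so that form is used everywhere.)

The partial bootstrap draws R row-resamples of size n with replacement.
For **score validation**, each replicate is re-standardized with its *own*
column means/SDs and its rows are projected as supplementary points onto
the first m original loading columns; the stacked nR×m cloud is tagged by
origin object. For **dimensionality**, each re-standardized replicate gets
its own SVD and contributes one nonincreasing row of replicate eigenvalues.
Retention rule: m* = 1 + the number of leading consecutive ranks k with
`min(σ*_k) − max(σ*_{k+1}) > 0` (bands at trim level 0 by default;
percentile bands at a user α can be substituted). When no pair separates,
m* = 1. Note a consequence worth knowing: any data set with one dominant
factor separates rank 1 from rank 2 and therefore yields m* = 2, never 1 —
the criterion retains up to and including the first rank whose band touches
the next. This is the rule as published and is implemented verbatim.

Confidence polygons are convex hulls of each object's cloud restricted to
the first two dimensions. Area uses the shoelace sum of consecutive 2×2
determinants, halved, in absolute value (invariant to winding and cyclic
rotation; hulls are emitted counter-clockwise). Centroids use the standard
signed-area-weighted formula; with |S| < 1e-12 the vertex mean is returned
and the polygon flagged degenerate. Collinear clouds degrade to flagged
zero-area segments rather than raising. Polygon overlap (flag +
intersection area) is delegated to shapely.

Centroid validation builds two average-linkage (UPGMA, Euclidean)
dendrograms — original scores vs polygon centroids — and compares the
partitions obtained by cutting each tree at the midpoint of its largest
merge-height gap (a labeled heuristic; published analyses cut by
inspection). Agreement is the plain Rand index from pair counting.

## EEG feature front-end

Raw single-channel series (assumed µV; log10 features shift additively
under unit rescaling) are band-pass filtered 1–40 Hz with a 4th-order
Butterworth applied forward-reverse (zero phase; stopband attenuation
doubles in dB), segmented into consecutive non-overlapping 1-second
zero-mean epochs (at most 150 kept, in temporal order; recordings with
fewer than a configured minimum are excluded together with the subject's
other condition, keeping the design balanced). The Bartlett averaged
periodogram (rectangular window, one-sided density normalization; Parseval
holds to machine precision; 1 Hz resolution at 400 Hz/1 s) yields per-band
features with edges inclusive on both sides — a peak exactly at 8 Hz
belongs to theta and alpha alike, so their maxima coincide there. Band
power is the trapezoidal integral over peak ± 1 Hz clipped to the band
(half-width configurable; ±1 Hz is the smallest symmetric window the 1 Hz
resolution supports). Time-domain features per epoch: RMS, SD (n−1),
moment skewness g1 = m3/m2^1.5 (the adjusted Fisher–Pearson variant is
available), and peak-to-peak range; the across-epoch median of each is
reported. Artifact rejection, when enabled, is a deliberately simple
amplitude-threshold rule (reject an epoch if any sample deviates more than
k·SD from the series mean) — a labeled, non-faithful stand-in for dedicated
EEG artifact methodology, off by default.

## Synthetic generators: what they emulate, what they do not

The feature-matrix generator draws `x_j = w_j f + w2_j g + s_j e_j` with
unit-variance latents and `s_j = sqrt(1 − w_j² − w2_j²)`, then copies two
columns exactly (alpha_max := alpha_power, sd := rms), emulating the
redundancies of spectral/time EEG features. With equal loadings the
population correlation is equicorrelated, so a target first-eigenvalue
fraction t maps to loadings via `ρ = (pt − 1)/(p − 1)` and
`λ1 = 1 + (p−1)ρ`; the default t = 0.84 reproduces a leading eigenvalue
near 8.4 of trace 10. The two-factor variant adds a weak contrast factor
(+ on the two beta columns, − on the two theta columns) with
`4·0.185 ≈ 0.74` as its population eigenvalue, mirroring the classical
"overall amplitude + beta-vs-theta contrast" structure; under the
non-overlap rule it yields m* = 2. An optional condition shift on `f`
plants two clusters for end-to-end clustering checks. Per-subject
substreams (seeded `(seed, subject)`) make rows stable when subjects are
added.

The EEG generator sums 1/f-power background noise with an alpha oscillation
(subject-specific peak uniform in 8–13 Hz; probability 1/24 of sitting
exactly at the 8 Hz boundary, emulating boundary-peak subjects), weaker
beta and theta tones, and a slow alpha envelope. Eyes-closed ("A") alpha
amplitude ~18 µV vs ~7 µV open, giving alpha blocking. A shared per-subject
lognormal amplitude scale (SD 0.45 on the log) couples all
amplitude-dependent features; a small quadratic waveform asymmetry whose
coefficient rides the same latent couples skewness to them. Resulting
pairwise Spearman correlations are all positive at n = 48, but the
skewness pairs typically sit near 0.2–0.4 — weaker than the ≥ 0.6 seen in
real occipital data, because waveform-level asymmetry survives filtering
and epoching only partially. Passing tests therefore demonstrate the
machinery on data with the right *sign and shape* of dependence, not a
physiologically calibrated copy; absolute log-power levels likewise depend
on the PSD normalization and are not matched to any published table.

## Numerical choices

- SVD sign fixing: each loading column is flipped so its largest-magnitude
  entry is positive (deterministic, comparison-stable); degenerate
  eigenvalue ties keep the LAPACK ordering and are non-identifiable.
- Percentile CI convention: 1-based order statistics at `ceil(R·α/2)` and
  `R − ceil(R·α/2) + 1` (25th/976th at R = 1000, α = 0.05); α = 0 returns
  the min/max range.
- α-trimming of clouds: convex-hull peeling — delete the current hull's
  vertices while at least `ceil((1−α)M)` points would remain — chosen as a
  standard nonparametric bivariate trim with no distributional assumption;
  Mahalanobis-distance trimming is available behind a switch.
- Replicates in which resampling makes a column constant (impossible for
  continuous data in practice) are dropped and logged, reducing the
  effective R, rather than patched.
- Resampling uses one substream per replicate (`(seed, r)`), so any single
  replicate can be regenerated in isolation and extending R preserves
  existing replicates.
- UPGMA is delegated to scipy's linkage; merge-tie behavior is scipy's
  (deterministic). Newick branch lengths are parent-height minus
  child-height, making the tree ultrametric.
- When m* = 1 the pipeline still builds 2-D polygons (m = 2) and reports
  m* separately — polygons need a plane.

## Problem sizes

Default study conditions are 24 subjects × 2 conditions (48 rows), 10
variables, R = 1000, matching the intended application scale; the test
suite uses R = 100–200 and 155-second synthetic recordings, sizes chosen so
the full suite runs in well under a minute while keeping every Monte-Carlo
band loose relative to its estimator noise.

## Known limitations

- Polygons are 2-D only; higher-dimensional polytopes are out of scope.
- The non-overlap criterion is R-sensitive at the band extremes (min/max of
  more replicates is wider); the percentile-band option mitigates this.
- The generator's Spearman floor (see above) and its stylized 1/f-plus-tones
  waveform are not substitutes for recorded EEG.
- Covariance-matrix (unstandardized) PCA is not offered; the pipeline is
  correlation-based by design.
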