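# Methods

This note records the scientific model behind `contrafc`, the parameters
that matter, the design choices made where the method description left the
design open, and the known limits of what the synthetic validation shows.

## Analysis model

**Connectivity.** Each scan contributes one ROI x ROI Pearson correlation
matrix, computed over the concatenated retained frames of all runs of that
scan (two 200-frame runs at TR = 2.07 s by default). Raw Pearson r is used
throughout; no Fisher z-transform is applied anywhere, because the
downstream statistic correlates matrix entries directly and a monotone
transform would change its value. Per-run matrices averaged afterwards are
*not* used: concatenation weights every retained frame equally and matches
the acquisition of several runs feeding a single analysis.

**Contralesional restriction.** All statistics are computed on the
principal submatrix of the hemisphere opposite the lesion (150 of 300 ROIs
for the default parcellation). Hemisphere membership is the sign of the
RAS x-coordinate; ROIs exactly on the midline are a hard error at load time
(optionally dropped with `midline="drop"`), because the truncation assumes
a clean left/right split and silent assignment would hide atlas
mismatches. Cerebellar ROIs follow the same x-sign rule; no
crossed-laterality remapping is applied.

**Pre/post similarity.** For each subject the 2-D correlation coefficient
`c` — the Pearson correlation of corresponding entries of the pre- and
post-operative matrices — is computed for the whole hemispheric matrix and
for each analyzed network's principal submatrix. The default `full` mode
sums over every entry, including the unit diagonal and both triangles of
the symmetric matrix, which is the literal definition of the statistic.
Because the shared diagonal inflates similarity between correlation
matrices (on average; there are individual counterexamples), an `offdiag`
mode is provided as a documented sensitivity option. Networks need at
least 3 ROIs in the hemisphere to be scored: a 2 x 2 correlation submatrix
has a single distinct off-diagonal value, so its full-mode coefficient is
identically 1 regardless of the data. ROIs of the three less
well-characterised communities (striatal-orbitofrontal-amygdalar, medial
temporal lobe) and unlabeled ROIs receive no per-network score but remain
inside the hemisphere-level comparison.

**Group comparison.** The group-wise coefficient `G_y` is the arithmetic
mean of `c_{x,y}` over the subjects of one surgery group. Groups are
compared with a Welch unequal-variance t-test at Welch–Satterthwaite
degrees of freedom, one-tailed with the fixed alternative that the
minimally invasive group is *more* similar (configurable via
`alternative=`). No multiple-testing correction is applied across the 11
network comparisons by default — the hemisphere-level test is the primary
analysis and the per-network tests are exploratory — but a Holm adjustment
is available behind a flag. Baseline categorical covariates use the
two-tailed Fisher exact test with the point-probability rule (sum of all
tables, at fixed margins, no more probable than the observed one); this
rule reproduces published contingency statistics exactly and is what
`scipy.stats.fisher_exact` implements.

**Scan-pair selection.** When a subject has several post-operative scans,
the most recent is analysed (the longest interval after surgery, also
minimising transient blood-brain-barrier effects on the BOLD signal after
thermal ablation); date ties break on the lexicographically smallest scan
identifier so the pipeline is deterministic.

## Preprocessing

Stage order is fixed: low-pass filter → nuisance regression → frame
censoring → run QC.

- **Low-pass, < 0.1 Hz retained.** The filter applies the squared
  magnitude response of an order-4 Butterworth,
  `|H(f)|² = 1 / (1 + (f/f_c)^(2·order))`, in the frequency domain. This
  has the identical gain profile to forward–backward (filtfilt)
  application of the same Butterworth, zero phase by construction, and
  exact DC preservation, but none of the edge-state transients of
  recursive filtering, which at 400-frame run lengths otherwise dominate
  the stop-band residual. The realization is a package design choice; the
  order and cutoff are configurable. Reapplying the filter is not an exact
  identity (no Butterworth-response filter is a projection), but content
  well inside the passband changes by < 1 % of the fluctuation amplitude.
- **Nuisance regression.** Design: intercept, whole-brain global signal
  (per-frame mean over all ROIs), then any external waveforms (stand-ins
  for CSF / white-matter / motion regressors). Coefficients are fit by OLS
  on retained frames only; fitted values are subtracted from every frame
  so censor masks remain applicable. A numerically null global signal —
  exactly what remains after a previous global regression, by projection
  geometry — is dropped rather than allowed to make the design singular.
- **Frame censoring.** Frame *t* (t ≥ 1) is censored when the RMS over
  ROIs of the backward difference exceeds 0.5 % of the run's grand RMS
  intensity — a DVARS-style criterion restated at ROI level, since the
  voxelwise definition needs volumetric data. The statistic is computed on
  the raw (pre-filter, pre-regression) input by default
  (`censor_on="raw"`), where motion artifact is sharpest; the grand-RMS
  normalisation is only meaningful on data that still carries its baseline
  intensity. Frame 0 is never censored by this rule and no neighbour
  augmentation is applied. A single-frame spike necessarily censors two
  frames — the spike and the recovery frame — because both backward
  differences are large.
- **Run QC.** A run fails when its censored fraction exceeds 0.5. The
  quantitative exclusion rule is this package's stand-in (the method
  description's exclusion criterion is not fully specified);
  `max_censored_fraction` is configurable. A failed run drops the whole
  subject, with the reason and the censored fractions logged.

## Synthetic cohort

The generator emulates the *statistical* structure the analysis assumes,
not the physics of BOLD acquisition.

- **Covariance.** ROIs correlate at `rho_within = 0.5` inside a network
  (networks mirrored across hemispheres, so homotopic pairs of the same
  network also correlate at `rho_within`) and `rho_between = 0.05`
  elsewhere; unlabeled ROIs carry only `rho_between`. These defaults put
  hemisphere-level pre/post similarity in the 0.74–0.80 range and small
  networks near 0.97 at study-scale frame counts — the range a real
  test-retest comparison of correlation matrices occupies. Per-hemisphere
  network sizes default to the canonical parcellation counts
  (SDN 17, SLN 3, CON 8, AN 6, DMN 31, PMN 3, VN 19, FPN 15, SN 8, VAN 5,
  DAN 7; 28 unlabeled), 150 ROIs per hemisphere.
- **Disruption.** Surgical impact on network *y* is a covariance-space
  mixture: the post-operative correlation block becomes
  `(1−δ)·block + δ·R` with `R` a random correlation matrix (normalised
  Wishart, k+2 df). Acting on covariance rather than on time series makes
  the ground-truth disruption magnitude exactly parameterised, so
  recovery claims have a known answer. Mixing a principal block can in
  principle break positive semidefiniteness; the result is checked
  (Cholesky) and projected to the nearest correlation-normalised PSD
  matrix when needed, with the projection flagged. The default cohort
  disrupts four networks (SDN, FPN, SN, DAN) at δ = 0.6 in the craniotomy
  group and δ = 0.2 in the LITT group, 12 subjects per group.
- **Signal scale.** Frames are i.i.d. draws from N(0, Σ) scaled by
  `noise_scale = 0.2` a.u. on a `baseline = 100` a.u. mean intensity
  (0.2 % fluctuations — ROI-averaged BOLD fluctuates less than single
  voxels), plus a shared 0.005 Hz sinusoidal drift of amplitude 1 a.u.
  (removed by the global regressor, as in real data), plus whole-brain
  spike frames at rate 0.02 offset by 10 % of the grand RMS (far above
  the 0.5 % censor threshold, while normal frame-to-frame changes,
  `√2·0.2 ≈ 0.28` a.u., stay below the ≈ 0.5 a.u. threshold). These
  scales were fixed once from the censoring arithmetic.
- **What the generator does not model.** Temporal autocorrelation of the
  BOLD signal (frames are white before drift addition; the low-pass stage
  induces smoothness regardless), hemodynamic response, physiological
  (cardiac/respiratory) noise, spatially structured motion, registration
  error, and any volumetric effect. Passing the validation studies
  therefore shows that the *pipeline* is correct and calibrated for data
  satisfying its assumptions — not that real scans satisfy them.

## Validation studies

All studies run the full pipeline (preprocessing included) on replicate
synthetic cohorts, seeded deterministically.

- **Type-I calibration.** Both groups get identical disruption (δ = 0.4 on
  the four default networks); across 200 replicate cohorts the
  hemisphere-level one-tailed Welch p is close to uniform and the
  rejection rate at α = 0.05 falls in [0.03, 0.07].
- **Dose response.** Mean hemisphere similarity over 50 subjects per level
  decreases strictly across δ ∈ {0, 0.25, 0.5, 0.75, 1} (≈ 0.81 → 0.27 at
  default scan lengths).
- **Power.** With δ = 0.6 vs 0.2 and 1,000 frames per scan, the pipeline
  reports the less-disrupted group as more similar with p < 0.05 in well
  over 80 % of 100 replicates.

Problem sizes (200/100/50 replicates, default frame counts) are the
package's chosen validation scale; they keep the full suite in the
minutes range on a single CPU while leaving the binomial uncertainty of
the estimated rates well inside the asserted bands.

## Numerical choices

- Correlation matrices are symmetrized (`(C+Cᵀ)/2`), clipped to [−1, 1],
  and get an exact unit diagonal; a constant ROI series is a hard error
  (detected with a relative tolerance of 1e-12 on the column std), never a
  silent NaN.
- `corr2` clips to [−1, 1] against rounding and raises on a constant
  summed region (zero denominator) rather than returning NaN.
- Matrix square roots for simulation use Cholesky with a 1e-12 jitter,
  falling back to an eigendecomposition square root for semidefinite
  matrices.
- Welch t, its Satterthwaite df and p come from `scipy.stats.ttest_ind`;
  the test suite checks them against a numerically integrated t-density
  written from first principles, and checks `scipy`'s Fisher exact
  against exhaustive hypergeometric enumeration.
- All output tables are written with a fixed float format, so repeated
  runs on identical inputs are byte-identical.

## Known limitations

- The ROI-level censoring statistic is a proxy for the voxelwise
  criterion; on real extractions the two can flag different frames.
- The one-tailed alternative is fixed by design (minimally invasive group
  more similar); users testing a different hypothesis must flip
  `alternative` explicitly.
- Group comparisons assume one score per subject per network; longitudinal
  designs with several post-operative scans per subject are reduced to a
  single pair by the most-recent-scan rule rather than modelled.
- The 2-D correlation treats matrix entries as exchangeable observations;
  it inherits the diagonal-inflation issue (mitigated by `offdiag` mode)
  and ignores the dependence between entries sharing an ROI.
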