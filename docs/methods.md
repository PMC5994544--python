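# Methods

`metabostrat` re-implements, end to end, a plasma untargeted-metabolomics
stratification analysis for primary progressive multiple sclerosis (PPMS):
peak-table preprocessing, exact-mass annotation, PLS-DA/VIP marker
discovery validated by repeated splits and label-shuffling permutations,
paired longitudinal testing, and pathway over-representation with
topology impact. The patient-level data behind the original study are
access-restricted, so the package ships a synthetic-cohort generator
whose defaults emulate the published study conditions; every statistical
guarantee the test suite asserts is a property of the method evaluated on
those synthetic conditions, not a reproduction of patient results.

## The synthetic study (module `simdata`)

**Intensity model.** Peak heights are log-normal. On the natural-log
scale a biological sample's channel is

    log x_ij = mu_j + batch_bj + h_i + delta_j * 1[case_i] + eps_ij

with `mu_j` the peak's base log-abundance (N(11.5, 1)); `batch_bj` a
per-batch, per-peak run-day offset (SD 0.10); `h_i` a per-sample
multiplicative handling effect shared by all channels of the sample
including internal standards (CV 15%); `delta_j = log2FC_j * ln 2` the
designed case shift; and `eps_ij` biological noise. Effects are injected
as shifts of the log-mean, i.e. of the median on the raw scale, which is
robust to the distribution's heavy right tail.

**Study conditions.** Defaults mirror the published design: cross-
sectional cohorts of 13+13 (exploration), 20+20 (validation), 10+10
(RRMS) and 40+20 (Parkinson's disease); 534 annotated analyte peaks plus
5 internal-standard channels; 20 designed markers whose log2 fold
changes are the reported panel values (−0.07 … −0.55); per-batch pooled
QC replicates carrying technical noise only (CV 6%, keeping the median
QC RSD below the study's 10% acceptance bound); solvent blanks carrying
5% of peaks at biological level and the rest near zero; and a
longitudinal arm of 15 subjects sampled at 0, 12 and 24 months with one
designed declining marker (expected baseline/24-month ratio 1.84).

**Calibration of marker noise.** Each published marker row prints a
log2 fold change, a raw Welch p-value, and the group size, which
together pin down the per-group SD that reproduces the printed t
statistic: `sigma = |FC| * sqrt(2/n) / t_quantile`. The generator uses
the mean of the two cohorts' implied SDs per marker, so simulating at
the default effect sizes reproduces the panel's reported univariate
statistics in expectation. Two consequences are worth stating plainly.
First, the implied per-marker CVs are small (1–8%), lower than typical
inter-individual plasma-metabolomics variation; the printed table is
internally consistent only with this dispersion, and the generator
follows the table. Second, twenty jointly informative markers at these
signal-to-noise ratios make the synthetic cohorts close to perfectly
separable by a multivariate model (repeated-split mean AUC ≈ 1.0),
whereas the study reported mean AUCs of 0.73–0.79. The gap is expected:
the generator draws marker noise independently per metabolite, while
real plasma panels are strongly correlated (13 of the 20 markers are
glycerophospholipids), which lowers the effective dimensionality of the
real signal. Passing tests therefore demonstrate correctness and
calibration of the machinery, not the discriminative performance
attainable on patients. Non-marker peaks use a global biological CV of
30%, a mid-range value for untargeted plasma features; after
autoscaling, their absolute CV does not affect any downstream statistic.

**Determinism.** One master seed drives everything. Peak-universe
attributes (masses, base abundances, marker positions, blank subsets)
derive from the master seed alone, so all cohorts share a peak panel;
each cohort and the longitudinal arm draw samples from fixed-offset
substreams (`default_rng([seed, crc32(label)])`). Identical
configurations write byte-identical fixture files. When the marker count
equals the bundled 20-metabolite panel, marker peaks carry the panel's
reported neutral masses, so exact-mass annotation recovers their
identities; designed markers are never drawn as blank contaminants.

**Not modeled.** Missing values (off by default; an optional
missing-at-random mask exists), m/z drift, retention times, correlated
metabolite families, chromatographic artifacts, and raw spectra.

## Preprocessing (module `preprocess`)

* **Minimum intensity** (default threshold 2000 instrument units): a
  peak is kept iff its maximum over biological samples reaches the
  threshold — the "detected anywhere" semantics of common peak-filtering
  tools. The filter is idempotent and threshold 0 is the identity.
* **Blank filter**: a peak is excluded iff *every* biological group's
  median is strictly below the blank median (conservative ALL
  quantifier; ANY is available as a switch since the original rule's
  quantifier is ambiguous). Tables without blanks raise rather than
  silently skipping.
* **Internal-standard normalization**: all arithmetic on the log scale.
  `single_is_ratio` divides by the geometric mean of the IS channels;
  `nomis` removes, per analyte, the least-squares projection onto the
  centered log-IS panel; `ccmn` first residualizes the IS panel against
  the biological group factor so designed group differences cannot be
  removed through IS channels that happen to correlate with class. Both
  regression schemes are log-scale least-squares residualizations — the
  contract (remove IS-predictable technical variance, keep biology)
  rather than the original publications' full derivations. Corrections
  are estimated on and applied to biological and QC injections; blanks
  carry no working-level internal standards and are left untouched.
* **Batch alignment**: per selected peak, each batch receives the
  additive log-offset that equalizes its QC mean with the grand QC mean
  (multiplicative on the raw scale, preserving positivity). Restricting
  the peak list (e.g. to a marker panel) leaves other peaks bit-identical.

## Chemometrics (module `chemometrics`)

**PLS-DA.** Class labels are dummy-coded {0, 1} and centered; X is
autoscaled (zero mean, unit ddof-1 variance; constant columns raise and
are dropped by callers). Components follow the NIPALS sequence — weight
`w ∝ X'y` (unit norm), scores `t = Xw`, loadings `p = X't/t't`,
y-loading `c = y't/t't`, rank-one deflation of X and y. With a single
binary response each component converges in one step, so no iteration
tolerance is exercised (the 1e-10/500-iteration guard matters only for
multi-response extensions). Regression coefficients
`b = W (P'W)^{-1} c` reproduce fitted responses from autoscaled X;
prediction applies the *training* centers/spreads. Score vectors are
mutually orthogonal by construction; R²X/R²Y per component come from
the deflation residuals and are nondecreasing in the component count.
The implementation is checked in the test suite against
scikit-learn's `PLSRegression` (same NIPALS family) to 1e-10; the
library is used only as an independent oracle, never as the engine.

**VIP.** `VIP_j = sqrt(p * Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` over
components `a ≤ h`, where `SSY_a = c_a² t_a't_a` is the y-variance
captured by component a. The mean of squared VIP over variables is
exactly 1, which the suite asserts to 1e-8 on every fitted model. Both
the cumulative-through-h scores and single-component profiles are
exposed. Marker *selection* uses the cumulative scores for h = 1 and
h = 2: the PLS toolchains used in this field report one VIP column per
component count, each cumulative through that component, and a
published four-column VIP table (components 1 and 2 in two cohorts) is
only reproducible under that reading. Single-component VIP was tried
and rejected: once a model's first component captures the class axis,
the markers' deflated residuals are near zero and their component-2
profile carries no signal, so a per-component rule cannot reproducibly
re-select true markers.

**Metrics.** AUC is Mann–Whitney pair counting with ties counted ½
(computed via rank sums; verified against brute-force pair enumeration
on all short score vectors). PPV/NPV/accuracy are evaluated at a
response threshold of 0.5, the midpoint of the dummy coding; PPV/NPV
are NaN when no sample is called on the respective side and are
excluded from summary means. Q²(cum) = 1 − PRESS/SS over stratified
7-fold cross-validation with refitting (folds are reduced when a class
is smaller than the fold count; folds seeded).

## Validation statistics (module `validate`)

* **Repeated splits**: 100 stratified 70/30 train/test splits;
  autoscaling is estimated on the training part only; per-metric means
  carry t-based 95% CIs. Stratification is mandatory — unstratified
  30% test sets at n = 13/group can be single-class.
* **Permutation nulls**: `p = (1 + #{null ≥ observed}) / (B + 1)`, the
  standard bias-avoiding estimator, exact under exchangeability; B
  defaults to 100 and is configurable. The two-cohort marker-overlap
  statistic shuffles labels independently within each cohort and
  re-runs the full selection. For null calibration tests, labels are
  shuffled anew each iteration; a single fixed shuffle retains chance
  dataset-level association at these sample sizes and is not a
  calibrated null.
* **Marker selection**: a variable is a marker iff cumulative VIP ≥ 1
  through components 1 and 2 in *both* cohort models and its univariate
  AUC ≥ 0.60. The univariate AUC is direction-free (max(AUC, 1−AUC))
  on the pooled cohorts. At the study's dimensions this rule has an
  irreducible chance-concordance floor: a null peak passes both
  cohorts' VIP conditions with probability ≈1.5% and the pooled AUC
  filter about half of the time, so among ~514 null peaks a median of
  ~4–5 chance markers accompany the designed ones. This floor is a
  property of the thresholds and dimensions, not of the implementation;
  the suite documents it by asserting the designed-marker recovery
  (≥75% at 3× effects, observed 20/20) alongside the stricter
  false-marker bound, which the floor prevents.
* **Univariate**: Welch t with Welch–Satterthwaite df (zero-variance
  equal-mean columns get t = 0, p = 1 by convention), BH step-up FDR,
  percentile bootstrap AUC CIs over 500 stratified resamples, one-way
  ANOVA with Tukey–Kramer post hoc comparisons (valid at unequal n),
  paired t-tests on complete visit pairs with fold change oriented
  earlier/later (a decline reports a fold > 1), and confounder checks
  (Pearson chi-square without continuity correction for sex × group,
  ANOVA for age across cohorts, per-metabolite OLS slope on age).
  Degenerate paired differences with zero spread map to p = 0 for a
  nonzero shared shift and p = 1 for no shift.

## Annotation (module `annotate`)

Theoretical masses are neutral monoisotopic masses summed from IUPAC
atomic masses (C 12 exactly, H 1.00782503, N 14.0030740, O 15.9949146,
P 30.9737616, S 31.9720707) over C/H/N/O/P/S. Measured masses are
treated as de-adducted neutral masses — the convention under which the
published panel's printed ppm errors reproduce; electron mass is
ignored, and adduct arithmetic is out of scope. Matches within ±10 ppm
(inclusive) are all reported, ranked by absolute error; annotation is
putative, not unique assignment. Of the 20 published panel rows, 19
reproduce to within ±0.02 ppm of the printed error (printed precision
plus atomic-mass rounding); the citrulline row differs by 0.029 ppm and
is attributable to a different atomic-mass table in the original
software, so it is excluded from the golden fixtures.

## Pathways (module `pathway`)

Over-representation uses the exact upper-tail hypergeometric
probability P(X ≥ k) for k panel compounds among K pathway members,
n selected, N background, with BH-FDR across pathways; the default
background is the union of pathway members (the mapped-compound
convention), switchable to any compound universe. Pathway impact is the
share of relative betweenness centrality (normalized by
(|V|−1)(|V|−2)/2) carried by the hit compounds; graphs with fewer than
three nodes have no in-between positions and score zero. The bundled
pathway library is a hand-drawn synthetic set of six toy compound
graphs around the panel's chemistry (glycerophospholipid, linoleic
acid, arachidonic acid, tryptophan, arginine/citrulline,
creatine/creatinine); it exists for tests and worked examples and is
not a curated database, so its specific p-values carry no biological
meaning.

## Problem sizes used by the test suite

The suite runs the statistical surfaces at the sizes the analysis
design names: 100-iteration split evaluations on 20+20 cohorts with 534
peaks; marker recovery over 20 seeded replicate study pairs; 200-replicate
permutation calibration at B = 99 on compact null tables (12 peaks,
10+10 samples); longitudinal fold recovery at a 500-subject oracle
scale and detection at the study's 15 subjects over 25 replicates. The
full suite completes in well under a minute of CPU time apart from
these Monte-Carlo blocks, which take a few seconds each.

## Known limitations

* Independent-noise markers overstate multivariate separability
  relative to the correlated panels of real plasma data (see
  calibration above).
* The permutation machinery reports p ≥ 1/(B+1); the original study's
  overlap p = 0.004 from 100 shuffles is not representable on that
  grid, so B is configurable rather than guessed.
* NOMIS/CCMN are implemented as their log-linear residualization core,
  not the original publications' full estimators.
* The blank-filter quantifier and the batch-alignment scale (additive
  log vs. raw) are interpretation choices, each exposed as an option.
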