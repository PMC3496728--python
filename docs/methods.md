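# Methods

## The quantification model

qPCR reports a threshold cycle Ct, the cycle at which amplification
fluorescence crosses a fixed threshold; under ideal (100%) efficiency one Ct
unit corresponds to one doubling of starting template. Relative expression
of a target gene against a housekeeping reference on the same cDNA is

    dCt(colony, zt)  = mean over replicates of Ct_target − same for Ct_reference
    ddCt(colony, zt) = dCt(colony, zt) − calibrator(gene, colony)
    fold             = 2^(−ddCt)

Technical replicates are averaged on the Ct scale before differencing, the
standard "mean of triplicates" convention; no automatic outlier rejection is
applied because the assay design specifies triplicates but no rejection
rule. Missing reference cells are an error, never imputed. PCR-efficiency
correction (Pfaffl-style) and multi-reference normalization are out of
scope.

**Calibrator.** Two rules are supported: `mean_over_time` (default; each
(gene, colony) series is calibrated against its own across-time mean, so the
geometric mean fold over the day is 1) and `first_timepoint`. The default
matches plotting expression as deviations around a per-gene daily mean.
Because the z-scoring below is affine-invariant, the calibrator choice does
not affect any downstream statistic — only the fold column itself.

**z-scores.** Each (gene, colony) series is standardized to zero mean and
unit sample (n−1) standard deviation. The z-score is taken on the log2
relative expression scale, i.e. on −ddCt, not on the fold change: a cosine
oscillation injected on the Ct scale is exactly a cosine on −ddCt but a
distorted exponential of one on the fold scale, and "number of standard
deviations above/below the mean" statements in the field are made on the
plotted (log-linear) scale. Per-colony standardization removes colony
baseline differences before cross-colony averaging; the consensus profile
reports the per-timepoint mean z and its standard error (cross-colony sample
SD / √n).

A constant series has no spread; it standardizes to all zeros with a
warning rather than an error, so flat reference-gene checks stay usable.

## The cosinor model

Rhythmicity is modeled by the single-component cosinor with the period fixed
at τ = 24 h, appropriate for data entrained to a 12:12 light:dark cycle:

    y(t) = M + A·cos(2π(t − φ)/τ),  A ≥ 0, φ ∈ [0, 24)

M is the mesor (rhythm-adjusted mean), A the amplitude and φ the acrophase
(hour of peak). The fitted curve's peak-trough amplitude is 2A exactly.
Free-period fits and multi-component cosinors are out of scope, as are
nonparametric rhythm tests (JTK/Lomb–Scargle-style).

**Closed-form fit (`fit_ls`).** Because the model is linear in
(M, A·cosφ', A·sinφ'), ordinary least squares of y on
{1, cos(2πt/24), sin(2πt/24)} gives the exact optimum; A = √(βc² + βs²) and
φ = (24/2π)·atan2(βs, βc) mod 24. Preconditions: ≥ 4 points and ≥ 3 distinct
timepoints mod 24 (otherwise the design is singular). A constant series is
reported as A = 0, R² = 0 with a warning (the usual R² convention fails at
SST = 0). R²adj = 1 − (1 − R²)(n − 1)/(n − k − 1) with k = 2 counting the two
trigonometric regressors; with the 7-timepoint design n = 7, so
R²adj = 1.5·R² − 0.5, which reproduces every cleanly printed R²→R²adj pair
in the reference screen (0.86→0.79, 0.66→0.49, 0.46→0.19) and is negative
whenever R² < 1/3.

**Monte-Carlo fit (`fit_mc`).** The stochastic route mirrors rhythm screens
built on mass random simulation: draw many candidate parameter sets, score
each by R² against the data, and average the best `top_k` (arithmetic mean
for M, A and R²; circular mean for φ). It is bit-reproducible given its
seed. Two search modes exist:

* `search="phase"` (default): candidates are acrophases drawn uniformly on
  [0, 24); M and A given φ are set by conditional least squares (amplitude
  clamped at 0). The top-k average then converges on the closed-form
  optimum already at moderate `n_sims` — at the default 10⁵ draws / top 400
  the amplitude and R² agree with `fit_ls` to ~10⁻³.
* `search="box"`: (M, A, φ) drawn jointly and uniformly from the data-driven
  box M ∈ [min y, max y], A ∈ [0, max y − min y], φ ∈ [0, 24). This is the
  faithful model of a pure 3-parameter random search, but averaging the
  top k of n draws from a d-dimensional box understates the optimum by an
  order-statistic bias that scales like (k/n)^(2/d) in R²; at 10⁵ draws with
  k = 400 the R² bias is ≈ 0.06, vanishing (≈ 0.003) only at the ~10⁷-draw
  scale such screens historically ran. The phase-conditional default was
  chosen precisely so that desk-scale runs report unbiased fit statistics;
  the box mode is retained for fidelity studies and behaves identically as
  n_sims grows.

The default `n_sims = 100_000, top_k = 400` keeps a laptop run in
milliseconds per gene; `n_sims = 10_000_000` reproduces the historical
search scale when wanted.

**Significance (`fit_pvalue`).** The MATLAB-era procedure behind printed
cosine p-values is not specified, so the package defaults to a transparent
permutation test: shuffle the series over the sampled timepoints `n_perm`
times, refit by least squares, and report p = (1 + #{R²_perm ≥ R²_obs}) /
(n_perm + 1). This is exact under exchangeability of the null; its type-I
error at α = 0.05 measures 0.05–0.06 over 1000 simulated flat series. Ties
count toward the numerator, so on an equispaced grid a perfect cosine does
not attain the theoretical minimum p: rotations/reflections of its sampled
values are themselves perfect cosines. A parametric cosinor F-test
(`cosinor_ftest`, F = (R²/2)/((1−R²)/(n−3))) is offered as an alternative.

**Peak time.** Reported both continuously (φ) and as the sampled ZT with the
smallest circular distance to φ, ties broken toward the earlier timepoint;
a flat fit (A = 0) has no peak and reports NaN. The default grid is
ZT {2, 6, 10, 14, 18, 22, 26} — 7 points every 4 h across one day, with the
final point wrapping past the 24-h boundary; ZT values ≥ 24 are reduced
mod 24 only for phase arithmetic.

## The rhythm screen

Per gene, an additive two-way ANOVA (colony + timepoint) is fitted by OLS on
the per-colony values — z-scores by default, fold changes optionally. The
unreplicated layout (one value per colony × timepoint cell) estimates main
effects only: timepoint on (T−1) df, colony on (C−1) df, residual on
(T−1)(C−1) df. On z-scored input the colony effect is 0 by construction (the
standardization removes it); the timepoint effect is the quantity of
interest. An effect whose sum of squares is numerically zero is reported as
F = 0, p = 1 even when the residual SS is also zero.

**Classification.** A gene's oscillation is significant under

* `p_only` (default): ANOVA timepoint p ≤ 0.05 AND cosine p ≤ 0.05;
* `strict`: additionally R²adj ≥ 0.5.

Both rules are exposed because the field's own usage is inconsistent at the
boundary (a gene with R²adj = 0.49 and both p-values significant is a
different call under each); `p_only` is the default as it matches how such
screens' headline gene lists are assembled in practice. The rule is monotone
in the evidence: decreasing either p or increasing R²adj never turns a
significant call non-significant. No multiple-testing correction is applied
across genes, matching the screen this mirrors.

**Phase consistency.** Genes whose per-colony least-squares acrophases
disagree by more than 6 h (largest pairwise circular distance; flat colonies
excluded) are flagged `consistent_across_colonies = False`. The 6-h
threshold — a quarter period — is this package's operationalization of
"not consistent across nests"-style footnotes, which come with no printed
rule.

## Domain conservation

Pairwise global (Needleman–Wunsch) alignment with affine gaps under
BLOSUM62, gap open 10, gap extend 0.5, end gaps free — the EMBOSS needle
defaults, with the gap convention that an internal run of L gap columns
costs open + (L−1)·extend. Identity % is identical residue pairs over the
full alignment length (gap columns count in the denominator, the needle
convention); similarity % counts residue pairs with a positive substitution
score. A domain is conserved iff identity ≥ 40% (inclusive). Window
conservation counts identical non-gap pairs over a fixed span of alignment
columns while every column counts toward the window length. Domain
coordinates are 1-based inclusive, the biologist convention. The test suite
carries an independently written affine-gap dynamic program (itself
validated against exhaustive alignment-path enumeration on tiny instances)
as the scoring oracle. Multiple sequence alignment, domain-database lookups
and phylogenetics are out of scope.

## The synthetic-data generator

The generator emulates the study design the statistics were built for:
3 colonies × 7 timepoints every 4 h across one 12:12 LD day × triplicate
reactions, one flat EF1α reference, and targets

    Ct = baseline + colony_offset − A_ct·cos(2π(zt − φ)/24) + ε

with ε ~ N(0, 0.25 Ct) per replicate and colony offsets ~ N(0, 0.5 Ct) drawn
once per colony and shared across genes (a global template-amount shift,
which reference normalization and per-colony calibration remove). The minus
sign encodes qPCR physics: a transcript peak is a Ct trough. The default
eight-gene panel has four true oscillators at 1.0–1.6 Ct amplitude (two- to
three-fold peak/trough), two peaking at ZT 18 and two anti-phase at ZT 6,
and four flat genes. Amplitudes ≥ 1 Ct match the two-fold-and-up daily
swings clock genes show; 0.25 Ct replicate noise is a typical well-behaved
TaqMan triplicate spread.

What it does **not** emulate: pooling variance across the 12 individuals per
sample, RNA-extraction and reverse-transcription batch effects, PCR
efficiency differences between genes, amplification failures/dropout, or
gene-specific colony × time interactions. Passing the recovery tests
therefore demonstrates that the statistical chain detects the designed
effect sizes under well-behaved noise — not that every real dataset of this
shape would classify as cleanly.

Protein fixtures are random sequences over the 20-residue alphabet with an
exact number of substituted positions and no indels, so a gap-free global
alignment has a known identity count by construction (the 58-residue /
6-substitution default mirrors a 52-of-58 conserved-window structure).

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; pipeline sub-streams are derived per gene by hashing (seed, gene)
  so results do not depend on evaluation order, and derived seeds stay below
  2³¹.
* Simulation sizes in the shipped checks: 50 series for the Monte-Carlo vs
  least-squares comparison at 10⁵ draws, 200 simulated studies for recovery
  (with 2·10⁴-draw fits and 199 permutations, ample for a 0.05 threshold
  with p resolved to 0.005), 1000 series for permutation calibration, 200
  random pairs for the alignment oracle.
* Permutation p-values use the add-one estimator and count ties at a 10⁻¹²
  R² tolerance.
* Sample (n−1) standard deviations everywhere.
* Degenerate inputs fail loudly (missing cells, duplicate keys, singular
  designs, out-of-range identities) except where a defined value exists and
  is flagged by warning (constant series, single-colony aggregation).

## Known limitations

* The fixed 24-h period is assumed, not estimated; genuinely non-24-h
  rhythms would fit poorly by design.
* With 7 timepoints the permutation null has only 5040 distinct orderings
  and the equispaced grid adds symmetry ties, so the attainable p-value
  floor is coarse; n_perm beyond ~999 buys little.
* The unreplicated two-way ANOVA cannot detect colony × time interactions;
  a gene oscillating anti-phase in different colonies can pass the ANOVA
  while the phase-consistency flag is the only indicator.
* Identity/similarity percentages depend on the alignment parameters; the
  needle defaults are a convention, not a biological truth, and values near
  the 40% threshold should be read with that in mind.
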