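# Methods

## Study design being modeled

A rate-zonal density gradient separates the cells of one bacterial symbiont
population by size. Four gradient fractions, ordered by increasing cell size
and named after the size class they best represent (XS < S < M < L), plus the
unfractionated tissue homogenate, are profiled by shotgun metaproteomics
(spectral counts) in 4 biological replicates of sulfur-rich and 3 of
sulfur-depleted host specimens. Cell sizes (longest dimension) are measured
microscopically per fraction and in the homogenate; flow cytometry of
DNA-stained cells resolves two scatter populations of small and large
symbionts. The question per protein: does its relative abundance change along
the size axis XS→L?

## Size classing

Objects below 2 µm are treated as imaging artifacts and objects above 20 µm
as aggregates; both bounds are inclusive. The class boundaries are the 25th /
50th / 75th percentiles of the filtered homogenate sizes, computed with
linear interpolation between order statistics (the common "type 7"
estimator; the estimator is configurable since boundary values depend
slightly on it). Classes are left-closed, right-open intervals except L,
which closes at 20 µm — so a cell exactly at a boundary belongs to the upper
class. When one fraction has the top share for two classes it represents the
class where its share is higher; the displaced class takes its next-ranked
fraction (ties between fractions go to the fraction nearer the gradient top;
ties between classes to the smaller size class). The output records the rank
of the fraction actually used, making fallback decisions auditable.

## Count normalization

Cross-sample comparability uses median-of-ratios (RLE) size factors: the
reference for protein *i* is its geometric mean across samples, computed over
proteins detected in every sample (zeros would collapse the geometric mean);
the factor of sample *j* is the **linear-scale** median of the ratios
y_ij / r_i. Factors are rescaled to geometric mean 1 so normalized values
keep count-like magnitude (the rescaling convention is arbitrary and cancels
in all downstream ratios). Values are intentionally not length-normalized,
so a protein's trend can be traced across samples. Note DESeq2 takes the
median of *log* ratios — identical for an odd reference count, geometric vs
arithmetic central-pair mean for an even one; the package's tests exploit
the odd case to cross-check against pydeseq2 exactly.

Within-sample comparability uses NSAF computed from *unfiltered* counts:
SAF = count / protein length (aa), NSAF = SAF / ΣSAF per sample, and
%orgNSAF = 100 · SAF / Σ(same-organism SAF). %orgNSAF for an organism with
zero total counts in a sample is undefined (NaN plus an error record), not 0.

The prevalence filter (≥5 spectral counts in ≥4 of 16 S-rich, or ≥3 of 12
S-depleted, gradient-fraction samples; stricter ≥6-of-8 / ≥4-of-6 variants
for pairwise contrasts) is applied before RLE and before both significance
arms. The significance arms run on symbiont proteins only: host proteins
enter the NSAF tables and the host-enrichment contrast, but the
fraction-trend question is about symbiont cell stages, and planted
host-enriched proteins genuinely trend over fractions by construction.

## Ordered-profile significance

Per protein and replicate the profile is v_t = log2(x_t + 1) − log2(x_XS + 1)
over the ordered fractions (pseudocount 1, baseline = first fraction; both
configurable). A protein is retained when (a) the mean pairwise Pearson
correlation between its replicate profiles is ≥ 0.5 (a "minimum pairwise"
switch is provided since the consistency rule could be read either way), and
(b) the largest absolute entry of its mean profile is ≥ 0.5. A replicate
profile with zero variance fails (a).

Model profiles are all step sequences of length T−1 with unit steps in
{−c..c} (defaults c = 2, m = 50 profiles retained, the documented defaults of
the short-series clustering method this arm follows); when more than m
candidates exist, m maximally distinct ones are kept greedily under
correlation distance (seed = largest summed distance, then max-min distance,
ties by lexicographic step order). Mean profiles are assigned to the
best-correlated model profile (ties to the lowest id; zero-variance mean
profiles unassigned).

Significance: for each of the T! = 24 permutations of fraction order the
profiles are re-based to the permuted first fraction and re-assigned; the
expected count E_p of profile p is the mean over permutations. Since profiles
are differences of log abundances, the permuted profile is recoverable from
the original one (w_t = v_π(t) − v_π(0)), so the permutation null is exact,
not approximate. The observed count n_p is tested with the binomial tail
P(X ≥ n_p), X ~ Bin(N, E_p/N), BH-corrected across profiles at FDR 0.05 —
BH rather than a family-wise correction because the procedure controls a
false discovery rate. All proteins assigned to a significant profile form
the profile-significant set; significant profiles are additionally grouped
at pairwise correlation ≥ 0.5 (connected components).

## Random-forest stability selection

Forests of T trees classify the 16 (or 12) fraction samples into the 4 size
classes (or one of the 6 pairwise class contrasts) from normalized protein
abundances. F forests are grown, each from a generator spawned
deterministically from (base seed, forest index), so the ensemble is
reproducible and order-independent. Desk scale is F = 100, T = 500; the
study-scale F = 2000, T = 10000 is a configuration change, not a code path.

The default importance is signed out-of-bag permutation importance: per
bootstrap tree, the accuracy drop on its out-of-bag samples when one
feature's out-of-bag values are permuted, averaged over trees (features
unused by a tree contribute 0; negative values occur when permutation
improves accuracy). An alternative, exactly sign-symmetric measure is
provided (`gini_corrected`): the forest is grown on the features plus a
row-permuted shadow copy and a feature's score is its summed Gini importance
minus its shadow's; a feature with no real association is exchangeable with
its shadow. At T = 500 the shadow measure has lower power on correlated
trending proteins (credit splitting), hence the permutation importance
default.

Per forest, each feature's heuristic p-value is computed against the
mirrored null built from non-positive importances,
null = {v ≤ 0} ∪ {−v : v < 0}, as p = #{null ≥ v}/|null| — irrelevant
features are sign-symmetric around zero, so the mirrored non-positive scores
estimate the null distribution. A protein is selected when p < 0.05 in
strictly more than 90% of the forests.

**Null construction for type-I validation.** The type-I property of this
consensus rule is validated under the permutation-null ensemble: every forest
trains on labels freshly permuted by its own generator
(`forest_ensemble(..., permute_labels=True)`). A single fixed label
permutation would not do: with 16 samples and ~300 features, a handful of
features are genuinely (if accidentally) aligned with any fixed labeling at
the dataset level, every forest ranks them identically, and no consensus
over forests can — or should — reject them; re-permuting per forest tests
exactly what the consensus rule is responsible for, namely that no feature
is systematically favored by the importance p-values independent of the
labels. With permuted labels the expected number of selected proteins is
~(probability p < 0.05 in >90 of 100 independent nulls) · n_proteins ≈ 0.

## Trend classification and clustering

Significant = profile-significant OR forest-selected (set union, as the two
arms capture different signal shapes; no p-value combination). Trends are
classified on replicate-mean RLE-normalized abundances over XS→L with
tolerance 0: monotonic-up requires every successive step ≥ 0 and a strictly
higher mean in L than XS (mirrored for down); anything else is "other". The
classification is invariant to positive affine transforms. For heatmap
ordering, z-scored mean profiles are clustered with complete linkage on
1 − Pearson distance and cut at height 0.5 (echoing the repeated use of 0.5
as a correlation threshold elsewhere in the procedure); zero-variance
proteins go to a dedicated "flat" cluster outside the tree.

## Exact count tests

Counts are modeled NB with variance µ + φµ² (φ = 0 handled as exact
Poisson). Libraries are equalized to integer pseudo-counts
pseudo_ij = round(y_ij · ḡ/s_j) with ḡ the geometric mean of the size
factors and round-half-to-even; since median-of-ratios factors are
themselves proportional to effective depth, dividing by s_j is the whole
equalization (no second depth term). A single common dispersion is estimated
by profile maximum likelihood (group means plugged in; log-grid over
[1e-6, 10] then bounded refinement). Plug-in means bias φ̂ downward at small
group sizes (measured ≈ ×0.65 at n = 4+4) — acceptable here because the test
is used with its own φ̂ consistently, and the quantile-adjusted moderated
machinery of the dedicated count-model packages is out of scope by design;
per-protein agreement with those packages is not claimed, calibration of the
test itself is (type-I ≈ 5% at the true φ, verified on 2000 null proteins).

The test conditions on the total: group sums are NB with sizes n_A/φ and
n_B/φ (exact for iid NB with common mean and dispersion); given t = A + B,
P(a|t) ∝ P_A(a)·P_B(t−a), and the two-sided p sums all outcomes with
conditional probability ≤ that of the observed split (relative float slack
1 + 1e-7, as exact tests conventionally use). t = 0 gives p = 1. Log2 fold
changes add a prior of 0.5 to each group mean. BH across proteins at
q < 0.05.

Host enrichment: host proteins, prevalence-filtered over the XS/S/homogenate
samples of one condition (min samples = number of biological replicates),
tested {XS, S} vs {Hom}; "enriched" requires significance AND a higher mean
RLE-normalized abundance in the fractions than in homogenate — an abundance
direction constraint, not a second test.

## Flow cytometry

Gating is by user-supplied axis-aligned rectangles in log10(FSC) ×
log10(SSC) with inclusive boundaries, mirroring manual dot-plot gating;
overlapping rectangles are a configuration error (a boundary event would be
double-labeled). Per sample and population the median fluorescence intensity
(MFI) is the median FI (mean of the central pair for even counts). The
DNA-content fold is reported two ways, since "average fold" is ambiguous:
the arithmetic mean of per-sample MFI₂/MFI₁ ratios (primary) and the ratio
of across-sample mean MFIs. Samples with an empty population or MFI₁ = 0
are excluded with a warning; no valid sample is an error, never a division
by zero.

## Synthetic data

The generator emulates the study design, not the instruments: NB spectral
counts (dispersion 0.1) around lognormal baseline abundances (median 20
counts, log-sd 1) scaled by lognormal library-size multipliers (CV 0.3, a
free choice — fraction-level depth variation is not reported); 40 of 300
symbiont proteins planted with a fold-2 change per fraction step (half up,
half down; the homogenate mean is the equal-weight average of the fraction
means); 100 host proteins, 10 of them elevated 5× in XS and S only;
per-fraction lognormal sizes with medians 3.0/4.6/6.0/8.0 µm (σ_log = 0.25)
whose equal-weight concatenation forms the homogenate, so quartile
calibration holds by construction; two flow populations 10× apart in
FSC/SSC with σ_log10 = 0.12 and an FI median ratio of 9.7 (population 1 at
800 rfu). All generators are pure functions of (config, seed) with
independent derived streams.

What the generator does **not** model — and hence what passing tests do not
establish about real data: zero inflation beyond NB sampling, correlated
proteins within pathways, shared-peptide inference artifacts, fraction
cross-contamination, batch effects between specimens, doublets/debris in
flow data, and non-lognormal size tails. The prevalence filter and the
replicate-consistency filter are exercised by sparsity and noise, not by
structured artifacts.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at the generator's default
scale (300 + 100 proteins, 28 + 7 samples, 100 forests × 500 trees, 10⁴ flow
events per sample, 2000-protein calibration experiments) — sizes chosen so
the full statistical properties (power ≥ 0.8, FDR ≤ 0.1, type-I ≈ 5%) are
measurable in minutes on one CPU. Numerical conventions: correlations
rounded to 12 decimals before argmax so exact ties break deterministically
toward lower ids; conditional pmfs normalized in log space; banker's
rounding for pseudo-counts; float-slack 1 + 1e-7 when comparing point
probabilities in exact tests.

## Known limitations

- The exact test is a single-common-dispersion conditional test, not the
  moderated tagwise empirical-Bayes machinery of dedicated count packages;
  per-protein results can differ even though both are calibrated.
- Stability selection on a fixed dataset cannot reject dataset-level chance
  associations (see the null-construction note above); at study scale this
  is mitigated by ~4× more proteins and a real biological signal structure,
  but the residual risk is inherent to consensus rules over a fixed sample.
- The quartile estimator, log-ratio baseline, pseudocount, replicate
  consistency statistic and cluster cut height are all conventions exposed
  as parameters; results at boundaries (ties, zero variance) depend on the
  documented tie-breaks.
- FCS container parsing is out of scope; flow events arrive as CSV.
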