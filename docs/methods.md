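# Methods

## The model

`rges` scores the hypothesis that a drug which *reverses* a disease's
transcriptional state is more likely to be therapeutically active against
it.  Three quantities are computed.

### Per-profile reverse gene expression score (RGES)

A drug perturbation profile is a vector of differential-expression values
over the landmark-gene universe (the ~978 directly measured genes of
L1000-style platforms; scoring is restricted to this universe by default
because imputed genes dilute the signal).  Genes are ranked by value, rank
1 = most upregulated; ties break by ascending gene identifier so results
are bit-reproducible.  For a disease gene set of size m with ascending
ranked positions V(1..m) among n genes, the two one-sided
Kolmogorov–Smirnov-type maxima are

    a = max_j [ j/m − V(j)/n ]        b = max_j [ V(j)/n − (j−1)/m ]

and the enrichment score is `es = a if a > b else −b` (positive: the set
piles up at the top of the list).  Then

    RGES = es_up − es_down  ∈ [−2, 2].

There is **no** zero-clamping when `es_up` and `es_down` share a sign (the
clamped "connectivity score" variant concentrates mass at 0 and is kept
only as a documented contrast, not implemented).  A strongly negative RGES
means disease-upregulated genes were pushed to the bottom of the list and
disease-downregulated genes to the top — reversal.  Spearman/Pearson/cosine
similarity between profile values and signature fold changes are provided
as benchmarking alternatives, and a gene-set permutation null (random
disjoint up/down sets of the same sizes) supplies an optional P value; the
add-one-smoothed two-sided estimator is used.

### Disease signatures

Built from a differential-expression table by strict thresholds
`|log2FC| > 1.5` and `adjusted P < 0.001`, split by fold-change sign.  The
magnitude interpretation of the fold-change cut (rather than signed) is a
deliberate choice: both directions are required downstream, and a single
printed threshold producing both sets is only coherent as a magnitude cut.
Genes outside the universe are dropped with a logged count; missing
adjusted P excludes a gene, never imputes.  Signatures with ≤ 50 genes
trigger a "poorly powered" warning (the working floor below which
disease–efficacy correlations were not considered reliable), but are not
refused.

### Summarized RGES (sRGES)

One compound yields many profiles (cell lines × doses × durations ×
replicates).  Scores from different assay conditions are not comparable:
longer treatment and higher dose give stronger reversal.  Conditions are
binned 2×2 at 10 μM and 24 h, boundary values on the reference side, so
the reference condition (10 μM, 24 h — the most common assay condition) is
its own bin.  For each non-reference bin, compounds profiled in the *same
cell line* under both the reference and that bin contribute one paired
difference of bin-mean RGES; the bin's offset is the mean paired
difference (reference − target), an additive adjustment toward the
reference.  Bins supported by fewer than `min_pairs = 10` pairs fall back
to offset 0 with a warning.  A linear-in-(log dose, time) model was
considered and rejected for the default: with only two observed levels per
factor in typical data the saturated 2×2 mean model is equivalent and has
no parametric assumptions.

Cell lines are weighted by transcriptional similarity to the tumours being
targeted: mean Spearman correlation between the cell line and individual
tumours over shared genes, clamped at 0 (a negatively correlated cell line
should not carry negative weight), then divided by the maximum so the most
tumour-like line has weight exactly 1.  The compound summary is

    sRGES = Σ_i w(cell_i) · (RGES_i + offset[bin_i]) / Σ_i w(cell_i).

The normalization by Σw (not by the profile count N) makes the summary a
proper weighted mean, invariant to duplicating a zero-weight profile.
Profiles in cell lines absent from the weight table receive the mean
available weight with a warning; if Σw = 0 the unweighted mean is used.
`best` (minimum RGES), `median` and `mean` of the raw scores are available
as comparison strategies; on synthetic studies the weighted summary
consistently correlates better with efficacy than `best`, which is noisy
because it selects an extreme order statistic.

### Reversal genes

Compounds with efficacy data are split at median IC50 < 10 μM
(effective) vs ≥ 10 μM (ineffective); medians use the lower-middle value
for even counts so the summary is always an observed measurement.  Each
compound is reduced to the single profile carrying its median RGES (same
lower-middle convention; RGES ties break by profile id).  Each signature
gene's normalized position (rank/n ∈ (0, 1], small = top) is compared
between groups with a one-sided Mann–Whitney–Wilcoxon test.

Directionality is the most error-prone sign in the pipeline, so it is
stated twice: with rank 1 at the top, a disease-**up** gene is reversed
when effective compounds push it toward the *bottom* — positions
stochastically **greater** in the effective group; a disease-**down** gene
is the mirror image (alternative "less").  The test is exact (full
enumeration, via `scipy.stats.mannwhitneyu(method="exact")`) when the
combined group size is ≤ 20 and there are no ties, otherwise the
tie-corrected normal approximation with continuity correction.  P values
are Benjamini–Hochberg adjusted across all tested genes (the FDR-style
0.25 cut implies an FDR procedure; BH is the default choice) and genes
with adjusted P < 0.25 are flagged.  A leave-one-compound-out sweep —
leaving out each labeled compound from *either* group — marks as *robust*
only genes flagged in every trial; robust genes are by construction a
subset of the full-set significant genes.

## Synthetic studies

The generator plants all of the structure the method assumes, so every
estimator can be validated against recorded truth without downloads.  It
is parameterized in **normalized rank positions** because every downstream
statistic is rank-based.  Per profile, each gene receives a latent position
t: background genes t ~ U(0, 1); planted reversal genes are shifted by the
profile's effective shift σ (up genes t+σ, down genes t−σ, clipped into
(0, 1)); emitted values are a strictly decreasing transform of t (normal
quantiles, so they look like z-scored differential expression — any such
transform yields identical ranks).  The effective shift is

    σ = strength(compound) · rho(cell line) − elevation(bin)/2 + N(0, noise_sd)

Defaults (chosen once as the study conditions): 978 genes, 50+50 signature
genes all planted, 30 effective + 30 ineffective compounds,
`reversal_strength = 0.3`, condition elevations +0.10 (low/long), +0.15
(high/short), +0.20 (low/short), `noise_sd = 0.05`, three cell lines with
tumour-similarity rho 0.9/0.6/0.3, IC50 link
`ic50 = exp(3 − 8·strength + ε)`, sd(ε) = 0.5, which puts a strength-0.3
compound near 1.8 μM and a null compound near 20 μM so the 10 μM threshold
splits groups non-trivially.  Effective compounds draw strength
0.3·U(0.5, 1.5), ineffective 0.3·U(0, 0.15).

Under this position model the realized RGES is ≈ −2σ (the KS maxima are
b_up ≈ σ and a_down ≈ σ), which is why a planted RGES elevation e maps to
a shift attenuation of e/2.  The −2 slope is accurate for |σ| ≳ 0.1 and
steeper near the null (a max-statistic effect), so realized bin elevations
in a full study are faithful for strongly reversing compounds and somewhat
inflated for near-null ones.  `simulate_condition_rges` therefore plants
additive effects *directly on the RGES scale* and is the reference fixture
for validating offset estimation in isolation (recovery within ±0.02 at
300 pairs, noise sd 0.05).  Cell/tumour expression uses a shared-factor
mixture (`cell = rho·F + √(1−rho²)·noise`, `tumour = F + 0.5·noise`) whose
expected rank correlation is proportional to rho, so max-normalized
weights recover rho ratios.

What the generator does **not** emulate: L1000 plate/batch effects,
realistic noise covariance between genes, imputed-gene structure,
cross-study IC50 heterogeneity, or dose–response curve shapes.  Passing
tests therefore demonstrate the estimators recover the structure they
assume, not that the assumptions hold in any particular real dataset.

## Numerical and design notes

- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds; rank ties break lexicographically; medians use the lower-middle
  convention; table readers parse floats in round-trip mode and writers
  use shortest-repr formatting, so every serialization round-trips
  bit-exactly and a pipeline rerun from the same inputs is byte-identical.
- `min_overlap = 3` signature genes per direction are required for a
  score; fewer is refused rather than silently scored, since one- or
  two-gene KS maxima are dominated by single ranks.
- Offsets are *added* to target-bin scores (offset = reference − target),
  so realistic data yield negative offsets (reference reverses hardest).
- Problem sizes in the test suite and acceptance script (hundreds of
  profiles, 10–20 seeds per experiment) were chosen as the smallest runs
  at which the recovery experiments are stable; the generator scales to
  larger studies unchanged.
- The CLI subcommands (`signature`, `score`, `srges`, `reversal`,
  `simulate`) are thin wrappers over the library; exit code 1 signals a
  data error, 2 a usage error, and outputs are written atomically.

## Known limitations

- The condition model is additive per 2×2 bin; real dose–time effects are
  continuous and compound-specific.
- Weighting assumes tumour similarity is adequately summarized by one
  rank correlation over shared landmark genes.
- The permutation null for single-profile RGES P values redraws gene sets
  of the same sizes; it conditions on the profile's ranking, not on
  biological co-expression structure.
- LOCO robustness guards against single-compound leverage only; it does
  not address correlated compounds (e.g. analogues) acting as a clique.
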