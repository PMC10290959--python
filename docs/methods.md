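# Methods

This note records the statistical model, the conventions chosen where the
design was genuinely open, the synthetic data the test suite runs on, and
the limits of what those tests demonstrate.

## Stratified weighted concordance

For one hypothesis (a metabolite x paired with a gene or signature y),
observations are pooled over the datasets in which both features are
measured. Within stratum (dataset) d with n_d paired observations and
per-observation weight w_d = 1/n_d, every unordered pair (i, j)
contributes mass w_d² to exactly one of: concordant C
(sign(x_i−x_j) = sign(y_i−y_j) ≠ 0), discordant D (opposite non-zero
signs), tied on x only (T_x), tied on y only (T_y), or tied on both
(T_xy). Pairs never cross strata, so each stratum's total pair mass is
(n_d−1)/(2n_d) < ½ regardless of its size — a 200-sample cohort cannot
out-vote a 20-sample cohort by more than a factor of ~2.

Two tie conventions for c are implemented because the field uses both:

- **half_tie (default)**: c = (C + T_x/2)/(C + D + T_x). Pairs tied on the
  response are incomparable; predictor ties count one half. This is the
  convention of the established survival-concordance routines and is the
  default because the original computation of this statistic family is
  done with such a routine.
- **full_tie**: c = (C + T)/(C + D + T) with T all tied mass — the simpler
  printed form. Note that with ties its null expectation exceeds ½, so the
  centred z-score is conservative in one tail; this is inherent to the
  formula, not to the implementation.

c_scaled = 2c − 1. With no ties and one stratum, c_scaled equals Kendall's
τ_a exactly (asserted against an independent implementation in the tests).

### Null variance and inference

Writing u_ij = sign(x_i−x_j), v_ij = sign(y_i−y_j) and
K = Σ_{i<j} w_i w_j u_ij v_ij, one has c − ½ = K / (2·A) where
A = C + D + T_x (half_tie) is invariant under permutations of y within
strata. Under within-stratum exchangeability, Var₀(K) is the classical
tie-corrected null variance of the Kendall S statistic, computed per
stratum from the tie-group sizes of x and y and scaled by w_d⁴ (weights
are equal within a stratum), summed over strata; hence
Var₀(c) = Var₀(K)/(4A²) and z = (c − ½)/√Var₀(c) = K/√Var₀(K). The same
construction applies to full_tie with A replaced by the total pair mass.
A within-stratum permutation estimator (n_perm ≥ 100) is retained as the
validation oracle; on random tied, stratified instances the closed form
agrees with 10,000-permutation estimates to well within 1%. Two-tailed
normal p-values are BH-adjusted across the tested pairs; pairs covered by
fewer than 2 datasets are reported but excluded from the adjustment (m =
number of tested pairs).

Degenerate inputs are values, not errors: a constant y gives an undefined
c and NaN p; a zero denominator is flagged the same way. Only the case of
no comparable pairs at all (every stratum smaller than 2) raises.

Complexity is O(n²) per stratum per pair, accepted deliberately: at the
cohort sizes this method targets (tens to low hundreds of samples per
dataset) the crossing of universes dominates, and the screen is trivially
parallel over pairs.

## Metabolomics preprocessing

Stage order per dataset: batch median scaling (multiplicative, per
metabolite, only when ≥ 2 batches) → PQN → log2 → per-tissue missingness
filter → minimum imputation.

- **PQN**: reference spectrum = per-metabolite median over the reference
  samples (normal samples when any exist, otherwise all tumour samples),
  restricted to metabolites with < 20% missing values among those samples
  (strict inequality, as is the > 80% filter bound); fewer than 3 eligible
  metabolites is an error because a median of quotients over fewer spectra
  is unreliable. Per-sample dilution factor = median of sample/reference
  quotients over jointly observed metabolites; a sample with no overlap
  gets factor 1 with a warning. PQN is exactly scale-equivariant:
  multiplying a sample by k multiplies its factor by k and leaves the
  normalized values unchanged.
- **Missingness filter**: applied separately per tissue group on the
  normalized data; a feature is removed when it exceeds the threshold in
  any group present.
- **Imputation**: per-feature minimum within the dataset ("minimum value
  recorded" is read per metabolite per dataset; the alternative global
  minimum reading would couple unrelated metabolites' scales). Under the
  generator's abundance-dependent missingness, the missing cells are
  concentrated in the low tail, which is what makes a minimum a defensible
  fill-in; imputation never alters an observed cell or a feature minimum.
- On clean data (no missingness, one batch, unit dilution) the pipeline
  provably drops nothing, imputes nothing and applies no batch factors,
  reducing to log2∘PQN. It does not reduce to log2 alone: PQN estimates a
  near-unit but noisy factor from any finite number of metabolites, with
  spread shrinking as the reference panel grows.
- PQN factors are identifiable only up to the reference's overall level,
  so recovery against generator truth normalizes both sides to geometric
  mean 1. At 10% metabolite noise CV the median relative error is under
  2%; at the generator's default 1-log2-unit biological variation with
  ~25 metabolites, errors around 20% are expected estimator noise, not a
  defect.

## Reaction-network distances

Reactions are nodes; two reactions are adjacent when they share a
non-currency metabolite; genes attach to the reactions they catalyze
(gene–protein–reaction logic flattened: any annotated gene counts).
Distance(gene, metabolite) = 1 + minimum reaction-to-reaction hops from
any reaction the gene catalyzes to any reaction containing the
metabolite; traversal is undirected (reversibility annotations are
ignored as unreliable), capped at 10 hops, beyond which — or for
endpoints absent from the network — the distance is undefined. Proximal =
defined distance ≤ 2. Currency metabolites (water, protons, ATP/ADP,
NAD(P)(H), CO₂, phosphate, CoA by default; fully configurable) are
removed from connectivity entirely, including as distance targets: without
the exclusion every distance collapses to ≤ 3 network-wide, and the empty
list reproduces that naive metric on purpose. Distances are validated
exactly against an independent Floyd–Warshall all-pairs oracle on random
networks of up to 50 reactions.

The proximal-enrichment test is a two-sided Fisher exact test of
significant × proximal restricted to pairs with defined distance; the
2×2 table is always emitted alongside the sample odds ratio (infinite
when a single cell is empty; a Haldane-corrected +0.5 ratio is reported
for that case) — margins of zero make the ratio undefined.

## Pathway DA/DF scores

Differential testing defaults to two-sided Wilcoxon rank-sum per feature
(exact null when both groups have ≤ 8 tie-free observations, otherwise
the tie-corrected normal approximation), BH within dataset and omics
layer, significance at q < 0.1, direction from the tumour-minus-normal
median difference. A precomputed differential table (e.g. from a
moderated linear model) can be supplied instead; only the FDR call is
applied to it. DA = (#up − #down)/#measured, DF = (#up + #down)/#measured,
with "measured" counted per dataset so a constituent absent from one
cohort's matrices does not dilute that cohort's score (|DA| ≤ DF ≤ 1
always). Pathways enter the analysis when at least one constituent is
measured in at least 5 of the contributing tumour/normal datasets
(threshold configurable). Cross-omics agreement per pathway is the
Spearman correlation between the metabolite-DF and transcript-DF vectors
over datasets (≥ 4 datasets, non-constant vectors), BH across pathways;
synchrony is tallied as the sign of DA_transcript × DA_metabolite per
(pathway, dataset), zero products counting as neither.

## Neighbourhood enrichment

For each metabolite with ≥ 1 significant gene partner: selected = its
significant genes, universe = the screened gene universe (the genes
actually tested, not the genome — selections can only come from tested
genes), one upper-tail hypergeometric test per pathway with ≥ 1 member in
the universe, BH within metabolite (matching the per-metabolite framing
of the screen; a global mode exists), significance at q < 0.01. The
two-sided Fisher helper uses the "sum of outcome probabilities ≤
observed" convention, stated here because conventions differ across
software.

## Signature scores

The per-sample score of a gene set walks the genes of that sample in
descending expression order and accumulates the difference between the
in-set ECDF (weighted by rank^α, α = 0.25 by default; α = 0 gives the
Kolmogorov–Smirnov-like variant) and the out-of-set ECDF, returning the
summed difference. Ties receive average ranks for the weights; traversal
among tied values follows input order, making scores deterministic.
Scores are purely rank-based — any strictly increasing transform of a
sample leaves them unchanged — so no across-sample rescaling is applied
(the downstream concordance screen is itself rank-based, making affine
rescaling irrelevant; this differs from tools that rescale tumour-purity
scores). Signature gene lists are data (GMT), not code; leave-one-gene-out
variants are first-class. Signature–metabolite screens delegate to the
concordance machinery with signatures as x, metabolites as y, dataset as
stratum, q < 0.05; tumour-only samples by default with an all-samples
flag, since descriptions of this analysis conflict on the point.

## Synthetic data

`SyntheticSpec` defaults describe a desk-scale analogue of a 15-cohort
compendium: sample sizes (18…110) heterogeneous across 15 datasets, 300
genes, 60 metabolites, metabolite presence probability 0.8 per
(metabolite, dataset) to emulate heterogeneous coverage, tumour fraction
0.7, latent immune fraction ~ Beta(2, 5) (a right-skewed minority
infiltrate) loading on an immune gene block and hub metabolites, gene
baselines U(3, 8) and metabolite baselines U(10, 16) on the log2 scale
with unit noise, per-sample dilution log-uniform in [0.5, 2], optional
multi-batch structure with log2-normal batch factors, and logistic MNAR
missingness in the within-dataset z-score of log2 abundance (intercept
−2.2, slope 1.3 ≈ 10–15% missingness concentrated at low abundance,
which is the regime minimum imputation presumes). Planted pairs draw a
latent N(0,1) signal per gene; the gene adds it directly, the paired
metabolite adds slope × signal. Everything is reproducible bit-for-bit
from the spec seed.

Benchmark designs fix what their question needs: the recovery design
(5 datasets × 30 samples, 20 planted pairs in a 20×50 grid, slope 3× the
noise sd) uses complete metabolite coverage so that recall measures the
screen's power under dilution, batch and MNAR distortion rather than
coverage dropout, which the default presence 0.8 would otherwise
dominate; the calibration design is a single clean stratum of 30 samples
with all effects zeroed.

What the generator does *not* emulate: realistic metabolite–metabolite
covariance, platform-specific intensity distributions, RNA-seq counts
(transcripts are TPM-like positive values; their preprocessing is a
log2 pass-through by design), or tumour/normal abundance shifts — the
DA/DF stage is therefore demonstrated on constructed differentials and
behaves as a calibrated null on generator output. Passing tests show the
statistics are correct and calibrated under these mechanisms, not that
the pipeline is robust to every artefact of real acquisitions.

## Problem sizes and numerical conventions

The shipped test and acceptance runs use: 200 random instances (n ≤ 100,
≤ 4 strata) for the exact enumeration oracle; 2,000 replicates at n = 30
for calibration (3 Monte-Carlo-SE acceptance band around 0.05); 20
replicates of the recovery design; 10,000 permutations for variance
cross-checks; networks ≤ 50 reactions for the all-pairs oracle;
enumeration universes ≤ 25 for the exact-test oracles. Floating-point
outputs are written at 6 significant digits; screens order output rows
lexicographically by (x, y); BH never reorders ranks; all thresholds come
from `AnalysisConfig` and nowhere else; every random operation takes an
explicit seed and the pipeline records it, so reruns produce
byte-identical TSVs.

## Known limitations

- The z-test relies on the normal approximation of the Kendall-type
  score; below ~15 observations per stratum its tails are approximate
  (calibration is verified at n = 30).
- Pair screening is quadratic in stratum size and linear in the number of
  pairs; genome-scale universes (~4.4M pairs) require parallelization
  over pairs, which the design permits but this package does not manage.
- The half_tie/full_tie duality cannot be resolved from formulas alone;
  results at high tie rates (heavy imputation) differ between the two and
  the default is a documented convention choice.
- Network distances ignore stoichiometry, compartments and reaction
  direction; they are hop counts, not flux distances.
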