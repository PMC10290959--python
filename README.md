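# gmconcord

Stratified, sample-size-weighted concordance meta-analysis of
gene–metabolite covariation across heterogeneous tumour multi-omics
cohorts — with the standardized metabolomics preprocessing, reaction-network
distances, tumour/normal pathway scoring, neighbourhood enrichment and
immune-signature screens that surround it, exercised end-to-end on a
synthetic multi-cohort generator with known ground truth.

## The problem

Paired metabolomics/transcriptomics compendia pool many cancer cohorts that
differ in platform, sample size, dilution, batch structure and metabolite
coverage. Parametric correlations pooled across such cohorts are easily
driven by a few large studies or by scale artefacts. This package implements
a rank-based alternative: within each dataset *d*, every unordered sample
pair (i, j) with both a metabolite *m* and a gene *g* measured is classified
as **concordant** when sign(m_i − m_j) = sign(g_i − g_j) ≠ 0 and
**discordant** when the signs oppose; pairs never cross datasets. With
per-observation weights w = 1/n_d, the concordance fraction is

```
c = (C + T_x/2) / (C + D + T_x)            (default half-tie convention)
c = (C + T) / (C + D + T)                  (full-tie convention, selectable)
```

where C, D are weighted concordant/discordant masses and T_x the mass of
pairs tied on the predictor. The scaled statistic **c_scaled = 2c − 1 ∈
[−1, 1]** is a Somers'-D-type quantity and equals Kendall's τ_a when there
are no ties and a single stratum. Inference uses z = (c − ½)/√Var₀(c),
where Var₀ is the tie-aware closed-form null variance of the weighted
within-stratum Kendall score under exchangeability (a within-stratum
permutation estimator is provided as a cross-check), with two-tailed normal
p-values and Benjamini–Hochberg correction. A pair surviving q < 0.01 is a
gene–metabolite interaction (GMI).

Around the core statistic the package provides:

- **preprocess** — batch median scaling, probabilistic quotient
  normalization (reference from normal samples when available, metabolites
  with < 20% missingness), log2, per-tissue > 80%-missingness filtering,
  minimum-value imputation;
- **network** — reaction-step distances on a bipartite
  gene–reaction–metabolite graph (same reaction = distance 1; consecutive
  reactions = 2), currency metabolites excluded from connectivity,
  "proximal" = distance ≤ 2, Fisher enrichment of significant × proximal;
- **pathway** — Wilcoxon tumour/normal differentials (exact for small
  groups), DA = (#up − #down)/#measured and DF = (#up + #down)/#measured
  pathway scores, cross-dataset Spearman correlation of DF scores;
- **enrichment** — hypergeometric over-representation of pathways among
  each metabolite's significant gene partners;
- **signatures** — per-sample ssGSEA-style scores of immune gene sets,
  leave-one-gene-out variants, and signature–metabolite concordance screens;
- **synthetic** — a multi-cohort generator with planted monotone
  gene–metabolite dependencies, a latent immune-cell fraction driving a
  gene block and hub metabolites, per-sample dilution, batch factors,
  heterogeneous metabolite coverage and abundance-dependent (MNAR)
  missingness.

## Worked example

```bash
python analysis/01_simulate.py        # 6 cohorts, 182 samples, truth tables
python analysis/02_preprocess.py
python analysis/03_gmi_screen.py
python analysis/04_network_distance.py
python analysis/06_neighbourhood_enrichment.py
python analysis/07_immune_signatures.py
```

The screen step prints:

```
universes: 25 metabolites x 80 genes = 2000 candidate pairs
27 significant pairs at q < 0.01
planted pairs recovered: 6/6
top metabolites by number of significant partners (immune hubs expected on top):
x_id
M022    12
M021     9
```

All six planted monotone pairs are recovered, and the two hub metabolites
driven by the latent immune fraction dominate the GMI degree distribution,
mirroring how a shared cell-mixture signal manufactures many distal
associations. The distance step then reports

```
2x2 (sig x proximal): [[6, 0], [88, 296]]
significant pairs are enriched for proximal interactions: OR = inf (Haldane-corrected 43.55), Fisher p = 1.73e-04
```

— the planted enzyme–substrate pairs sit at reaction distance 1, so
significant pairs are strongly enriched for proximal ones — and the
signature step confirms the mechanism:

```
ImmuneScore vs latent immune fraction: Spearman rho 0.95 (median across datasets)
top metabolites for ImmuneScore (planted hubs M021/M022 expected):
M022  0.423341 2.245999e-08
M021  0.372402 1.226266e-06
```

The same stages are available as a CLI (`gmconcord simulate|preprocess|gmi|
distance|pathway-scores|enrich|signatures|all`) for use on any manifest of
TSV matrices.

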