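# proteohet

Proteogenomic detection of variant peptides and heterogeneity/survival
statistics for multi-metastasis tumour cohorts.

## What this is for

In cohort proteogenomics, RNA-seq-called variants are turned into candidate
variant protein sequences, and mass-spectrometry peptide identifications are
screened for **non-reference peptides (NRPs)** — peptides that cannot be
mapped to any reference protein and therefore witness a translated sequence
variant. Downstream, protein abundance profiles of many metastases per
patient are clustered to characterise intra-patient heterogeneity, and the
clusters are linked to overall survival. `proteohet` implements this whole
chain for post-mortem multi-metastasis melanoma-style cohorts:

- **`variantdb`** — applies all combinations of in-frame variants per
  30-amino-acid window (frameshifts singly, translated to the first
  downstream stop), drops genes with more than 10 000 combinations per
  sample, and deduplicates the cohort-wide sequences by MD5 with a
  provenance table (sample, prediction type, original header, MD5).
- **`nrpcall`** — tryptic digestion (≤2 missed cleavages), I/L-collapsed
  reference subtraction (MS cannot distinguish Ile from Leu), 1% FDR +
  validation filtering, cohort-wide mapping against the variant database
  with a unique-gene requirement, missed-cleavage merging, and binary
  NRP × sample presence matrices with a minimum-3-patients filter.
- **`variant_stats`** — population allele-frequency classification
  (absent → *novel*, AF > 1% → *frequent*, 0 < AF ≤ 1% → *removed*), a
  one-sided exact binomial test for genes with an excess of novel mutations
  against the pooled reference novel:frequent ratio (BH-corrected), and
  deleteriousness-score averaging (scaled C-score ≥ 20 → deleterious).
- **`matrix_prep`** — log2 transform, artifact floor (log2 < 10 → missing),
  median-scale normalisation, replicate averaging, ≤10% missingness filter,
  left-censored MinProb imputation (q = 0.02, tune.sigma = 1), RNA-seq
  three-metric quality classification, RPKM/TPM, raw-count transcript
  filter (>9 in ≥30% of samples) and the ≥60% tumour-content sample filter.
- **`hetero_stats`** — consensus clustering (PAM on 1 − Pearson distance
  over resampled sample subsets, delta-area elbow for k), Welch differential
  abundance with BH, cluster-specific upregulation (all pairwise contrasts),
  one-sided Fisher NRP enrichment, classic weighted running-sum pre-ranked
  GSEA with gene-label permutations, gene-wise protein–RNA Spearman
  correlation and Pearson/Jaccard sample similarity.
- **`survival`** — Kaplan–Meier with Greenwood variance, log-rank, Cox
  proportional hazards (lifelines), per-protein Cox ranking on patient-level
  collapsed abundance feeding a survival GSEA (NES > 0 = upregulated with
  shorter overall survival), single-sample signature scores and the
  majority-cluster (>50%) patient classification.
- **`synth`** — a deterministic synthetic cohort generator (patients with
  1–9 metastases, planted SNVs/indels with known population AFs, PSM tables,
  a 4-cluster block-structured abundance matrix with intensity-dependent
  missingness, cluster-linked exponential survival) so every stage can be
  scored against known ground truth without any external data.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the default
synthetic cohort (24 patients, 124 metastasis samples, 168 planted
variants, 4 abundance clusters with clusters 1 and 3 carrying a 3× hazard):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/02_build_variant_db.py
python analysis/03_call_nrps.py
python analysis/04_mutation_stats.py
python analysis/05_prepare_matrices.py
python analysis/06_heterogeneity.py
python analysis/07_survival.py
```

Selected output from a run (seed 42):

```
NRP catalogue: 180 entries ({'in_frame': 149, 'frameshift': 31})
present in >=3 patients: 69
recall of planted variant peptides: 0.995

chosen k = 4 (delta-area: {2: 0.468, 3: 0.401, 4: 0.133, 5: 0.076, 6: 0.027})
adjusted Rand index vs planted clusters: 1.000

group dominant: n=10, KM median = 3.1 months
group other: n=13, KM median = 42.1 months
log-rank: chi2 = 10.43, p = 0.0012
Cox (dominant high-hazard clusters): HR = 4.65 (95% CI 1.70-12.73), p = 0.0028
PATHWAY_C1    es  0.669  nes  2.090  p 0.002
PATHWAY_C3    es  0.849  nes  2.553  p 0.002
```

Reading this: of the planted variant peptides, 99.5% are recovered and none
of the 180 called NRPs maps back to the I/L-collapsed reference proteome;
consensus clustering picks k = 4 by the delta-area elbow and reproduces the
planted partition exactly (ARI = 1); patients whose metastases are mostly in
the two planted high-hazard clusters die markedly earlier, and the
survival-ranked GSEA flags exactly those clusters' pathway blocks as
upregulated with shorter survival (NES > 0).

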