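# Methods

This note documents the models, conventions and parameter choices behind
`proteohet`, and what the synthetic-cohort results do and do not establish.

## Variant protein database (`variantdb`)

Variants live in transcript-relative CDS coordinates (0-based, half-open;
VCF files are written 1-based with the transcript id as CHROM). Transcript
models are single-CDS and intronless: splice variants and novel ORFs are
represented as alternative sequence records passed through with their
prediction type, not as exon graphs, because this package models the
*output shape* of upstream transcript-discovery tools rather than the tools
themselves.

**Frame classification.** A variant is in-frame iff the absolute allele
length difference is a multiple of 3; SNVs are in-frame.

**Window combinations.** Combinations of in-frame variants are enumerated
within windows of `window_aa` residues (default 30). Windows are anchored
at each variant's first affected residue; for each anchor every non-empty
subset of the in-frame variants inside the window is generated and subsets
are deduplicated across windows. This covers all co-occurrence within one
window length without quadratic blow-up, at the cost of never combining
variants more than `window_aa` residues apart. Variants whose reference
spans overlap are mutually exclusive in a subset (each still appears as a
singleton). Frameshift variants are never combined with anything: the
shifted downstream sequence is already fully determined by the single
shift.

**Per-gene cap.** A gene is dropped for a sample when its total combination
count across all transcripts exceeds `max_combinations_per_gene` (default
10 000); the count includes frameshift singletons, and the boundary is
inclusive (exactly 10 000 is kept). Enumeration refuses windows with more
than 25 in-frame variants rather than materialising 2^26+ subsets.

**Emission.** In-frame records carry the affected residue window plus
`window_aa` flanking residues each side (clipped at the protein ends) so
any tryptic peptide overlapping the variant is representable; frameshift
records run from the first affected codon to the first downstream stop plus
the upstream flank. Stop-gains emit the truncated translation (type
in-frame); stop-losses read through to the next stop or transcript end.
Subsets that leave the protein unchanged (synonymous) emit nothing, so the
reference sequence never enters the variant database. Sequences are
deduplicated cohort-wide by MD5 of the amino-acid string; the FASTA header
is the digest and a provenance table keeps one row per (sample, prediction)
so peptide hits can be mapped back to their transcriptomic evidence.

## NRP calling (`nrpcall`)

Digestion is tryptic (cleave C-terminal of K/R except before P, via
`pyteomics.parser.cleave`), up to 2 missed cleavages, peptide length 7–50.
Peptides are compared I/L-collapsed (every I → L) throughout, since MS
cannot distinguish the isobaric pair. A PSM survives reference subtraction
iff its collapsed peptide is not a substring of any collapsed reference
protein *and* q ≤ 0.01 *and* the external validation flag is set; substring
containment (not tryptic-set membership) is the stricter reading of
"mapped", and reference mapping takes precedence over variant mapping.
Validation is ingested as a boolean PSM column and never recomputed —
spectrum-level rescoring is out of scope.

Candidates are mapped cohort-wide (a peptide predicted in any sample is
searched in all samples); peptides matching sequences of more than one gene
are discarded *before* missed-cleavage merging (the stricter order, since
the original order is not documented), and matches spanning several
prediction types within one gene are labelled `multi`. Missed-cleavage
merging joins records of the same gene when one collapsed peptide extends
the other and their database-record hit sets intersect (shared variant
evidence); merging is a transitive fixpoint, invariant to input order, and
the merged key is the shortest member. Presence matrices are binary (≥1
validated PSM), and association analyses use only NRPs seen in ≥3 patients.

## Variant statistics (`variant_stats`)

The allele-frequency rule partitions {absent} ∪ [0, 1]: absent or AF = 0 →
*novel*, AF > 0.01 → *frequent*, 0 < AF ≤ 0.01 → *removed* (uncertain
band; the 1% boundary itself is removed). AF = 0 is folded into *novel*
("not present in the reference population") to keep the classification
total.

No specific test is named in the literature for "more novel mutations than
expected"; we use the simplest exact test consistent with a pooled
reference ratio: with r₀ the reference population's novel:frequent ratio
(pooled over genes by default; mean of per-gene ratios available via
`mode="per_gene_mean"`), each observed mutation is novel with probability
p₀ = r₀/(1+r₀) under the null, and a gene with k novel of n mutations gets
the one-sided binomial tail P(X ≥ k), BH-corrected across genes
(flag at adjusted p < 0.05). Deleteriousness scores are supplied per
genomic mapping and averaged; the flag threshold is a scaled C-score of 20.

## Matrix preparation (`matrix_prep`)

The proteomic pipeline order is fixed: log2 → artifact floor (log2 < 10 →
missing) → per-replicate median centring plus the global median → replicate
averaging. The global median is computed over all observed values *before*
centring (the alternative, post-centring, is not what "adding the global
median" implies). Replicate averaging ignores missing values rather than
propagating them, maximising retained data ahead of the 10% missingness
filter, which is applied *after* averaging ("across the metastases").

MinProb imputation draws missing cells of sample *s* from
Normal(μ_s, σ) with μ_s the q-quantile (default 0.02) of that sample's
observed values and σ = tune.sigma × median over proteins of the
per-protein observed standard deviation — the conventional left-censored
imputer contract. Observed cells are never altered and the draw is
deterministic under the seed. Samples with fewer than 3 observed values are
an error.

RNA-seq quality uses three metrics with fixed thresholds — good requires
mRNA content > 76.84%, > 3.6 M assigned reads and assigned-read percentage
> 48.3% simultaneously; poor requires ≤ 60%, ≤ 2.3 M and ≤ 38.9%
simultaneously; anything else is medium. Replicate selection maximises
(assigned reads, M assigned reads) lexicographically with a lexicographic
id tie-break. Transcript filtering keeps raw counts > 9 (strict) in at
least ⌈30% of samples⌉; tumour-content filtering keeps samples at ≥ 60%.

## Heterogeneity statistics (`hetero_stats`)

**PAM.** Partition around medoids with deterministic BUILD + best-swap
iterations; instances where the number of candidate medoid sets is small
(≤ 50 000 cost evaluations) are solved exactly by enumeration, which also
makes the small-instance behaviour coincide with exhaustive search.

**Consensus clustering.** For each k (default 2–6), 1000 resamples
(tests and drivers use 100; stated where used) of 80% of the samples are
clustered with PAM on 1 − Pearson correlation distance; consensus(i,j) is
the co-clustering rate over co-samplings. Final assignments per k come from
PAM on 1 − consensus. The consensus CDF area A(k) follows the standard
definition; the relative increase Δ(k) = (A(k) − A(k−1))/A(k−1) (Δ = A at
the smallest k) drives the elbow: chosen k is the largest k with Δ(k) ≥ 0.1
(configurable — the published practice is visual judgement, so any fixed
threshold is a convention). Computation runs in canonical sorted-sample
order so column permutations permute results identically. Input must be a
complete (imputed) matrix restricted to proteins quantified in ≥ 90% of
samples.

**Differential abundance.** Welch's t-test on log2 intensities (standard
for imputed label-free matrices; no test is canonical here), two-sided,
BH within each contrast; effect = mean difference. Cluster-specific
upregulation requires positive effect and adjusted p < 0.05 against *every*
other cluster (all pairwise contrasts, which is what makes the resulting
sets "unique" per cluster); one-vs-rest is a caller-side variation.
Degenerate zero-variance/equal-mean proteins get p = 1.

**GSEA.** Classic weighted running-sum statistic (weight 1): hits increment
by |score|/Σ|score in set|, misses decrement by 1/(N − set size); ES is the
maximum deviation. Significance uses gene-label permutations (the input is
a pre-ranked list, so phenotype permutation is unavailable):
NES = ES / mean(|permuted ES| of the same sign), p is the same-sign tail
with add-one smoothing, BH across sets. Sets with < 10 members in the
ranked universe are skipped.

**Fisher enrichment** is the one-sided (greater) exact test on the 2×2
presence × group table; all-zero presence rows return p = 1. **Similarity**
uses pairwise-complete Pearson on abundance and Jaccard on NRP presence
(two empty samples have Jaccard 1).

## Survival (`survival`)

Kaplan–Meier, log-rank and Cox fits delegate to lifelines; the module adds
Greenwood variance explicitly for auditability. The Cox partial likelihood
uses lifelines' Efron tie handling; all survival times in this package's
cohorts are continuous and tie-free, where Efron and Breslow coincide
exactly. Non-convergence is flagged on the returned fit, never silent.

Per-protein survival ranking collapses metastases to one value per patient
(the mean) before a univariate Cox fit — a deterministic surrogate for a
patient random effect that removes pseudo-replication; a true frailty model
is a possible extension, and this approximation is the main deliberate
deviation from a mixed-effects formulation. Ranking is by signed z,
descending, so positive scores (and NES > 0 downstream) mean upregulated in
patients with shorter overall survival. Proteins missing in > 50% of
patients are excluded.

Signature scores are the mean z-score over the signature's genes present
(≥ 3 required) — the conventional single-sample score when the original
formula is not available; marker lists are user-supplied GMT, and external
predictors (e.g. immune-dysfunction scores) are ingested, never computed.
The majority-cluster rule classifies a patient as dominant iff strictly
more than 50% of their clustered metastases fall in the target cluster
pair; exactly 50% is "other".

## Synthetic cohort (`synth`)

The generator emulates the data *structure* of a post-mortem
multi-metastasis cohort with known ground truth. Defaults: 24 patients with
1–9 metastases (~120 samples), 120 genes with one 300–600 nt CDS each
(ATG + non-stop codons + stop), 120 SNVs + 24 in-frame + 24 frameshift
indels, an AF spectrum of 40% population-absent / 15% rare (0,1%] / 45%
frequent (>1%), 4 abundance clusters with pathway blocks shifted by 2.5
log2 units over a 0.5-unit within-cluster spread (a 5σ effect), 2
replicates per sample, 10% MNAR missingness, 1% low-intensity artifact
cells, and exponential survival with a 49-month baseline median,
administrative censoring at 120 months and hazard multipliers (3, 1, 3, 1)
over the four clusters.

Design notes:

- Planted SNVs are non-synonymous by construction (stop-gains excluded);
  planted peptides are *derived*, not asserted: each sample's variant
  records are built with `variantdb` itself, digested, and only peptides
  absent from the I/L-collapsed reference proteome count as planted truth.
- Each variant has an anchor patient; other patients carry it with the
  Hardy–Weinberg carrier probability implied by its population AF, so
  frequent variants recur across patients (making the ≥3-patients filter
  meaningful) while population-absent variants stay private. Within a
  carrying patient, metastases share the variant with probability
  `variant_concordance` (default 0.8; the real inter-metastasis concordance
  is not documented, so it is a knob, not a constant).
- PSM scores are N(25, 5) for true peptides and N(10, 3) for noise, with
  q-values computed rank-based against the known noise population as
  decoys; 5% of planted PSMs are marked validation-failed. The values are
  arbitrary — only the monotone separation matters.
- Missingness is MNAR: the missingness probability is a logistic function
  of log2 intensity whose midpoint is calibrated by bisection to the target
  missing fraction, which is exactly the regime the MinProb imputer models.
- Metastases of one patient are correlated in cluster membership: each
  patient has a preferred cluster (balanced across patients) adopted with
  probability `cluster_cohesion` (default 0.6), mirroring the
  patient-enrichment of clusters seen in real cohorts. A patient's hazard
  multiplier is the mean of their metastases' cluster multipliers.

What the generator does **not** emulate: real spectra or retention times,
read-level RNA-seq, splice-graph complexity, correlated protein co-abundance
beyond the planted blocks, germline/somatic structure, or realistic
protein-count scales (120 proteins vs ~10 000 in a real matrix). Passing
tests therefore demonstrate algorithmic correctness and calibration under
the planted model, not performance on real LC–MS/MS data.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use reduced problem sizes
chosen to keep each check in minutes on one CPU: consensus-clustering
recovery uses 16-patient cohorts with 100 resamples over 20 seeds;
survival-GSEA sign recovery uses default-size cohorts with reduced variant
counts (the abundance/survival layers do not depend on variant counts) and
100 permutations over 20 seeds; Cox recovery uses 100 simulations at
n = 200. Tolerances: exact-oracle comparisons (Fisher, binomial tail, GSEA
ES, PAM small instances) assert agreement to 1e-12; floating-point identities
(median centring, idempotence) to 1e-9. MD5 collisions between distinct
sequences are checked and raised, not assumed away. Tie-breaks are
deterministic everywhere (sorted keys, lexicographic ids, lowest index).
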