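# Methods

## The signature catalogue

The registry ships 48 scoring systems derived from 39 biomarker gene sets
(`src/icbench/data/registry.yaml` plus GMT/TSV sidecars). Nine
self-contained signatures (IFN-gamma, EIGS, TIG, CRMA, ESCS, F-TBRS, IRG,
TLS, Renal-101) are additionally scored as single-set enrichment scores;
those `*_ssGSEA` entries reuse the parent's gene-list file byte-for-byte,
so the two computations can never drift apart. Composition invariants
(48 systems; 23 self-contained / 11 competitive / 5 deconvolution-like
sets; 46 continuous and 2 categorical scores; 33 positive / 15 negative
directions) are asserted in the test suite.

Two cataloguing choices deserve a note. First, the TIRP overall-expression
score is classed with the competitive group: although it does not rank
genes with an enrichment walk, its bin-matched control genes make the
score a comparison of the signature against the rest of the transcriptome,
and that classing keeps the 23/11/5 set partition coherent. Second, the
single-gene fractalkine marker is registered as *CX3CL1* (negative
direction).

### Gene-list provenance

Gene lists and weights transcribed verbatim from their source
publications: the eight single-gene markers, CYT, IFN-gamma, EIGS, CRMA,
ESCS, TLS, Renal-101, TIG (with its published weights), F-TBRS, APM, the
IMPRES pair table, and the MCP-counter CD8 T-cell marker. These live in
`gene_sets.gmt`.

For the remaining entries the full published tables (e.g. the
162-gene Immunophenoscore table, the 100-gene MIAS list, the member
pathways of IPRES/IMS/PASS) could not be transcribed reliably. Those ship
as **synthetic reconstructions** in `gene_sets_synthetic.gmt`: real HGNC
symbols drawn from the relevant biology (melanocytic lineage for MPS, core
matrisome for C-ECM, cell-type markers for the IIS/TIS families), sized to
the printed counts (CRMA = 8, EIGS = 18, TLS = 9, Renal-101 = 26,
F-TBRS = 19, C-ECM = 58, MIAS = 100, IIS = 26 sets, TIS = 8 sets,
IPRES = 26 sets, IMS = 27 sets, PASS = 15 sets), and flagged
`provenance: synthetic` in the manifest. Every computation is faithful to
its method; only those gene memberships are stand-ins, so scores built on
them should not be compared against published per-cohort values.

TIDE, MFP, EcoTyper, CD8T_CIBERSORTx, CD8T_xCell, and Immunoscore depend
on externally trained models and are adapter entries: their per-sample
values are joined from user-supplied score tables and left NA otherwise.

## Scoring

All arithmetic self-contained kernels (single gene, mean, weighted sum,
PCA, marker mean) operate on log2(TPM + 1). TPM is heavy-tailed, and
averaging on the raw scale lets a single highly expressed gene dominate a
signature; the log scale matches how the cited signatures are used in
practice. A `use_log=False` flag allows raw-scale sensitivity checks. The
geometric mean uses a +1 pseudocount and subtracts 1, so an all-zero
signature maps to 0 and a single-gene set reduces to that gene's value.

Missing signature genes: scores are computed over the present subset when
coverage is ≥ 50% (always with a warning and a recorded missing fraction)
and refuse to compute below that. IMPRES pairs with either gene absent are
skipped; ties contribute 0, which is what bounds the score in [0, 15].

PCA scores fix the sign of the first component so it correlates
non-negatively with the signature mean — without a rule the sign is
arbitrary, which would make directional testing meaningless. TMEscore is
computed as one PC1 over the union of its immune and stromal member sets
rather than a difference of two per-set PCs; with the sign rule above this
preserves the score's orientation while keeping a single PCA kernel.

The overall-expression (TIRP) kernel bins genes into 50 equal-frequency
bins by mean expression, samples 100 control genes per signature gene from
the same bin with a seeded generator, and reports the mean z-score excess
of signature genes over their controls. Defaults follow the conventions of
overall-expression scoring; both are parameters.

## Single-sample GSEA

For one sample, genes are ordered by descending expression (ties in the
ordering broken by gene id so results are deterministic; rank values are
average-tie ranks). The enrichment score is the area form
ES = Σ_i (P_hit(i) − P_miss(i)) with P_hit weighting signature genes by
rank^α and P_miss spreading uniform mass over non-signature genes.
α = 0.25 by default, exposed as a parameter. Because only within-sample
ranks enter, the ES is invariant under any strictly monotone transform of
a sample's expression — the property that makes competitive scores robust
to normalization differences, and one the tests assert.

NES divides every ES of a run by the global max − min over all samples and
sets of that run (a per-set mode exists for combination scores whose
sources normalized per set). A zero range yields NES 0 with a warning.
Combination scores are sums (IIS, TIS), means (IPRES), or weighted sums
(IMS, PASS-PRE, PASS-ON) of member-set NES values.

The preranked-GSEA operator (used to characterize which pathways the
catalogue's frequently used genes enrich) is the classical weighted-KS
maximum deviation with gene-label permutations: NES = ES / mean(|ES_perm|)
over same-sign permutation scores, p = same-sign tail frequency with
add-one smoothing. Gene frequencies are counted over the 39 underlying
sets, not the 48 scoring systems, so a signature scored twice counts once.

## Benchmark statistics

- **Stratification**: strict inequalities at the 6-month PFS boundary;
  samples at exactly 6 months, or with a RECIST category that needs a
  missing PFS, are unevaluable and excluded rather than guessed.
- **Wilcoxon**: exact enumeration when n₁ + n₂ ≤ 20 without ties,
  otherwise the normal approximation with tie and continuity corrections
  (scipy). The alternative is oriented by the registry direction; AUC is
  U/(n₁n₂) from the same statistic, so AUC and p can never disagree about
  orientation.
- **Fisher**: one-sided for 2×2 (scipy); 2×k tables are tested exactly by
  enumerating tables with the observed margins, with a seeded Monte Carlo
  fallback when enumeration would exceed ~2·10⁶ tables.
- **Paired t**: two-sided on on−pre differences; all-zero differences
  report p = 1 by convention, constant non-zero differences (undefined t)
  return a flagged record carrying the mean change.
- **Survival**: groups are score > mean ("high") vs ≤ mean; log-rank and
  Cox (Efron tie handling, Wald CI) via lifelines, validated in the tests
  against a hand-accumulated O−E table and a partial-likelihood grid
  oracle. The Cox covariate defaults to the dichotomized group, matching
  the KM/forest pairing; `cox_on_continuous=True` uses the raw score.
  Non-convergent fits come back flagged, not raised.
- **Multiple testing**: per-dataset p-values are reported raw; BH
  adjustment is applied to pathway-enrichment p-values and is available
  for benchmark records via a config switch.

## Synthetic cohorts

Expression: per-gene log2-scale means ~ N(3, 2²), per-sample Gaussian
noise (SD 1 by default), exponentiated to TPM-like values. Responders
(34.2% of samples by default, the pooled objective response rate of
curated ICB cohorts) have the planted signature genes shifted by
`effect_size` × noise-SD on the log2 scale, with the sign following the
planted direction. RECIST categories and PFS are drawn so the 6-month
rule reproduces the intended labels exactly (responders get PFS in
[7, 36] months; SD-nonresponders in [0.5, 5.5]), deliberately avoiding
the unevaluable boundary. Survival times are exponential with hazard
baseline × exp(β·z(score)) and independent exponential censoring. Paired
cohorts add a per-patient random effect (SD 0.5) shared between the pre
and on biopsies, plus a configurable on-treatment shift of the planted
genes, optionally in responders only.

What this does *not* emulate: negative-binomial count overdispersion,
gene-gene correlation beyond the planted block, batch structure across
datasets, or deconvolvable cell-mixture composition. Passing tests
demonstrate the statistical machinery is calibrated and the pipeline
recovers planted truth; they do not certify performance of any biomarker
on real tumors.

## Problem sizes and numerical choices

The test suite exercises: exhaustive enrichment-score equivalence on all
transcriptomes of ≤ 8 genes and every proper subset; exact Wilcoxon and
Fisher enumeration oracles on small instances; AUC–U duality for all
group sizes up to 10+10; type-I error of the directional test at n = 50
per group over 2000 null replicates (accepted band 3–7%); Cox HR recovery
for a true HR of 2 at n = 500 (accepted band 1.6–2.5) and 95% CI coverage
over 200 null replicates at n = 120; planted-signature power (effect 1.5
SD, n = 100, ≥ 90% over 100 seeds); and end-to-end planted recovery on a
2000-gene, 120-sample cohort. Cohort sizes were chosen to make these
checks sharp while keeping the default suite fast on a single CPU.

Determinism: every stochastic component (control-gene sampling,
permutations, simulation) takes an explicit seed; reruns with the same
seed are bit-identical, and the CLI golden-file test pins one full
pipeline run.

## Known limitations

- Synthetic gene lists (above) make the affected built-in scores
  structurally faithful but not literally the published signatures.
- The Immunophenoscore is computed as a flat weighted sum rather than the
  source's z-scored sub-category averaging; with the synthetic gene table
  a faithful reimplementation of the weighting scheme would add no
  fidelity.
- NES values are normalized within a run; scores computed on different
  cohorts are not on a common scale (the benchmark only ever compares
  within a dataset, which is also why no batch correction is attempted).
- No gene-identifier alias mapping: symbols are upper-cased and matched
  literally; mismatches surface as coverage warnings.
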