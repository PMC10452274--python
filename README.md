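# icbench

Scoring and benchmarking of transcriptomic biomarkers for immune
checkpoint blockade (ICB) response.

Only a minority of cancer patients benefit from ICB therapy (anti-PD-1,
anti-PD-L1, anti-CTLA-4), and dozens of transcriptomic biomarkers have been
proposed to predict who will. `icbench` is for computational oncologists
and methods developers who want to compute those published scores from a
gene-by-sample expression matrix and evaluate them — or their own custom
signatures — against clinical outcome with one standardized statistical
workflow.

## What it computes

**A catalogue of 48 scoring systems from 39 biomarker gene sets**, spanning
three designs:

- *Self-contained* scores (23) use only the marker genes: single-gene
  markers (PD-L1, CXCL9, ...), arithmetic means (CYT = mean of *GZMA* and
  *PRF1*; IFN-gamma; EIGS; TLS; Renal-101; ...), geometric means (CRMA),
  weighted sums (TIG, Immunophenoscore, IRG, MPS), PCA-based scores
  (F-TBRS, TMEscore), and the IMPRES score, which counts how many of 15
  ordered checkpoint-gene pairs (A, B) satisfy expr(A) > expr(B) and is
  therefore an integer in [0, 15].
- *Competitive* scores (20) compare marker genes against the rest of the
  transcriptome via single-sample GSEA. For a sample with genes walked in
  descending expression order, the enrichment score is

      ES = Σ_i [ P_hit(i) − P_miss(i) ],

  where P_hit accumulates rank^α mass over signature genes (α = 0.25) and
  P_miss uniform mass over the rest; NES = ES / (max ES − min ES) over the
  cohort run. Single-set scores (APM, C-ECM, MIAS, nine `*_ssGSEA`
  variants of self-contained signatures), multi-set combinations (IIS and
  TIS sums, IPRES mean, IMS / PASS-PRE / PASS-ON weighted sums), and the
  overall-expression TIRP score (bin-matched control genes) belong here.
- *Deconvolution-like* scores (5): CD8 T-cell abundance as the mean
  log-expression of MCP-counter markers is computed natively;
  CIBERSORTx-, xCell-, EcoTyper-, and TIDE-derived values are imported
  from user-supplied score tables ("adapter" entries).

Each entry carries its expected direction of association with response
(33 positive, 15 negative), which orients the statistical tests.

**A benchmark workflow**: patients are stratified by RECIST category plus
a 6-month progression-free-survival rule (CR/PR/SD with PFS > 6 months are
responders; PD, or SD with PFS < 6 months, are nonresponders). Continuous
scores get a direction-oriented one-sided Wilcoxon rank-sum test and the
AUC (read from the same Mann-Whitney U statistic, AUC = U / n₁n₂);
categorical scores get Fisher's exact test; paired pre-/on-treatment
biopsies get a paired t-test; survival endpoints get a mean-split
Kaplan-Meier log-rank test and a univariate Cox proportional-hazards model
(HR, Wald 95% CI). A Spearman correlation landscape over the continuous
scores and a frequency-ranked preranked-GSEA operator characterize what
the biomarker catalogue collectively measures.

**A synthetic-cohort generator** with known ground truth (log-normal
TPM-like expression, a 34.2% responder fraction, planted signature effects,
paired biopsies, score-linked exponential survival) so the whole pipeline
is testable without any data downloads.

## Worked example

```python
import icbench as ib

registry = ib.load_builtin_registry()          # the 48-system catalogue
config = ib.SimulationConfig(
    seed=7, n_genes=2000, n_samples=100,
    planted_signature=("GZMA", "PRF1"),        # plant the CYT signature
    effect_size=1.5,                           # +1.5 SD in responders
    extra_genes=tuple(registry.all_genes()),   # registry genes in universe
    survival_beta=0.8,                         # score-linked hazard
)
expr, clinical, truth = ib.simulate_cohort(config)
records, summary = ib.run_dataset_benchmark(
    expr, clinical, registry, dataset_name="sim_cohort", seed=7
)
print(summary.head(5).to_string(index=False))
```

```
score_name  n_significant
       CYT              5
      PD-1              2
      ESCS              2
  TMEscore              2
   PASS-ON              2
```

The planted CYT signature tops the ranking with all five of its tests
significant (response + log-rank and Cox for both endpoints); inspecting
its records:

```
CYT response test: p=1.38e-12, AUC=0.928, n=34+66
CYT OS Cox: HR=3.17 (95% CI 1.92, 5.24), p=6.88e-06
```

A one-sided p of 1.4e-12 with AUC 0.93 says the planted 1.5-SD shift makes
CYT separate the 34 responders from the 66 nonresponders almost perfectly;
the Cox HR of 3.2 for the high-CYT group reflects the simulated hazard
link. Other scores reach sporadic significance at roughly the nominal
false-positive rate.

The same pipeline runs from the shell:

```bash
icbench simulate --seed 7 --out-dir cohort/
icbench score --expr cohort/expression.tsv --out scores.tsv
icbench benchmark --expr cohort/expression.tsv \
    --clinical cohort/clinical.tsv --seed 7 --out-dir results/
icbench characterize --scores scores.tsv --out-dir landscape/
```

Custom signatures are scored with `icbench score --custom-gmt my_sets.gmt
--calc ssgsea` (or `mean` / `sum`); a single-gene set is scored as that
gene's log2(TPM+1).

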