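# ectoscreen

Ectopic activation of tissue-specific genes — genes normally restricted to
testis, placenta or embryonic stem cells (ESC) and silent in breast — is a
recurrent feature of tumours and a source of prognostic biomarkers.
`ectoscreen` implements a complete discovery pipeline for this setting,
aimed at computational biologists working with bulk expression cohorts:

1. **Tissue predominance.** On a multi-tissue normal panel, a gene is
   predominant in a tissue when the Z-score of that tissue's mean log2
   expression, `Z = (x − mean) / std` over non-foetal tissues, exceeds 60%
   of the maximum attainable Z, `0.6 (N − 1) / √N` (3.7 for a detailed
   list of N = 40 tissues, 2.5 for N = 19 pooled groups). Candidates must
   additionally be lowly expressed in breast (linear breast mean below
   1/10 of the predominant tissue's).
2. **Ectopic activation.** Per gene, the ON/OFF threshold is
   `mean + 2·SD` of its signal in non-tumour samples; genes activated in
   more than 10% of tumour samples are retained.
3. **Survival screen.** For each retained gene, every threshold on the
   15th–85th tumour-expression percentile grid (half-percentile steps) is
   tested as an ON/OFF split by the two-group logrank test, on the full
   training cohort and on 3-fold × 5 cross-validation subsets.
   A threshold is significant at logrank p < 0.05, Benjamini–Hochberg
   FDR < 0.2 and hazard ratio > 1 (univariate Cox on the ON indicator);
   the reference threshold is the most stable one across the CV subsets.
   Reference thresholds propagate to other cohorts as percentile ranks,
   and a gene is validated when significant in ≥ 2 of 3 validation
   cohorts with p < 0.1 in the remaining one.
4. **GEC (Gene Expression Classifier).** Samples are scored by the number
   of activated panel genes; counts 0–1 vs ≥ 2 define favourable /
   unfavourable groups, evaluated by logrank tests, univariate and
   multivariate Cox models (age, molecular subtype, stage) and
   subtype-stratified analyses. The GEC− (0 genes) vs GEC+ (≥ K−1 genes)
   extremes feed a Mann–Whitney + 1.5-fold differential-expression filter.

Real cohort data of this kind lives in controlled-access or large public
repositories, so the package ships a synthetic-study generator
(`ectoscreen.synthetic`) that emulates the statistical structure — planted
tissue-predominant genes, ectopic activations at controlled frequencies,
exponential proportional-hazards survival tied to activation counts,
per-cohort platform shifts — together with a planted-truth manifest, so
the whole pipeline is testable end to end.

## Worked example

```python
import ectoscreen as es
from ectoscreen.io import PipelineCohort, run_pipeline

config = es.SimulationConfig(seed=7)          # 1 training + 3 validation cohorts
roles = ["training", "validation", "validation", "validation"]
cohorts = [PipelineCohort(c.cohort_id, role, c.expression, c.clinical)
           for c, role in zip(es.generate_cohorts(config), roles)]
panel = es.generate_normal_panel(config)

result = run_pipeline(cohorts, seed=7,
                      normal_panel_expression=panel.expression,
                      normal_panel_samples=panel.samples,
                      grid_step=2.0)

print("tissue-predominant candidates:", len(result.tissue_candidates))
print("frequently activated (>10%):", len(result.frequent_genes))
print("genes with a reference threshold:", len(result.screen_candidates))
print("validated biomarkers:", result.panel)
```

prints

```
tissue-predominant candidates: 30
frequently activated (>10%): 25
genes with a reference threshold: 7
validated biomarkers: ['G0005', 'G0002', 'G0004', 'G0003', 'G0001']
```

The generator planted 30 tissue-predominant genes (all recovered), 25 of
them tumour-activatable above the 10% frequency gate, and made G0001–G0005
prognostic (per-activation hazard ratios 2.5–3). The screen finds
reference thresholds for 7 genes and the validation step discards the two
false positives, returning exactly the five planted biomarkers. The GEC
evaluation on the same study,

```python
print(result.gec_evaluation[["n_low", "n_high", "logrank_p", "cox_hr"]].round(4))
```

```
           n_low  n_high  logrank_p  cox_hr
cohort_id                                  
cohort_02    127     123        0.0  2.2069
cohort_03    129     121        0.0  2.7076
cohort_04    127     123        0.0  2.7540
cohort_01    305     295        0.0  2.4874
```

shows the low (0–1 activated genes) vs high (≥ 2) stratification:
`logrank_p` is the low-vs-high logrank p-value and `cox_hr` the hazard
ratio per additional activated gene, reflecting the strong planted effect.

The same pipeline runs from the shell: `ectoscreen simulate` writes a
synthetic study to disk, `ectoscreen run --manifest ... --seed ... --out ...`
executes all stages from files, and `specificity` / `activation` /
`screen` / `validate` / `gec` / `de` run single stages.

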