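# hkgini

Housekeeping protein-coding genes — the genes used as normalization
references in qPCR, western blotting and integrated transcriptome studies —
are usually defined from *average* expression across tissue types, which
ignores how much expression varies between the individual donors inside
each tissue. `hkgini` implements a selection procedure that scores both
axes of variation with the Gini index and calls housekeeping genes only
where expression is equal across samples *and* across donors within every
tissue. It is aimed at people analysing GTEx-style multi-tissue bulk
RNA-seq cohorts (per-tissue GCT v1.2 TPM matrices plus a donor phenotype
table), and it ships a seeded synthetic cohort generator with planted gene
classes so the entire pipeline is testable without downloading anything.

## The statistic

For a non-negative expression vector *x₁…xₙ* (TPM), the Gini index is the
mean absolute difference between every pair of observations, scaled by
twice the mean:

```
G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² μ)
```

G = 0 means perfect equality; the upper bound (n−1)/n is reached when a
single sample holds all expression. Internally the equivalent sorted-rank
form `G = 2 Σᵢ i·x₍ᵢ₎ / (n Σx) − (n+1)/n` is used, which is O(n log n) and
agrees with the pairwise definition to 1e-12.

Three Gini axes are computed per gene:

| axis | vector scored | captures |
|---|---|---|
| Gini-subject | all samples of all tissues, pooled | overall inequality incl. tissue effects |
| Gini-tissue | each single tissue's samples | donor-to-donor inequality within a tissue |
| Gini-TPM | the per-tissue mean TPMs | classical tissue-level inequality only |

The pipeline: drop PAR-Y duplicate gene records, split biotypes, keep
protein-coding genes whose unweighted mean of per-tissue mean TPMs exceeds
0.05, then call housekeeping genes with Gini < 0.2 on the subject axis, on
the tissue axis (below threshold in *every* tissue), and as the
intersection of the two lists. Tau (tissue-specificity index), CV, mean
TPM, tissue-pass counts, sex-stratified Gini-tissue and the standard group
contrasts (Welch/paired t-tests, Pearson r²) are computed alongside.

## Worked example

```python
from hkgini import (SimConfig, generate_cohort, split_by_biotype,
                    filter_expressed, build_score_table, call_housekeeping,
                    evaluate_recovery)

cohort, catalog, truth = generate_cohort(SimConfig(seed=1))
coding, noncoding = split_by_biotype(catalog)          # 500 / 1500 genes
kept, n_removed = filter_expressed(cohort, coding, 0.05)
print(len(kept), n_removed)                            # 460 40
scores = build_score_table(cohort, kept)
call = call_housekeeping(scores, gini_threshold=0.2, mode="lt")
print(len(call.subject_axis), len(call.tissue_axis), len(call.intersection))
# 110 342 103
print(evaluate_recovery(call, truth).summary)
#               n_called  precision  recall
# subject_axis     110.0   0.909091     1.0
# tissue_axis      342.0   0.292398     1.0
# intersection     103.0   0.970874     1.0
```

The 40 genes removed by the 0.05-TPM filter are exactly the planted silent
class. The intersection recovers all 100 planted stable housekeeping genes
(recall 1.0) at precision 0.97: the tissue axis alone admits 139
tissue-specific and all 100 tissue-variable genes — tight within each
tissue but very unequal between tissues — and the subject axis is what
removes them. The pooled mean Gini-subject (0.628) is far above the mean
within-tissue Gini (0.087), which is the reason the two axes must be
scored separately.

The same steps run as narrative scripts: `analysis/01_simulate_cohort.py`
through `analysis/04_sex_and_contrasts.py` write their tables under
`results/` (large regenerable artifacts go to `scratch/`). A thin CLI
(`hkgini simulate | ingest | score | call | stratify-sex | run-all`) wraps
the same functions for shell use; `hkgini run-all --seed 1 --out run/`
produces the full result bundle with provenance headers.

Real-cohort runs use the same code path: point `ingest`/`score` at a
directory of per-tissue `*.gct[.gz]` files and the donor phenotype TSV,
choose a tissue preset (`gtex52` excludes the two cultured-cell lines;
`major27` is one representative subtype per major organ), and the same
thresholds apply.

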