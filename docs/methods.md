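# Methods

## The selection procedure

`hkgini` treats housekeeping-gene selection as a two-axis inequality
problem. Each gene of a multi-tissue cohort is scored with the Gini index
on (a) the pooled vector of all samples from all tissues in the active
tissue set ("Gini-subject" — every sample counts as one individual, donors
contributing several tissues appear once per sample) and (b) each tissue's
samples separately ("Gini-tissue", one value per gene × tissue). A third
variant, "Gini-TPM", scores the vector of per-tissue mean TPMs and
reproduces the classical tissue-level-only definition for comparison.

The calling chain is: remove pseudoautosomal chrY duplicate records
(GENCODE `_PAR_Y` suffix, or a chrY record with an identically named chrX
twin in generic GFF3); keep protein-coding biotypes; keep genes whose
unweighted mean of per-tissue mean TPMs is strictly above the expression
cutoff; call genes below the Gini threshold on the subject axis, on the
tissue axis (threshold met in every scored tissue), and intersect the two
lists. The tissue axis deliberately admits genes with strong between-tissue
shifts — a gene expressed in a single tissue and exactly zero elsewhere has
Gini-tissue 0 in the zero tissues — so the intersection, not either axis
alone, is the stringent housekeeping set.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| expression cutoff | 0.05 | TPM | on the unweighted mean of tissue means; strict `>` |
| Gini threshold | 0.2 | — | calling default is strict `<`; tissue-pass counting uses `≤` |
| comparison modes | `lt` / `le` | — | both printed conventions exist in the literature; each is a parameter and is logged with results |
| Gini estimator | population (n² denominator) | — | unbiased n(n−1) form behind a flag; it only rescales by n/(n−1) |
| bin edges | 0.05…100, 11 edges | TPM | 12 half-open expression groups for the Gini-by-expression summary |

Choices behind these: the expression average is over tissues, not samples,
so a 4-donor tissue counts as much as an 800-donor one — otherwise large
tissues dominate the filter; the reported per-gene "mean TPM" is the same
quantity. CV uses the population standard deviation; Tau is computed on
raw (not log) per-tissue means — both are reported diagnostics, not
gatekeepers, so the housekeeping calls are insensitive to these
conventions. Tissues (or sex strata) with fewer than two samples yield an
undefined score (NaN); undefined cells are skipped in tissue-axis calls
and never counted as passes, and no imputation is ever done. When the
analysis is re-run on a tissue subset, the expression filter is recomputed
on that subset rather than reusing the full-cohort gene list, because the
tissue average changes.

## Numerical choices

The production Gini uses the sorted-rank identity (O(n log n)); the
brute-force pairwise form is kept as the oracle and they agree to 1e-12
relative tolerance. Constant vectors (including all-zero) return exactly
0.0 by short-circuit, so equality never carries a 1e-16 float residue into
threshold comparisons; the matrix form coerces input to one memory layout
before sorting so the same numbers sliced different ways give bitwise
identical scores. All-zero vectors have Gini 0 by the all-equal
convention; no epsilon shift is applied since TPM ≥ 0. CV at zero mean,
Tau at zero maximum or n = 1, and Pearson r on zero-variance input return
NaN rather than raising, because the expression filter runs first in the
pipeline.

## The synthetic cohort

The generator emulates the study conditions of a GTEx-like cohort at desk
scale: 20 tissues with strongly unbalanced sample counts (4–300, 1,420
samples total), 2,000 genes (500 protein-coding), values log-normal within
a tissue. Planted classes (counts in parentheses):

* **stable_housekeeping** (100): one gene-level log-mean (baseline
  ~30 TPM, gene-to-gene log-sd 0.3), between-tissue log-sd 0.05,
  within-tissue log-sd 0.15 → Gini ≈ 0.09 on both axes.
* **tissue_specific** (150): baseline ×10 in one home tissue (assigned
  round-robin), exact zero elsewhere.
* **within_tissue_stable_tissue_variable** (100): within-tissue log-sd
  0.15 but between-tissue log-sd 1.0 — the class that passes the tissue
  axis and fails the subject axis.
* **heterogeneous_marker** (100): within-tissue log-sd 0.35 in ordinary
  tissues (Gini ≈ 0.19, just under threshold) and 1.5 in the designated
  heterogeneous tissue — its heterogeneity is concentrated there.
* **sex_dimorphic** (10): stable-like, but male samples' within-tissue sd
  ×4 in one designated tissue, giving the male > female Gini ordering.
* **silent** (40): exact zeros; removed by the expression filter.
* **background_noncoding** (1,500): non-coding biotype, 90% dropout with
  sporadic tiny values.

The largest tissue is designated heterogeneous (all within-tissue sds ×1.8
— the whole-blood analogue with the highest per-tissue mean Gini), the
second largest quiet (×0.5 — the cerebellum/testis analogue), the third
largest carries the sex effect (so both sexes have ample samples).
Randomness uses one root seed with per-gene substreams spawned by gene
index and a separate stream for the donor layout, so the output is
byte-reproducible and adding genes never perturbs existing ones.

What the generator does *not* emulate: count-level (negative-binomial)
noise, library-size or batch effects, donor age trends, correlated gene
modules, and the long-tailed biotype mixture of a real annotation. Tests
passing on this cohort therefore demonstrate that the pipeline's logic —
filtering, the three axes, thresholding, intersection, stratification —
behaves as designed, not that any particular real-data gene list would be
reproduced. One visible idealisation: within a tissue the data are exactly
log-normal, so Gini-tissue and within-tissue CV are near-deterministic
functions of each other (median r² ≈ 0.99 across tissues); on real
cohorts the same correlation is strong but far from perfect.

## Scale and runtime

Default problem sizes were chosen so that the complete pipeline runs in
seconds and the whole test suite in well under a minute on one CPU: 1,420
samples pooled per gene for the subject axis, per-tissue vectors of 4–300
for the tissue axis, 1,000 random vectors of length ≤ 200 for the
oracle-equivalence check. A full-scale cohort (tens of thousands of genes,
~17k samples, 52 tissues) uses the identical code path through the
`gtex52` / `major27` presets and runs in tens of minutes.

## Known limitations

* The Gini estimate is biased low by the factor (n−1)/n at small n, so
  4-sample tissues systematically report lower Gini-tissue; the pipeline
  reports scores as estimated and leaves sample-size interpretation to the
  analyst (undefined only below n = 2).
* Tissue-axis calls treat exact-zero tissues as perfectly equal (Gini 0);
  real near-silent genes with sporadic detection instead score very high.
  Both behaviours are faithful to the definition but mean the tissue axis
  alone is not a housekeeping definition.
* No multiple-testing correction is applied: the pipeline performs two
  planned group contrasts, not a scan.
* Donor collapsing is not performed: a donor contributing two samples to
  one tissue is two observations.
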