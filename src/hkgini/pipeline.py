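"""Housekeeping-gene calling from multi-tissue expression cohorts.

Three Gini-index axes are scored per gene:

* **Gini-subject** — over the pooled concatenation of all samples from all
  tissues in the active tissue set (every sample is one "individual").
* **Gini-tissue** — within each single tissue's samples; one value per
  (gene, tissue), summarised by the per-gene mean over tissues.
* **Gini-TPM** — over the vector of per-tissue mean TPMs, i.e. the
  classical tissue-level inequality that ignores donor variation.

A housekeeping call combines an expression filter (unweighted mean of
per-tissue mean TPMs above a cutoff, default 0.05) with a Gini threshold
(default 0.2) on one or both axes: the subject axis keeps genes whose
pooled Gini is below threshold; the tissue axis keeps genes below
threshold in *every* scored tissue; the intersection of the two lists is
the stringent combined set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort
from .metrics import coefficient_of_variation, gini_matrix, tau

__all__ = [
    "GiniTissueResult",
    "ScoreTable",
    "HousekeepingCall",
    "tissue_mean_tpm",
    "filter_expressed",
    "score_gini_subject",
    "score_gini_tissue",
    "score_gini_tpm",
    "build_score_table",
    "count_tissue_passes",
    "call_housekeeping",
    "intersect_gene_lists",
    "stratify_by_sex",
    "compare_groups",
    "correlate_scores",
]

DEFAULT_TPM_CUTOFF = 0.05
DEFAULT_GINI_THRESHOLD = 0.2


def _check_genes(cohort: Cohort, genes) -> list[str]:
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    universe = set(cohort.gene_ids)
    missing = [g for g in genes if g not in universe]
    if missing:
        raise KeyError(f"gene(s) absent from cohort: {missing[:5]}")
    return genes


def tissue_mean_tpm(cohort: Cohort, genes) -> pd.DataFrame:
    """Per-tissue mean TPM: genes x tissues."""
    genes = _check_genes(cohort, genes)
    cols = {
        name: m.values.loc[genes].mean(axis=1) for name, m in cohort.tissues.items()
    }
    return pd.DataFrame(cols, index=genes)


def filter_expressed(
    cohort: Cohort, genes, tpm_cutoff: float = DEFAULT_TPM_CUTOFF
) -> tuple[list[str], int]:
    """Keep genes whose unweighted mean of per-tissue mean TPMs exceeds
    the cutoff (strictly).  Returns (kept genes, number removed).

    The average is over tissues, not samples, so a small tissue counts as
    much as a large one — the same convention the reported per-gene
    "average TPM" uses.
    """
    if tpm_cutoff < 0:
        raise ValueError("tpm_cutoff must be >= 0")
    means = tissue_mean_tpm(cohort, genes).mean(axis=1)
    kept = [g for g in means.index if means.loc[g] > tpm_cutoff]
    return kept, len(means) - len(kept)


def score_gini_subject(cohort: Cohort, genes) -> pd.Series:
    """Gini per gene over all samples of all tissues pooled together."""
    genes = _check_genes(cohort, genes)
    pooled = cohort.pooled_values(genes)
    return pd.Series(gini_matrix(pooled.to_numpy()), index=genes, name="gini_subject")


@dataclass
class GiniTissueResult:
    """Per-tissue Gini grid with its two marginal summaries."""

    grid: pd.DataFrame  # genes x tissues; NaN where a tissue has < 2 samples
    per_gene_mean: pd.Series  # mean over tissues (NaN cells skipped)
    per_tissue_mean: pd.Series  # mean over genes


def score_gini_tissue(cohort: Cohort, genes) -> GiniTissueResult:
    """Gini per gene within each tissue's samples independently.

    Tissues with fewer than 2 samples yield NaN for every gene: a single
    observation carries no inequality information.
    """
    genes = _check_genes(cohort, genes)
    cols = {}
    for name, m in cohort.tissues.items():
        cols[name] = gini_matrix(m.values.loc[genes].to_numpy(), min_n=2)
    grid = pd.DataFrame(cols, index=genes)
    return GiniTissueResult(
        grid=grid,
        per_gene_mean=grid.mean(axis=1, skipna=True),
        per_tissue_mean=grid.mean(axis=0, skipna=True),
    )


def score_gini_tpm(cohort: Cohort, genes) -> pd.Series:
    """Gini per gene over the vector of per-tissue mean TPMs."""
    means = tissue_mean_tpm(cohort, genes)
    if means.shape[1] < 2:
        raise ValueError("Gini-TPM needs at least 2 tissues")
    return pd.Series(
        gini_matrix(means.to_numpy()), index=means.index, name="gini_tpm"
    )


def count_tissue_passes(
    grid: pd.DataFrame,
    threshold: float = DEFAULT_GINI_THRESHOLD,
    mode: str = "le",
) -> pd.Series:
    """Per gene, how many tissues' Gini-tissue values satisfy the
    threshold comparison.  NaN cells (undefined scores) never count.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if mode == "le":
        passes = grid.le(threshold)
    elif mode == "lt":
        passes = grid.lt(threshold)
    else:
        raise ValueError(f"unknown comparison mode {mode!r}; use 'lt' or 'le'")
    return passes.where(grid.notna(), False).sum(axis=1).astype(int)


@dataclass
class ScoreTable:
    """Per-gene metric table plus the per-tissue Gini grid behind it."""

    table: pd.DataFrame  # columns: mean_tpm, gini_subject, gini_tissue_mean,
    #           gini_tpm, tau, cv, tissue_pass_count
    gini_tissue: GiniTissueResult
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def build_score_table(
    cohort: Cohort,
    genes,
    pass_threshold: float = DEFAULT_GINI_THRESHOLD,
    pass_mode: str = "le",
) -> ScoreTable:
    """Score every metric for the given genes on the cohort's tissue set."""
    genes = _check_genes(cohort, genes)
    means = tissue_mean_tpm(cohort, genes)
    gsub = score_gini_subject(cohort, genes)
    gtis = score_gini_tissue(cohort, genes)
    if means.shape[1] >= 2:
        gtpm = score_gini_tpm(cohort, genes)
    else:  # one tissue: cross-tissue inequality is undefined
        gtpm = pd.Series(np.nan, index=genes, name="gini_tpm")
    mean_arr = means.to_numpy()
    table = pd.DataFrame(
        {
            "mean_tpm": means.mean(axis=1),
            "gini_subject": gsub,
            "gini_tissue_mean": gtis.per_gene_mean,
            "gini_tpm": gtpm,
            "tau": [tau(row) for row in mean_arr],
            "cv": [coefficient_of_variation(row) for row in mean_arr],
            "tissue_pass_count": count_tissue_passes(
                gtis.grid, pass_threshold, pass_mode
            ),
        },
        index=genes,
    )
    return ScoreTable(
        table=table,
        gini_tissue=gtis,
        params={
            "tissues": list(cohort.tissue_names),
            "pass_threshold": pass_threshold,
            "pass_mode": pass_mode,
        },
    )


@dataclass
class HousekeepingCall:
    """The three called gene lists plus the parameters that produced them."""

    subject_axis: list[str]
    tissue_axis: list[str]
    intersection: list[str]
    params: dict = field(default_factory=dict)


def _passes(value: float, threshold: float, mode: str) -> bool:
    if np.isnan(value):
        return False
    return value <= threshold if mode == "le" else value < threshold


def call_housekeeping(
    scores: ScoreTable,
    gini_threshold: float = DEFAULT_GINI_THRESHOLD,
    mode: str = "lt",
    tissue_set=None,
) -> HousekeepingCall:
    """Call housekeeping genes on both Gini axes.

    subject_axis: genes whose pooled Gini-subject satisfies the threshold.
    tissue_axis: genes satisfying it in *every* tissue of ``tissue_set``
    (default: every tissue the grid scored; tissues whose score is
    undefined (NaN, <2 samples) are skipped rather than failed).
    intersection: set intersection, in score-table order.
    """
    if not 0 < gini_threshold < 1:
        raise ValueError("gini_threshold must lie in (0, 1)")
    if mode not in ("lt", "le"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    grid = scores.gini_tissue.grid
    if tissue_set is None:
        tissue_set = list(grid.columns)
    else:
        tissue_set = list(tissue_set)
        unknown = [t for t in tissue_set if t not in grid.columns]
        if unknown:
            raise KeyError(f"tissue(s) not scored: {unknown}")
    sub = grid[tissue_set]
    ok = sub.le(gini_threshold) if mode == "le" else sub.lt(gini_threshold)
    ok = ok | sub.isna()  # undefined tissues are skipped, not failed
    tissue_axis_mask = ok.all(axis=1) & sub.notna().any(axis=1)

    gsub = scores.table["gini_subject"]
    subject_axis = [
        g for g in scores.genes if _passes(gsub.loc[g], gini_threshold, mode)
    ]
    tissue_axis = [g for g in scores.genes if tissue_axis_mask.loc[g]]
    inter = intersect_gene_lists(subject_axis, tissue_axis)
    return HousekeepingCall(
        subject_axis=subject_axis,
        tissue_axis=tissue_axis,
        intersection=inter,
        params={
            "gini_threshold": gini_threshold,
            "mode": mode,
            "tissue_set": tissue_set,
            **scores.params,
        },
    )


def intersect_gene_lists(*lists) -> list[str]:
    """Exact set intersection of >= 2 gene lists, in first-list order."""
    if len(lists) < 2:
        raise ValueError("need at least two gene lists")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [g for g in lists[0] if g in common]


def stratify_by_sex(
    cohort: Cohort, tissue: str, gene: str
) -> tuple[float, float]:
    """Gini-tissue for one gene computed separately on male and female
    samples of one tissue.  A sex with fewer than 2 samples scores NaN.
    """
    if tissue not in cohort.tissues:
        raise KeyError(f"unknown tissue {tissue!r}")
    m = cohort.tissues[tissue]
    if gene not in m.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    row = m.values.loc[gene]
    sexes = cohort.subjects.table["sex"]
    out = []
    for sex in ("male", "female"):
        cols = [
            s
            for s in m.sample_ids
            if sexes.get(m.subject_of_sample[s], "unknown") == sex
        ]
        if len(cols) < 2:
            out.append(float("nan"))
        else:
            out.append(float(gini_matrix(row[cols].to_numpy()[None, :])[0]))
    return out[0], out[1]


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    paired: bool
    significant: bool


def compare_groups(
    a, b, paired: bool = False, alpha: float = 0.05
) -> GroupComparison:
    """Two-sided t-test between two score vectors.

    Unpaired uses Welch's correction; paired requires aligned, equal-length
    vectors.  Identical paired vectors report statistic 0 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError(
                f"paired comparison needs equal lengths, got {a.size} vs {b.size}"
            )
        diff = a - b
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(a, b)
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=float(stat),
        p_value=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        paired=paired,
        significant=bool(p < alpha),
    )


def correlate_scores(x, y) -> tuple[float, float]:
    """Pearson correlation and its square; NaN for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("score vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("undefined entries in score vectors")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
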