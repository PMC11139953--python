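"""Seeded synthetic multi-tissue cohorts with known gene-class truth.

The generator emulates the structure of a GTEx-style bulk cohort: a few
dozen tissues with strongly unbalanced donor counts (4 up to a few
hundred), non-negative TPM-like values that are log-normal within a
tissue, a protein-coding / non-coding biotype split with non-coding genes
mostly at zero, and planted gene classes that exercise every decision the
housekeeping pipeline makes:

* ``stable_housekeeping`` — one log-mean shared across tissues and donors,
  small within- and between-tissue spread; the class the combined call
  should recover.
* ``tissue_specific`` — high expression in one designated tissue, exact
  zero elsewhere (testis-only-marker analogue).
* ``within_tissue_stable_tissue_variable`` — tight within every tissue but
  large tissue-to-tissue mean shifts; passes the tissue axis, fails the
  subject axis.
* ``heterogeneous_marker`` — large within-tissue spread, largest in the
  designated heterogeneous tissue (whole-blood analogue).
* ``sex_dimorphic`` — within-tissue spread inflated in males only, in one
  designated tissue (PZP-in-liver analogue).
* ``silent`` — all zeros; removed by the expression filter.
* ``background_noncoding`` — mostly zeros with sporadic tiny values.

One tissue is designated heterogeneous (within-tissue noise scaled up for
every gene) and one quiet (scaled down), reproducing the blood-vs-
cerebellum contrast in per-tissue average Gini.  Randomness uses one root
seed with per-gene substreams spawned by gene index, so adding genes never
perturbs existing ones and the same seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneRecord
from .io import Cohort, ExpressionMatrix, SubjectTable, write_gct
from .pipeline import HousekeepingCall

__all__ = [
    "SimConfig",
    "TruthLabels",
    "GENE_CLASSES",
    "generate_cohort",
    "evaluate_recovery",
    "write_cohort",
    "RecoveryReport",
]

GENE_CLASSES = (
    "stable_housekeeping",
    "tissue_specific",
    "within_tissue_stable_tissue_variable",
    "heterogeneous_marker",
    "sex_dimorphic",
    "silent",
    "background_noncoding",
)

CODING_CLASSES = frozenset(GENE_CLASSES[:6])

#: Strongly unbalanced per-tissue sample counts (ascending), echoing the
#: 4-to-800 spread of real multi-tissue cohorts at desk scale.
DEFAULT_SAMPLES = (
    4, 8, 10, 12, 16, 20, 24, 30, 36, 40,
    50, 60, 70, 80, 90, 100, 120, 150, 200, 300,
)

DEFAULT_CLASS_COUNTS = {
    "stable_housekeeping": 100,
    "tissue_specific": 150,
    "within_tissue_stable_tissue_variable": 100,
    "heterogeneous_marker": 100,
    "sex_dimorphic": 10,
    "silent": 40,
    "background_noncoding": 1500,
}


@dataclass
class SimConfig:
    """Generator parameters.  Defaults give 20 tissues, 2,000 genes and
    1,440 samples — the full pipeline runs in seconds at this scale."""

    samples_per_tissue: tuple = DEFAULT_SAMPLES
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    baseline_log_mean: float = math.log(30.0)  # ~30 TPM baseline
    gene_level_sd: float = 0.3          # gene-to-gene baseline spread
    stable_within_sd: float = 0.15      # log-sd within a tissue, stable class
    stable_between_sd: float = 0.05     # tissue-to-tissue shift, stable class
    variable_between_sd: float = 1.0    # tissue shifts, tissue-variable class
    marker_within_sd: float = 0.35      # heterogeneous markers, ordinary tissues
    marker_het_sd: float = 1.5          # heterogeneous markers, designated tissue
    tissue_specific_fold: float = 10.0  # fold over baseline in the home tissue
    sex_effect_fold: float = 4.0        # male within-sd multiplier, one tissue
    het_tissue_scale: float = 1.8       # tissue-wide noise scale, heterogeneous
    quiet_tissue_scale: float = 0.5     # tissue-wide noise scale, quiet tissue
    heterogeneous_tissue_index: int | None = None  # default: largest tissue
    quiet_tissue_index: int | None = None          # default: 2nd largest
    sex_tissue_index: int | None = None            # default: 3rd largest
    sex_ratio: float = 0.5
    noncoding_detect_prob: float = 0.1  # non-coding genes: P(non-zero cell)
    noncoding_log_mean: float = math.log(0.2)
    noncoding_log_sd: float = 1.0
    seed: int = 1

    def validate(self) -> None:
        if len(self.samples_per_tissue) < 2:
            raise ValueError("need at least 2 tissues")
        if any(n < 1 for n in self.samples_per_tissue):
            raise ValueError("every tissue needs at least 1 sample")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        unknown = set(self.class_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {sorted(unknown)}")
        for name in (
            "gene_level_sd", "stable_within_sd", "stable_between_sd",
            "variable_between_sd", "marker_within_sd", "marker_het_sd",
            "het_tissue_scale", "quiet_tissue_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0 <= self.noncoding_detect_prob <= 1:
            raise ValueError("noncoding_detect_prob must lie in [0, 1]")

    # designated tissues, resolved by sample-count rank (ties by index)
    def _designated(self) -> tuple[int, int, int]:
        order = sorted(
            range(len(self.samples_per_tissue)),
            key=lambda i: (self.samples_per_tissue[i], i),
        )
        het = (
            self.heterogeneous_tissue_index
            if self.heterogeneous_tissue_index is not None
            else order[-1]
        )
        quiet = (
            self.quiet_tissue_index
            if self.quiet_tissue_index is not None
            else order[-2]
        )
        sex = (
            self.sex_tissue_index
            if self.sex_tissue_index is not None
            else order[-3] if len(order) >= 3 else order[0]
        )
        return het, quiet, sex


@dataclass
class TruthLabels:
    """Per-gene planted class assignment."""

    labels: pd.Series  # index gene_id -> class name

    def genes_in(self, gene_class: str) -> list[str]:
        if gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {gene_class!r}")
        return list(self.labels.index[self.labels == gene_class])

    @property
    def coding_genes(self) -> list[str]:
        return list(self.labels.index[self.labels.isin(CODING_CLASSES)])

    def to_tsv(self, path) -> None:
        self.labels.rename("gene_class").rename_axis("gene_id").to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "TruthLabels":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(labels=df["gene_class"])


def _tissue_noise_scales(config: SimConfig) -> np.ndarray:
    het, quiet, _ = config._designated()
    scales = np.ones(len(config.samples_per_tissue))
    scales[het] = config.het_tissue_scale
    scales[quiet] = config.quiet_tissue_scale
    return scales


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene_index,)))


def generate_cohort(config: SimConfig) -> tuple[Cohort, GeneCatalog, TruthLabels]:
    """Generate a seeded cohort, its gene catalog, and truth labels."""
    config.validate()
    n_tissues = len(config.samples_per_tissue)
    het_idx, quiet_idx, sex_idx = config._designated()
    scales = _tissue_noise_scales(config)
    tissue_names = [f"tissue_{i:02d}" for i in range(n_tissues)]

    # --- donors and sample layout (meta stream, gene-independent) ------
    meta = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2**20,))
    )
    n_donors = max(config.samples_per_tissue) + 50
    donors = [f"GTEX-S{i:04d}" for i in range(n_donors)]
    donor_sex = np.where(
        meta.random(n_donors) < config.sex_ratio, "male", "female"
    )
    donor_age = meta.integers(21, 71, size=n_donors)
    tissue_samples: list[list[str]] = []
    tissue_donor_idx: list[np.ndarray] = []
    for t, n_t in enumerate(config.samples_per_tissue):
        idx = meta.choice(n_donors, size=n_t, replace=False)
        tissue_donor_idx.append(idx)
        tissue_samples.append(
            [f"{donors[d]}-{t:02d}{j:03d}-SM" for j, d in enumerate(idx)]
        )

    # male mask per tissue, used by the sex-dimorphic class
    male_masks = [donor_sex[idx] == "male" for idx in tissue_donor_idx]

    # --- gene roster ---------------------------------------------------
    gene_classes: list[str] = []
    for cls in GENE_CLASSES:
        gene_classes.extend([cls] * config.class_counts.get(cls, 0))
    n_genes = len(gene_classes)
    gene_ids = [f"SIMG{i:05d}.1" for i in range(n_genes)]
    symbols = [f"SIM{i:05d}" for i in range(n_genes)]

    # --- per-gene expression -------------------------------------------
    per_tissue_rows: list[list[np.ndarray]] = [[] for _ in range(n_tissues)]
    n_specific_assigned = 0
    for g, cls in enumerate(gene_classes):
        rng = _gene_rng(config.seed, g)
        rows = _simulate_gene(
            cls, rng, config, scales, male_masks,
            het_idx, sex_idx, n_specific_assigned,
        )
        if cls == "tissue_specific":
            n_specific_assigned += 1
        for t in range(n_tissues):
            per_tissue_rows[t].append(rows[t])

    # --- assemble ------------------------------------------------------
    symbol_series = pd.Series(symbols, index=gene_ids)
    matrices = []
    for t, name in enumerate(tissue_names):
        values = pd.DataFrame(
            np.vstack([per_tissue_rows[t][g] for g in range(n_genes)]),
            index=gene_ids,
            columns=tissue_samples[t],
        )
        subject_map = {
            s: donors[d] for s, d in zip(tissue_samples[t], tissue_donor_idx[t])
        }
        matrices.append(
            ExpressionMatrix(
                tissue_name=name,
                values=values,
                symbols=symbol_series,
                subject_of_sample=subject_map,
            )
        )
    subjects = SubjectTable(
        pd.DataFrame(
            {"sex": donor_sex, "age": donor_age},
            index=pd.Index(donors, name="subject_id"),
        )
    )
    cohort = Cohort(
        tissues={m.tissue_name: m for m in matrices},
        subjects=subjects,
        gene_ids=list(gene_ids),
    )
    catalog = GeneCatalog(
        GeneRecord(
            gene_id=gid,
            symbol=sym,
            biotype="protein_coding" if cls in CODING_CLASSES else "lncRNA",
            chromosome="chr1",
            par_y_flag=False,
        )
        for gid, sym, cls in zip(gene_ids, symbols, gene_classes)
    )
    truth = TruthLabels(
        labels=pd.Series(gene_classes, index=pd.Index(gene_ids, name="gene_id"))
    )
    return cohort, catalog, truth


def _simulate_gene(
    cls: str,
    rng: np.random.Generator,
    config: SimConfig,
    scales: np.ndarray,
    male_masks: list[np.ndarray],
    het_idx: int,
    sex_idx: int,
    specific_serial: int,
) -> list[np.ndarray]:
    """One gene's TPM row for every tissue, by planted class."""
    counts = config.samples_per_tissue
    n_tissues = len(counts)
    base = config.baseline_log_mean + rng.normal(0.0, config.gene_level_sd)

    if cls == "silent":
        return [np.zeros(n) for n in counts]

    if cls == "background_noncoding":
        rows = []
        for n in counts:
            detected = rng.random(n) < config.noncoding_detect_prob
            vals = np.where(
                detected,
                np.exp(rng.normal(config.noncoding_log_mean, config.noncoding_log_sd, n)),
                0.0,
            )
            rows.append(vals)
        return rows

    if cls == "tissue_specific":
        home = specific_serial % n_tissues
        rows = []
        for t, n in enumerate(counts):
            if t == home:
                mu = base + math.log(config.tissue_specific_fold)
                rows.append(np.exp(mu + 0.3 * scales[t] * rng.normal(size=n)))
            else:
                rows.append(np.zeros(n))
        return rows

    if cls == "stable_housekeeping":
        between, within = config.stable_between_sd, config.stable_within_sd
    elif cls == "within_tissue_stable_tissue_variable":
        between, within = config.variable_between_sd, config.stable_within_sd
    elif cls == "heterogeneous_marker":
        between, within = 0.1, config.marker_within_sd
    elif cls == "sex_dimorphic":
        between, within = config.stable_between_sd, config.stable_within_sd
    else:  # pragma: no cover - roster is validated upstream
        raise ValueError(f"unknown gene class {cls!r}")

    rows = []
    for t, n in enumerate(counts):
        mu_t = base + rng.normal(0.0, between)
        sd = np.full(n, within * scales[t])
        if cls == "heterogeneous_marker" and t == het_idx:
            sd[:] = config.marker_het_sd * scales[t]
        if cls == "sex_dimorphic" and t == sex_idx:
            sd[male_masks[t]] *= config.sex_effect_fold
        rows.append(np.exp(mu_t + sd * rng.normal(size=n)))
    return rows


@dataclass
class RecoveryReport:
    """Precision/recall of each called list against the stable class,
    plus per-class membership counts in each list."""

    summary: pd.DataFrame    # rows subject_axis/tissue_axis/intersection
    confusion: pd.DataFrame  # planted class x called list -> count

    def __str__(self) -> str:
        return (
            "recovery vs planted stable_housekeeping class:\n"
            + self.summary.to_string()
        )


def evaluate_recovery(call: HousekeepingCall, truth: TruthLabels) -> RecoveryReport:
    """Score called lists against the planted stable_housekeeping class.

    Precision of an empty list is NaN (undefined), its recall 0.
    """
    universe = set(truth.labels.index)
    for name in ("subject_axis", "tissue_axis", "intersection"):
        stray = [g for g in getattr(call, name) if g not in universe]
        if stray:
            raise ValueError(
                f"called gene(s) outside the truth universe in {name}: {stray[:3]}"
            )
    stable = set(truth.genes_in("stable_housekeeping"))
    rows = {}
    confusion = {}
    for name in ("subject_axis", "tissue_axis", "intersection"):
        called = set(getattr(call, name))
        tp = len(called & stable)
        rows[name] = {
            "n_called": len(called),
            "precision": tp / len(called) if called else float("nan"),
            "recall": tp / len(stable) if stable else float("nan"),
        }
        confusion[name] = {
            cls: len(called & set(truth.genes_in(cls))) for cls in GENE_CLASSES
        }
    return RecoveryReport(
        summary=pd.DataFrame(rows).T,
        confusion=pd.DataFrame(confusion),
    )


def write_cohort(cohort: Cohort, catalog: GeneCatalog, truth: TruthLabels, outdir) -> None:
    """Write the cohort as per-tissue GCT + phenotype/truth/catalog TSVs."""
    os.makedirs(outdir, exist_ok=True)
    for name, matrix in cohort.tissues.items():
        write_gct(matrix, os.path.join(outdir, f"{name}.gct"))
    sex_code = {"male": 1, "female": 2}
    pheno = pd.DataFrame(
        {
            "SUBJID": cohort.subjects.table.index,
            "SEX": [
                sex_code.get(s, 99) for s in cohort.subjects.table["sex"]
            ],
            "AGE": cohort.subjects.table["age"].to_numpy(),
        }
    )
    pheno.to_csv(os.path.join(outdir, "subject_phenotypes.tsv"), sep="\t", index=False)
    truth.to_tsv(os.path.join(outdir, "truth_labels.tsv"))
    catalog.to_tsv(os.path.join(outdir, "gene_catalog.tsv"))
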