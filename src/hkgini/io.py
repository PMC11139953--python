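"""Expression cohort I/O: GCT v1.2 matrices, subject phenotypes, tissue presets.

A cohort is a set of per-tissue gene x sample TPM matrices (GCT v1.2, the
format the GTEx portal distributes per tissue) sharing one gene universe,
plus a subject phenotype table.  Samples, not donors, are the unit of
observation; the donor id is carried only for stratification.
"""

from __future__ import annotations

import gzip
import io as _io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SubjectTable",
    "Cohort",
    "read_gct",
    "write_gct",
    "read_subject_phenotypes",
    "assemble_cohort",
    "tissue_preset",
    "CELL_LINE_TISSUES",
    "GTEX52",
    "MAJOR27",
]

#: Cultured-cell expression files excluded from every tissue cohort.
CELL_LINE_TISSUES = (
    "cells_cultured_fibroblasts",
    "cells_ebv-transformed_lymphocytes",
)

#: The 52 retained GTEx v8 tissue subtypes (54 portal files minus the two
#: cultured-cell lines above), canonical lower-snake-case names.
GTEX52 = (
    "adipose_subcutaneous",
    "adipose_visceral_omentum",
    "adrenal_gland",
    "artery_aorta",
    "artery_coronary",
    "artery_tibial",
    "bladder",
    "brain_amygdala",
    "brain_anterior_cingulate_cortex_ba24",
    "brain_caudate_basal_ganglia",
    "brain_cerebellar_hemisphere",
    "brain_cerebellum",
    "brain_cortex",
    "brain_frontal_cortex_ba9",
    "brain_hippocampus",
    "brain_hypothalamus",
    "brain_nucleus_accumbens_basal_ganglia",
    "brain_putamen_basal_ganglia",
    "brain_spinal_cord_cervical_c-1",
    "brain_substantia_nigra",
    "breast_mammary_tissue",
    "cervix_ectocervix",
    "cervix_endocervix",
    "colon_sigmoid",
    "colon_transverse",
    "esophagus_gastroesophageal_junction",
    "esophagus_mucosa",
    "esophagus_muscularis",
    "fallopian_tube",
    "heart_atrial_appendage",
    "heart_left_ventricle",
    "kidney_cortex",
    "kidney_medulla",
    "liver",
    "lung",
    "minor_salivary_gland",
    "muscle_skeletal",
    "nerve_tibial",
    "ovary",
    "pancreas",
    "pituitary",
    "prostate",
    "skin_not_sun_exposed_suprapubic",
    "skin_sun_exposed_lower_leg",
    "small_intestine_terminal_ileum",
    "spleen",
    "stomach",
    "testis",
    "thyroid",
    "uterus",
    "vagina",
    "whole_blood",
)

#: One representative, well-sampled subtype per major organ (27 tissues).
MAJOR27 = (
    "adipose_subcutaneous",
    "adrenal_gland",
    "artery_aorta",
    "bladder",
    "brain_cerebellum",
    "brain_cortex",
    "breast_mammary_tissue",
    "colon_transverse",
    "esophagus_mucosa",
    "heart_atrial_appendage",
    "liver",
    "lung",
    "minor_salivary_gland",
    "muscle_skeletal",
    "nerve_tibial",
    "ovary",
    "pancreas",
    "pituitary",
    "prostate",
    "skin_sun_exposed_lower_leg",
    "small_intestine_terminal_ileum",
    "spleen",
    "stomach",
    "testis",
    "thyroid",
    "uterus",
    "vagina",
)

#: GTEx sample ids look like GTEX-ABCD-0011-...; the donor is the first
#: two dash-delimited tokens.
DEFAULT_SUBJECT_PATTERN = r"^([^-]+-[^-]+)"


def tissue_preset(name: str) -> list[str]:
    """Return the ordered tissue-name list for a named preset."""
    presets = {"gtex52": GTEX52, "major27": MAJOR27}
    if name not in presets:
        raise ValueError(
            f"unknown tissue preset {name!r}; known: {sorted(presets)}"
        )
    return list(presets[name])


def subject_of(sample_id: str, pattern: str = DEFAULT_SUBJECT_PATTERN) -> str:
    m = re.match(pattern, sample_id)
    if m is None:
        raise ValueError(
            f"sample id {sample_id!r} does not match subject pattern {pattern!r}"
        )
    return m.group(1)


@dataclass
class ExpressionMatrix:
    """One tissue's gene x sample TPM table.

    ``values`` is a DataFrame indexed by versioned gene id with sample-id
    columns; ``symbols`` keeps the GCT Description column.
    """

    tissue_name: str
    values: pd.DataFrame
    symbols: pd.Series
    subject_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError(
                f"negative expression value in tissue {self.tissue_name!r}"
            )
        missing = [s for s in self.values.columns if s not in self.subject_of_sample]
        if missing:
            raise ValueError(f"samples without subject mapping: {missing[:3]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SubjectTable:
    """Donor phenotype table: subject_id -> sex / age."""

    table: pd.DataFrame  # index subject_id, columns sex, age

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate subject_id: {dup}")

    def sex_of(self, subject_id: str) -> str:
        return str(self.table.loc[subject_id, "sex"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Cohort:
    """Ordered per-tissue matrices + donor phenotypes over one gene universe."""

    tissues: dict[str, ExpressionMatrix]
    subjects: SubjectTable
    gene_ids: list[str]

    @property
    def tissue_names(self) -> list[str]:
        return list(self.tissues)

    @property
    def n_samples(self) -> int:
        return sum(m.n_samples for m in self.tissues.values())

    def subset(self, tissue_names) -> "Cohort":
        """Restrict to the given tissues (order as given); values untouched."""
        missing = [t for t in tissue_names if t not in self.tissues]
        if missing:
            raise KeyError(f"unknown tissue(s): {missing}")
        return Cohort(
            tissues={t: self.tissues[t] for t in tissue_names},
            subjects=self.subjects,
            gene_ids=list(self.gene_ids),
        )

    def pooled_values(self, genes=None) -> pd.DataFrame:
        """Concatenate all tissues' sample columns (genes x all samples)."""
        frames = [m.values for m in self.tissues.values()]
        pooled = pd.concat(frames, axis=1)
        if genes is not None:
            pooled = pooled.loc[list(genes)]
        return pooled

    def orphan_samples(self) -> list[str]:
        """Samples whose subject is absent from the phenotype table."""
        known = set(self.subjects.table.index)
        return [
            s
            for m in self.tissues.values()
            for s, subj in m.subject_of_sample.items()
            if subj not in known
        ]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": self.tissue_names,
                "n_samples": [m.n_samples for m in self.tissues.values()],
                "n_genes": [len(m.gene_ids) for m in self.tissues.values()],
            }
        )


def _open_read(source):
    if hasattr(source, "read"):
        return False, source
    path = str(source)
    if path.endswith(".gz"):
        return True, _io.TextIOWrapper(gzip.open(path, "rb"))
    return True, open(path, "r")


def read_gct(
    source,
    tissue_name: str,
    subject_pattern: str = DEFAULT_SUBJECT_PATTERN,
) -> ExpressionMatrix:
    """Read a GCT v1.2 stream or path into an :class:`ExpressionMatrix`.

    GCT v1.2: line 1 is ``#1.2``; line 2 is ``<n_rows>\\t<n_cols>``; line 3
    is the header ``Name  Description  <sample ids...>``; then one data row
    per gene.  Gzip-transparent for paths ending in ``.gz``.
    """
    close, fh = _open_read(source)
    try:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"not a GCT v1.2 file: version line {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) != 2:
            raise ValueError(f"malformed GCT dimensions line: {dims!r}")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["Name", "Description"]:
            raise ValueError(f"malformed GCT header: {header[:2]!r}")
        sample_ids = header[2:]
        if len(sample_ids) != n_cols:
            raise ValueError(
                f"GCT dimension mismatch: expected {n_cols} samples, "
                f"found {len(sample_ids)}"
            )
        body = pd.read_csv(
            fh, sep="\t", header=None, names=header, index_col=0, dtype={0: str}
        )
    finally:
        if close:
            fh.close()
    if body.shape[0] != n_rows:
        raise ValueError(
            f"GCT dimension mismatch: expected {n_rows} rows, found {body.shape[0]}"
        )
    values = body[sample_ids].astype(float)
    if values.isna().any().any():
        raise ValueError("GCT contains blank or non-numeric expression cells")
    if (values.to_numpy() < 0).any():
        raise ValueError("GCT contains negative expression values")
    subject_map = {s: subject_of(s, subject_pattern) for s in sample_ids}
    return ExpressionMatrix(
        tissue_name=tissue_name,
        values=values,
        symbols=body["Description"].astype(str),
        subject_of_sample=subject_map,
    )


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix back to GCT v1.2 (deterministic %.6g formatting)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        n_rows, n_cols = matrix.values.shape
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        symbols = matrix.symbols
        for i, gid in enumerate(matrix.gene_ids):
            row = "\t".join(f"{v:.6g}" for v in arr[i])
            fh.write(f"{gid}\t{symbols.loc[gid]}\t{row}\n")


_SEX_CODES = {1: "male", 2: "female", "1": "male", "2": "female"}


def read_subject_phenotypes(source) -> SubjectTable:
    """Read the donor phenotype TSV (subject id, SEX, AGE).

    Sex uses the 1=male / 2=female integer convention; any other code
    decodes to ``unknown``.
    """
    close, fh = _open_read(source)
    try:
        df = pd.read_csv(fh, sep="\t")
    finally:
        if close:
            fh.close()
    cols = {c.upper(): c for c in df.columns}
    for needed in ("SUBJID", "SEX", "AGE"):
        if needed not in cols:
            raise ValueError(f"phenotype table missing column {needed!r}")
    out = pd.DataFrame(
        {
            "sex": [_SEX_CODES.get(v, "unknown") for v in df[cols["SEX"]]],
            "age": df[cols["AGE"]].to_numpy(),
        },
        index=pd.Index(df[cols["SUBJID"]].astype(str), name="subject_id"),
    )
    return SubjectTable(out)


def assemble_cohort(
    matrices,
    subjects: SubjectTable,
    exclude=CELL_LINE_TISSUES,
) -> Cohort:
    """Assemble per-tissue matrices into a cohort on a shared gene order.

    Tissues named in ``exclude`` (the cultured-cell files, by default) are
    dropped.  Matrices whose gene sets are equal but permuted are
    reindexed to the first matrix's order; a genuine gene-universe
    difference is an error naming the first discrepancy.
    """
    kept = [m for m in matrices if m.tissue_name not in set(exclude)]
    if not kept:
        raise ValueError("no tissues left after exclusion")
    canonical = kept[0].gene_ids
    canonical_set = set(canonical)
    tissues: dict[str, ExpressionMatrix] = {}
    for m in kept:
        if m.tissue_name in tissues:
            raise ValueError(f"duplicate tissue name: {m.tissue_name}")
        gene_set = set(m.gene_ids)
        if gene_set != canonical_set:
            diff = (gene_set ^ canonical_set)
            raise ValueError(
                f"gene universes differ: tissue {m.tissue_name!r} vs "
                f"{kept[0].tissue_name!r}, first discrepancy {sorted(diff)[0]!r}"
            )
        if m.gene_ids != canonical:
            m = ExpressionMatrix(
                tissue_name=m.tissue_name,
                values=m.values.reindex(canonical),
                symbols=m.symbols.reindex(canonical),
                subject_of_sample=dict(m.subject_of_sample),
            )
        tissues[m.tissue_name] = m
    return Cohort(tissues=tissues, subjects=subjects, gene_ids=list(canonical))
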