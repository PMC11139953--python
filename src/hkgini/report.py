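"""End-to-end orchestration: config-driven runs and summary tables.

``run_full_analysis`` executes the whole chain — ingest or simulate,
expression filter, the three Gini axes, housekeeping calls on both axes,
tissue-pass counts, the pooled-vs-within-tissue paired contrast, the
Gini-by-expression-bin summary, and (for synthetic cohorts) planted-class
recovery — and writes every table with a provenance header so a run is
reproducible from its outputs alone.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GeneCatalog, deduplicate_par, split_by_biotype
from .io import (
    CELL_LINE_TISSUES,
    Cohort,
    assemble_cohort,
    read_gct,
    read_subject_phenotypes,
    tissue_preset,
)
from .metrics import DEFAULT_BIN_EDGES, bin_by_expression
from .pipeline import (
    GiniTissueResult,
    ScoreTable,
    build_score_table,
    call_housekeeping,
    compare_groups,
    filter_expressed,
)
from .simulate import SimConfig, TruthLabels, evaluate_recovery

__all__ = ["RunConfig", "run_full_analysis", "summarize_per_tissue"]


@dataclass
class RunConfig:
    """Fully resolved parameters of one analysis run."""

    out_dir: str
    gct_dir: str | None = None          # ingest mode: directory of *.gct[.gz]
    phenotypes: str | None = None       # ingest mode: phenotype TSV
    catalog: str | None = None          # optional gene-catalog TSV
    simulate: bool = False              # simulate mode instead of ingest
    seed: int = 1
    tissue_subset: list[str] | None = None  # explicit list or preset name
    tpm_cutoff: float = 0.05
    gini_threshold: float = 0.2
    call_mode: str = "lt"               # housekeeping-call comparison
    pass_mode: str = "le"               # tissue-pass-count comparison
    bin_edges: list[float] = field(
        default_factory=lambda: list(DEFAULT_BIN_EDGES)
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _provenance(config: RunConfig) -> str:
    fields = ", ".join(f"{k}={v!r}" for k, v in sorted(asdict(config).items()))
    return f"# hkgini {__version__} | {fields}\n"


def _write_table(df: pd.DataFrame, path: str, config: RunConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", float_format="%.6g", **kwargs)


def _write_gene_list(genes, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        for g in genes:
            fh.write(g + "\n")


def _load_cohort(config: RunConfig) -> tuple[Cohort, GeneCatalog | None, TruthLabels | None]:
    if config.simulate:
        from .simulate import generate_cohort

        cohort, catalog, truth = generate_cohort(SimConfig(seed=config.seed))
        return cohort, catalog, truth
    if config.gct_dir is None or config.phenotypes is None:
        raise ValueError("ingest mode needs gct_dir and phenotypes")
    paths = sorted(
        glob.glob(os.path.join(config.gct_dir, "*.gct"))
        + glob.glob(os.path.join(config.gct_dir, "*.gct.gz"))
    )
    if not paths:
        raise FileNotFoundError(f"no GCT files under {config.gct_dir!r}")
    matrices = []
    for p in paths:
        name = os.path.basename(p)
        for suffix in (".gct.gz", ".gct"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        matrices.append(read_gct(p, tissue_name=name))
    subjects = read_subject_phenotypes(config.phenotypes)
    cohort = assemble_cohort(matrices, subjects, exclude=CELL_LINE_TISSUES)
    catalog = GeneCatalog.from_tsv(config.catalog) if config.catalog else None
    truth_path = (
        os.path.join(config.gct_dir, "truth_labels.tsv") if config.gct_dir else None
    )
    truth = (
        TruthLabels.from_tsv(truth_path)
        if truth_path and os.path.exists(truth_path)
        else None
    )
    return cohort, catalog, truth


def _resolve_tissues(config: RunConfig, cohort: Cohort) -> list[str]:
    subset = config.tissue_subset
    if subset is None:
        return cohort.tissue_names
    if isinstance(subset, str):
        subset = tissue_preset(subset)
    unknown = [t for t in subset if t not in cohort.tissues]
    if unknown:
        raise KeyError(f"unknown tissue(s) in subset: {unknown}")
    return list(subset)


def summarize_per_tissue(
    gini_tissue: GiniTissueResult,
    cohort: Cohort,
    threshold: float = 0.2,
    mode: str = "lt",
) -> pd.DataFrame:
    """One row per tissue: sample count, mean Gini-tissue over genes, and
    the number of genes passing the threshold in that tissue alone."""
    grid = gini_tissue.grid
    cmp = grid.lt(threshold) if mode == "lt" else grid.le(threshold)
    rows = []
    for name in cohort.tissue_names:
        rows.append(
            {
                "tissue": name,
                "n_samples": cohort.tissues[name].n_samples,
                "mean_gini_tissue": float(grid[name].mean(skipna=True)),
                "n_housekeeping": int(cmp[name].where(grid[name].notna(), False).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict of the in-memory results (score table, call, summaries)
    keyed by artifact name; the same content lands under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    cohort, catalog, truth = _load_cohort(config)
    tissues = _resolve_tissues(config, cohort)
    active = cohort.subset(tissues)

    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    stage(f"cohort: {len(active.tissue_names)} tissues, {active.n_samples} samples, "
          f"{len(active.gene_ids)} genes")

    # biotype partition (catalog-driven when available)
    if catalog is not None:
        catalog, n_par = deduplicate_par(catalog)
        coding, noncoding = split_by_biotype(catalog)
        coding = [g for g in coding if g in set(active.gene_ids)]
        noncoding = [g for g in noncoding if g in set(active.gene_ids)]
        stage(f"annotation: {n_par} PAR-Y records removed, "
              f"{len(coding)} coding / {len(noncoding)} non-coding")
    else:
        coding, noncoding = list(active.gene_ids), []
        stage("annotation: no catalog given; treating all genes as coding")

    kept, n_removed = filter_expressed(active, coding, config.tpm_cutoff)
    stage(f"expression filter (> {config.tpm_cutoff} TPM): "
          f"{len(kept)} kept, {n_removed} removed")

    scores = build_score_table(
        active, kept, pass_threshold=config.gini_threshold,
        pass_mode=config.pass_mode,
    )
    call = call_housekeeping(
        scores, gini_threshold=config.gini_threshold, mode=config.call_mode
    )
    stage(f"housekeeping call (Gini {config.call_mode} {config.gini_threshold}): "
          f"subject axis {len(call.subject_axis)}, tissue axis "
          f"{len(call.tissue_axis)}, intersection {len(call.intersection)}")

    per_tissue = summarize_per_tissue(
        scores.gini_tissue, active, config.gini_threshold, config.call_mode
    )

    # paired pooled-vs-within contrast over scored genes
    contrast = compare_groups(
        scores.table["gini_subject"].to_numpy(),
        scores.table["gini_tissue_mean"].to_numpy(),
        paired=True,
    )
    stage(f"paired contrast: mean Gini-subject {contrast.mean_a:.3f} vs mean "
          f"Gini-tissue {contrast.mean_b:.3f} (p={contrast.p_value:.3g})")

    # Gini-subject by expression bin
    bins = scores.table["mean_tpm"].map(
        lambda v: bin_by_expression(v, config.bin_edges)
    )
    binned = (
        scores.table.assign(expression_bin=bins)
        .groupby("expression_bin")["gini_subject"]
        .agg(["count", "mean", "median"])
    )

    results: dict = {
        "scores": scores,
        "call": call,
        "per_tissue": per_tissue,
        "contrast": contrast,
        "binned": binned,
        "cohort": active,
        "log": log,
    }

    # coding vs non-coding contrast, when the catalog gives both groups
    if noncoding:
        from .pipeline import score_gini_subject

        nc_scores = score_gini_subject(active, noncoding)
        results["coding_vs_noncoding"] = compare_groups(
            score_gini_subject(active, coding).to_numpy(),
            nc_scores.to_numpy(),
            paired=False,
        )

    if truth is not None:
        recovery = evaluate_recovery(call, truth)
        results["recovery"] = recovery
        stage("recovery:\n" + recovery.summary.to_string())

    # ---- write bundle -------------------------------------------------
    out = config.out_dir
    config.to_yaml(os.path.join(out, "run_config.yaml"))
    _write_table(scores.table, os.path.join(out, "scores.tsv"), config,
                 index_label="gene_id")
    _write_table(scores.gini_tissue.grid, os.path.join(out, "gini_tissue_grid.tsv"),
                 config, index_label="gene_id")
    _write_table(per_tissue, os.path.join(out, "per_tissue_summary.tsv"), config)
    _write_table(binned, os.path.join(out, "gini_by_expression_bin.tsv"), config,
                 index_label="expression_bin")
    for name in ("subject_axis", "tissue_axis", "intersection"):
        _write_gene_list(getattr(call, name),
                         os.path.join(out, f"housekeeping_{name}.txt"), config)
    if truth is not None:
        _write_table(results["recovery"].summary,
                     os.path.join(out, "recovery_summary.tsv"), config,
                     index_label="list")
        _write_table(results["recovery"].confusion,
                     os.path.join(out, "recovery_confusion.tsv"), config,
                     index_label="gene_class")
    cardinalities = {
        "n_tissues": len(active.tissue_names),
        "n_samples": int(active.n_samples),
        "n_genes_scored": len(kept),
        "n_genes_removed_by_tpm_filter": int(n_removed),
        "n_subject_axis": len(call.subject_axis),
        "n_tissue_axis": len(call.tissue_axis),
        "n_intersection": len(call.intersection),
        "mean_gini_subject": float(np.round(contrast.mean_a, 6)),
        "mean_gini_tissue": float(np.round(contrast.mean_b, 6)),
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(cardinalities, fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return results
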