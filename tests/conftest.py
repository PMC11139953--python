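import io

import numpy as np
import pandas as pd
import pytest

from hkgini.io import Cohort, ExpressionMatrix, SubjectTable
from hkgini.pipeline import build_score_table, call_housekeeping
from hkgini.simulate import SimConfig, evaluate_recovery, generate_cohort


def make_matrix(tissue, values, gene_ids=None, subjects=None, symbols=None):
    """Small ExpressionMatrix from a nested list (genes x samples)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i}.1" for i in range(n_genes)]
    sample_ids = [f"GTEX-{tissue[:2].upper()}{j:02d}-0001-SM" for j in range(n_samples)]
    subjects = subjects or [f"GTEX-{tissue[:2].upper()}{j:02d}" for j in range(n_samples)]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(
        tissue_name=tissue,
        values=df,
        symbols=pd.Series(symbols or gene_ids, index=gene_ids),
        subject_of_sample=dict(zip(sample_ids, subjects)),
    )


def make_cohort(matrices, sexes=None):
    subjects = sorted({s for m in matrices for s in m.subject_of_sample.values()})
    sexes = sexes or {}
    table = pd.DataFrame(
        {
            "sex": [sexes.get(s, "unknown") for s in subjects],
            "age": [50] * len(subjects),
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return Cohort(
        tissues={m.tissue_name: m for m in matrices},
        subjects=SubjectTable(table),
        gene_ids=matrices[0].gene_ids,
    )


@pytest.fixture
def toy_gff3():
    lines = [
        "##gff-version 3",
        "chr1\tHAVANA\tgene\t100\t200\t.\t+\t.\t"
        "ID=ENSG1.1;gene_id=ENSG1.1;gene_type=protein_coding;gene_name=AAA",
        "chr1\tHAVANA\texon\t100\t150\t.\t+\t.\t"
        "ID=exon1;gene_id=ENSG1.1;gene_type=protein_coding;gene_name=AAA",
        "chr2\tHAVANA\tgene\t300\t400\t.\t-\t.\t"
        "ID=ENSG2.1;gene_id=ENSG2.1;gene_type=protein_coding;gene_name=BBB",
        "chr3\tHAVANA\tgene\t10\t90\t.\t+\t.\t"
        "ID=ENSG3.1;gene_id=ENSG3.1;gene_type=lncRNA;gene_name=CCC",
    ]
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def toy_gct_text():
    return (
        "#1.2\n"
        "3\t2\n"
        "Name\tDescription\tGTEX-AB12-0001-SM\tGTEX-CD34-0002-SM\n"
        "G1.1\tAAA\t1.5\t2.5\n"
        "G2.1\tBBB\t0\t10\n"
        "G3.1\tCCC\t3\t3\n"
    )


# ---- default synthetic cohort, shared across test modules -------------

@pytest.fixture(scope="session")
def sim_default():
    config = SimConfig(seed=1)
    cohort, catalog, truth = generate_cohort(config)
    return config, cohort, catalog, truth


@pytest.fixture(scope="session")
def sim_scores(sim_default):
    from hkgini.annotation import split_by_biotype
    from hkgini.pipeline import filter_expressed

    config, cohort, catalog, truth = sim_default
    coding, _ = split_by_biotype(catalog)
    kept, n_removed = filter_expressed(cohort, coding, 0.05)
    scores = build_score_table(cohort, kept)
    return scores, kept, n_removed


@pytest.fixture(scope="session")
def sim_call(sim_default, sim_scores):
    _, _, _, truth = sim_default
    scores, _, _ = sim_scores
    call = call_housekeeping(scores, gini_threshold=0.2, mode="lt")
    return call, evaluate_recovery(call, truth)
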