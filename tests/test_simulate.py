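"""Synthetic cohort generator: determinism, planted structure, recovery."""

import hashlib
import os

import numpy as np
import pandas as pd
import pytest

from hkgini.annotation import split_by_biotype
from hkgini.pipeline import (
    filter_expressed,
    score_gini_tpm,
    stratify_by_sex,
)
from hkgini.simulate import (
    GENE_CLASSES,
    RecoveryReport,
    SimConfig,
    TruthLabels,
    evaluate_recovery,
    generate_cohort,
    write_cohort,
)


def file_hashes(directory):
    out = {}
    for name in sorted(os.listdir(directory)):
        with open(os.path.join(directory, name), "rb") as fh:
            out[name] = hashlib.sha256(fh.read()).hexdigest()
    return out


class TestConfig:
    def test_invalid_configs_rejected_before_generation(self):
        with pytest.raises(ValueError):
            SimConfig(samples_per_tissue=(4,)).validate()
        with pytest.raises(ValueError):
            SimConfig(class_counts={"no_such_class": 5}).validate()
        with pytest.raises(ValueError):
            SimConfig(stable_within_sd=-1).validate()
        with pytest.raises(ValueError):
            SimConfig(sex_ratio=2.0).validate()

    def test_default_scale(self, sim_default):
        _, cohort, catalog, truth = sim_default
        assert len(cohort.tissue_names) == 20
        assert len(cohort.gene_ids) == 2000
        assert cohort.n_samples == sum(SimConfig().samples_per_tissue)
        assert min(m.n_samples for m in cohort.tissues.values()) == 4

    def test_every_gene_labelled_exactly_once(self, sim_default):
        _, cohort, _, truth = sim_default
        assert list(truth.labels.index) == cohort.gene_ids
        assert set(truth.labels) <= set(GENE_CLASSES)


class TestDeterminism:
    def test_same_seed_byte_identical_output(self, tmp_path):
        small = dict(
            samples_per_tissue=(4, 6, 8, 10),
            class_counts={
                "stable_housekeeping": 10,
                "tissue_specific": 8,
                "silent": 4,
                "background_noncoding": 20,
            },
        )
        for sub in ("a", "b"):
            cohort, catalog, truth = generate_cohort(SimConfig(seed=7, **small))
            write_cohort(cohort, catalog, truth, tmp_path / sub)
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_different_seeds_differ(self):
        kw = dict(samples_per_tissue=(4, 6), class_counts={"stable_housekeeping": 5})
        a, _, _ = generate_cohort(SimConfig(seed=1, **kw))
        b, _, _ = generate_cohort(SimConfig(seed=2, **kw))
        assert not np.allclose(
            a.pooled_values().to_numpy(), b.pooled_values().to_numpy()
        )

    def test_adding_genes_does_not_perturb_existing_ones(self):
        """Per-gene substreams: growing the last class leaves every
        earlier gene's values bit-identical."""
        base = {"stable_housekeeping": 5, "silent": 2, "background_noncoding": 3}
        bigger = dict(base, background_noncoding=6)
        kw = dict(samples_per_tissue=(4, 6, 8))
        a, _, _ = generate_cohort(SimConfig(seed=3, class_counts=base, **kw))
        b, _, _ = generate_cohort(SimConfig(seed=3, class_counts=bigger, **kw))
        shared = a.gene_ids
        pd.testing.assert_frame_equal(
            a.pooled_values(shared), b.pooled_values(shared)
        )


class TestPlantedStructure:
    def test_degenerate_zero_sd_config_gives_zero_gini(self):
        from hkgini.pipeline import score_gini_subject, score_gini_tissue

        cfg = SimConfig(
            samples_per_tissue=(4, 6),
            class_counts={"stable_housekeeping": 5},
            gene_level_sd=0.0,
            stable_within_sd=0.0,
            stable_between_sd=0.0,
            het_tissue_scale=1.0,
            quiet_tissue_scale=1.0,
        )
        cohort, _, _ = generate_cohort(cfg)
        assert (score_gini_subject(cohort, cohort.gene_ids) == 0).all()
        assert (score_gini_tissue(cohort, cohort.gene_ids).grid == 0).all().all()

    def test_silent_genes_are_exactly_the_filtered_ones(self, sim_default):
        _, cohort, catalog, truth = sim_default
        coding, _ = split_by_biotype(catalog)
        kept, n_removed = filter_expressed(cohort, coding, 0.05)
        removed = set(coding) - set(kept)
        assert removed == set(truth.genes_in("silent"))
        assert n_removed == len(removed)

    def test_noncoding_background_is_mostly_zero_and_lowly_expressed(self, sim_default):
        _, cohort, catalog, truth = sim_default
        nc = truth.genes_in("background_noncoding")
        pooled = cohort.pooled_values(nc).to_numpy()
        assert (pooled == 0).mean() > 0.8
        assert pooled[pooled > 0].mean() < 2.0

    def test_tissue_specific_gene_gini_tpm_near_max(self, sim_default):
        _, cohort, _, truth = sim_default
        genes = truth.genes_in("tissue_specific")[:10]
        gtpm = score_gini_tpm(cohort, genes)
        n = len(cohort.tissue_names)
        assert (gtpm > 0.9 * (n - 1) / n).all()

    def test_class_separation_on_subject_axis(self, sim_scores, sim_default):
        """Median pooled Gini orders: stable < tissue-variable < specific."""
        _, _, _, truth = sim_default
        scores, _, _ = sim_scores
        med = {
            cls: scores.table.loc[truth.genes_in(cls), "gini_subject"].median()
            for cls in (
                "stable_housekeeping",
                "within_tissue_stable_tissue_variable",
                "tissue_specific",
            )
        }
        assert (
            med["stable_housekeeping"]
            < med["within_tissue_stable_tissue_variable"]
            < med["tissue_specific"]
        )

    def test_designated_tissues_bracket_mean_gini(self, sim_scores, sim_default):
        """The heterogeneous tissue has the largest per-tissue mean
        Gini-tissue (blood analogue); the quiet one the smallest."""
        config, _, _, _ = sim_default
        scores, _, _ = sim_scores
        het, quiet, _ = config._designated()
        per_tissue = scores.gini_tissue.per_tissue_mean
        assert per_tissue.idxmax() == f"tissue_{het:02d}"
        assert per_tissue.idxmin() == f"tissue_{quiet:02d}"

    def test_sex_dimorphic_genes_show_male_excess(self, sim_default):
        config, cohort, _, truth = sim_default
        sex_tissue = f"tissue_{config._designated()[2]:02d}"
        for gene in truth.genes_in("sex_dimorphic"):
            male, female = stratify_by_sex(cohort, sex_tissue, gene)
            assert male > female


class TestRecovery:
    def test_perfect_call_scores_one(self, sim_default):
        from hkgini.pipeline import HousekeepingCall

        _, _, _, truth = sim_default
        stable = truth.genes_in("stable_housekeeping")
        call = HousekeepingCall(
            subject_axis=stable, tissue_axis=stable, intersection=stable
        )
        rep = evaluate_recovery(call, truth)
        assert (rep.summary["precision"] == 1.0).all()
        assert (rep.summary["recall"] == 1.0).all()

    def test_empty_call_recall_zero_precision_undefined(self, sim_default):
        from hkgini.pipeline import HousekeepingCall

        _, _, _, truth = sim_default
        call = HousekeepingCall(subject_axis=[], tissue_axis=[], intersection=[])
        rep = evaluate_recovery(call, truth)
        assert (rep.summary["recall"] == 0.0).all()
        assert rep.summary["precision"].isna().all()

    def test_universe_mismatch_rejected(self, sim_default):
        from hkgini.pipeline import HousekeepingCall

        _, _, _, truth = sim_default
        call = HousekeepingCall(
            subject_axis=["NOT-A-GENE.1"], tissue_axis=[], intersection=[]
        )
        with pytest.raises(ValueError, match="NOT-A-GENE"):
            evaluate_recovery(call, truth)

    def test_default_cohort_recovery_report_type(self, sim_call):
        _, rep = sim_call
        assert isinstance(rep, RecoveryReport)
        assert set(rep.summary.index) == {
            "subject_axis", "tissue_axis", "intersection"
        }


class TestTruthIO:
    def test_truth_tsv_round_trip(self, tmp_path, sim_default):
        _, _, _, truth = sim_default
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        again = TruthLabels.from_tsv(path)
        pd.testing.assert_series_equal(truth.labels, again.labels,
                                       check_names=False)
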