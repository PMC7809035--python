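"""Tests for the ground-truth generator: determinism, planted structure, errors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from micronet import signatures as sig
from micronet import synthetic as synth
from conftest import null_truth


class TestDeterminism:
    def test_cohort_byte_identical_for_same_seed(self):
        a = synth.generate_cohort(synth.default_truth(seed=9, n_subjects=40))
        b = synth.generate_cohort(synth.default_truth(seed=9, n_subjects=40))
        assert a[0].values.to_csv() == b[0].values.to_csv()
        assert a[2].to_csv() == b[2].to_csv()

    def test_streams_are_independent_of_other_outputs(self):
        """Generating extra outputs never perturbs the cohort draw."""
        t1 = synth.default_truth(seed=9, n_subjects=40)
        before = synth.generate_cohort(t1)[0].values
        synth.generate_sn_counts(t1, cells=200)
        synth.generate_gwas_summary(t1)
        after = synth.generate_cohort(t1)[0].values
        pd.testing.assert_frame_equal(before, after)

    def test_different_seeds_differ(self):
        a = synth.generate_cohort(synth.default_truth(seed=1, n_subjects=40))[0]
        b = synth.generate_cohort(synth.default_truth(seed=2, n_subjects=40))[0]
        assert not a.values.equals(b.values)


class TestValidation:
    def test_small_module_rejected(self):
        truth = synth.default_truth(seed=0, n_subjects=40, genes_per_module=10)
        with pytest.raises(ValueError, match="fewer than 20"):
            synth.generate_cohort(truth)

    def test_nonpositive_noise_rejected(self):
        truth = synth.default_truth(seed=0, n_subjects=40)
        bad = dataclasses.replace(truth, noise_sds={**truth.noise_sds, "gene": 0.0})
        with pytest.raises(ValueError, match="strictly positive"):
            synth.generate_cohort(bad)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            synth.generate_cohort(synth.default_truth(seed=0, n_subjects=10))

    def test_overlapping_signatures_rejected(self):
        truth = synth.default_truth(seed=0, n_subjects=40)
        spec = dict(truth.signature_spec)
        spec["astrocyte"] = spec["microglia"][:5]
        bad = dataclasses.replace(truth, signature_spec=spec)
        with pytest.raises(ValueError, match="overlap"):
            bad.validate()


class TestCohortStructure:
    def test_fpkm_positive_and_phenotypes_on_sqrt_scale(self, small_cohort):
        expr, assignment, phen = small_cohort
        assert (expr.values.to_numpy() > 0).all()
        np.testing.assert_allclose(phen["amyloid"], phen["amyloid_sqrt"] ** 2)
        assert set(phen["sex"].unique()) <= {0.0, 1.0}
        assert set(phen["study"].unique()) <= {0.0, 1.0}

    def test_module_sizes_meet_floor(self, small_cohort):
        _, assignment, _ = small_cohort
        assert (assignment.sizes() >= 20).all()


class TestReferenceProfiles:
    def test_fourfold_rule_holds_for_planted_genes(self):
        truth = synth.default_truth(seed=4, n_subjects=40)
        profiles = synth.generate_reference_profiles(truth)
        bulk = profiles["bulk"].values.mean(axis=1)
        mic = profiles["microglia"].values.mean(axis=1)
        planted = truth.signature_spec["microglia"]
        assert (mic[planted] >= 4 * bulk[planted]).all()
        assert (mic[planted] > 1).all()

    def test_round_trip_recovers_each_signature_exactly(self):
        truth = synth.default_truth(seed=4, n_subjects=40)
        profiles = synth.generate_reference_profiles(truth)
        bulk = profiles["bulk"].values.mean(axis=1)
        for cell_type, planted in truth.signature_spec.items():
            recovered = sig.derive_enriched_set(
                profiles[cell_type].values.mean(axis=1), [bulk], name=cell_type
            )
            assert recovered.genes == frozenset(planted)

    def test_unplanted_gene_in_no_recovered_set(self):
        truth = synth.default_truth(seed=4, n_subjects=40)
        profiles = synth.generate_reference_profiles(truth)
        bulk = profiles["bulk"].values.mean(axis=1)
        planted_all = {g for genes in truth.signature_spec.values() for g in genes}
        free = next(g for g in truth.gene_ids if g not in planted_all)
        for cell_type in truth.signature_spec:
            recovered = sig.derive_enriched_set(
                profiles[cell_type].values.mean(axis=1), [bulk]
            )
            assert free not in recovered.genes

    def test_empty_signature_rejected(self):
        truth = synth.default_truth(seed=4, n_subjects=40)
        bad = dataclasses.replace(
            truth, signature_spec={**truth.signature_spec, "oligo": []}
        )
        with pytest.raises(ValueError, match="empty signature"):
            synth.generate_reference_profiles(bad)


class TestLongitudinal:
    def test_two_visits_rejected(self):
        truth = synth.default_truth(seed=0, n_subjects=40)
        with pytest.raises(ValueError):
            synth.generate_longitudinal(truth, visits=2)

    def test_slopes_shared_with_cohort_phenotypes(self):
        truth = synth.default_truth(seed=5, n_subjects=40)
        _, _, phen = synth.generate_cohort(truth)
        lc = synth.generate_longitudinal(truth, visits=4)
        pd.testing.assert_series_equal(
            lc.true_slopes, phen["decline_slope"], check_names=False
        )


class TestCellImages:
    def test_exact_component_count_and_planting(self):
        from skimage.measure import label

        truth = synth.default_truth(seed=11, n_subjects=40)
        images = synth.generate_cell_images(truth, cells_per_subject=25, n_subjects=3)
        for mask in images.masks:
            assert label(mask > 0, connectivity=2).max() == 25

    def test_too_few_cells_rejected(self):
        truth = synth.default_truth(seed=11, n_subjects=40)
        with pytest.raises(ValueError):
            synth.generate_cell_images(truth, cells_per_subject=5)

    def test_packing_limit_raises(self):
        truth = synth.default_truth(seed=11, n_subjects=40)
        with pytest.raises(ValueError, match="packing"):
            synth.generate_cell_images(
                truth, cells_per_subject=100, n_subjects=2, image_shape=(80, 80)
            )

    def test_tiff_round_trip(self, tmp_path):
        import tifffile

        truth = synth.default_truth(seed=11, n_subjects=40)
        images = synth.generate_cell_images(truth, cells_per_subject=12, n_subjects=2)
        synth.write_tiffs(images, tmp_path)
        sid = images.subject_ids[0]
        back = tifffile.imread(tmp_path / f"{sid}_mask.tif")
        np.testing.assert_array_equal(back, images.masks[0])


class TestSnCounts:
    def test_counts_are_nonnegative_integers(self):
        truth = synth.default_truth(seed=3, n_subjects=40)
        counts = synth.generate_sn_counts(truth, cells=200)
        data = counts.counts.data
        assert (data >= 0).all() and np.allclose(data, np.round(data))

    def test_too_few_cells_or_clusters_rejected(self):
        truth = synth.default_truth(seed=3, n_subjects=40)
        with pytest.raises(ValueError):
            synth.generate_sn_counts(truth, cells=100)
        with pytest.raises(ValueError):
            synth.generate_sn_counts(truth, cells=200, n_clusters=3)

    def test_every_cell_labeled(self):
        truth = synth.default_truth(seed=3, n_subjects=40)
        counts = synth.generate_sn_counts(truth, cells=200)
        assert counts.metadata["cluster"].isin(["Mic1", "Mic2", "Mic3", "Mic4"]).all()
        assert counts.metadata["subject_id"].notna().all()


class TestGwasSummary:
    def test_planted_genes_recovered_as_superset(self):
        truth = synth.default_truth(seed=6, n_subjects=40)
        probes, intervals, ad_genes = synth.generate_gwas_summary(truth)
        flags = sig.gwas_gene_flags(intervals, probes)
        assert set(ad_genes) <= flags.genes

    def test_zero_probes_rejected(self):
        truth = synth.default_truth(seed=6, n_subjects=40)
        with pytest.raises(ValueError):
            synth.generate_gwas_summary(truth, probes_per_gene=0)


def test_null_truth_breaks_module_trait_links():
    """With zero path coefficients the m5/tau association is at chance level."""
    from conftest import light_scores

    pvals = []
    for seed in range(1, 7):
        scores, phen = light_scores(null_truth(seed, n_subjects=200))
        from micronet import association as assoc

        pvals.append(assoc.associate(scores["m5"], "tau_sqrt", phen).p)
    assert min(pvals) > 1e-4  # no systematic signal
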