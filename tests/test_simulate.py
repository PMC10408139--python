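"""Generators: determinism, planted-effect identifiability, cohort structure."""

import numpy as np
import pandas as pd
import pytest

from oxsig.diffexpr import cpm_normalize, differential_expression
from oxsig.signature import GeneSignature
from oxsig.simulate import (
    ClinicalSimConfig,
    ContrastEffects,
    MouseDesign,
    PlantedEffects,
    human_gene_symbols,
    mouse_gene_symbols,
    simulate_clinical_cohort,
    simulate_mouse_counts,
    simulate_ortholog_map,
    simulate_reference_cohort,
)


def _null_effects(dispersion=0.05):
    return PlantedEffects(contrasts={}, dispersion=dispersion)


class TestMouseCounts:
    def test_same_seed_bit_identical(self):
        design = MouseDesign(n_per_group=3, n_genes=50)
        c1, m1, _ = simulate_mouse_counts(design, _null_effects(), seed=7)
        c2, m2, _ = simulate_mouse_counts(design, _null_effects(), seed=7)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ(self):
        design = MouseDesign(n_per_group=3, n_genes=50)
        c1, _, _ = simulate_mouse_counts(design, _null_effects(), seed=1)
        c2, _, _ = simulate_mouse_counts(design, _null_effects(), seed=2)
        assert not c1.equals(c2)

    def test_metadata_carries_all_factors(self):
        design = MouseDesign(n_per_group=2, n_genes=20)
        counts, meta, _ = simulate_mouse_counts(design, _null_effects(), seed=0)
        assert counts.shape == (20, 16)
        cells = meta.groupby(["sex", "genotype", "treatment"]).size()
        assert len(cells) == 8 and (cells == 2).all()
        assert list(meta["sample_id"]) == list(counts.columns)

    def test_rejects_overlapping_up_down(self):
        with pytest.raises(ValueError, match="overlap"):
            ContrastEffects(up={"Sim00001": 1.0}, down={"Sim00001": 1.0})

    def test_rejects_small_groups_and_zero_lfc(self):
        with pytest.raises(ValueError, match="n_per_group"):
            MouseDesign(n_per_group=1, n_genes=50)
        with pytest.raises(ValueError, match="log2FC"):
            ContrastEffects(up={"Sim00001": 0.0}, down={})

    def test_rejects_planted_genes_outside_universe(self):
        design = MouseDesign(n_per_group=2, n_genes=20)
        effects = PlantedEffects(
            contrasts={("F", "KO"): ContrastEffects(up={"Sim99999": 1.0}, down={})}
        )
        with pytest.raises(ValueError, match="universe"):
            simulate_mouse_counts(design, effects, seed=0)

    def test_null_false_positive_rate_calibrated(self):
        """With nothing planted, a two-group test finds ~5% of genes at p<0.05."""
        design = MouseDesign(n_per_group=5, n_genes=400)
        fractions = []
        for seed in range(10):
            counts, meta, _ = simulate_mouse_counts(design, _null_effects(), seed=seed)
            expr = cpm_normalize(counts)
            sub = meta[(meta.sex == "F") & (meta.genotype == "KO")]
            deg = differential_expression(
                expr[sub.sample_id.tolist()], sub.treatment.to_numpy(),
                "room_air", "hyperoxia",
            )
            fractions.append((deg.p_value < 0.05).mean())
        mc_sd = np.sqrt(0.05 * 0.95 / (400 * 10))
        assert abs(np.mean(fractions) - 0.05) < 3 * mc_sd

    def test_planted_log2fc_recovered(self):
        """One gene planted at log2FC=+2 is estimated within +-0.5."""
        gene = "Sim00005"
        effects = PlantedEffects(
            contrasts={("F", "KO"): ContrastEffects(up={gene: 2.0}, down={})},
            dispersion=0.05,
        )
        design = MouseDesign(n_per_group=10, n_genes=100)
        counts, meta, _ = simulate_mouse_counts(design, effects, seed=11)
        expr = cpm_normalize(counts)
        sub = meta[(meta.sex == "F") & (meta.genotype == "KO")]
        deg = differential_expression(
            expr[sub.sample_id.tolist()], sub.treatment.to_numpy(),
            "room_air", "hyperoxia",
        )
        assert abs(deg.loc[gene, "log2_fold_change"] - 2.0) < 0.5
        # only the targeted cell is shifted
        other = meta[(meta.sex == "M") & (meta.genotype == "KO")]
        deg_other = differential_expression(
            expr[other.sample_id.tolist()], other.treatment.to_numpy(),
            "room_air", "hyperoxia",
        )
        assert abs(deg_other.loc[gene, "log2_fold_change"]) < 1.0


class TestReferenceCohort:
    def test_shape_and_determinism(self):
        expr = simulate_reference_cohort(n_samples=578, n_genes=200, seed=1)
        assert expr.shape == (200, 578)
        again = simulate_reference_cohort(n_samples=578, n_genes=200, seed=1)
        pd.testing.assert_frame_equal(expr, again)
        other = simulate_reference_cohort(n_samples=578, n_genes=200, seed=2)
        assert not expr.equals(other)

    def test_minimum_samples_boundary(self):
        assert simulate_reference_cohort(3, 20, seed=0).shape == (20, 3)
        with pytest.raises(ValueError):
            simulate_reference_cohort(2, 20, seed=0)

    def test_shared_covariance_component_present(self):
        """The low-rank component induces nonzero cross-gene correlation."""
        expr = simulate_reference_cohort(n_samples=400, n_genes=50, seed=3)
        corr = np.corrcoef(expr.to_numpy())
        off = corr[np.triu_indices(50, k=1)]
        assert np.abs(off).max() > 0.2


class TestClinicalCohort:
    @staticmethod
    def _signature(n_up=20, n_down=20):
        genes = human_gene_symbols(200)
        return GeneSignature("sig", frozenset(genes[:n_up]),
                             frozenset(genes[100 : 100 + n_down]))

    def test_default_composition_gives_111_rows(self):
        expr, clinical, truth = simulate_clinical_cohort(
            (43, 40, 13, 15), delta=0.0, signature=self._signature(),
            n_genes=200, seed=1,
        )
        assert len(clinical) == 111
        assert expr.shape == (200, 111)
        assert list(clinical.bpd_severity.value_counts().sort_index()) == [43, 40, 13, 15]
        assert truth.delta == 0.0

    def test_sexes_alternate_within_strata(self):
        _, clinical, _ = simulate_clinical_cohort(
            (4, 4, 4, 4), delta=0.0, signature=self._signature(), n_genes=200, seed=1,
        )
        by_sev = clinical.groupby("bpd_severity")["sex"].apply(list)
        for sexes in by_sev:
            assert sexes == ["F", "M", "F", "M"]

    def test_covariates_decline_with_severity(self):
        _, clinical, _ = simulate_clinical_cohort(
            (43, 40, 13, 15), delta=0.0, signature=self._signature(),
            n_genes=200, seed=5,
        )
        assert np.corrcoef(clinical.gestational_age_weeks, clinical.bpd_severity)[0, 1] < -0.2
        assert np.corrcoef(clinical.birth_weight_g, clinical.bpd_severity)[0, 1] < -0.2
        assert set(clinical.oxygen_28d.unique()) <= {0, 1}

    def test_rejects_tiny_cohort_and_foreign_signature(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_clinical_cohort((1, 1, 1, 0), 0.0, self._signature(), 200, seed=0)
        bad = GeneSignature("bad", frozenset(["NOTAGENE"]), frozenset())
        with pytest.raises(ValueError, match="universe"):
            simulate_clinical_cohort((5, 5, 5, 5), 0.0, bad, 200, seed=0)

    def test_determinism(self):
        args = dict(severity_counts=(10, 10, 5, 5), delta=0.5,
                    signature=self._signature(), n_genes=200, seed=9)
        e1, c1, _ = simulate_clinical_cohort(**args)
        e2, c2, _ = simulate_clinical_cohort(**args)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(c1, c2)


class TestOrthologMapGenerator:
    def test_all_one_to_one(self):
        symbols = mouse_gene_symbols(50)
        omap = simulate_ortholog_map(symbols, 1.0, 0.0, 0.0, seed=1)
        assert len(omap) == 50
        assert dict(omap.pairs) == {s: s.upper() for s in symbols}

    def test_all_missing_reports_drop_list(self):
        symbols = mouse_gene_symbols(20)
        omap = simulate_ortholog_map(symbols, 0.0, 0.0, 1.0, seed=1)
        assert len(omap) == 0
        assert sorted(omap.unmapped_sources) == sorted(symbols)

    def test_mixture_fractions_within_sampling_error(self):
        symbols = mouse_gene_symbols(1000)
        n11 = n1m = nmiss = 0
        n_seeds = 5
        for seed in range(n_seeds):
            omap = simulate_ortholog_map(symbols, 0.8, 0.1, 0.1, seed=seed)
            targets = omap.source_to_targets()
            n1m += sum(1 for t in targets.values() if len(t) > 1)
            n11 += sum(1 for t in targets.values() if len(t) == 1)
            nmiss += len(omap.unmapped_sources)
        total = 1000 * n_seeds
        for observed, p in [(n11, 0.8), (n1m, 0.1), (nmiss, 0.1)]:
            sd = np.sqrt(p * (1 - p) * total)
            assert abs(observed - p * total) < 4 * sd

    def test_rejects_fraction_sum_above_one(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_ortholog_map(["Sox2"], 0.8, 0.3, 0.1, seed=0)
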