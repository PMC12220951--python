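"""Synthetic-data generators: determinism, conservation, planted truth."""

import math

import numpy as np
import pandas as pd
import pytest

from gmscreen import omics, simulate
from gmscreen.errors import ParameterError


class TestScreenGenerator:
    def test_construction_matches_manifest(self):
        params = simulate.ScreenSimParams(
            n_genes=10, n_hit_genes=2, cells_per_well=50, seed=1
        )
        cells, truth = simulate.gen_screen_cells(params)
        assert len(truth.planted_hit_genes) == 2
        for gene in truth.planted_hit_genes:
            sirnas = cells.loc[cells["gene"] == gene, "sirna_id"].unique()
            assert len(sirnas) == 3

    def test_determinism(self):
        params = simulate.ScreenSimParams(n_genes=5, n_hit_genes=1,
                                          cells_per_well=40, seed=9)
        a, _ = simulate.gen_screen_cells(params)
        b, _ = simulate.gen_screen_cells(params)
        pd.testing.assert_frame_equal(a, b)

    def test_controls_on_every_plate_and_cell_conservation(self):
        params = simulate.ScreenSimParams(n_genes=45, n_hit_genes=0,
                                          cells_per_well=30, genes_per_plate=20,
                                          seed=2)
        cells, _ = simulate.gen_screen_cells(params)
        for _, plate_cells in cells.groupby("plate"):
            assert (plate_cells["gene"] == "NEG_CTRL").any()
            assert (plate_cells.groupby("well").size() == 30).all()

    def test_null_screen_has_no_elevated_wells(self):
        """hit_effect=0: planted 'hits' indistinguishable from background."""
        params = simulate.ScreenSimParams(
            n_genes=12, n_hit_genes=4, cells_per_well=400, hit_effect=0.0,
            plate_effect_sd=0.0, seed=3,
        )
        cells, truth = simulate.gen_screen_cells(params)
        frac = cells.groupby("gene")["micronucleus_count"].apply(lambda c: (c >= 1).mean())
        hit_mean = frac[truth.planted_hit_genes].mean()
        other = frac[~frac.index.isin(truth.planted_hit_genes)].mean()
        assert hit_mean == pytest.approx(other, abs=0.01)

    def test_hit_fraction_matches_binomial_closed_form(self):
        """Full knockdown: positive fraction ~ Binomial(n, base + effect)."""
        params = simulate.ScreenSimParams(
            n_genes=2, n_hit_genes=1, cells_per_well=2000,
            baseline_positive_fraction=0.05, hit_effect=0.25,
            knockdown_efficiency_range=(1.0, 1.0), plate_effect_sd=0.0, seed=7,
        )
        cells, truth = simulate.gen_screen_cells(params)
        w = 0.05 + 0.25  # planted positive fraction of hit wells
        sd = math.sqrt(w * (1 - w) / 2000)
        hit = cells[cells["gene"] == truth.planted_hit_genes[0]]
        for _, well_cells in hit.groupby(["plate", "well"]):
            frac = (well_cells["micronucleus_count"] >= 1).mean()
            assert abs(frac - w) < 4 * sd

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            simulate.ScreenSimParams(n_genes=5, n_hit_genes=6)
        with pytest.raises(ParameterError):
            simulate.ScreenSimParams(baseline_positive_fraction=1.5)
        with pytest.raises(ParameterError):
            simulate.ScreenSimParams(cells_per_well=0)


class TestVariantCohortGenerator:
    def test_manifest_lists_qualifying_genes(self):
        spec = {
            "A": {"n_truncating": 1, "n_missense": 1, "n_other": 0},
            "B": {"n_truncating": 0, "n_missense": 2, "n_other": 1},
            "C": {"n_truncating": 2, "n_missense": 0, "n_other": 0},
        }
        table, truth = simulate.gen_variant_cohort(burden_spec=spec, seed=4)
        assert truth.planted_shortlist_genes == ["A"]
        assert set(table["gene"]) == {"A", "B", "C"}

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            simulate.gen_variant_cohort(
                burden_spec={"A": {"n_truncating": -1, "n_missense": 1}}, seed=0
            )

    def test_planted_shortlist_count_control(self):
        spec = simulate.burden_spec_with_shortlist(100, 37, seed=5)
        _, truth = simulate.gen_variant_cohort(burden_spec=spec, seed=5)
        assert len(truth.planted_shortlist_genes) == 37

    def test_determinism(self):
        a, _ = simulate.gen_variant_cohort(n_genes=50, seed=8)
        b, _ = simulate.gen_variant_cohort(n_genes=50, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestAmpliconGenerator:
    def test_counts_sum_to_depth(self):
        params = simulate.SelectSimParams(depth_per_timepoint=777, seed=1)
        counts, truth = simulate.gen_amplicon_data(params)
        assert all(c.total == 777 for c in counts)
        assert truth.variant_truth == {"variant": 0.0}

    def test_neutral_ratio_near_one(self):
        params = simulate.SelectSimParams(
            selection_per_day=0.0, depth_per_timepoint=20000, seed=2
        )
        counts, _ = simulate.gen_amplicon_data(params)
        for c in counts:
            assert c.variant / c.wt_prime == pytest.approx(1.0, abs=0.1)

    def test_expected_fold_change_closed_form(self):
        """s=-0.1/day over 10 days: mean FC over 1,000 replicates ~ e^-1."""
        params = simulate.SelectSimParams(selection_per_day=-0.1, seed=3)
        rng = np.random.default_rng(params.seed)
        fcs = []
        for _ in range(1000):
            counts, _ = simulate.gen_amplicon_counts(params, rng=rng)
            early, late = counts
            fcs.append((late.variant / late.wt_prime) / (early.variant / early.wt_prime))
        assert np.mean(fcs) == pytest.approx(math.exp(-1), abs=0.01)

    def test_days_must_increase(self):
        with pytest.raises(ParameterError):
            simulate.SelectSimParams(days=(12.0, 2.0))

    def test_fastq_determinism(self, tmp_path):
        params = simulate.SelectSimParams(depth_per_timepoint=100, seed=6)
        files1, _, _ = simulate.gen_amplicon_data(params, "fastq", tmp_path / "a")
        files2, _, _ = simulate.gen_amplicon_data(params, "fastq", tmp_path / "b")
        for day in files1:
            assert files1[day].read_bytes() == files2[day].read_bytes()


class TestOmicsGenerator:
    def test_planted_fields_satisfy_rules(self):
        table, truth = simulate.gen_omics_cohort(
            n_patients=2000,
            label_mix={"brca1_methylation": 0.2, "brca2_variant_loh": 0.2},
            seed=7,
        )
        merged = table.set_index("patient_id")
        for pid, label in truth.patient_truth.items():
            deficiency = label.split("|")[0]
            row = merged.loc[pid]
            if deficiency == "BRCA1-deficient":
                assert row["brca1_methylation_beta"] >= 0.25
                assert row["brca1_expression_z"] <= -2
            elif deficiency == "BRCA2-deficient":
                assert (
                    row["brca2_gistic"] == -2
                    or (row["brca2_pathogenic_germline"] or row["brca2_pathogenic_somatic"])
                    and row["brca2_gistic"] == -1
                )

    def test_all_intact_mix_classifies_intact(self):
        table, truth = simulate.gen_omics_cohort(n_patients=500, label_mix={}, seed=9)
        labelled = omics.classify_omics(table)
        assert (labelled["deficiency_label"] == "intact").all()
        assert all(v.split("|")[0] == "intact" for v in truth.patient_truth.values())

    def test_bad_label_mix(self):
        with pytest.raises(ParameterError):
            simulate.gen_omics_cohort(label_mix={"brca1_homdel": 0.9,
                                                 "brca2_homdel": 0.2})
        with pytest.raises(ParameterError):
            simulate.gen_omics_cohort(label_mix={"unknown": 0.1})

    def test_determinism(self):
        a, _ = simulate.gen_omics_cohort(n_patients=100, seed=3)
        b, _ = simulate.gen_omics_cohort(n_patients=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestTruthManifest:
    def test_round_trip(self, tmp_path):
        manifest = simulate.TruthManifest(
            seed=12,
            planted_hit_genes=["A", "B"],
            planted_shortlist_genes=["C"],
            variant_truth={"v1": -0.1},
            patient_truth={"P1": "intact|normal"},
        )
        path = tmp_path / "truth.txt"
        manifest.write(path)
        back = simulate.TruthManifest.read(path)
        assert back == manifest
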