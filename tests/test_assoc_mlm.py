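"""Stage-2 interaction GWAS: model specs, covariate elimination, per-marker
fits, two-step orchestration, and the private-QTL hierarchy contract."""

import numpy as np
import pandas as pd
import pytest

from privateqtl import phenotypes, simdata
from privateqtl.assoc_mlm import (
    _ModelData,
    build_spec,
    fit_marker_mlm,
    mlm_scan,
    random_control,
    rank_accumulation,
    run_two_step,
    select_covariates,
)
from privateqtl.simdata import PlantedEffect, SimTruth, VarianceComponents

from conftest import make_noise_free_records


class TestBuildSpec:
    def test_ssp_maps_to_full_interaction_model(self):
        spec = build_spec("ssp")
        assert spec.target_term == "S:D:G"
        assert set(spec.random_terms) == {"1", "S", "D", "S:D"}
        assert "S:D:G" in spec.fixed_terms and "S:G" in spec.fixed_terms

    def test_ssd_fed_targets_sex_by_genotype_on_fed_records(self):
        spec = build_spec("ssd_fed")
        assert spec.subset == {"diet": "fed"}
        assert spec.fixed_terms == ["S", "G", "S:G"]
        assert spec.target_term == "S:G"
        assert set(spec.random_terms) == {"1", "S"}

    def test_single_sex_diet_size_targets_genotype(self):
        spec = build_spec("size_female_fed")
        assert spec.subset == {"sex": "F", "diet": "fed"}
        assert spec.fixed_terms == ["G"]
        assert spec.target_term == "G"
        assert spec.random_terms == ["1"]

    def test_plasticity_specs_target_diet_by_genotype(self):
        for name in ("delta_female", "delta_male", "delta_lineage"):
            assert build_spec(name).target_term == "D:G"

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            build_spec("wing_length")


class TestFitMarkerMlm:
    def test_monomorphic_marker_skipped(self, small_panel, planted_records):
        spec = build_spec("ssp")
        dose = pd.Series(np.zeros(small_panel.n_lineages),
                         index=small_panel.lineage_ids, name="const")
        fit = fit_marker_mlm(planted_records, dose, spec)
        assert fit.status == "monomorphic"

    def test_target_coefficient_recovers_planted_contrast_exactly(
            self, small_panel):
        """Noise-free limit: the three-way coefficient equals the planted
        effect and matches factorial least squares."""
        beta = 0.17
        mid = small_panel.marker_ids[30]
        truth = SimTruth(planted_effects=[PlantedEffect(mid, "GxSxD", beta)],
                         variance_components=VarianceComponents(0, 0, 0, 0, 0, 1e-4),
                         seed=5)
        rec = simdata.simulate_individuals(
            small_panel, None, truth,
            design={"n_per_group": 4, "n_blocks": 1}, seed=5)
        fit = fit_marker_mlm(rec, small_panel.dose(mid), build_spec("ssp"))
        assert fit.effect == pytest.approx(beta, abs=0.01)
        assert fit.p_value < 1e-10

    def test_missing_calls_drop_lineages(self, small_panel, planted_records):
        mid = small_panel.marker_ids[3]
        dose = small_panel.dose(mid).copy()
        dose.iloc[:5] = np.nan
        fit = fit_marker_mlm(planted_records, dose, build_spec("ssp"))
        assert fit.n_lineages_used == small_panel.n_lineages - 5


class TestSelectCovariates:
    def test_no_covariates_returns_empty(self, planted_records):
        assert select_covariates(planted_records, None, build_spec("ssp")) == []

    def test_planted_confounder_retained_additively(self, small_panel,
                                                    small_covariates):
        # make Wolbachia status shift size additively
        truth = SimTruth(seed=31)
        rec = simdata.simulate_individuals(
            small_panel, small_covariates, truth,
            design={"n_per_group": 10, "n_blocks": 1}, seed=31)
        wolb = pd.Series(small_covariates.wolbachia,
                         index=small_covariates.lineage_ids)
        rec = rec.copy()
        rec["size_log"] += 0.15 * rec["lineage_id"].map(wolb)
        retained = select_covariates(rec, small_covariates, build_spec("ssp"))
        assert ("wolbachia", "x") in retained

    def test_null_covariate_retention_rate_near_alpha(self, small_panel):
        """Independent covariates should be retained at roughly alpha."""
        rng = np.random.default_rng(32)
        truth = SimTruth(seed=32)
        rec = simdata.simulate_individuals(
            small_panel, None, truth,
            design={"n_per_group": 10, "n_blocks": 1}, seed=32)
        # 30 pure-noise "inversions" (independent of everything)
        inv = pd.DataFrame(
            (rng.random((small_panel.n_lineages, 10)) < 0.3).astype(int),
            columns=list(simdata.INVERSION_CATALOGUE[:10]),
            index=small_panel.lineage_ids)
        cov = simdata.LineageCovariates(
            list(small_panel.lineage_ids),
            np.zeros(small_panel.n_lineages, int), inv,
            np.empty((small_panel.n_lineages, 0)))
        retained = select_covariates(rec, cov, build_spec("ssp"), alpha=0.05)
        # 10 covariates x 4 terms tested; expect ~2 retained terms, allow slack
        assert len(retained) <= 8


class TestRankAccumulation:
    def _tables(self, n, hit_ranks):
        s1 = pd.DataFrame({"marker_id": [f"m{i}" for i in range(n)],
                           "rank": np.arange(1, n + 1)})
        p = np.full(n, 0.5)
        for r in hit_ranks:
            p[r - 1] = 1e-8
        mlm = pd.DataFrame({"marker_id": [f"m{i}" for i in range(n)],
                            "p_value": p})
        return s1, mlm

    def test_counting_oracle(self):
        s1, mlm = self._tables(6, [2, 5])
        curve, plateau = rank_accumulation(s1, mlm)
        assert curve["cumulative_hits"].tolist() == [0, 1, 1, 1, 2, 2]
        assert plateau == 5

    def test_no_hits_gives_zero_curve(self):
        s1, mlm = self._tables(5, [])
        curve, plateau = rank_accumulation(s1, mlm)
        assert (curve["cumulative_hits"] == 0).all()
        assert plateau == 0

    def test_monotone_nondecreasing_for_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            hits = sorted(rng.choice(np.arange(1, n + 1),
                                     size=int(rng.integers(0, n)),
                                     replace=False))
            curve, _ = rank_accumulation(*self._tables(n, hits))
            assert (np.diff(curve["cumulative_hits"]) >= 0).all()

    def test_mismatched_marker_sets_rejected(self):
        s1, mlm = self._tables(5, [1])
        with pytest.raises(ValueError):
            rank_accumulation(s1, mlm.iloc[:3])


class TestTwoStep:
    def test_threshold_one_makes_all_fitted_markers_candidates(
            self, small_panel, small_covariates, planted_records,
            lineage_summary):
        recs = phenotypes.remove_block_effects(planted_records)
        res = run_two_step(small_panel, None, recs, lineage_summary,
                           "ssp", k=20, threshold=1.0)
        assert len(res.candidates) == res.counts["n_mlm_fitted"]

    def test_planted_marker_becomes_candidate(self, small_panel,
                                              planted_records,
                                              lineage_summary):
        recs = phenotypes.remove_block_effects(planted_records)
        res = run_two_step(small_panel, None, recs, lineage_summary,
                           "ssp", k=30)
        assert small_panel.marker_ids[50] in set(res.candidates["marker_id"])

    def test_random_control_deterministic_and_bounded(
            self, small_panel, planted_records):
        recs = phenotypes.remove_block_effects(planted_records)
        spec = build_spec("ssp")
        excluded = set(small_panel.marker_ids[:100])
        t1, s1 = random_control(small_panel, excluded, 5, recs, spec, seed=9)
        t2, s2 = random_control(small_panel, excluded, 5, recs, spec, seed=9)
        assert t1["marker_id"].tolist() == t2["marker_id"].tolist()
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], rtol=1e-6)
        with pytest.raises(ValueError):
            random_control(small_panel, set(small_panel.marker_ids), 5,
                           recs, spec, seed=9)


class TestPrivateQtlContract:
    """A context-free effect must not masquerade as a context-dependent one."""

    def test_pure_additive_effect_yields_null_three_way_test(self, small_panel):
        mid = small_panel.marker_ids[20]
        truth = SimTruth(planted_effects=[PlantedEffect(mid, "G", 0.3)],
                         seed=41)
        rec = simdata.simulate_individuals(
            small_panel, None, truth,
            design={"n_per_group": 10, "n_blocks": 1}, seed=41)
        ssp_fit = fit_marker_mlm(rec, small_panel.dose(mid), build_spec("ssp"))
        size_fit = fit_marker_mlm(rec, small_panel.dose(mid),
                                  build_spec("size_fed"))
        assert size_fit.p_value < 1e-6          # strong additive signal
        assert ssp_fit.p_value > 0.01           # no three-way signal

    def test_three_way_effect_detected_by_ssp_spec(self, small_panel,
                                                   planted_records):
        mid = small_panel.marker_ids[50]
        fit = fit_marker_mlm(planted_records, small_panel.dose(mid),
                             build_spec("ssp"))
        assert fit.p_value < 1e-4
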