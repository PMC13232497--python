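"""Phenotype stage: group filter, block removal, BLUPs, derived indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from privateqtl import phenotypes, simdata
from privateqtl.phenotypes import (
    derive_indices,
    estimate_blups,
    filter_groups,
    independent_plasticity,
    remove_block_effects,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["lineage_id", "sex", "diet", "block",
                                       "size_log"])


class TestFilterGroups:
    def test_fewer_than_min_dropped_exactly(self):
        rows = []
        for i in range(10):
            rows.append((f"A", "F", "fed", "b1", 1.0 + i))
        for i in range(9):
            rows.append((f"B", "F", "fed", "b1", 2.0 + i))
        rec = _records(rows)
        kept, report = filter_groups(rec, min_n=10)
        assert set(kept["lineage_id"]) == {"A"}
        assert len(kept) == 10
        assert report.iloc[0]["lineage_id"] == "B"
        assert report.iloc[0]["n_records"] == 9

    def test_min_n_one_is_identity(self, planted_records):
        kept, report = filter_groups(planted_records, min_n=1)
        assert len(kept) == len(planted_records)
        assert report.empty

    def test_single_undersized_group_count(self, planted_records):
        # remove a few records from one group to push it under threshold
        rec = planted_records.copy()
        mask = ((rec["lineage_id"] == "line_001") & (rec["sex"] == "F")
                & (rec["diet"] == "fed"))
        rec = pd.concat([rec[~mask], rec[mask].head(4)])
        kept, report = filter_groups(rec, min_n=10)
        assert len(kept) == len(rec) - 4
        assert len(report) == 1


class TestRemoveBlockEffects:
    def test_single_block_centers_on_grand_mean(self):
        rec = _records([("A", "F", "fed", "b1", v) for v in (1.0, 2.0, 3.0)])
        out = remove_block_effects(rec)
        np.testing.assert_allclose(out["size_log"], [-1.0, 0.0, 1.0])

    def test_block_means_zero_and_matches_least_squares(self, planted_records):
        out = remove_block_effects(planted_records)
        means = out.groupby("block")["size_log"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        # explicit dummy regression gives the same residuals
        dummies = pd.get_dummies(planted_records["block"]).to_numpy(float)
        y = planted_records["size_log"].to_numpy()
        coef, *_ = np.linalg.lstsq(dummies, y, rcond=None)
        np.testing.assert_allclose(out["size_log"], y - dummies @ coef,
                                   atol=1e-10)


class TestEstimateBlups:
    def test_null_variance_limit_returns_sex_means(self):
        rng = np.random.default_rng(0)
        rows = []
        for lid in ("A", "B", "C", "D"):
            for sex, mu in (("F", 1.2), ("M", 1.0)):
                for diet in ("fed", "starved"):
                    for _ in range(15):
                        rows.append((lid, sex, diet, "b1",
                                     mu + rng.normal(0, 0.05)))
        rec = _records(rows)
        blups, diag = estimate_blups(rec)
        for diet in ("fed", "starved"):
            assert diag.variance_components[diet]["lineage_intercept"] < 1e-3
            sub = rec[(rec["diet"] == diet) & (rec["sex"] == "F")]
            np.testing.assert_allclose(blups[f"b_female_{diet}"],
                                       sub["size_log"].mean(), atol=0.03)

    def test_known_effect_recovery_correlation(self, small_panel):
        vc = simdata.VarianceComponents(0.02, 0.004, 0.004, 0.001, 0.002, 0.01)
        truth = simdata.SimTruth(variance_components=vc, seed=21)
        rec = simdata.simulate_individuals(
            small_panel, None, truth,
            design={"n_per_group": 30, "n_blocks": 3}, seed=21)
        blups, _ = estimate_blups(rec)
        cm = (rec.groupby(["lineage_id", "sex", "diet"], observed=True)
              ["size_log"].mean())
        truth_ff = cm.xs(("F", "fed"), level=("sex", "diet"))
        r = np.corrcoef(blups.set_index("lineage_id")["b_female_fed"]
                        .loc[truth_ff.index], truth_ff)[0, 1]
        assert r > 0.9

    def test_missing_sex_gives_missing_blup(self):
        rng = np.random.default_rng(1)
        rows = []
        for lid in ("A", "B", "C"):
            for sex in ("F", "M"):
                if lid == "A" and sex == "M":
                    continue
                for diet in ("fed", "starved"):
                    for _ in range(12):
                        rows.append((lid, sex, diet, "b1", rng.normal(1.0, 0.1)))
        blups, _ = estimate_blups(_records(rows))
        b = blups.set_index("lineage_id")
        assert np.isnan(b.loc["A", "b_male_fed"])
        assert not np.isnan(b.loc["A", "b_female_fed"])

    def test_shrinkage_never_exceeds_raw_deviation(self):
        """Balanced intercept-only BLUPs shrink toward the stratum mean."""
        from privateqtl.lmm import fit_grouped_lmm
        rng = np.random.default_rng(2)
        L, n = 20, 16
        lin = np.repeat(np.arange(L), n)
        y = 1 + rng.normal(0, 0.2, L)[lin] + rng.normal(0, 0.2, len(lin))
        X = np.ones((len(y), 1))
        fit = fit_grouped_lmm(y, X, X.copy(), lin, structure="diag")
        raw = np.array([y[lin == l].mean() for l in range(L)])
        pred = np.array([fit.blups["group"][l][0] for l in range(L)])
        assert np.all(np.abs(pred) <= np.abs(raw - y.mean()) + 1e-10)

    def test_requires_two_lineages_and_both_sexes(self):
        rec = _records([("A", "F", "fed", "b1", 1.0)] * 12)
        with pytest.raises(ValueError):
            estimate_blups(rec)


class TestDeriveIndices:
    def test_worked_arithmetic_example(self):
        blups = pd.DataFrame([{
            "lineage_id": "A", "b_female_fed": 1.0, "b_female_starved": 0.7,
            "b_male_fed": 0.8, "b_male_starved": 0.6}])
        out = derive_indices(blups).iloc[0]
        assert out["ssd_fed"] == pytest.approx(0.2)
        assert out["ssd_starved"] == pytest.approx(0.1)
        assert out["delta_female"] == pytest.approx(0.3)
        assert out["delta_male"] == pytest.approx(0.2)
        assert out["ssp"] == pytest.approx(0.1)
        assert out["b_lineage_fed"] == pytest.approx(0.9)
        assert out["delta_lineage"] == pytest.approx(0.25)

    def test_equal_blups_give_zero_indices(self):
        blups = pd.DataFrame([{
            "lineage_id": "A", "b_female_fed": 0.5, "b_female_starved": 0.5,
            "b_male_fed": 0.5, "b_male_starved": 0.5}])
        out = derive_indices(blups).iloc[0]
        for col in ("ssd_fed", "ssd_starved", "delta_female", "delta_male",
                    "delta_lineage", "ssp"):
            assert out[col] == 0.0

    @given(st.lists(st.tuples(*[st.floats(-2, 2) for _ in range(4)]),
                    min_size=1, max_size=30))
    def test_ssp_identity_holds_for_random_quadruples(self, quads):
        blups = pd.DataFrame(
            [{"lineage_id": f"l{i}", "b_female_fed": a, "b_female_starved": b,
              "b_male_fed": c, "b_male_starved": d}
             for i, (a, b, c, d) in enumerate(quads)])
        out = derive_indices(blups)
        np.testing.assert_allclose(
            out["ssp"], out["ssd_fed"] - out["ssd_starved"], atol=1e-12)
        np.testing.assert_allclose(
            out["delta_lineage"],
            (out["delta_female"] + out["delta_male"]) / 2, atol=1e-12)

    def test_incomplete_lineage_flagged(self):
        blups = pd.DataFrame([
            {"lineage_id": "A", "b_female_fed": 1.0, "b_female_starved": 0.7,
             "b_male_fed": 0.8, "b_male_starved": 0.6},
            {"lineage_id": "B", "b_female_fed": 1.0,
             "b_female_starved": np.nan, "b_male_fed": 0.8,
             "b_male_starved": 0.6}])
        out = derive_indices(blups)
        assert out["complete"].tolist() == [True, False]
        assert np.isnan(out.loc[1, "ssp"])


class TestIndependentPlasticity:
    def _summary(self, fed_f, st_f):
        # mirror the same values for males; only female columns are asserted
        return derive_indices(pd.DataFrame(
            [{"lineage_id": f"l{i}", "b_female_fed": f, "b_female_starved": s,
              "b_male_fed": f, "b_male_starved": s}
             for i, (f, s) in enumerate(zip(fed_f, st_f))]))

    def test_perfect_linearity_gives_zero_residuals(self):
        out = independent_plasticity(
            self._summary([0.0, 1.0, 2.0], [0.5, 1.5, 2.5]))
        np.testing.assert_allclose(out["delta_female_indep"], 0.0, atol=1e-12)

    def test_closed_form_three_point_regression(self):
        out = independent_plasticity(
            self._summary([0.0, 1.0, 2.0], [0.0, 1.0, 3.0]))
        np.testing.assert_allclose(out["delta_female_indep"],
                                   [1 / 6, -1 / 3, 1 / 6], atol=1e-12)

    def test_residuals_orthogonal_to_fed_blups(self, lineage_summary):
        comp = lineage_summary[lineage_summary["complete"]]
        for sex in ("female", "male"):
            r = np.corrcoef(comp[f"delta_{sex}_indep"],
                            comp[f"b_{sex}_fed"])[0, 1]
            assert abs(r) < 1e-10

    def test_refuses_fewer_than_three_lineages(self):
        with pytest.raises(ValueError):
            independent_plasticity(self._summary([0.0, 1.0], [0.0, 1.0]))
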