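import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpfam import (
    ConfigurationError,
    GeneFamilyMap,
    GeneRecord,
    SampleMetadata,
    count_deviating_families,
    flag_deviations,
    relative_levels,
    sum_families,
)
from rpfam import stoichiometry as stoich_mod
from rpfam.stoichiometry import _t_pvalues, stoichiometry_table


@pytest.fixture
def tiny_map():
    return GeneFamilyMap(
        [
            GeneRecord("a", "FAM1", "RPS", False, 500),
            GeneRecord("b", "FAM1", "RPS", False, 600),
            GeneRecord("c", "FAM2", "RPL", False, 700),
            GeneRecord("p", "FAM2", "RPL", True, 400),
        ]
    )


class TestSumFamilies:
    def test_member_sum_and_single_member(self, tiny_map):
        expr = pd.DataFrame({"s": [3.0, 7.0, 5.0]}, index=["a", "b", "c"])
        fam = sum_families(expr, tiny_map)
        assert fam.at["FAM1", "s"] == 10.0
        assert fam.at["FAM2", "s"] == 5.0

    def test_column_totals_conserved(self, tiny_map, small_panel):
        counts, fam_map, _, _ = small_panel
        expr = counts.values.loc[list(fam_map.non_pseudogene_ids)].astype(float)
        fam = sum_families(expr, fam_map)
        assert np.allclose(fam.sum(axis=0), expr.sum(axis=0))

    def test_pseudogene_excluded(self, tiny_map):
        expr = pd.DataFrame({"s": [1.0, 1.0, 1.0, 99.0]}, index=["a", "b", "c", "p"])
        fam = sum_families(expr, tiny_map)
        assert fam.at["FAM2", "s"] == 1.0

    def test_unknown_gene_rejected(self, tiny_map):
        expr = pd.DataFrame({"s": [1.0] * 4}, index=["a", "b", "c", "zzz"])
        with pytest.raises(ConfigurationError, match="zzz"):
            sum_families(expr, tiny_map)


class TestRelativeLevels:
    def test_hand_case_odd_median(self):
        fam = pd.DataFrame({"s": [10.0, 20.0, 40.0]}, index=["f1", "f2", "f3"])
        rel = relative_levels(fam)
        assert list(rel["s"]) == [0.5, 1.0, 2.0]

    def test_all_equal_gives_ones(self):
        fam = pd.DataFrame(np.full((5, 3), 7.0), columns=list("abc"))
        assert (relative_levels(fam) == 1.0).all().all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        fam = pd.DataFrame(rng.uniform(1, 100, size=(9, 4)))
        scaled = fam * pd.Series([0.1, 3.0, 42.0, 1e6], index=fam.columns)
        pd.testing.assert_frame_equal(relative_levels(fam), relative_levels(scaled))

    def test_median_is_one_for_odd_family_count(self):
        rng = np.random.default_rng(4)
        fam = pd.DataFrame(rng.uniform(1, 100, size=(81, 6)))
        rel = relative_levels(fam)
        assert np.allclose(rel.median(axis=0), 1.0)

    def test_zero_median_names_group(self):
        fam = pd.DataFrame({"good": [1.0, 2.0], "broken": [0.0, 0.0]})
        with pytest.raises(ConfigurationError, match="broken"):
            relative_levels(fam)


class TestFlags:
    def test_strict_boundaries_and_rule(self):
        rel = pd.DataFrame({"s": [0.5, 2.0, 2.5, 0.4, 1.0]})
        flags = flag_deviations(rel)
        assert list(flags["s"]) == ["none", "none", "high", "low", "none"]

    def test_idempotent_pure_function(self):
        rng = np.random.default_rng(5)
        rel = pd.DataFrame(rng.uniform(0, 3, size=(10, 4)))
        pd.testing.assert_frame_equal(flag_deviations(rel), flag_deviations(rel))

    def test_counts_and_cutoff_subset(self):
        flags = pd.DataFrame(
            {
                "t1": ["low", "none", "high", "none"],
                "t2": ["none"] * 4,
                "t3": ["low", "high", "low", "high"],
            }
        )
        counts, over = count_deviating_families(flags, cutoff=3)
        assert list(counts) == [2, 0, 4]
        assert over == ["t3"]


class TestDeviationTTest:
    def test_closed_form_two_replicates(self):
        """Ratios {2.6, 2.4} vs threshold 2: mean 2.5, SE 0.1, t = 5 on df = 1."""
        p = _t_pvalues(np.array([[2.6, 2.4]]), 2.0)[0]
        t_manual = (2.5 - 2.0) / (np.std([2.6, 2.4], ddof=1) / np.sqrt(2))
        assert t_manual == pytest.approx(5.0)
        assert p == pytest.approx(2 * (1 - stats.t.cdf(5.0, df=1)), rel=1e-9)
        assert p == pytest.approx(0.126, abs=1e-3)

    def test_replicates_on_threshold_give_p_one(self):
        assert _t_pvalues(np.array([[2.0, 2.0]]), 2.0)[0] == 1.0

    def test_matches_scipy_oracle_on_random_cases(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            vals = rng.uniform(0.1, 3.0, size=rng.integers(2, 8))
            thr = rng.uniform(0.3, 2.5)
            if np.std(vals, ddof=1) == 0:
                continue
            expected = stats.ttest_1samp(vals, thr).pvalue
            assert _t_pvalues(vals[None, :], thr)[0] == pytest.approx(expected, rel=1e-9)

    def test_requires_two_replicates(self):
        rel = pd.DataFrame({"X.r1": [1.0]}, index=["FAM1"])
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "library_id": ["X.r1"],
                    "sample_code": ["X"],
                    "replicate": [1],
                    "series": ["other"],
                }
            )
        )
        with pytest.raises(ConfigurationError, match="replicate"):
            stoich_mod.test_deviation_significance(rel, meta, "FAM1", "X", 2.0)


class TestStoichiometryTable:
    def test_structure_and_consistency(self, small_panel):
        from rpfam import average_replicates, compute_rpkm

        counts, fam_map, meta, _ = small_panel
        lengths = fam_map.lengths()
        rp = list(fam_map.non_pseudogene_ids)
        expr_lib = compute_rpkm(
            CountMatrix_subset(counts, rp), {g: lengths[g] for g in rp}
        )
        expr_grp = average_replicates(expr_lib, meta)
        fam_lib = sum_families(expr_lib.values, fam_map)
        fam_grp = sum_families(expr_grp.values, fam_map)
        table = stoichiometry_table(fam_grp, fam_lib, meta)
        assert set(table.columns) == {
            "family_id", "sample_code", "relative_level", "flag",
            "threshold_tested", "p_value", "p_adj",
        }
        assert len(table) == fam_grp.shape[0] * fam_grp.shape[1]
        # flags are a pure function of the relative level
        low = table[table.relative_level < 0.5]
        assert (low.flag == "low").all()
        assert (table.p_adj >= table.p_value - 1e-12).all()
        assert table.p_value.between(0, 1).all()


def CountMatrix_subset(counts, genes):
    from rpfam import CountMatrix

    return CountMatrix(
        values=counts.values.loc[genes], library_totals=counts.library_totals
    )


class TestParameterRecovery:
    def test_planted_ratios_recovered_and_baseline_quiet(self):
        """A family planted at 0.3x is flagged low (and one at 2.5x high) in
        >= 90% of sample groups, while baseline families stay unflagged."""
        from rpfam import (
            PlantedFamily,
            ScenarioSpec,
            average_replicates,
            compute_rpkm,
            generate_dataset,
        )

        spec = ScenarioSpec(
            n_families=30,
            n_groups=30,
            seed=1,
            planted={
                0: PlantedFamily("substoichiometric", ratio=0.3),
                1: PlantedFamily("superfluous", ratio=2.5),
            },
        )
        counts, fam_map, meta, truth = generate_dataset(spec)
        expr = average_replicates(compute_rpkm(counts, fam_map.lengths()), meta)
        rel = relative_levels(sum_families(expr.values, fam_map))
        flags = flag_deviations(rel)
        assert (flags.loc["RPF001"] == "low").mean() >= 0.9
        assert (flags.loc["RPF002"] == "high").mean() >= 0.9
        baseline = truth.family_truth.query("scenario == 'baseline'").family_id
        assert (flags.loc[baseline] != "none").to_numpy().mean() <= 0.05
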