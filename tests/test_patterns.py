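import numpy as np
import pandas as pd
import pytest

from rpfam import (
    ConfigurationError,
    GeneFamilyMap,
    GeneRecord,
    PatternParams,
    classify_family_patterns,
    fuzzy_cmeans,
    zscore,
)


class TestZscore:
    def test_hand_case_sample_sd(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        z, constant = zscore(df)
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])
        assert not constant["g"]

    def test_constant_profile_flagged_as_zeros(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"])
        z, constant = zscore(df)
        assert (z.loc["g"] == 0.0).all()
        assert constant["g"]

    def test_row_means_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 50, size=(12, 8)))
        z, _ = zscore(df)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)


def _blobs(rng, centers, n_per, scale=0.05):
    data = np.vstack([rng.normal(c, scale, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pd.DataFrame(data, index=[f"g{i}" for i in range(len(data))]), labels


class TestFuzzyCmeans:
    def test_k1_gives_full_membership_and_mean_center(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(8, 4)))
        fc = fuzzy_cmeans(df, PatternParams(k=1, n_starts=2, seed=0))
        assert (fc.membership == 1.0).all().all()
        assert np.allclose(fc.centers.iloc[0], df.mean(axis=0), atol=1e-6)

    def test_separated_groups_recovered_crisply(self):
        rng = np.random.default_rng(3)
        df, labels = _blobs(rng, [(0.0, 0.0, 0.0), (5.0, 5.0, 5.0)], 15)
        fc = fuzzy_cmeans(df, PatternParams(k=2, m=2.0, n_starts=5, seed=0))
        assert (fc.membership.max(axis=1) > 0.95).all()
        hard = fc.hard_labels.to_numpy()
        assert len(set(zip(hard, labels))) == 2  # one-to-one label mapping

    def test_objective_non_increasing_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            df = pd.DataFrame(rng.normal(size=(30, 5)))
            fc = fuzzy_cmeans(df, PatternParams(k=3, n_starts=1, seed=1))
            assert (np.diff(fc.objective_trace) <= 1e-8).all()

    def test_membership_rows_sum_to_one_and_centers_in_range(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(-2, 2, size=(40, 6)))
        fc = fuzzy_cmeans(df, PatternParams(k=4, n_starts=3, seed=2))
        assert np.allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)
        assert ((fc.membership >= 0) & (fc.membership <= 1)).all().all()
        lo, hi = df.min(axis=0), df.max(axis=0)
        assert ((fc.centers >= lo - 1e-9) & (fc.centers <= hi + 1e-9)).all().all()

    def test_near_hard_fuzzifier_matches_kmeans(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(6)
        df, _ = _blobs(rng, [(0, 0), (4, 0), (0, 4)], 12)
        fc = fuzzy_cmeans(df, PatternParams(k=3, m=1.05, n_starts=10, seed=0))
        km = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(df)
        pairs = set(zip(fc.hard_labels.to_numpy(), km.labels_))
        assert len(pairs) == 3  # identical partitions up to label permutation

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(25, 4)))
        a = fuzzy_cmeans(df, PatternParams(k=3, n_starts=4, seed=9))
        b = fuzzy_cmeans(df, PatternParams(k=3, n_starts=4, seed=9))
        pd.testing.assert_frame_equal(a.membership, b.membership)
        assert a.objective == b.objective

    def test_more_profiles_than_clusters_required(self):
        df = pd.DataFrame(np.eye(2))
        with pytest.raises(ConfigurationError, match="k=3"):
            fuzzy_cmeans(df, PatternParams(k=3))


@pytest.fixture
def pair_map():
    return GeneFamilyMap(
        [
            GeneRecord("a1", "FAMA", "RPS", False, 500),
            GeneRecord("a2", "FAMA", "RPS", False, 500),
            GeneRecord("b1", "FAMB", "RPL", False, 500),
            GeneRecord("b2", "FAMB", "RPL", False, 500),
        ]
    )


SERIES = {"meristem": [f"M{i}" for i in range(1, 7)]}


class TestClassifyFamilyPatterns:
    def _expr(self, a1, a2, b1, b2):
        return pd.DataFrame(
            [a1, a2, b1, b2], index=["a1", "a2", "b1", "b2"], columns=SERIES["meristem"]
        )

    def test_scaled_profiles_similar_mirrored_different(self, pair_map):
        base = [1.0, 2.0, 4.0, 8.0, 6.0, 3.0]
        mirrored = [10.0 - x for x in base]  # affine flip, Pearson r = -1
        expr = self._expr(base, [3 * x for x in base], base, mirrored)
        calls = classify_family_patterns(expr, pair_map, SERIES).set_index("family_id")
        assert calls.at["FAMA", "label"] == "similar"
        assert calls.at["FAMA", "min_pairwise_r"] == pytest.approx(1.0)
        assert calls.at["FAMB", "label"] == "different"
        assert calls.at["FAMB", "min_pairwise_r"] == pytest.approx(-1.0)

    def test_invariant_to_positive_rescaling(self, pair_map):
        rng = np.random.default_rng(8)
        prof = rng.uniform(1, 50, size=(4, 6))
        expr = self._expr(*prof)
        scaled = expr.mul(pd.Series({"a1": 10.0, "a2": 0.2, "b1": 7.0, "b2": 1.0}), axis=0)
        one = classify_family_patterns(expr, pair_map, SERIES)
        two = classify_family_patterns(scaled, pair_map, SERIES)
        pd.testing.assert_frame_equal(one, two)

    def test_single_expressed_member_insufficient(self, pair_map):
        base = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        low = [0.01] * 6
        expr = self._expr(base, low, base, low)
        calls = classify_family_patterns(expr, pair_map, SERIES).set_index("family_id")
        assert (calls["label"] == "insufficient_data").all()

    def test_unknown_series_code_rejected(self, pair_map):
        expr = self._expr(*np.ones((4, 6)))
        with pytest.raises(ConfigurationError, match="NOPE"):
            classify_family_patterns(expr, pair_map, {"meristem": ["M1", "NOPE"] * 3})

    def test_short_series_not_evaluated(self, pair_map):
        base = [1.0, 5.0, 9.0]
        expr = pd.DataFrame(
            [base, base[::-1], base, base],
            index=["a1", "a2", "b1", "b2"],
            columns=["SD.g1", "SD.g2", "SD.g3"],
        )
        calls = classify_family_patterns(
            expr, pair_map, {"germination": list(expr.columns)}
        )
        assert (calls["label"] == "insufficient_data").all()

    def test_planted_scenarios_recovered(self, small_panel):
        from rpfam import average_replicates, compute_rpkm

        counts, fam_map, meta, truth = small_panel
        lengths = {**fam_map.lengths(), **truth.gene_lengths.astype(int).to_dict()}
        expr = average_replicates(compute_rpkm(counts, lengths), meta)
        calls = classify_family_patterns(
            expr.values, fam_map, meta.series_groups()
        ).set_index("family_id")
        fam_truth = truth.family_truth.set_index("family_id")
        concerted = fam_truth.query("scenario == 'concerted'").index
        contrasting = fam_truth.query("scenario == 'contrasting'").index
        assert (calls.loc[concerted, "label"] == "similar").all()
        assert (calls.loc[contrasting, "label"] == "different").all()
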