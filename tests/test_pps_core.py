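import json
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import ppskit as pk
from ppskit.pps_core import (
    NEGATIVE_RISK,
    POSITIVE_RISK,
    columnwise_pearson,
    select_signs,
)

from conftest import random_cohort


class TestAlleleMeans:
    def test_direct_arithmetic(self, tiny_genotypes, tiny_outcome):
        means = pk.compute_allele_means(
            tiny_genotypes, tiny_outcome, tiny_genotypes.subject_ids
        )
        assert means["rs1"] == {1: 0.5, 2: 1.5, 3: 4.0}

    def test_unobserved_category_absent_and_degenerate_flagged(self):
        g = pk.genotype_matrix_from_arrays([[2.0], [2.0], [2.0]], ["A", "B", "C"], ["rs1"])
        outcome = pk.OutcomeData(delta_sse=pd.Series([1, 2, 3], index=["A", "B", "C"]))
        means = pk.compute_allele_means(g, outcome, ["A", "B", "C"])
        assert means["rs1"] == {2: 2.0}  # single category: excluded downstream
        with pytest.raises(pk.SizeError):
            pk.derive_recoding(means["rs1"])

    def test_agrees_with_groupby_oracle(self):
        rng = np.random.default_rng(42)
        g, outcome = random_cohort(rng, 20, 8)
        means = pk.compute_allele_means(g, outcome, g.subject_ids)
        for snp in g.snp_ids:
            oracle = outcome.delta_sse.groupby(g.data[snp]).mean()
            assert means[snp] == {int(c): m for c, m in oracle.items()}


class TestDeriveRecoding:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ({1: -0.5, 2: 0.3, 3: 1.2}, {1: -1, 2: 0, 3: 1}),
            ({1: 0.2, 3: 0.9}, {1: -1, 3: 1}),
            ({1: 0.5, 2: 0.5, 3: 1.0}, {1: -1, 2: 0, 3: 1}),  # tie: lower code lower rank
            ({1: 1.2, 2: 0.3, 3: -0.5}, {1: 1, 2: 0, 3: -1}),
        ],
    )
    def test_orientation_rules(self, means, expected):
        assert pk.derive_recoding(means) == expected

    def test_antisymmetry_under_outcome_negation(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            means = {c: float(rng.normal()) for c in (1, 2, 3)}
            flipped = {c: -m for c, m in means.items()}
            fwd = pk.derive_recoding(means)
            # negation reverses ranks when all means are distinct
            if len(set(means.values())) == 3:
                assert pk.derive_recoding(flipped) == {c: -s for c, s in fwd.items()}


class TestApplyRecoding:
    def test_mapping_missing_and_unseen_categories(self, caplog):
        g = pk.GenotypeMatrix(
            pd.DataFrame({"rs1": [1.0, 2.0, 3.0, np.nan]}, index=list("ABCD"))
        )
        A = pk.apply_recoding(g, {"rs1": {1: -1, 2: 1}})  # category 3 unseen
        assert A["rs1"].tolist()[:2] == [-1.0, 1.0]
        assert np.isnan(A.loc["C", "rs1"])  # unseen category -> missing
        assert np.isnan(A.loc["D", "rs1"])  # missing stays missing

    def test_missing_map_is_key_error(self, tiny_genotypes):
        with pytest.raises(KeyError, match="rs3"):
            pk.apply_recoding(tiny_genotypes, {"rs1": {1: -1, 3: 1}, "rs2": {1: -1, 2: 1}})


class TestPearson:
    def test_perfect_and_undefined(self):
        assert pk.pearson_r([1, 2, 1, 2], [1, 2, 1, 2]) == pytest.approx(1.0)
        assert np.isnan(pk.pearson_r([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pk.pearson_r(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_textbook_example(self):
        x = np.array([-1, 0, 1, 1], dtype=float)
        y = np.array([1, 1, 2, 2], dtype=float)
        assert pk.pearson_r(x, y) == pytest.approx(1.5 / np.sqrt(2.75))

    def test_length_mismatch(self):
        with pytest.raises(pk.SizeError):
            pk.pearson_r([1, 2], [1, 2, 3])

    def test_columnwise_matches_scalar_with_missing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        X[rng.random(X.shape) < 0.15] = np.nan
        y = rng.normal(size=25)
        r_vec = columnwise_pearson(X, y)
        for j in range(6):
            assert r_vec[j] == pytest.approx(pk.pearson_r(X[:, j], y), nan_ok=True)

    def test_invariant_under_affine_label_recoding(self):
        # r with labels {1,2} equals r with labels {0,1}
        rng = np.random.default_rng(9)
        x = rng.choice([-1.0, 0.0, 1.0], size=40)
        d = rng.choice([1.0, 2.0], size=40)
        assert pk.pearson_r(x, d) == pytest.approx(pk.pearson_r(x, d - 1))


class TestFiltersAndSigns:
    def test_initial_filter_threshold_semantics(self):
        # three columns engineered around the 0.1 bound
        y = pd.Series([1, 1, 1, 2, 2, 2], index=list("ABCDEF"))
        outcome = pk.OutcomeData(delta_sse=y - 1)  # labels equal y
        A = pd.DataFrame(
            {
                "keep": [-1, -1, 0, 0, 1, 1],     # r well above 0.1
                "weak": [1, -1, 0, 0, -1, 1],     # r = 0 -> excluded
                "const": [0, 0, 0, 0, 0, 0],      # undefined -> excluded
            },
            index=list("ABCDEF"),
            dtype=float,
        )
        kept = pk.initial_correlation_filter(A, outcome, list("ABCDEF"), threshold=0.1)
        assert kept == ["keep"]

    def test_split_signed_indicators_reconstruction(self):
        rng = np.random.default_rng(2)
        A = pd.DataFrame(rng.choice([-1.0, 0.0, 1.0, np.nan], size=(30, 5)))
        A1, A2 = pk.split_signed_indicators(A)
        assert set(np.unique(A1.to_numpy()[~np.isnan(A1.to_numpy())])) <= {-1.0, 0.0}
        assert set(np.unique(A2.to_numpy()[~np.isnan(A2.to_numpy())])) <= {0.0, 1.0}
        pd.testing.assert_frame_equal(A1 + A2, A)

    def test_sign_selection_rules(self):
        d = np.array([1, 1, 2, 2, 1, 2], dtype=float)
        a1 = np.array([-1, -1, 0, 0, 0, -1], dtype=float)   # weak/negative signal
        a2 = np.array([0, 0, 1, 1, 0, 1], dtype=float)      # strong positive signal
        assert pk.select_signed_variant(a1, a2, d) == POSITIVE_RISK
        const = np.zeros(6)
        assert pk.select_signed_variant(a1, const, d) == NEGATIVE_RISK
        assert pk.select_signed_variant(const, const, d) is None
        # exact tie -> positive-risk variant
        assert pk.select_signed_variant(a2, a2, d) == POSITIVE_RISK

    def test_stability_round_zero_survives_negative_does_not(self):
        # column 'zero' has r exactly 0 in any half (orthogonal pattern),
        # column 'neg' correlates negatively everywhere
        ids = [f"S{i}" for i in range(8)]
        d = pd.Series([1, 2, 1, 2, 1, 2, 1, 2], index=ids)
        outcome = pk.OutcomeData(delta_sse=d - 1)
        cols = pd.DataFrame(
            {"pos": (d - 1.0), "neg": (1.0 - d)}, index=ids, dtype=float
        )
        survivors = pk.stability_filter_round(cols, outcome, ids, np.random.default_rng(0))
        assert survivors == ["pos"]

    def test_survivors_shrink_monotonically(self):
        rng = np.random.default_rng(8)
        g, outcome = random_cohort(rng, 60, 30)
        means = pk.compute_allele_means(g, outcome, g.subject_ids)
        maps = {s: pk.derive_recoding(m) for s, m in means.items() if len(m) >= 2}
        A = pk.apply_recoding(g.select_snps(list(maps)), maps)
        counts = []
        survivors = list(A.columns)
        for i in range(4):
            survivors = pk.stability_filter_round(
                A.loc[:, survivors], outcome, g.subject_ids, np.random.default_rng(i)
            )
            counts.append(len(survivors))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert set(survivors) <= set(A.columns)


class TestModelAndScoring:
    def _model(self):
        return pk.build_pps_model(
            ["rs1", "rs2"],
            {"rs1": {1: -1, 2: 0, 3: 1}, "rs2": {1: -1, 3: 1}},
            {"rs1": POSITIVE_RISK, "rs2": NEGATIVE_RISK},
        )

    def test_restricted_maps_by_sign(self):
        model = self._model()
        by_id = {s.snp_id: s for s in model.survivors}
        assert by_id["rs1"].score_map == {1: 0, 2: 0, 3: 1}
        assert by_id["rs2"].score_map == {1: -1, 3: 0}

    def test_json_round_trip_lossless(self, tmp_path):
        model = self._model()
        model.cutpoint = 0.5
        model.provenance = {"master_seed": 3, "stage_counts": [["input", 2]]}
        path = tmp_path / "model.json"
        model.save(path)
        again = pk.PPSModel.load(path)
        assert again.to_json() == model.to_json()

    def test_scoring_matches_per_subject_loop_oracle(self):
        rng = np.random.default_rng(17)
        g, _ = random_cohort(rng, 25, 6)
        maps = {s: {1: -1, 2: 0, 3: 1} for s in g.snp_ids}
        signs = {s: rng.choice([NEGATIVE_RISK, POSITIVE_RISK]) for s in g.snp_ids}
        model = pk.build_pps_model(g.snp_ids, maps, signs)
        scores = pk.score_subjects(model, g)
        for sid in g.subject_ids:
            expected = sum(
                s.score_map.get(int(g.data.loc[sid, s.snp_id]), 0)
                for s in model.survivors
            )
            assert scores[sid] == expected
        assert (scores.abs() <= len(model.survivors)).all()

    def test_all_missing_subject_scores_zero(self):
        g = pk.GenotypeMatrix(
            pd.DataFrame({"rs1": [np.nan, 1.0, 2.0]}, index=list("ABC"))
        )
        model = pk.build_pps_model(
            ["rs1"], {"rs1": {1: -1, 2: 0, 3: 1}}, {"rs1": POSITIVE_RISK}
        )
        assert pk.score_subjects(model, g)["A"] == 0

    def test_missing_survivor_snp_is_scoring_error(self, tiny_genotypes):
        model = pk.build_pps_model(
            ["rs9"], {"rs9": {1: -1, 3: 1}}, {"rs9": POSITIVE_RISK}
        )
        with pytest.raises(pk.ScoringError, match="rs9"):
            pk.score_subjects(model, tiny_genotypes)

    def test_empty_model_warns_and_scores_zero(self, tiny_genotypes):
        with pytest.warns(UserWarning, match="no surviving"):
            model = pk.build_pps_model([], {}, {})
        assert (pk.score_subjects(model, tiny_genotypes) == 0).all()


class TestEndToEnd:
    def test_same_seed_gives_byte_identical_model(self):
        scenario = pk.make_scenario("moderate")
        g, outcome, _ = pk.generate_cohort(scenario)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, _, _ = pk.derive_pps(g, outcome, seed=5)
            m2, _, _ = pk.derive_pps(g, outcome, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_survivor_counts_shrink_through_stages(self):
        g, outcome, _ = pk.generate_cohort(pk.make_scenario("strong"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, assign, report = pk.derive_pps(g, outcome, seed=2)
        counts = dict(model.provenance["stage_counts"])
        stages = [
            "initial_r_filter",
            "sign_selection",
            "stability_pre_round1",
            "stability_pre_round2",
            "stability_post_round1",
            "stability_post_round2",
        ]
        values = [counts[s] for s in stages]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert len(model.survivors) == values[-1]
        assert len(assign.derivation_ids) == 97
        assert len(assign.validation_ids) == 32

    def test_recoding_antisymmetry_full_pipeline_orientation(self):
        # negating the outcome flips every derived recode map on distinct means
        rng = np.random.default_rng(23)
        g, outcome = random_cohort(rng, 40, 10)
        neg = pk.OutcomeData(delta_sse=-outcome.delta_sse)
        means = pk.compute_allele_means(g, outcome, g.subject_ids)
        means_neg = pk.compute_allele_means(g, neg, g.subject_ids)
        for snp in g.snp_ids:
            m = means[snp]
            if len(m) >= 2 and len(set(m.values())) == len(m):
                fwd = pk.derive_recoding(m)
                rev = pk.derive_recoding(means_neg[snp])
                assert rev == {c: -s for c, s in fwd.items()}


@given(seed=st.integers(0, 1000))
def test_stability_filter_is_subset_of_input(seed):
    rng = np.random.default_rng(seed)
    g, outcome = random_cohort(rng, 16, 5)
    A = g.data - 2.0  # categories 1/2/3 -> -1/0/1 without estimation
    survivors = pk.stability_filter_round(A, outcome, g.subject_ids, rng)
    assert set(survivors) <= set(A.columns)
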