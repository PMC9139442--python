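"""Agreement metrics, confidence tiers, similarity matrices, stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugsig.evaluation import (DatasetEvaluation, classify_confidence,
                                classify_reference_table, concordance_index,
                                drug_similarity, jaccard_index,
                                load_reference_validation_table, spearman_rho,
                                spearman_test, stratify_by_score)
from drugsig.signatures import DrugEfficacySignature


def oracle_ci(pred, obs):
    """Exhaustive pairwise enumeration of the concordance index."""
    num = den = 0.0
    for i, j in itertools.combinations(range(len(pred)), 2):
        if obs[i] == obs[j]:
            continue
        den += 1
        if pred[i] == pred[j]:
            num += 0.5
        elif (pred[i] < pred[j]) == (obs[i] < obs[j]):
            num += 1
    return num / den if den else float("nan")


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(30):
            x = np.round(rng.normal(size=8), 1)  # ties likely
            y = np.round(rng.normal(size=8), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))

    def test_exact_permutation_pvalue_small_n(self):
        x = np.arange(6.0)
        rho, p = spearman_test(x, x)
        assert rho == 1.0
        assert p == pytest.approx(2 / 720)  # only +-identity reach |rho|=1


class TestConcordanceIndex:
    def test_identical_and_reversed_orderings(self):
        x = np.array([0.1, 0.5, 0.2, 0.9])
        assert concordance_index(x, x) == 1.0
        assert concordance_index(x, -x) == 0.0

    def test_three_sample_worked_example(self):
        # pairs: (1,3)&(1,2) concordant, (3,2)&(2,3) discordant, (1,2)&(1,3) concordant
        assert concordance_index([1, 3, 2], [1, 2, 3]) == pytest.approx(2 / 3)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 8))
            pred = rng.integers(0, 4, n).astype(float)
            obs = rng.integers(0, 4, n).astype(float)
            ours = concordance_index(pred, obs)
            expected = oracle_ci(pred, obs)
            if np.isnan(expected):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        pred = rng.normal(size=15)
        obs = rng.normal(size=15)
        base = concordance_index(pred, obs)
        assert concordance_index(np.exp(pred), obs ** 3) == pytest.approx(base)

    def test_random_permutation_concentrates_at_half(self, rng):
        obs = np.arange(20.0)
        values = [concordance_index(rng.permutation(20).astype(float), obs)
                  for _ in range(300)]
        assert abs(np.mean(values) - 0.5) < 0.02

    def test_all_observed_tied_is_undefined(self):
        assert np.isnan(concordance_index([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))


def _evals(rhos, drug="d", ci=None):
    return [DatasetEvaluation(drug_id=drug, dataset_id=f"ds{i}",
                              spearman_rho=r, concordance_index=ci)
            for i, r in enumerate(rhos)]


class TestConfidenceTiers:
    def test_published_high_confidence_example(self):
        # Lapatinib's printed per-dataset correlations
        call = classify_confidence(_evals([0.68, 0.54, 0.5, 0.34, 0.26, 0.9]))
        assert call.tier == "high"

    def test_published_medium_confidence_example(self):
        # Cisplatin's printed per-dataset correlations
        assert classify_confidence(_evals([0.37, 0.29])).tier == "medium"

    def test_uninformative_everywhere_is_low(self):
        assert classify_confidence(_evals([0.0, 0.0, 0.0])).tier == "low"

    def test_ci_alone_can_lift_to_high(self):
        evals = _evals([0.1], ci=0.7)
        assert classify_confidence(evals).tier == "high"

    def test_monotone_in_rho(self, rng):
        order = {"low": 0, "medium": 1, "high": 2}
        for _ in range(50):
            rhos = list(rng.uniform(-0.5, 0.6, size=int(rng.integers(1, 5))))
            base = order[classify_confidence(_evals(rhos)).tier]
            i = int(rng.integers(0, len(rhos)))
            bumped = list(rhos)
            bumped[i] += float(rng.uniform(0, 0.4))
            assert order[classify_confidence(_evals(bumped)).tier] >= base

    def test_no_evaluations_rejected(self):
        with pytest.raises(ValueError):
            classify_confidence([])


class TestReferenceTable:
    def test_medium_or_better_count_matches_print(self):
        table = classify_reference_table()
        assert (table["computed_confidence"] != "low").sum() == 28

    def test_labels_reproduced_except_documented_boundary_rows(self):
        table = classify_reference_table()
        mismatch = table[table["computed_confidence"].str.capitalize()
                         != table["confidence"]]
        # two drugs print rho = 0.4 yet carry a medium label; the stated
        # rule (rho >= 0.4 -> high) flips exactly those
        assert set(mismatch["drug"]) == {"BIBW2992", "Temsirolimus"}

    def test_table_shape(self):
        table = load_reference_validation_table()
        assert len(table) == 28
        assert {"drug", "GRAY", "Caldas", "confidence"} <= set(table.columns)


class TestSimilarity:
    def _signatures(self):
        return [DrugEfficacySignature("d1", ["a", "b"], ["c"], pd.DataFrame()),
                DrugEfficacySignature("d2", ["b", "c"], ["d"], pd.DataFrame()),
                DrugEfficacySignature("d3", ["x"], ["y"], pd.DataFrame())]

    def test_jaccard_worked_example_and_oracle(self, rng):
        assert jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        for _ in range(30):
            a = set(rng.choice(20, rng.integers(0, 10), replace=False))
            b = set(rng.choice(20, rng.integers(1, 10), replace=False))
            expected = len(a & b) / len(a | b)
            assert jaccard_index(a, b) == pytest.approx(expected)

    def test_matrices_symmetric_with_unit_diagonal(self, rng):
        auc = pd.DataFrame(rng.uniform(0, 1, (15, 3)),
                           columns=["d1", "d2", "d3"])
        rho, signif, jac = drug_similarity(auc, self._signatures())
        for m in (rho, jac):
            np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
            np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0)
        assert jac.loc["d1", "d2"] == pytest.approx(
            jaccard_index({"a", "b", "c"}, {"b", "c", "d"}))

    def test_disjoint_sample_coverage_gives_missing_entry(self):
        auc = pd.DataFrame({"d1": [0.1, 0.2, 0.3, np.nan, np.nan, np.nan],
                            "d2": [np.nan, np.nan, np.nan, 0.5, 0.6, 0.7],
                            "d3": np.linspace(0, 1, 6)})
        rho, _, _ = drug_similarity(auc, self._signatures())
        assert np.isnan(rho.loc["d1", "d2"])
        assert not np.isnan(rho.loc["d1", "d3"])

    def test_significance_flag_tracks_pvalue(self, rng):
        n = 30
        x = rng.normal(size=n)
        auc = pd.DataFrame({"d1": x, "d2": x + rng.normal(0, 0.1, n),
                            "d3": rng.normal(size=n)})
        _, signif, _ = drug_similarity(auc, self._signatures())
        assert signif.loc["d1", "d2"]
        assert not signif.loc["d1", "d3"]


class TestStratify:
    def test_hundred_distinct_scores_split_ten_ten(self, rng):
        scores = pd.Series(rng.permutation(100).astype(float))
        tiers = stratify_by_score(scores)
        assert (tiers == "bottom").sum() == 10
        assert (tiers == "top").sum() == 10
        assert (tiers == "middle").sum() == 80

    def test_constant_scores_collapse_to_one_tier(self):
        tiers = stratify_by_score(pd.Series(np.ones(20)))
        assert set(tiers) == {"bottom"}

    def test_tiers_partition_the_samples(self, rng):
        tiers = stratify_by_score(pd.Series(rng.normal(size=37)))
        assert tiers.isin(["bottom", "middle", "top"]).all()
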