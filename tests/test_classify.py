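import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_oracle
from sigstrat.classify import (
    CATEGORIES,
    ClassificationParams,
    call_sample_status,
    change_enrichment,
    classify_samples,
    count_beyond_threshold,
    four_way_category,
    score_bin_compare,
    signature_score,
    zscore_classify,
)
from sigstrat.data import ExpressionMatrix, GeneSignature, ValidationError
from sigstrat.simulate import CohortConfig, generate_cohort


def make_expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"G{i}" for i in range(values.shape[0])],
        [f"S{i}" for i in range(values.shape[1])],
    )


class TestParams:
    def test_defaults(self):
        p = ClassificationParams()
        assert p.low_threshold == -0.5 and p.high_threshold == 1.0
        assert p.fisher_alpha == 0.1 and p.fold_change_cut == 1.5

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            ClassificationParams(fisher_alpha=1.5)

    def test_threshold_order(self):
        with pytest.raises(ValidationError):
            ClassificationParams(low_threshold=2.0, high_threshold=1.0)


class TestCounting:
    def test_all_zero_matrix(self):
        em = make_expr(np.zeros((4, 3)))
        sig = GeneSignature("s", tuple(em.gene_ids))
        counts, _, _ = count_beyond_threshold(em, sig, -0.5, "at_or_below")
        assert (counts == 0).all()

    def test_boundary_inclusive(self):
        # a gene exactly at -0.5 counts ("-0.5 or under")
        em = make_expr([[-0.5, -0.49]])
        sig = GeneSignature("s", ("G0",))
        counts, _, _ = count_beyond_threshold(em, sig, -0.5, "at_or_below")
        assert counts.tolist() == [1, 0]

    def test_boundary_inclusive_high(self):
        em = make_expr([[1.0, 0.999]])
        sig = GeneSignature("s", ("G0",))
        counts, _, _ = count_beyond_threshold(em, sig, 1.0, "at_or_above")
        assert counts.tolist() == [1, 0]

    def test_random_matrix_vs_enumeration(self, rng):
        em = make_expr(rng.normal(size=(10, 5)))
        sig = GeneSignature("s", tuple(em.gene_ids))
        counts, _, _ = count_beyond_threshold(em, sig, -0.5, "at_or_below")
        for j in range(5):
            expected = sum(1 for i in range(10) if em.values[i, j] <= -0.5)
            assert counts.iloc[j] == expected

    def test_missing_never_counted(self):
        em = make_expr([[np.nan, -1.0]])
        sig = GeneSignature("s", ("G0",))
        counts, avail, _ = count_beyond_threshold(em, sig, -0.5, "at_or_below")
        assert counts.tolist() == [0, 1]
        assert avail.tolist() == [0, 1]

    def test_all_genes_absent_rejected(self, rng):
        em = make_expr(rng.normal(size=(3, 3)))
        sig = GeneSignature("s", ("X1", "X2"))
        with pytest.raises(ValidationError, match="X1"):
            count_beyond_threshold(em, sig, 0.0, "at_or_below")

    def test_absent_genes_dropped_with_warning(self, rng):
        em = make_expr(rng.normal(size=(3, 3)))
        sig = GeneSignature("s", ("G0", "G1", "ABSENT"))
        with pytest.warns(UserWarning, match="absent"):
            _, _, used = count_beyond_threshold(em, sig, 0.0, "at_or_below")
        assert used == ("G0", "G1")

    def test_monotone_in_threshold(self, rng):
        em = make_expr(rng.normal(size=(20, 8)))
        sig = GeneSignature("s", tuple(em.gene_ids))
        c1, _, _ = count_beyond_threshold(em, sig, -0.5, "at_or_below")
        c2, _, _ = count_beyond_threshold(em, sig, -0.2, "at_or_below")
        assert (c2 >= c1).all()


class TestCalls:
    def test_uniform_cohort_all_negative(self):
        counts = pd.Series([5, 5, 5, 5], index=list("abcd"))
        out = call_sample_status(counts, 20, alpha=0.1)
        assert not out["positive"].any()
        assert (out["p_value"] >= 0.5).all()

    def test_single_extreme_sample(self):
        counts = pd.Series([20] + [0] * 9, index=[f"s{i}" for i in range(10)])
        out = call_sample_status(counts, 20, alpha=0.1)
        # cohort mean = 2; expected p from the enumeration oracle
        expected_p = fisher_oracle(20, 0, 2, 18, "greater")
        assert out.loc["s0", "p_value"] == pytest.approx(expected_p, abs=1e-12)
        assert out.loc["s0", "positive"]
        assert not out["positive"].iloc[1:].any()

    def test_sample_permutation_invariance(self, rng):
        counts = pd.Series(rng.integers(0, 21, size=12), index=[f"s{i}" for i in range(12)])
        out1 = call_sample_status(counts, 20)
        perm = rng.permutation(12)
        out2 = call_sample_status(counts.iloc[perm], 20)
        assert (out2.loc[out1.index, "p_value"] == out1["p_value"]).all()

    def test_count_exceeding_size_rejected(self):
        with pytest.raises(ValidationError):
            call_sample_status(pd.Series([25, 0]), 20)

    def test_planted_concordance(self):
        hits = []
        for seed in range(10):
            c = generate_cohort(CohortConfig(seed=seed, category_probs=(0.75, 0.0, 0.25, 0.0)))
            res = classify_samples(c.expression, c.ra_signature, c.erk_signature)
            truth_ra = c.truth["category"].str.startswith("RA-D")
            called_ra = res.table["ra_call"] == "RA-D"
            hits.append((truth_ra == called_ra).mean())
        assert np.mean(hits) >= 0.95

    def test_null_cohort_conservative(self):
        # i.i.d. noise: positive-call rate should not exceed alpha + 3 SE
        rates = []
        for seed in range(10):
            c = generate_cohort(
                CohortConfig(seed=seed, effect_ra=0.0, effect_erk=0.0, anti_corr_loading=0.0)
            )
            res = classify_samples(c.expression, c.ra_signature, c.erk_signature)
            rates.append((res.table["ra_call"] == "RA-D").mean())
            rates.append((res.table["erk_call"] == "ERK-I").mean())
        n = 200 * len(rates)
        se = np.sqrt(0.1 * 0.9 / n)
        assert np.mean(rates) <= 0.1 + 3 * se


class TestFourWay:
    def test_pairing(self):
        ra = pd.Series(["RA-D", "RA-ND"], index=["a", "b"], dtype="string")
        erk = pd.Series(["ERK-I", "ERK-NI"], index=["a", "b"], dtype="string")
        cat = four_way_category(ra, erk)
        assert cat["a"] == "RA-D/ERK-I"
        assert cat["b"] == "RA-ND/ERK-NI"

    def test_mismatched_universe_rejected(self):
        ra = pd.Series(["RA-D"], index=["a"], dtype="string")
        erk = pd.Series(["ERK-I"], index=["b"], dtype="string")
        with pytest.raises(ValidationError, match="universes differ"):
            four_way_category(ra, erk)

    def test_order_invariance(self):
        ra = pd.Series(["RA-D", "RA-ND", "RA-D"], index=["a", "b", "c"], dtype="string")
        erk = pd.Series(["ERK-NI", "ERK-I", "ERK-I"], index=["c", "a", "b"], dtype="string")
        cat = four_way_category(ra, erk)
        assert cat["a"] == "RA-D/ERK-I"
        assert cat["c"] == "RA-D/ERK-NI"

    def test_partition_sums_to_cohort(self):
        c = generate_cohort(CohortConfig(seed=5, n_samples=80))
        res = classify_samples(c.expression, c.ra_signature, c.erk_signature)
        assert res.category_counts().sum() == 80

    def test_unclassifiable_when_all_missing(self, rng):
        vals = rng.normal(size=(6, 4))
        vals[:3, 0] = np.nan  # sample S0 missing every RA gene
        em = make_expr(vals)
        ra = GeneSignature("ra", ("G0", "G1", "G2"))
        erk = GeneSignature("erk", ("G3", "G4", "G5"))
        res = classify_samples(em, ra, erk)
        assert res.table.loc["S0", "category"] == "unclassifiable"


class TestZScore:
    def test_all_positive(self):
        em = make_expr(np.ones((3, 4)))
        sig = GeneSignature("s", tuple(em.gene_ids))
        labels, retained = zscore_classify(em, sig)
        assert len(retained) == 3
        assert (labels == "high").all()

    def test_self_standardized_cohort_is_error(self, rng):
        vals = rng.normal(size=(5, 10))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        em = make_expr(z)
        sig = GeneSignature("s", tuple(em.gene_ids))
        with pytest.raises(ValidationError, match="not cohort-upregulated"):
            zscore_classify(em, sig)

    def test_planted_subgroup_recovered(self, rng):
        n_hi, n_lo = 30, 30
        z = rng.normal(size=(20, n_hi + n_lo)) * 0.3
        z[:, :n_hi] += 1.0  # hydrogel-high subgroup shifted vs external reference
        z[:, n_hi:] -= 0.5  # rest of the cohort sits below the reference
        em = make_expr(z)
        sig = GeneSignature("s", tuple(em.gene_ids))
        labels, _ = zscore_classify(em, sig)
        truth = np.array(["high"] * n_hi + ["low"] * n_lo)
        assert (labels.to_numpy() == truth).mean() >= 0.95


class TestChangeEnrichment:
    def test_identical_matrices(self, rng):
        vals = rng.normal(size=(20, 5))
        cancer = make_expr(vals)
        normal = make_expr(vals)
        sig = GeneSignature("s", tuple(cancer.gene_ids[:5]))
        out = change_enrichment(cancer, normal, sig, "down")
        assert out["percent_changed"] == 0.0
        assert out["test"].p_value == 1.0

    def test_planted_enrichment(self, rng):
        g, n = 1050, 30
        vals = rng.normal(size=(g, n)) * 0.3
        normal = make_expr(rng.normal(size=(g, 6)) * 0.3)
        vals[:50] -= 1.0  # signature genes shifted down in cancer
        cancer = ExpressionMatrix(vals, normal.gene_ids, [f"T{i}" for i in range(n)])
        sig = GeneSignature("s", tuple(normal.gene_ids[:50]))
        out = change_enrichment(cancer, normal, sig, "down", 1.5)
        assert out["test"].p_value < 0.001

    def test_signature_exhausts_universe_rejected(self, rng):
        vals = rng.normal(size=(5, 4))
        cancer, normal = make_expr(vals), make_expr(vals)
        sig = GeneSignature("s", tuple(cancer.gene_ids))
        with pytest.raises(ValidationError, match="background"):
            change_enrichment(cancer, normal, sig, "down")

    def test_gene_universe_mismatch_rejected(self, rng):
        cancer = make_expr(rng.normal(size=(5, 4)))
        normal = ExpressionMatrix(
            rng.normal(size=(4, 3)), [f"H{i}" for i in range(4)], [f"N{i}" for i in range(3)]
        )
        sig = GeneSignature("s", ("G0",))
        with pytest.raises(ValidationError, match="universe"):
            change_enrichment(cancer, normal, sig, "down")


class TestScores:
    def test_single_gene_signature_identity(self, rng):
        em = make_expr(rng.normal(size=(4, 6)))
        sig = GeneSignature("s", ("G2",))
        out = signature_score(em, sig)
        assert np.allclose(out.scores.to_numpy(), em.values[2])

    def test_constant_matrix(self):
        em = make_expr(np.full((5, 4), 2.5))
        sig = GeneSignature("s", ("G0", "G3"))
        out = signature_score(em, sig)
        assert np.allclose(out.scores, 2.5)

    def test_empty_intersection_rejected(self, rng):
        em = make_expr(rng.normal(size=(3, 3)))
        with pytest.raises(ValidationError):
            signature_score(em, GeneSignature("s", ("nope",)))

    def test_anti_correlated_scores(self):
        neg = 0
        for seed in range(20):
            c = generate_cohort(CohortConfig(seed=seed))
            ra = signature_score(c.expression, c.ra_signature).scores
            erk = signature_score(c.expression, c.erk_signature).scores
            if np.corrcoef(ra, erk)[0, 1] < 0:
                neg += 1
        assert neg >= 19

    def test_score_bin_compare_tertiles(self, rng):
        idx = [f"s{i}" for i in range(30)]
        b = pd.Series(np.arange(30, dtype=float), index=idx)
        a = pd.Series(rng.normal(size=30), index=idx)
        out = score_bin_compare(a, b, n_bins=3)
        assert out["n_samples"].sum() == 30
        assert len(out) == 3
        assert out.loc[0, "mean_score_a"] == pytest.approx(a.iloc[:10].mean())
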