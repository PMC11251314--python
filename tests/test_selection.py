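"""Filter cascades: boundary strictness, ranking, reports, estimator API,
and equivalence with the brute-force oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from refval import (
    CandidateTable,
    ExpressionMatrix,
    FilterThresholds,
    ReferenceGeneSelector,
    ValidationGeneSelector,
    analyze,
    build_candidate_table,
    query_candidate_rank,
    select_reference_candidates,
    select_validation_candidates,
)
from _oracle import oracle_reference, oracle_validation, random_gene_pool


def matrix_from_pool(pool):
    genes = list(pool)
    k = len(next(iter(pool.values())))
    return ExpressionMatrix.from_values(genes, [f"c{j}" for j in range(k)],
                                        [pool[g] for g in genes])


class TestCascadeSemantics:
    def test_toy_matrix_splits_cleanly(self, toy_matrix):
        res = analyze(toy_matrix)
        assert res.reference.gene_ids == ["g_ref"]
        assert res.validation.gene_ids == ["g_val"]
        assert res.reference_report.input_count == 3
        assert [c for _, c in res.reference_report.survivors] == [2, 1, 1, 1, 1]
        assert [c for _, c in res.validation_report.survivors] == [2, 1, 1]

    def test_reference_gene_record_values(self, toy_matrix):
        table, _ = select_reference_candidates(toy_matrix)
        rec = table.records[0]
        assert (rec.rank, rec.gene_id) == (1, "g_ref")
        assert rec.sd == 0.0 and rec.cv == 0.0
        assert rec.log2_mean == pytest.approx(6.0)

    def test_validation_records_have_no_cv(self, toy_matrix):
        table, _ = select_validation_candidates(toy_matrix)
        assert all(rec.cv is None for rec in table.records)

    def test_empty_matrix_yields_empty_tables(self):
        m = ExpressionMatrix(pd.DataFrame(columns=["a", "b"], dtype=float))
        res = analyze(m)
        assert len(res.reference) == 0 and len(res.validation) == 0
        assert res.reference_report.input_count == 0
        assert all(c == 0 for _, c in res.reference_report.survivors)


class TestBoundaryStrictness:
    """A value sitting exactly on a cutoff fails that cutoff."""

    def test_mean_exactly_at_floor_is_excluded(self):
        # constant TPM 32 -> mean log2 exactly 5, sd 0
        m = ExpressionMatrix.from_values(["g"], list("abcdef"), [[32.0] * 6])
        table, report = select_reference_candidates(m)
        assert len(table) == 0
        # survives expression, sd and deviation filters; dies at the mean floor
        assert dict(report.survivors)["deviation_ceiling"] == 1
        assert dict(report.survivors)["mean_floor"] == 0

    def test_deviation_exactly_two_is_excluded(self):
        # log2 = [6,6,6,6,6,8.4]: outlier deviation 5*(8.4-6)/6 = 2 exactly,
        # while sd ~ 0.98 still passes the sd ceiling
        vals = [64.0] * 5 + [2.0 ** 8.4]
        m = ExpressionMatrix.from_values(["g"], list("abcdef"), [vals])
        table, report = select_reference_candidates(m)
        assert len(table) == 0
        assert dict(report.survivors)["sd_ceiling"] == 1
        assert dict(report.survivors)["deviation_ceiling"] == 0

    def test_sd_exactly_one_fails_both_paths(self):
        # log2 = [7,7,5,5,6]: sum sq dev = 4, sample sd = sqrt(4/4) = 1.0
        vals = [128.0, 128.0, 32.0, 32.0, 64.0]
        m = ExpressionMatrix.from_values(["g"], list("abcde"), [vals])
        ref, ref_rep = select_reference_candidates(m)
        val, val_rep = select_validation_candidates(m)
        assert len(ref) == 0 and len(val) == 0
        assert dict(ref_rep.survivors)["sd_ceiling"] == 0
        assert dict(val_rep.survivors)["sd_floor"] == 0


class TestRanking:
    def test_reference_ranks_follow_cv_ascending(self):
        entries = [("gA", 0.1, 6.0, 0.03), ("gB", 0.05, 7.0, 0.01),
                   ("gC", 0.2, 6.5, 0.02)]
        table = build_candidate_table("reference", entries)
        assert table.gene_ids == ["gB", "gC", "gA"]
        assert [r.rank for r in table.records] == [1, 2, 3]

    def test_validation_ranks_follow_sd_descending(self):
        entries = [("gA", 2.0, 6.0, None), ("gB", 6.5, 7.0, None),
                   ("gC", 4.0, 6.5, None)]
        table = build_candidate_table("validation", entries)
        assert table.gene_ids == ["gB", "gC", "gA"]

    def test_ties_break_lexicographically(self):
        entries = [("zz", 0.1, 6.0, 0.02), ("aa", 0.1, 6.0, 0.02)]
        table = build_candidate_table("reference", entries)
        assert table.gene_ids == ["aa", "zz"]

    def test_query_candidate_rank(self):
        table = build_candidate_table(
            "reference",
            [("g1", 0.1, 6.0, 0.01), ("g2", 0.1, 6.0, 0.02), ("g3", 0.1, 6.0, 0.03)],
        )
        assert query_candidate_rank(table, "g3").rank == 3
        assert query_candidate_rank(table, "g1").rank == 1
        assert query_candidate_rank(table, "absent") is None

    def test_table_invariants_enforced(self):
        from refval import CandidateRecord

        with pytest.raises(ValueError):
            CandidateTable("reference", [
                CandidateRecord(1, "a", 0.1, 6.0, 0.3),
                CandidateRecord(2, "b", 0.1, 6.0, 0.1),
            ])


class TestOracleEquivalence:
    """The vectorised cascades agree with a per-gene brute-force evaluation
    of the raw inequalities, including order and reported statistics."""

    @pytest.mark.parametrize("trial", range(8))
    def test_random_pools_match_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        pool = random_gene_pool(rng, int(rng.integers(20, 200)),
                                int(rng.integers(2, 11)))
        matrix = matrix_from_pool(pool)
        ref, _ = select_reference_candidates(matrix)
        val, _ = select_validation_candidates(matrix)
        expect_ref = oracle_reference(pool)
        expect_val = oracle_validation(pool)
        assert [(r.rank, r.gene_id) for r in ref.records] == [
            (rank, g) for rank, g, *_ in expect_ref
        ]
        assert [(r.rank, r.gene_id) for r in val.records] == [
            (rank, g) for rank, g, *_ in expect_val
        ]
        for rec, (_, _, sd, mean, cv) in zip(ref.records, expect_ref):
            assert rec.sd == pytest.approx(sd, abs=1e-9)
            assert rec.log2_mean == pytest.approx(mean, abs=1e-9)
            assert rec.cv == pytest.approx(cv, abs=1e-9)

    def test_population_divisor_matches_oracle(self):
        rng = np.random.default_rng(42)
        pool = random_gene_pool(rng, 120, 5)
        matrix = matrix_from_pool(pool)
        ref, _ = select_reference_candidates(matrix, ddof=0)
        expect = oracle_reference(pool, ddof=0)
        assert [r.gene_id for r in ref.records] == [g for _, g, *_ in expect]


class TestCascadeProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_counts_non_increasing_and_disjoint_outputs(self, seed):
        rng = np.random.default_rng(seed)
        pool = random_gene_pool(rng, 60, int(rng.integers(2, 8)))
        matrix = matrix_from_pool(pool)
        res = analyze(matrix)
        for rep in (res.reference_report, res.validation_report):
            counts = [rep.input_count] + [c for _, c in rep.survivors]
            assert all(b <= a for a, b in zip(counts, counts[1:]))
        # first survivor count = genes positive everywhere
        n_pos = sum(all(v > 0 for v in vals) for vals in pool.values())
        assert res.reference_report.survivors[0][1] == n_pos
        # mutual exclusion at default thresholds (sd<1 vs sd>1)
        assert not (set(res.reference.gene_ids) & set(res.validation.gene_ids))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_condition_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pool = random_gene_pool(rng, 50, 6)
        matrix = matrix_from_pool(pool)
        perm = rng.permutation(6)
        shuffled = ExpressionMatrix(matrix.data.iloc[:, perm])
        a, b = analyze(matrix), analyze(shuffled)
        assert a.reference.gene_ids == b.reference.gene_ids
        assert a.validation.gene_ids == b.validation.gene_ids

    def test_relaxed_thresholds_reduce_to_expression_filter(self, rng):
        pool = random_gene_pool(rng, 150, 5)
        matrix = matrix_from_pool(pool)
        thr = FilterThresholds(sd_max=1e18, dev_max=1e18, mean_min=-1e18, cv_max=1e18)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ill-defined CV warning expected
            table, report = select_reference_candidates(matrix, thr)
        positive = {g for g, vals in pool.items()
                    if all(v > 0 for v in vals)
                    and np.log2(np.asarray(vals)).mean() > 0}
        # only genes with a positive mean can clear the CV ratio filter
        assert set(table.gene_ids) == positive

    def test_scaling_shifts_mean_keeps_sd(self, rng):
        pool = random_gene_pool(rng, 40, 6)
        matrix = matrix_from_pool(pool)
        doubled = ExpressionMatrix(matrix.data * 2.0)
        a = ReferenceGeneSelector().fit(matrix.to_samples_frame()).statistics_
        b = ReferenceGeneSelector().fit(doubled.to_samples_frame()).statistics_
        mask = a["log2_mean"].notna()
        np.testing.assert_allclose(
            b.loc[mask, "log2_mean"], a.loc[mask, "log2_mean"] + 1.0, atol=1e-9
        )
        np.testing.assert_allclose(
            b.loc[mask, "log2_sd"], a.loc[mask, "log2_sd"], atol=1e-9
        )

    def test_ill_defined_cv_warns_when_mean_floor_disabled(self):
        # mean log2 = -1: reaches the CV stage only when mean_min <= 0
        m = ExpressionMatrix.from_values(["g"], ["a", "b"], [[0.5, 0.5]])
        thr = FilterThresholds(mean_min=-10.0)
        with pytest.warns(UserWarning, match="ill-defined"):
            table, _ = select_reference_candidates(m, thr)
        assert len(table) == 0


class TestEstimatorAPI:
    def test_selector_mixin_transform(self, toy_matrix):
        X = toy_matrix.to_samples_frame()
        sel = ReferenceGeneSelector().fit(X)
        assert list(sel.get_support(indices=False)) == [True, False, False]
        reduced = sel.transform(X)
        assert reduced.shape == (6, 1)

    def test_clone_and_params_roundtrip(self):
        sel = ReferenceGeneSelector(cv_max=0.1, ddof=0)
        params = sel.get_params()
        assert params["cv_max"] == 0.1 and params["ddof"] == 0
        sel2 = clone(sel).set_params(cv_max=0.3)
        assert sel2.get_params()["cv_max"] == 0.3

    def test_plain_array_input_gets_positional_ids(self):
        X = np.array([[64.0, 4.0]] * 6)
        X[1::2, 1] = 1024.0
        sel = ValidationGeneSelector().fit(X)
        assert sel.candidate_table_.gene_ids == ["g1"]

    def test_rejects_negative_and_single_sample(self):
        with pytest.raises(ValueError):
            ReferenceGeneSelector().fit(np.array([[1.0, -1.0], [1.0, 2.0]]))
        with pytest.raises(ValueError):
            ReferenceGeneSelector().fit(np.array([[1.0, 2.0]]))
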