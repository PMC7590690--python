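import numpy as np
import pandas as pd
import pytest

from immunoscape.mutation import (
    MutationSet,
    bh_fdr,
    build_mutation_set,
    frequency_filter,
    is_nssm,
    logistic_enrichment,
    mutation_frequency_table,
    run_enrichment,
)
from immunoscape.types import ClinicalTable, VariantRecord


def rec(sample, gene, cls):
    return VariantRecord(sample, gene, cls)


class TestIsNssm:
    @pytest.mark.parametrize("cls,expected", [
        ("Missense_Mutation", True),
        ("Nonsense_Mutation", True),
        ("Nonstop_Mutation", True),
        ("Frame_Shift_Ins", True),
        ("Frame_Shift_Del", True),
        ("In_Frame_Ins", True),
        ("In_Frame_Del", True),
        ("Splice_Site", True),
        ("Silent", False),
        ("3'UTR", False),
        ("Intron", False),
        ("RNA", False),
    ])
    def test_maf_dialect_vocabulary(self, cls, expected):
        assert is_nssm(rec("s", "g", cls)) is expected

    def test_unknown_token_warns_and_excludes(self):
        with pytest.warns(UserWarning, match="unknown"):
            assert is_nssm(rec("s", "g", "Weird_Class_xyz")) is False

    def test_custom_vocabulary_overrides(self):
        assert is_nssm(rec("s", "g", "Silent"), {"Silent": True}) is True


class TestBuildMutationSet:
    def test_multiple_hits_one_gene_binary_entry_tmb_counts_variants(self):
        records = [rec("s1", "G", "Missense_Mutation")] * 3 + [
            rec("s1", "G", "Silent")]
        ms = build_mutation_set(records, ["s1", "s2"])
        assert ms.matrix.loc["G", "s1"] == 1
        assert ms.tmb["s1"] == 3

    def test_sample_without_variants_gets_zero_row(self):
        ms = build_mutation_set([rec("s1", "G", "Missense_Mutation")],
                                ["s1", "s2"])
        assert ms.tmb["s2"] == 0
        assert ms.matrix["s2"].sum() == 0

    def test_orphan_sample_is_error(self):
        with pytest.raises(ValueError, match="sX"):
            build_mutation_set([rec("sX", "G", "Missense_Mutation")], ["s1"])

    def test_matches_naive_double_loop(self, rng):
        samples = [f"s{i}" for i in range(8)]
        genes = [f"G{i}" for i in range(5)]
        classes = ["Missense_Mutation", "Silent", "Splice_Site"]
        records = [
            rec(samples[rng.integers(8)], genes[rng.integers(5)],
                classes[rng.integers(3)])
            for _ in range(60)
        ]
        ms = build_mutation_set(records, samples)
        nssm = {"Missense_Mutation", "Splice_Site"}
        for s in samples:
            assert ms.tmb[s] == sum(
                1 for r in records
                if r.sample_id == s and r.variant_classification in nssm)
            for g in ms.genes:
                expected = any(
                    r.sample_id == s and r.gene_symbol == g
                    and r.variant_classification in nssm for r in records)
                assert bool(ms.matrix.loc[g, s]) == expected

    def test_binarization_idempotent(self, rng):
        samples = [f"s{i}" for i in range(6)]
        records = [rec(samples[rng.integers(6)], f"G{rng.integers(4)}",
                       "Missense_Mutation") for _ in range(30)]
        ms = build_mutation_set(records, samples)
        # expand the binary matrix back into one record per (gene, sample)
        expanded = [rec(s, g, "Missense_Mutation")
                    for g in ms.genes for s in samples if ms.matrix.loc[g, s]]
        ms2 = build_mutation_set(expanded, samples)
        pd.testing.assert_frame_equal(
            ms.matrix.sort_index(), ms2.matrix.sort_index())


def _mutset_from_matrix(matrix):
    tmb = matrix.sum(axis=0).astype(int)
    return MutationSet(matrix, tmb)


class TestFrequencyFilter:
    def test_per_type_5pct_boundary(self):
        samples = [f"s{i}" for i in range(100)]
        m = pd.DataFrame(0, index=["keep", "drop"], columns=samples, dtype=np.int8)
        m.loc["keep", samples[:5]] = 1   # exactly 5%
        m.loc["drop", samples[:4]] = 1   # 4% -> strict '<' excludes
        clin = ClinicalTable(pd.DataFrame({"tumor_type": ["T"] * 100},
                                          index=samples))
        out = frequency_filter(_mutset_from_matrix(m), clin, "per_type")
        assert out == {"T": ["keep"]}

    def test_pan_cancer_half_percent_boundary(self):
        samples = [f"s{i}" for i in range(1000)]
        m = pd.DataFrame(0, index=["keep", "drop"], columns=samples, dtype=np.int8)
        m.loc["keep", samples[:5]] = 1   # 0.5% retained
        m.loc["drop", samples[:4]] = 1   # 0.4% excluded
        out = frequency_filter(_mutset_from_matrix(m), None, "pan_cancer")
        assert out == ["keep"]

    def test_tiny_threshold_keeps_all_mutated_genes(self):
        samples = [f"s{i}" for i in range(10)]
        m = pd.DataFrame(0, index=["a", "b"], columns=samples, dtype=np.int8)
        m.iloc[:, 0] = 1
        out = frequency_filter(_mutset_from_matrix(m), None, "pan_cancer",
                               pan_threshold=1e-9)
        assert set(out) == {"a", "b"}


class TestLogisticEnrichment:
    def test_null_gene_constant_tmb(self, rng):
        n = 400
        status = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n)
        coef, p, ok = logistic_enrichment(status, group, np.full(n, 10))
        assert ok
        assert abs(coef) < 0.5
        assert p > 0.05

    def test_matches_closed_form_log_odds_ratio(self):
        # 2x2 table (a, b; c, d) with constant TMB: b1 = ln(ad/bc)
        a, b, c, d = 20, 10, 8, 25  # group=1&mut, group=1&wt, group=0&mut, group=0&wt
        status = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        group = np.array([1] * (a + b) + [0] * (c + d))
        coef, p, ok = logistic_enrichment(status, group, np.full(len(group), 7))
        assert ok
        assert coef == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_constant_tmb_equals_covariate_free_fit(self, rng):
        import statsmodels.api as sm
        n = 300
        status = rng.integers(0, 2, n)
        group = (rng.random(n) < 0.3 + 0.3 * status).astype(float)
        coef, p, ok = logistic_enrichment(status, group, np.full(n, 42))
        X = np.column_stack([np.ones(n), status])
        free = sm.Logit(group, X).fit(disp=0)
        assert coef == pytest.approx(free.params[1], abs=1e-8)

    def test_separation_is_flagged_not_raised(self):
        status = np.array([1, 1, 1, 0, 0, 0])
        group = np.array([1, 1, 1, 0, 0, 0])
        coef, p, ok = logistic_enrichment(status, group, np.full(6, 5))
        assert not ok
        assert np.isnan(p)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_monotone_nondecreasing_in_sorted_p(self, rng):
        p = rng.uniform(size=50)
        adj = bh_fdr(np.sort(p))
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj <= 1).all()

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRunEnrichment:
    def _toy_inputs(self, rng, n=80):
        samples = [f"s{i}" for i in range(n)]
        group = np.array(["non_inflamed", "inflamed"] * (n // 2))
        calls = pd.DataFrame({"group": group}, index=samples)
        matrix = pd.DataFrame(
            rng.integers(0, 2, size=(4, n)).astype(np.int8),
            index=[f"G{i}" for i in range(4)], columns=samples)
        tmb = matrix.sum(axis=0) + rng.integers(1, 20, n)
        clin = ClinicalTable(pd.DataFrame(
            {"tumor_type": ["T1"] * (n // 2) + ["T2"] * (n // 2)},
            index=samples))
        return MutationSet(matrix, tmb), calls, clin

    def test_empty_after_filter_returns_empty(self, rng):
        ms, calls, clin = self._toy_inputs(rng)
        out = run_enrichment(ms, calls, clin, mode="pan_cancer",
                             pan_threshold=99.0)
        assert len(out) == 0

    def test_invariant_to_sample_and_gene_order(self, rng):
        ms, calls, clin = self._toy_inputs(rng)
        base = run_enrichment(ms, calls, clin, mode="pan_cancer")
        perm = rng.permutation(ms.matrix.columns)
        gperm = rng.permutation(ms.matrix.index)
        ms2 = MutationSet(ms.matrix.loc[gperm, perm], ms.tmb.loc[perm])
        shuffled = run_enrichment(ms2, calls.loc[perm], clin, mode="pan_cancer")
        merged = base.merge(shuffled, on="gene", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["coefficient_a"],
                                   merged["coefficient_b"], atol=1e-10)
        np.testing.assert_allclose(merged["fdr_a"], merged["fdr_b"], atol=1e-10)

    def test_stratum_with_empty_group_is_skipped_with_warning(self, rng):
        ms, calls, clin = self._toy_inputs(rng)
        # make T2 all-inflamed so its non-inflamed arm is empty
        t2 = clin.tumor_type[clin.tumor_type == "T2"].index
        calls.loc[t2, "group"] = "inflamed"
        with pytest.warns(UserWarning, match="skipped"):
            out = run_enrichment(ms, calls, clin, mode="per_type",
                                 per_type_threshold=1.0)
        assert set(out["stratum"]) <= {"T1"}


class TestFrequencyTable:
    def test_fraction_arithmetic(self):
        samples = [f"s{i}" for i in range(10)]
        m = pd.DataFrame(0, index=["G"], columns=samples, dtype=np.int8)
        m.loc["G", samples[:2]] = 1
        clin = ClinicalTable(pd.DataFrame({"tumor_type": ["T"] * 10},
                                          index=samples))
        out = mutation_frequency_table(_mutset_from_matrix(m), clin)
        row = out[(out.gene == "G") & (out.tumor_type == "T")].iloc[0]
        assert row["fraction"] == pytest.approx(0.2)
        assert row["n"] == 10

    def test_matches_tally_oracle(self, rng):
        samples = [f"s{i}" for i in range(12)]
        m = pd.DataFrame(rng.integers(0, 2, size=(3, 12)).astype(np.int8),
                         index=["A", "B", "C"], columns=samples)
        clin = ClinicalTable(pd.DataFrame(
            {"tumor_type": ["X"] * 5 + ["Y"] * 7}, index=samples))
        out = mutation_frequency_table(_mutset_from_matrix(m), clin)
        for _, row in out.iterrows():
            members = clin.tumor_type[clin.tumor_type == row.tumor_type].index
            assert row.fraction == pytest.approx(
                m.loc[row.gene, members].mean())
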