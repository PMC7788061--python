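"""Single-variant tests, BH FDR, aggregate set tests, sequential
elimination and fixed-effect meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathassoc.association import (
    SetTestConfig,
    _allelic_test,
    bh_fdr,
    fixed_effect_meta,
    gene_assoc,
    sequential_elimination,
    set_assoc,
    single_variant_assoc,
)
from pathassoc.datatypes import GeneSetCollection, GenotypeMatrix


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over j with p_j >= p_i of
    m*p_j/rank_j, computed by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        best = min(best, m * p[idx] / rank)
        q[idx] = min(best, 1.0)
    return q


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.01]) == pytest.approx([0.01])

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = bh_fdr(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, 200)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


class TestSingleVariant:
    def test_allelic_or_hand_value(self):
        # cases 30/170 minor/major alleles, controls 20/180
        d_case = np.r_[np.ones(30), np.zeros(70)]  # 100 cases, 30 het
        d_ctrl = np.r_[np.ones(20), np.zeros(80)]
        ln_or, se, p = _allelic_test(d_case, d_ctrl)
        assert np.exp(ln_or) == pytest.approx(1.588, abs=5e-4)

    def test_equal_frequencies_or_one(self):
        d = np.r_[np.ones(25), np.zeros(75)]
        ln_or, _, _ = _allelic_test(d, d)
        assert ln_or == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_skipped(self, null_cohort):
        gm = null_cohort["genotypes"]
        mono = GenotypeMatrix(
            sample_ids=gm.sample_ids,
            variant_ids=np.array(["m1", "p1"], dtype=object),
            dosage=np.column_stack(
                [np.zeros(gm.n_samples, dtype=np.int8), gm.dosage[:, 0]]
            ),
        )
        res = single_variant_assoc(mono, null_cohort["clinical"])
        assert res.loc[res["variant_id"] == "m1", "note"].item() == "monomorphic"
        assert res.loc[res["variant_id"] == "m1", "test"].item() == "skipped"

    def test_null_cohort_effects_center_on_zero(self, null_cohort):
        res = single_variant_assoc(null_cohort["genotypes"], null_cohort["clinical"])
        eff = res.loc[res["test"] != "skipped", "effect"].dropna()
        se = eff.std() / np.sqrt(len(eff))
        assert abs(eff.mean()) < 3 * se

    def test_rare_variant_falls_back_to_allelic(self, null_cohort):
        res = single_variant_assoc(null_cohort["genotypes"], null_cohort["clinical"])
        assert (res["test"] == "allelic").any()
        assert (res["test"] == "logistic").any()


class TestSetAssoc:
    def test_set_without_variants_reported(self, null_cohort):
        gs = GeneSetCollection.from_dict(
            {"real": list(null_cohort["genesets"])[0].genes, "ghost": ["NOPE1"]}
        )
        res = set_assoc(
            null_cohort["genotypes"],
            null_cohort["variants"],
            gs,
            null_cohort["clinical"],
        )
        ghost = res[res["set_id"] == "ghost"].iloc[0]
        assert ghost["genes_in_test"] == 0 and np.isnan(ghost["p_value"])
        assert ghost["note"] == "genes in test = 0"

    def test_rare_stratum_of_common_only_set_skipped(self, rng):
        n = 200
        gm = GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            variant_ids=np.array(["v1", "v2"], dtype=object),
            dosage=rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8),
        )
        variants = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
                "minor_allele": ["G", "T"],
                "maf": gm.maf(),
                "gene_id": ["G1", "G1"],
            }
        )
        clinical = pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "status": ["case"] * 100 + ["control"] * 100,
            }
        )
        gs = GeneSetCollection.from_dict({"setA": ["G1"]})
        res = set_assoc(
            gm, variants, gs, clinical, SetTestConfig(maf_stratum="rare")
        )
        row = res.iloc[0]
        assert row["n_variants_tested"] == 0 and np.isnan(row["p_value"])

    def test_config_requires_rho_endpoints(self):
        with pytest.raises(ValueError):
            SetTestConfig(rho_grid=(0.0, 0.5))

    def test_empty_collection_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            set_assoc(
                null_cohort["genotypes"],
                null_cohort["variants"],
                GeneSetCollection([]),
                null_cohort["clinical"],
            )


def test_set_assoc_by_stratum_columns_and_counts(null_cohort):
    """The strata report carries per-stratum SNV counts and FDRs, with
    the stratum counts partitioning consistently (common + rare <= all)."""
    from pathassoc.association import set_assoc_by_stratum

    out = set_assoc_by_stratum(
        null_cohort["genotypes"],
        null_cohort["variants"],
        null_cohort["genesets"],
        null_cohort["clinical"],
    )
    assert {"fdr_all", "fdr_common", "fdr_rare"} <= set(out.columns)
    assert len(out) == len(null_cohort["genesets"])
    assert (out["n_snvs_common"] + out["n_snvs_rare"] <= out["n_snvs_all"]).all()


class TestGeneAssoc:
    def test_duplicate_gene_ids_rejected(self, null_cohort):
        with pytest.raises(ValueError, match="duplicate"):
            gene_assoc(
                null_cohort["genotypes"],
                null_cohort["variants"],
                null_cohort["clinical"],
                genes=["GENE0001", "GENE0001"],
            )

    def test_single_variant_gene_matches_score_test(self, rng):
        from pathassoc.skat import skat_o_test

        n = 300
        gm = GenotypeMatrix(
            sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            variant_ids=np.array(["v1"], dtype=object),
            dosage=rng.binomial(2, 0.3, size=(n, 1)).astype(np.int8),
        )
        variants = pd.DataFrame(
            {
                "variant_id": ["v1"],
                "chrom": ["1"],
                "pos": [100],
                "ref": ["A"],
                "alt": ["G"],
                "minor_allele": ["G"],
                "maf": gm.maf(),
                "gene_id": ["G1"],
            }
        )
        clinical = pd.DataFrame(
            {"sample_id": gm.sample_ids, "status": ["case"] * 150 + ["control"] * 150}
        )
        res = gene_assoc(gm, variants, clinical)
        direct = skat_o_test(gm.dosage.astype(float), np.r_[np.ones(150), np.zeros(150)])
        assert res.iloc[0]["p_value"] == pytest.approx(direct.p_value, rel=1e-9)

    def test_bonferroni_flag_present(self, null_cohort):
        res = gene_assoc(
            null_cohort["genotypes"], null_cohort["variants"], null_cohort["clinical"]
        )
        tested = res["p_value"].notna()
        assert res.loc[tested, "bonferroni_threshold"].iloc[0] == pytest.approx(
            0.05 / tested.sum()
        )


class TestSequentialElimination:
    def test_null_cohort_gives_empty_selection(self, null_cohort):
        res = sequential_elimination(
            null_cohort["genotypes"],
            null_cohort["variants"],
            null_cohort["genesets"],
            null_cohort["clinical"],
        )
        assert len(res) == 0

    def test_causal_pathway_selected_first(self, causal_cohort):
        # flat weights match the fixture's common-variant architecture
        res = sequential_elimination(
            causal_cohort["genotypes"],
            causal_cohort["variants"],
            causal_cohort["genesets"],
            causal_cohort["clinical"],
            SetTestConfig(weight_beta=(1.0, 1.0)),
        )
        assert len(res) >= 1
        assert res.iloc[0]["pathway_id"] == "hsa04000"

    def test_fully_overlapping_causal_genes_yield_one_pathway(self, causal_cohort):
        causal_genes = list(causal_cohort["genesets"]["hsa04000"].genes)
        twin_sets = GeneSetCollection.from_dict(
            {
                "twinA": causal_genes,
                "twinB": causal_genes + ["GENE0020"],
            }
        )
        res = sequential_elimination(
            causal_cohort["genotypes"],
            causal_cohort["variants"],
            twin_sets,
            causal_cohort["clinical"],
            SetTestConfig(weight_beta=(1.0, 1.0)),
        )
        assert len(res) == 1
        assert res.iloc[0]["pathway_id"] in {"twinA", "twinB"}


class TestFixedEffectMeta:
    def test_single_study_identity(self):
        out = fixed_effect_meta([0.3], [0.1])
        assert out["ln_or"] == pytest.approx(0.3) and out["se"] == pytest.approx(0.1)

    def test_two_identical_studies(self):
        out = fixed_effect_meta([0.2, 0.2], [0.1, 0.1])
        assert out["ln_or"] == pytest.approx(0.2)
        assert out["se"] == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_weighted_example(self):
        out = fixed_effect_meta([np.log(2), 0.0], [0.2, 0.4])
        assert out["ln_or"] == pytest.approx(0.5545, abs=5e-5)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            fixed_effect_meta([0.1], [0.0])
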