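"""Pathway PRS: LD pruning, weight construction, the score formula and
control-percentile positivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathassoc.datatypes import GeneSetCollection, GenotypeMatrix
from pathassoc.prs import (
    build_prs_weights,
    classify_positivity,
    compute_pathway_prs,
    ld_prune,
    PathwayPRS,
)


def make_gm(dosage, prefix="v"):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i}" for i in range(dosage.shape[0])], dtype=object),
        variant_ids=np.array([f"{prefix}{j}" for j in range(dosage.shape[1])], dtype=object),
        dosage=dosage,
    )


def variant_frame(gm, chrom=None, pos=None, gene=None):
    m = gm.n_variants
    return pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "minor_allele": ["G"] * m,
            "maf": gm.maf(),
            "gene_id": gene if gene is not None else ["G1"] * m,
        }
    )


def brute_force_prune(X, chrom, pos, p, r2_threshold, window):
    order = np.argsort(p, kind="stable")
    kept = []
    Xc = X - X.mean(axis=0)
    for j in order:
        if Xc[:, j].std() == 0:
            continue
        ok = True
        for k in kept:
            if chrom[k] != chrom[j] or abs(pos[k] - pos[j]) > window:
                continue
            r = np.corrcoef(Xc[:, j], Xc[:, k])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


class TestLdPrune:
    def test_uncorrelated_all_retained(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(500, 6)))
        vt = variant_frame(gm)
        p = pd.Series(rng.uniform(0, 1, 6), index=gm.variant_ids)
        kept = ld_prune(gm, vt, p)
        assert set(kept) == set(gm.variant_ids)

    def test_duplicated_column_keeps_lower_p(self, rng):
        col = rng.binomial(2, 0.3, size=(200, 1))
        gm = make_gm(np.hstack([col, col]))
        vt = variant_frame(gm)
        p = pd.Series([0.5, 0.01], index=gm.variant_ids)
        kept = ld_prune(gm, vt, p)
        assert kept == ["v1"]

    def test_matches_brute_force_oracle(self, rng):
        for rep in range(5):
            r = np.random.default_rng(rep)
            base = r.binomial(2, r.uniform(0.1, 0.4, 10), size=(300, 10)).astype(float)
            # induce correlation: copy some columns with noise
            base[:, 3] = np.clip(base[:, 1] + r.binomial(1, 0.1, 300), 0, 2)
            base[:, 7] = np.clip(base[:, 5] + r.binomial(1, 0.1, 300), 0, 2)
            gm = make_gm(base)
            chrom = ["1"] * 5 + ["2"] * 5
            pos = [1000, 2000, 3000, 4000, 900000, 1000, 2000, 3000, 4000, 5000]
            vt = variant_frame(gm, chrom=chrom, pos=pos)
            p = pd.Series(r.uniform(0, 1, 10), index=gm.variant_ids)
            kept = ld_prune(gm, vt, p, r2_threshold=0.2, window_kb=500)
            oracle = brute_force_prune(
                base.astype(float), chrom, np.array(pos), p.to_numpy(), 0.2, 5e5
            )
            assert kept == [gm.variant_ids[j] for j in oracle]

    def test_empty_input(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(50, 2)))
        assert ld_prune(gm, variant_frame(gm), pd.Series(dtype=float)) == []


class TestWeights:
    def assoc_frame(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "effect", "p_value"])

    def setup_method(self):
        self.genesets = GeneSetCollection.from_dict({"pw1": ["G1"], "pw2": ["G1", "G2"]})

    def test_weight_is_log_or(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(20, 1)))
        vt = variant_frame(gm)
        assoc = self.assoc_frame([("v0", np.log(2.0), 0.01)])
        w = build_prs_weights(assoc, ["v0"], self.genesets, vt)
        assert w["weight"].iloc[0] == pytest.approx(0.6931, abs=5e-5)
        # variant in G1 contributes to both pathways containing G1
        assert set(w["pathway_id"]) == {"pw1", "pw2"}

    def test_above_alpha_excluded(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(20, 1)))
        assoc = self.assoc_frame([("v0", 0.5, 0.2)])
        w = build_prs_weights(assoc, ["v0"], self.genesets, variant_frame(gm))
        assert w.empty

    def test_unpruned_excluded(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(20, 1)))
        assoc = self.assoc_frame([("v0", 0.5, 0.001)])
        w = build_prs_weights(assoc, [], self.genesets, variant_frame(gm))
        assert w.empty

    def test_protective_weight_signed_by_default(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(20, 1)))
        assoc = self.assoc_frame([("v0", np.log(0.5), 0.01)])
        w = build_prs_weights(assoc, ["v0"], self.genesets, variant_frame(gm))
        assert w["weight"].iloc[0] == pytest.approx(-0.6931, abs=5e-5)
        assert not w["flipped"].any()

    def test_risk_orientation_flips_protective(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(20, 1)))
        assoc = self.assoc_frame([("v0", np.log(0.5), 0.01)])
        w = build_prs_weights(
            assoc, ["v0"], self.genesets, variant_frame(gm), orientation="risk"
        )
        assert w["weight"].iloc[0] == pytest.approx(0.6931, abs=5e-5)
        assert w["flipped"].all()


class TestScores:
    def test_zero_genotype_scores_zero(self):
        gm = make_gm(np.array([[0, 0], [1, 2]]))
        weights = pd.DataFrame(
            {
                "variant_id": ["v0", "v1"],
                "pathway_id": ["p", "p"],
                "gene_id": ["G1", "G1"],
                "weight": [np.log(2), np.log(1.5)],
                "p_value": [0.01, 0.01],
                "flipped": [False, False],
            }
        )
        prs = compute_pathway_prs(gm, weights)
        assert prs.scores.loc["s0", "p"] == 0.0
        # (ln2 * 1) + (ln1.5 * 2) = 1.5041
        assert prs.scores.loc["s1", "p"] == pytest.approx(1.5041, abs=5e-5)

    def test_single_snv_dosage_two(self):
        gm = make_gm(np.array([[2]]))
        weights = pd.DataFrame(
            {
                "variant_id": ["v0"],
                "pathway_id": ["p"],
                "gene_id": ["G1"],
                "weight": [np.log(2)],
                "p_value": [0.01],
                "flipped": [False],
            }
        )
        prs = compute_pathway_prs(gm, weights)
        assert prs.scores.iloc[0, 0] == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_empty_pathway_flagged_zero(self, rng):
        gm = make_gm(rng.binomial(2, 0.3, size=(10, 1)))
        weights = pd.DataFrame(
            {
                "variant_id": ["v0"],
                "pathway_id": ["p1"],
                "gene_id": ["G1"],
                "weight": [0.5],
                "p_value": [0.01],
                "flipped": [False],
            }
        )
        with pytest.warns(UserWarning, match="zero weighted"):
            prs = compute_pathway_prs(gm, weights, pathway_ids=["p1", "p2"])
        assert prs.empty_pathways == ("p2",)
        assert (prs.scores["p2"] == 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_weights(self, c):
        gm = make_gm(np.array([[0, 1], [2, 1], [1, 0]]))
        base = pd.DataFrame(
            {
                "variant_id": ["v0", "v1"],
                "pathway_id": ["p", "p"],
                "gene_id": ["G1", "G1"],
                "weight": [0.3, -0.2],
                "p_value": [0.01, 0.02],
                "flipped": [False, False],
            }
        )
        scaled = base.assign(weight=base["weight"] * c)
        s1 = compute_pathway_prs(gm, base).scores
        s2 = compute_pathway_prs(gm, scaled).scores
        assert np.allclose(s2.to_numpy(), c * s1.to_numpy())


class TestPositivity:
    def clinical_for(self, scores, n_controls):
        ids = list(scores.index)
        status = ["control"] * n_controls + ["case"] * (len(ids) - n_controls)
        return pd.DataFrame({"sample_id": ids, "status": status})

    def test_forty_distinct_controls_one_positive(self):
        scores = pd.DataFrame(
            {"p": np.arange(1.0, 41.0)},
            index=pd.Index([f"s{i}" for i in range(40)], name="sample_id"),
        )
        prs = PathwayPRS(scores=scores)
        out = classify_positivity(prs, self.clinical_for(scores, 40))
        # interpolated 97.5th percentile lies between the 39th and 40th
        # order statistics, so exactly the maximum control exceeds it
        assert out.positive["p"].sum() == 1

    def test_score_equal_to_threshold_not_positive(self):
        scores = pd.DataFrame(
            {"p": list(np.arange(1.0, 41.0)) + [0.0]},
            index=pd.Index([f"s{i}" for i in range(41)], name="sample_id"),
        )
        prs = PathwayPRS(scores=scores)
        out = classify_positivity(prs, self.clinical_for(scores, 40))
        case_id = "s40"
        scores.loc[case_id, "p"] = out.thresholds["p"]
        out2 = classify_positivity(PathwayPRS(scores=scores), self.clinical_for(scores, 40))
        assert not out2.positive.loc[case_id, "p"]

    def test_too_few_controls_rejected(self):
        scores = pd.DataFrame(
            {"p": np.arange(10.0)},
            index=pd.Index([f"s{i}" for i in range(10)], name="sample_id"),
        )
        with pytest.raises(ValueError, match="controls"):
            classify_positivity(PathwayPRS(scores=scores), self.clinical_for(scores, 10))

    def test_constant_controls_warn_nobody_positive(self):
        scores = pd.DataFrame(
            {"p": [1.0] * 30 + [5.0, 0.5]},
            index=pd.Index([f"s{i}" for i in range(32)], name="sample_id"),
        )
        with pytest.warns(UserWarning, match="constant"):
            out = classify_positivity(PathwayPRS(scores=scores), self.clinical_for(scores, 30))
        assert out.thresholds["p"] == 1.0
        assert out.positive["p"].sum() == 1  # only the 5.0 case exceeds

    def test_counts_are_row_sums(self, rng):
        scores = pd.DataFrame(
            rng.standard_normal((60, 3)),
            columns=["a", "b", "c"],
            index=pd.Index([f"s{i}" for i in range(60)], name="sample_id"),
        )
        out = classify_positivity(PathwayPRS(scores=scores), self.clinical_for(scores, 40))
        assert (out.n_positive == out.positive.sum(axis=1)).all()

    def test_monotone_rescaling_invariance(self, rng):
        scores = pd.DataFrame(
            rng.standard_normal((50, 2)),
            columns=["a", "b"],
            index=pd.Index([f"s{i}" for i in range(50)], name="sample_id"),
        )
        clin = self.clinical_for(scores, 30)
        out1 = classify_positivity(PathwayPRS(scores=scores), clin)
        out2 = classify_positivity(PathwayPRS(scores=scores * 3.0 + 1.0), clin)
        assert (out1.positive == out2.positive).all().all()
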