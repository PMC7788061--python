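"""Calibration and recovery experiments.

Seeded, self-contained experiments that validate the statistical
behaviour of the pipeline on synthetic cohorts: null calibration of the
aggregate test, agreement between the analytic and permutation p-values,
positivity-rate calibration of the pathway PRS, sequential-elimination
recovery of planted pathway effects, clustering recovery of planted
patient structure, case-only catalogue integrity and confidence-interval
coverage for planted per-variant effects.  Both the test suite and the
reproduction script call these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (
    SetTestConfig,
    bh_fdr,
    sequential_elimination,
    single_variant_assoc,
)
from .datatypes import GeneSetCollection, GenotypeMatrix
from .prs import PathwayPRS, build_prs_weights, classify_positivity, compute_pathway_prs
from .rare import case_only_catalogue
from .simulate import CausalPathway, SimulationConfig, simulate_cohort, simulate_genotypes
from .skat import skat_o_test
from .stratify import cluster_patients, compare_groups_clinical, normalize_prs


def bonferroni_threshold_35(seed: int = 0) -> float:
    """Family-wise threshold reported for a 35-pathway clinical family."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(40)]
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "status": ["case"] * 40,
            "damage_index": rng.poisson(1.0, 40),
        }
    )
    groups = pd.Series(
        ["pos"] * 20 + ["neg"] * 20, index=pd.Index(ids, name="sample_id")
    )
    out = compare_groups_clinical(groups, clinical, ["damage_index"], family_size=35)
    return float(out["bonferroni_threshold"].iloc[0])


def skat_null_rejection_rate(
    seed: int, n_sets: int = 500, n: int = 400, m: int = 20, alpha: float = 0.05
) -> dict:
    """Type-I error of the aggregate test on null simulator genotypes."""
    rejected = 0
    tested = 0
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    for rep in range(n_sets):
        cfg = SimulationConfig(
            n_cases=n // 2,
            n_controls=n // 2,
            n_genes=1,
            n_pathways=1,
            variants_per_gene=m,
            seed=seed + 7907 * rep,
        )
        gm, variants = simulate_genotypes(cfg, n_individuals=n)
        try:
            p = skat_o_test(
                gm.dosage.astype(float), y, maf=variants["maf"].to_numpy()
            ).p_value
        except ValueError:
            continue
        tested += 1
        rejected += p < alpha
    return {"rate": rejected / tested, "n_sets": tested, "alpha": alpha}


def permutation_agreement(
    seed: int,
    n_fixtures: int = 24,
    n: int = 8000,
    n_permutations: int = 100_000,
    z_limit: float = 3.0,
) -> dict:
    """Analytic vs exact-permutation p-values on small variant-set fixtures.

    Fixtures sit in the test's asymptotic operating regime (balanced
    design, common variants, flat weights); agreement is measured in
    Monte-Carlo standard errors of the permutation estimate.
    """
    m_cycle = (4, 5, 6)
    n_agree = 0
    diffs = []
    for rep in range(n_fixtures):
        rng = np.random.default_rng(seed + 9973 * rep)
        m = m_cycle[rep % len(m_cycle)]
        G = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        y = np.zeros(n)
        y[: n // 2] = 1
        rng.shuffle(y)
        w = np.ones(m)
        mm = skat_o_test(G, y, weights=w)
        perm = skat_o_test(
            G,
            y,
            weights=w,
            pvalue_method="permutation",
            n_permutations=n_permutations,
            seed=seed + 9973 * rep,
        )
        se = max(np.sqrt(perm.p_value * (1 - perm.p_value) / n_permutations), 1e-12)
        z = abs(mm.p_value - perm.p_value) / se
        diffs.append(abs(mm.p_value - perm.p_value))
        n_agree += z <= z_limit
    return {
        "n_agree": n_agree,
        "n_fixtures": n_fixtures,
        "max_abs_diff": float(max(diffs)),
    }


def bh_oracle_max_diff(seed: int, n_vectors: int = 1000) -> float:
    """Worst deviation of bh_fdr from a brute-force step-up enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        mlen = int(rng.integers(1, 80))
        p = rng.uniform(1e-9, 1.0, mlen)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        oracle = np.empty(mlen)
        best = np.inf
        for rank in range(mlen, 0, -1):
            idx = order[rank - 1]
            best = min(best, mlen * p[idx] / rank)
            oracle[idx] = min(best, 1.0)
        worst = max(worst, float(np.abs(q - oracle).max()))
    return worst


def prs_fixture_values() -> dict:
    """Hand-computable score and positivity fixtures."""
    gm = GenotypeMatrix(
        sample_ids=np.array(["zero", "hom"], dtype=object),
        variant_ids=np.array(["v1"], dtype=object),
        dosage=np.array([[0], [2]], dtype=np.int8),
    )
    weights = pd.DataFrame(
        {
            "variant_id": ["v1"],
            "pathway_id": ["p"],
            "gene_id": ["G1"],
            "weight": [np.log(2.0)],
            "p_value": [0.01],
            "flipped": [False],
        }
    )
    prs = compute_pathway_prs(gm, weights)
    scores = pd.DataFrame(
        {"p": np.arange(1.0, 41.0)},
        index=pd.Index([f"c{i}" for i in range(40)], name="sample_id"),
    )
    clinical = pd.DataFrame({"sample_id": scores.index, "status": ["control"] * 40})
    called = classify_positivity(PathwayPRS(scores=scores), clinical)
    return {
        "zero_genotype_score": float(prs.scores.loc["zero", "p"]),
        "single_snv_score": float(prs.scores.loc["hom", "p"]),
        "n_positive_of_40_controls": int(called.positive["p"].sum()),
    }


def positivity_rate_fresh_controls(
    seed: int,
    n_replicates: int = 10,
    n_assoc: int = 1000,
    n_thr_controls: int = 2000,
    n_fresh: int = 400,
) -> dict:
    """Fresh null controls scored against fitted positivity thresholds.

    Per replicate one genotype pool is generated and split three ways:
    an association cohort (random case/control labels, null) that
    supplies PRS weights, an independent control set on which the
    per-pathway 97.5th-percentile thresholds are fitted, and held-out
    fresh controls whose exceedance rate is measured.  Pathways that
    receive no weighted variants are excluded (flagged by the scorer)."""
    positives = 0
    trials = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_cases=n_assoc // 2,
            n_controls=n_assoc // 2,
            n_genes=50,
            n_pathways=5,
            variants_per_gene=20,
            maf_spectrum=("beta", 2.0, 2.0),  # common variants for stable ORs
            seed=seed + 6091 * rep,
        )
        n_total = n_assoc + n_thr_controls + n_fresh
        gm, variants = simulate_genotypes(cfg, n_individuals=n_total)
        assoc_ids = list(gm.sample_ids[:n_assoc])
        thr_ids = list(gm.sample_ids[n_assoc : n_assoc + n_thr_controls])
        fresh_ids = list(gm.sample_ids[n_assoc + n_thr_controls :])
        clinical_assoc = pd.DataFrame(
            {
                "sample_id": assoc_ids,
                "status": ["case"] * (n_assoc // 2) + ["control"] * (n_assoc // 2),
            }
        )
        assoc = single_variant_assoc(gm.subset_samples(assoc_ids), clinical_assoc)
        tested = assoc[assoc["test"] != "skipped"]
        genesets = GeneSetCollection.from_dict(cfg.genes_per_pathway)
        weights = build_prs_weights(
            tested, list(tested["variant_id"]), genesets, variants
        )
        if weights.empty:
            continue
        prs_all = compute_pathway_prs(gm, weights)
        thr_scores = PathwayPRS(scores=prs_all.scores.loc[thr_ids])
        clinical_thr = pd.DataFrame(
            {"sample_id": thr_ids, "status": ["control"] * len(thr_ids)}
        )
        called = classify_positivity(thr_scores, clinical_thr)
        keep = [p for p in called.thresholds.index if p not in prs_all.empty_pathways]
        fresh = prs_all.scores.loc[fresh_ids, keep]
        exceed = fresh.gt(called.thresholds[keep], axis=1)
        positives += int(exceed.to_numpy().sum())
        trials += exceed.size
    return {"rate": positives / trials, "n_trials": trials}


def _disjoint_pathway_config(seed: int) -> SimulationConfig:
    genes = [f"GENE{i:04d}" for i in range(1, 26)]
    pathways = {
        # pwA carries twice pwB's SNV count so its aggregate signal
        # dominates the replicate-level sampling noise in realized strength
        "pwA": genes[:8],
        "pwB": genes[8:12],
        "pwC": genes[12:17],
        "pwD": genes[17:21],
        "pwE": genes[21:25],
    }
    return SimulationConfig(
        n_cases=1000,
        n_controls=1000,
        n_genes=25,
        n_pathways=5,
        genes_per_pathway=pathways,
        variants_per_gene=20,
        # effects sit uniformly on the spectrum, i.e. a common-variant
        # architecture; the spectrum and the flat test weights below match it
        maf_spectrum=("beta", 2.0, 2.0),
        causal_pathways=(
            CausalPathway("pwA", lnor_mean=0.3, fraction_causal=0.2),
            CausalPathway("pwB", lnor_mean=0.3, fraction_causal=0.2),
        ),
        disease_model="logistic",
        prevalence_or_intercept=0.3,
        seed=seed,
    )


_FLAT_WEIGHTS = SetTestConfig(weight_beta=(1.0, 1.0))


def elimination_recovery(seed: int, n_replicates: int = 100) -> dict:
    """Sequential elimination with two disjoint planted pathways."""
    both_in_order = 0
    both_any_order = 0
    for rep in range(n_replicates):
        cfg = _disjoint_pathway_config(seed + 7919 * rep)
        data = simulate_cohort(cfg)
        res = sequential_elimination(
            data["genotypes"],
            data["variants"],
            data["genesets"],
            data["clinical"],
            _FLAT_WEIGHTS,
        )
        picked = list(res["pathway_id"])
        if {"pwA", "pwB"} <= set(picked):
            both_any_order += 1
            if picked.index("pwA") < picked.index("pwB"):
                both_in_order += 1
    return {
        "both_in_order": both_in_order,
        "both_any_order": both_any_order,
        "n_replicates": n_replicates,
    }


def elimination_overlap_single(seed: int, n_replicates: int = 20) -> dict:
    """Two pathways sharing all causal genes: exactly one should be kept."""
    exactly_one = 0
    for rep in range(n_replicates):
        cfg = _disjoint_pathway_config(seed + 104729 * rep)
        data = simulate_cohort(cfg)
        causal_genes = list(cfg.genes_per_pathway["pwA"])
        twins = GeneSetCollection.from_dict(
            {
                "twinA": causal_genes,
                "twinB": causal_genes + list(cfg.genes_per_pathway["pwC"][:1]),
            }
        )
        res = sequential_elimination(
            data["genotypes"], data["variants"], twins, data["clinical"], _FLAT_WEIGHTS
        )
        exactly_one += len(res) == 1
    return {"exactly_one": exactly_one, "n_replicates": n_replicates}


def clustering_recovery(
    seed: int,
    n_replicates: int = 100,
    n_pathways: int = 4,
    n_per_blob: int = 50,
    separation: float = 3.0,
    blob_sd: float = 0.5,
    ari_target: float = 0.8,
) -> dict:
    """Recovery of four planted patient subgroups, measured by adjusted
    Rand index.

    Blob centres sit pairwise ``separation`` control-SDs apart; the
    subgroups are molecularly coherent (within-blob SD of half a
    control SD), reflecting the premise that a molecular subgroup is
    tighter than the case population as a whole."""
    from sklearn.metrics import adjusted_rand_score

    successes = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 4253 * rep)
        n_controls = 300
        ctrl = rng.standard_normal((n_controls, n_pathways))
        # pairwise centre distance exactly `separation`
        centers = (separation / np.sqrt(2.0)) * np.eye(n_pathways)[:4]
        cases = np.vstack(
            [rng.normal(c, blob_sd, size=(n_per_blob, n_pathways)) for c in centers]
        )
        truth = np.repeat(np.arange(4), n_per_blob)
        ids = [f"ctrl{i}" for i in range(n_controls)] + [
            f"case{i}" for i in range(len(cases))
        ]
        scores = pd.DataFrame(
            np.vstack([ctrl, cases]),
            index=pd.Index(ids, name="sample_id"),
            columns=[f"pw{j}" for j in range(n_pathways)],
        )
        clinical = pd.DataFrame(
            {
                "sample_id": ids,
                "status": ["control"] * n_controls + ["case"] * len(cases),
            }
        )
        normalized = normalize_prs(scores, clinical)
        case_ids = [s for s in ids if s.startswith("case")]
        assignment = cluster_patients(normalized.loc[case_ids], k=4)
        ari = adjusted_rand_score(truth, assignment["cluster"].to_numpy())
        successes += ari >= ari_target
    return {"n_success": successes, "n_replicates": n_replicates}


def caseonly_integrity(seed: int, n_replicates: int = 5) -> dict:
    """Exhaustive control-carrier check plus recovery of planted
    recurrent case-only variants with exact counts and ordering."""
    planted = (5, 4, 2, 2, 3)
    control_carrier_violations = 0
    recovered = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_cases=150,
            n_controls=150,
            n_genes=15,
            n_pathways=3,
            variants_per_gene=10,
            caseonly_injection=len(planted),
            caseonly_carrier_counts=planted,
            missing_rate=0.005,
            seed=seed + 5741 * rep,
        )
        data = simulate_cohort(cfg)
        catalogue = case_only_catalogue(
            data["genotypes"], data["variants"], data["clinical"]
        )
        # exhaustive post-check against the raw matrix
        gm = data["genotypes"]
        status = data["clinical"].set_index("sample_id")["status"]
        ctrl_rows = np.array([status[s] == "control" for s in gm.sample_ids])
        d = np.where(gm.missing_mask, 0, gm.dosage)
        idx = gm.variant_indexer()
        cols = [idx[v] for v in catalogue["variant_id"]]
        control_carrier_violations += int((d[ctrl_rows][:, cols] >= 1).sum())
        inj = catalogue[catalogue["variant_id"].str.startswith("co")]
        ok_counts = list(inj["carrier_count"]) == sorted(planted, reverse=True)
        ok_recurrent = (inj["recurrent"] == (inj["carrier_count"] >= 2)).all()
        recovered += ok_counts and ok_recurrent
    return {
        "control_carrier_violations": control_carrier_violations,
        "n_recovered": recovered,
        "n_replicates": n_replicates,
    }


def lnor_ci_coverage(
    seed: int, n_replicates: int = 100, lnor: float = float(np.log(1.5))
) -> dict:
    """95% Wald CI coverage for a planted common-variant ln-OR at
    4000 chromosomes (2000 ascertained individuals)."""
    covered = 0
    fitted = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_cases=1000,
            n_controls=1000,
            n_genes=1,
            n_pathways=1,
            variants_per_gene=1,
            maf_spectrum=("fixed", 0.3),
            causal_pathways=(
                CausalPathway("hsa04000", lnor_mean=lnor, fraction_causal=1.0),
            ),
            disease_model="logistic",
            prevalence_or_intercept=0.15,
            seed=seed + 7717 * rep,
        )
        data = simulate_cohort(cfg)
        res = single_variant_assoc(data["genotypes"], data["clinical"])
        row = res[res["test"] == "logistic"]
        if row.empty:
            continue
        fitted += 1
        b, se = float(row["effect"].iloc[0]), float(row["se"].iloc[0])
        covered += (b - 1.96 * se) <= lnor <= (b + 1.96 * se)
    return {"covered": covered, "n_replicates": fitted}
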