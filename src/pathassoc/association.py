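"""Single-variant and aggregate case-control association testing.

Covers per-variant logistic/allelic tests, Benjamini-Hochberg FDR control,
gene- and pathway-level kernel association tests with MAF strata, the
sequential-elimination search for independent pathway signals, and
inverse-variance fixed-effect meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GeneSetCollection,
    GenotypeMatrix,
    case_control_indicator,
    validate_variant_table,
)
from .skat import DEFAULT_RHO_GRID, skat_o_test

logger = logging.getLogger(__name__)

#: Suggestive single-variant significance threshold surfaced as a flag.
SUGGESTIVE_P = 1e-4

#: MAF strata: common is strictly > 0.05, rare strictly < 0.01.
MAF_COMMON = 0.05
MAF_RARE = 0.01


@dataclass
class SetTestConfig:
    """Configuration for aggregate (gene / pathway / gene-set) tests."""

    maf_stratum: str = "all"  # all | common | rare
    weight_beta: tuple = (1.0, 25.0)
    rho_grid: tuple = DEFAULT_RHO_GRID
    pvalue_method: str = "moment_matching"
    n_permutations: int = 10_000
    min_variants: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.maf_stratum not in ("all", "common", "rare"):
            raise ValueError(f"unknown maf_stratum {self.maf_stratum!r}")
        grid = tuple(float(r) for r in self.rho_grid)
        if 0.0 not in grid or 1.0 not in grid:
            raise ValueError("rho_grid must contain both 0 and 1")
        self.rho_grid = grid
        if self.min_variants < 1:
            raise ValueError("min_variants must be >= 1")


def maf_stratum_mask(maf: np.ndarray, stratum: str) -> np.ndarray:
    maf = np.asarray(maf, dtype=float)
    if stratum == "all":
        return np.ones(maf.shape, dtype=bool)
    if stratum == "common":
        return maf > MAF_COMMON
    if stratum == "rare":
        return maf < MAF_RARE
    raise ValueError(f"unknown maf_stratum {stratum!r}")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} ( m * p_(j) / j )`` capped at 1, returned in
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Single-variant tests
# ---------------------------------------------------------------------------


def _allelic_test(d_case: np.ndarray, d_ctrl: np.ndarray) -> tuple:
    """2x2 allelic test with Haldane-Anscombe correction on zero cells."""
    a = float(d_case.sum())  # minor alleles, cases
    b = 2.0 * len(d_case) - a
    c = float(d_ctrl.sum())
    d = 2.0 * len(d_ctrl) - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ln_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * stats.norm.sf(abs(ln_or) / se)
    return ln_or, se, max(p, np.finfo(float).tiny)


def _expected_cells_ok(d_case, d_ctrl) -> bool:
    a = d_case.sum()
    c = d_ctrl.sum()
    n1, n0 = 2 * len(d_case), 2 * len(d_ctrl)
    tot = n1 + n0
    p_minor = (a + c) / tot
    expected = np.array(
        [n1 * p_minor, n1 * (1 - p_minor), n0 * p_minor, n0 * (1 - p_minor)]
    )
    return bool((expected >= 5).all())


def _logistic_fit(dosage: np.ndarray, y: np.ndarray, covariates) -> tuple | None:
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(y)), dosage])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    beta = res.params[1]
    se = res.bse[1]
    if not (np.isfinite(beta) and np.isfinite(se)) or se <= 0 or se > 50:
        return None
    p = res.pvalues[1]
    return float(beta), float(se), float(max(p, np.finfo(float).tiny))


def single_variant_assoc(
    genotypes: GenotypeMatrix,
    clinical: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant association of case status with minor-allele dosage.

    A logistic (Wald) model is used when the 2x2 allelic table has all
    expected cells >= 5 and the fit converges; otherwise the allelic test
    with Haldane-Anscombe correction.  Monomorphic or all-missing variants
    are skipped with the reason recorded.  Returns one row per variant
    with ln-OR (``effect``), ``se``, ``p_value``, BH ``fdr_q`` over the
    tested variants and a ``suggestive`` flag at p < 1e-4.
    """
    y_all = case_control_indicator(clinical, genotypes.sample_ids)
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        obs = ~genotypes.missing_mask[:, j]
        d = genotypes.dosage[obs, j].astype(float)
        y = y_all[obs]
        if d.size == 0:
            rows.append((vid, np.nan, np.nan, np.nan, "skipped", "all-missing"))
            continue
        if d.min() == d.max():
            rows.append((vid, np.nan, np.nan, np.nan, "skipped", "monomorphic"))
            continue
        if y.min() == y.max():
            raise ValueError("status column is constant")
        d_case, d_ctrl = d[y == 1], d[y == 0]
        fit = None
        if _expected_cells_ok(d_case, d_ctrl):
            fit = _logistic_fit(d, y, np.asarray(covariates)[obs] if covariates is not None else None)
            test = "logistic"
        if fit is None:
            fit = _allelic_test(d_case, d_ctrl)
            test = "allelic"
        rows.append((vid, *fit, test, ""))
    out = pd.DataFrame(
        rows, columns=["variant_id", "effect", "se", "p_value", "test", "note"]
    )
    tested = out["test"] != "skipped"
    out["fdr_q"] = np.nan
    if tested.any():
        out.loc[tested, "fdr_q"] = bh_fdr(out.loc[tested, "p_value"].to_numpy())
    out["suggestive"] = out["p_value"] < SUGGESTIVE_P
    return out


# ---------------------------------------------------------------------------
# Aggregate tests
# ---------------------------------------------------------------------------


def _run_set_test(
    genotypes: GenotypeMatrix,
    variant_ids: list,
    maf: np.ndarray,
    y: np.ndarray,
    config: SetTestConfig,
    covariates=None,
):
    sub = genotypes.subset_variants(variant_ids)
    return skat_o_test(
        sub.dosage,
        y,
        maf=maf,
        covariates=covariates,
        weight_beta=config.weight_beta,
        rho_grid=config.rho_grid,
        pvalue_method=config.pvalue_method,
        n_permutations=config.n_permutations,
        seed=config.seed,
        missing_mask=sub.missing_mask,
    )


def set_assoc(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    genesets: GeneSetCollection,
    clinical: pd.DataFrame,
    config: SetTestConfig | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kernel association test per gene set, with BH FDR across the family.

    Variants of a set are the union over its member genes, filtered by the
    configured MAF stratum.  Sets without testable variants are reported
    with a reason and excluded from the FDR family.
    """
    if len(genesets) == 0:
        raise ValueError("empty gene set collection")
    config = config or SetTestConfig()
    variants = validate_variant_table(variants)
    y = case_control_indicator(clinical, genotypes.sample_ids)
    vmask = maf_stratum_mask(variants["maf"].to_numpy(), config.maf_stratum)
    vt = variants.loc[vmask & variants["gene_id"].notna()]
    by_gene = vt.groupby("gene_id")["variant_id"]
    gene_to_variants = {g: list(v) for g, v in by_gene}
    maf_by_id = variants.set_index("variant_id")["maf"]

    rows = []
    for gs in genesets:
        genes_in_test = [g for g in gs.genes if g in gene_to_variants]
        vids = [v for g in genes_in_test for v in gene_to_variants[g]]
        base = {
            "set_id": gs.set_id,
            "display_name": gs.display_name,
            "level": "set",
            "n_genes": len(gs.genes),
            "genes_in_test": len(genes_in_test),
            "n_variants_tested": len(vids),
        }
        if not vids:
            rows.append({**base, "p_value": np.nan, "note": "genes in test = 0"})
            continue
        if len(vids) < config.min_variants:
            rows.append({**base, "p_value": np.nan, "note": "fewer than min_variants"})
            continue
        try:
            res = _run_set_test(
                genotypes, vids, maf_by_id.loc[vids].to_numpy(), y, config, covariates
            )
        except ValueError as exc:
            rows.append({**base, "p_value": np.nan, "note": str(exc)})
            continue
        rows.append(
            {**base, "p_value": res.p_value, "note": "", "rho_min": res.rho_min}
        )
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["fdr_q"] = np.nan
    if tested.any():
        out.loc[tested, "fdr_q"] = bh_fdr(out.loc[tested, "p_value"].to_numpy())
    return out


def gene_assoc(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SetTestConfig | None = None,
    genes: list | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-level kernel tests: each gene is a singleton set; BH across genes.

    Also flags genes passing the Bonferroni threshold 0.05 / n_genes_tested.
    """
    variants = validate_variant_table(variants)
    if genes is None:
        genes = [g for g in pd.unique(variants["gene_id"].dropna())]
    else:
        genes = list(genes)
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate gene ids")
    collection = GeneSetCollection.from_dict(
        {g: (g,) for g in genes}, provenance="gene"
    )
    out = set_assoc(genotypes, variants, collection, clinical, config, covariates)
    out = out.rename(columns={"set_id": "gene_id"}).drop(columns=["display_name"])
    out["level"] = "gene"
    tested = out["p_value"].notna()
    n_tested = int(tested.sum())
    out["bonferroni_threshold"] = 0.05 / n_tested if n_tested else np.nan
    out["bonferroni_sig"] = out["p_value"] < out["bonferroni_threshold"]
    return out


def sequential_elimination(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    genesets: GeneSetCollection,
    clinical: pd.DataFrame,
    config: SetTestConfig | None = None,
    fdr_threshold: float = 0.05,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Iterative search for independent pathway associations.

    Each round tests the remaining pathways on genes not yet eliminated;
    if the best pathway reaches FDR < ``fdr_threshold`` its member genes
    are removed from every remaining pathway and the search continues,
    otherwise it stops.  Returns one row per selected pathway in selection
    order with the FDR at selection.
    """
    if len(genesets) == 0:
        raise ValueError("empty gene set collection")
    current = genesets
    eliminated: set = set()
    selected = []
    for round_no in range(1, len(genesets.ids) + 1):
        if len(current) == 0:
            break
        res = set_assoc(genotypes, variants, current, clinical, config, covariates)
        res = res[res["p_value"].notna()]
        if res.empty:
            break
        top = res.sort_values(["fdr_q", "p_value"], kind="stable").iloc[0]
        if not (top["fdr_q"] < fdr_threshold):
            break
        pathway = top["set_id"]
        selected.append(
            {
                "round": round_no,
                "pathway_id": pathway,
                "fdr_at_selection": float(top["fdr_q"]),
                "p_at_selection": float(top["p_value"]),
            }
        )
        genes = set(current[pathway].genes)
        eliminated |= genes
        current = current.drop_genes(genes)
        logger.info(
            "elimination round %d: selected %s (FDR=%.3g), %d genes removed",
            round_no,
            pathway,
            top["fdr_q"],
            len(genes),
        )
    return pd.DataFrame(
        selected, columns=["round", "pathway_id", "fdr_at_selection", "p_at_selection"]
    )


def set_assoc_by_stratum(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    genesets: GeneSetCollection,
    clinical: pd.DataFrame,
    config: SetTestConfig | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-set tests across the three MAF strata in one table.

    One row per set with SNV counts and BH-adjusted FDR per stratum
    (``all`` imposes no filter, ``common`` is MAF > 0.05 strictly,
    ``rare`` MAF < 0.01 strictly); the FDR family is the sets tested
    within each stratum.
    """
    import dataclasses as _dc

    config = config or SetTestConfig()
    merged = None
    for stratum in ("all", "common", "rare"):
        res = set_assoc(
            genotypes,
            variants,
            genesets,
            clinical,
            _dc.replace(config, maf_stratum=stratum),
            covariates,
        )
        cols = res[["set_id", "n_variants_tested", "p_value", "fdr_q"]].rename(
            columns={
                "n_variants_tested": f"n_snvs_{stratum}",
                "p_value": f"p_{stratum}",
                "fdr_q": f"fdr_{stratum}",
            }
        )
        if merged is None:
            merged = res[["set_id", "display_name", "n_genes", "genes_in_test"]].merge(
                cols, on="set_id"
            )
        else:
            merged = merged.merge(cols, on="set_id")
    return merged


# ---------------------------------------------------------------------------
# Fixed-effect meta-analysis
# ---------------------------------------------------------------------------


def fixed_effect_meta(ln_ors, ses) -> dict:
    """Inverse-variance-weighted fixed-effect combination of ln-ORs."""
    b = np.asarray(ln_ors, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies supplied")
    if b.shape != s.shape:
        raise ValueError("effect and SE vectors differ in length")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("standard errors must be finite and positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = beta / se
    return {
        "ln_or": beta,
        "se": se,
        "p_value": float(2.0 * stats.norm.sf(abs(z))),
        "n_studies": int(b.size),
    }
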