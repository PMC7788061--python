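"""Pathway polygenic risk scores and positivity classification.

For each pathway, the PRS of an individual is the sum over the pathway's
nominally significant, LD-independent SNVs of ``ln(OR) x minor-allele
dosage``.  An individual is pathway-positive when their score strictly
exceeds the 97.5th percentile (linear interpolation) of the control score
distribution for that pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSetCollection,
    GenotypeMatrix,
    validate_clinical_table,
    validate_variant_table,
    warn,
)

logger = logging.getLogger(__name__)


@dataclass
class PathwayPRS:
    """Sample x pathway score matrix plus positivity calls.

    ``scores`` is a DataFrame indexed by sample id with one column per
    pathway.  After :func:`classify_positivity`, ``thresholds`` holds the
    per-pathway control percentile cut-offs, ``positive`` the boolean
    calls (strictly greater than the threshold) and ``n_positive`` the
    per-sample count of positive pathways.
    """

    scores: pd.DataFrame
    empty_pathways: tuple = ()
    thresholds: pd.Series | None = None
    positive: pd.DataFrame | None = None
    n_positive: pd.Series | None = None
    percentile: float | None = None


def ld_prune(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    p_values: pd.Series,
    r2_threshold: float = 0.2,
    window_kb: float = 500.0,
) -> list:
    """Greedy LD pruning by ascending p-value.

    Variants are visited from the smallest p; a variant is kept iff its
    dosage r^2 with every already-kept variant on the same chromosome
    within ``window_kb`` is below ``r2_threshold``.  Returns kept ids in
    visit order.  Missing genotypes are mean imputed before correlation.
    """
    if len(p_values) == 0:
        return []
    variants = validate_variant_table(variants)
    vinfo = variants.set_index("variant_id")
    missing = [v for v in p_values.index if v not in vinfo.index]
    if missing:
        raise ValueError(f"p-values for unknown variants: {missing[:5]}")
    sub = genotypes.subset_variants(list(p_values.index))
    X = sub.imputed()
    X = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt((X**2).sum(axis=0))
    order = np.argsort(p_values.to_numpy(), kind="stable")
    ids = p_values.index.to_numpy()
    chrom = vinfo.loc[ids, "chrom"].astype(str).to_numpy()
    pos = vinfo.loc[ids, "pos"].to_numpy()
    window = window_kb * 1000.0
    kept: list = []
    for j in order:
        if norms[j] == 0:
            continue  # monomorphic: never informative
        ok = True
        for k in kept:
            if chrom[k] != chrom[j] or abs(pos[k] - pos[j]) > window:
                continue
            r = float(X[:, j] @ X[:, k]) / (norms[j] * norms[k])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return [ids[j] for j in kept]


def build_prs_weights(
    assoc: pd.DataFrame,
    pruned_ids,
    genesets: GeneSetCollection,
    variants: pd.DataFrame,
    alpha: float = 0.05,
    orientation: str = "signed",
) -> pd.DataFrame:
    """Long-form weight table (variant, pathway, weight).

    Weights are the ln(OR) of the minor allele for retained variants with
    p < ``alpha``, mapped to every pathway containing the variant's gene.
    ``orientation="signed"`` keeps protective (negative) weights as the
    formula states; ``"risk"`` orients each weight to the risk allele
    (positive weight, dosage flipped at scoring time).
    """
    if orientation not in ("signed", "risk"):
        raise ValueError(f"unknown orientation {orientation!r}")
    variants = validate_variant_table(variants)
    gene_of = variants.set_index("variant_id")["gene_id"]
    keep = assoc[
        assoc["variant_id"].isin(set(pruned_ids))
        & (assoc["p_value"] < alpha)
        & np.isfinite(assoc["effect"])
    ]
    pathways_of_gene: dict = {}
    for gs in genesets:
        for g in gs.genes:
            pathways_of_gene.setdefault(g, []).append(gs.set_id)
    rows = []
    n_unmapped = 0
    for _, r in keep.iterrows():
        gene = gene_of.get(r["variant_id"])
        if gene is None or pd.isna(gene):
            n_unmapped += 1
            continue
        weight = float(r["effect"])
        flipped = False
        if orientation == "risk" and weight < 0:
            weight, flipped = -weight, True
        for pid in pathways_of_gene.get(gene, []):
            rows.append(
                {
                    "variant_id": r["variant_id"],
                    "pathway_id": pid,
                    "gene_id": gene,
                    "weight": weight,
                    "p_value": float(r["p_value"]),
                    "flipped": flipped,
                }
            )
    if n_unmapped:
        logger.info("%d weighted variants mapped to no gene; excluded", n_unmapped)
    return pd.DataFrame(
        rows, columns=["variant_id", "pathway_id", "gene_id", "weight", "p_value", "flipped"]
    )


def compute_pathway_prs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    pathway_ids=None,
) -> PathwayPRS:
    """Score every sample on every pathway: sum of weight x dosage.

    Missing dosages are replaced by the cohort mean dosage of the variant.
    Pathways with no weighted variants get an all-zero column and are
    flagged in ``empty_pathways``.
    """
    if pathway_ids is None:
        pathway_ids = list(pd.unique(weights["pathway_id"]))
    if weights.empty and not pathway_ids:
        raise ValueError("no PRS weights supplied")
    used = [v for v in pd.unique(weights["variant_id"])]
    index = genotypes.variant_indexer()
    unknown = [v for v in used if v not in index]
    if unknown:
        raise ValueError(f"weights refer to unknown variants: {unknown[:5]}")
    D = genotypes.subset_variants(used).imputed() if used else np.zeros((genotypes.n_samples, 0))
    col_of = {v: i for i, v in enumerate(used)}
    scores = {}
    empty = []
    for pid in pathway_ids:
        wp = weights[weights["pathway_id"] == pid]
        if wp.empty:
            scores[pid] = np.zeros(genotypes.n_samples)
            empty.append(pid)
            continue
        cols = [col_of[v] for v in wp["variant_id"]]
        w = wp["weight"].to_numpy(dtype=float)
        d = D[:, cols]
        if "flipped" in wp.columns and wp["flipped"].any():
            d = np.where(wp["flipped"].to_numpy()[None, :], 2.0 - d, d)
        scores[pid] = d @ w
    if empty:
        warn(f"pathways with zero weighted variants scored as 0: {empty}")
    frame = pd.DataFrame(scores, index=pd.Index(genotypes.sample_ids, name="sample_id"))
    return PathwayPRS(scores=frame, empty_pathways=tuple(empty))


def classify_positivity(
    prs: PathwayPRS,
    clinical: pd.DataFrame,
    percentile: float = 97.5,
    min_controls: int = 20,
) -> PathwayPRS:
    """Call pathway positivity against the control score distribution.

    The threshold per pathway is the linear-interpolation ``percentile``
    of control scores; positivity requires a strictly greater score.
    """
    clinical = validate_clinical_table(clinical)
    status = clinical.set_index("sample_id")["status"].reindex(prs.scores.index)
    if status.isna().any():
        missing = list(prs.scores.index[status.isna()][:5])
        raise ValueError(f"scored samples absent from clinical table: {missing}")
    controls = prs.scores.loc[status == "control"]
    if len(controls) < min_controls:
        raise ValueError(
            f"need >= {min_controls} controls for a stable percentile, got {len(controls)}"
        )
    thresholds = controls.quantile(percentile / 100.0, interpolation="linear")
    constant = controls.nunique() <= 1
    if constant.any():
        warn(f"constant control scores for {list(constant[constant].index)}; nobody positive")
    positive = prs.scores.gt(thresholds, axis=1)
    return replace(
        prs,
        thresholds=thresholds,
        positive=positive,
        n_positive=positive.sum(axis=1),
        percentile=percentile,
    )
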