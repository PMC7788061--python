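"""Rare-variant screens: per-individual coding burden, case-only variant
cataloguing with external control-panel subtraction, and the
homozygous-rare screen over a monogenic gene set."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    NON_SYNONYMOUS,
    GenotypeMatrix,
    case_control_indicator,
    check_consequences,
    validate_variant_table,
)

logger = logging.getLogger(__name__)


def _consequence_mask(variants: pd.DataFrame, consequence_class: str) -> np.ndarray:
    check_consequences(variants["consequence"])
    if consequence_class == "non-synonymous":
        allowed = NON_SYNONYMOUS
    elif consequence_class == "any":
        return np.ones(len(variants), dtype=bool)
    else:
        allowed = {consequence_class}
    return variants["consequence"].isin(allowed).to_numpy()


def per_individual_burden(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    maf_lt: float = 0.01,
    consequence_class: str = "non-synonymous",
    count_alleles: bool = False,
) -> pd.Series:
    """Number of qualifying variants carried by each sample.

    Qualifying: MAF < ``maf_lt``, consequence in the protein-altering
    class, dosage >= 1 (or the allele count itself with
    ``count_alleles=True``).  Missing genotypes contribute 0.
    """
    variants = validate_variant_table(variants)
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)]
    mask = (v["maf"].to_numpy() < maf_lt) & _consequence_mask(
        v.reset_index(), consequence_class
    )
    d = np.where(genotypes.missing_mask, 0, genotypes.dosage)[:, mask]
    counts = d.sum(axis=1) if count_alleles else (d >= 1).sum(axis=1)
    return pd.Series(counts, index=genotypes.sample_ids, name="rare_burden")


def case_only_catalogue(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    clinical: pd.DataFrame,
    external_panels: list | None = None,
    consequence_class: str = "non-synonymous",
) -> pd.DataFrame:
    """Catalogue of variants carried only by cases.

    A variant qualifies when it has >= 1 case carrier, zero non-missing
    control carriers in the study, and is absent from every supplied
    external panel (presence flag columns).  Restricted to the
    protein-altering class; sorted by descending case carrier count, then
    chromosome and position.  The ``recurrent`` column marks carrier
    count >= 2.  Control genotype missingness per variant is reported.
    """
    variants = validate_variant_table(variants)
    if external_panels is None:
        external_panels = [c for c in variants.columns if c.startswith("panel_")]
    if not external_panels:
        logger.warning("no external panels supplied: in-study-only subtraction")
    y = case_control_indicator(clinical, genotypes.sample_ids)
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)].reset_index()
    d = np.where(genotypes.missing_mask, 0, genotypes.dosage)
    case_carriers = (d[y == 1] >= 1).sum(axis=0)
    ctrl_carriers = (d[y == 0] >= 1).sum(axis=0)
    ctrl_missing_rate = genotypes.missing_mask[y == 0].mean(axis=0)
    panel_present = np.zeros(len(v), dtype=bool)
    for p in external_panels:
        if p not in v.columns:
            raise ValueError(f"panel column {p!r} missing from variant table")
        panel_present |= v[p].to_numpy(dtype=bool)
    qualifies = (
        (case_carriers >= 1)
        & (ctrl_carriers == 0)
        & ~panel_present
        & _consequence_mask(v, consequence_class)
    )
    out = v.loc[
        qualifies,
        ["variant_id", "chrom", "pos", "ref", "alt", "gene_id", "consequence", "sift_label"],
    ].copy()
    out["carrier_count"] = case_carriers[qualifies]
    out["control_missing_rate"] = ctrl_missing_rate[qualifies]
    out["recurrent"] = out["carrier_count"] >= 2
    out = out.sort_values(
        ["carrier_count", "chrom", "pos"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    # hard post-condition: no catalogued variant has a control carrier
    check = (d[y == 0][:, qualifies] >= 1).sum()
    if check:
        raise AssertionError("case-only catalogue contains control carriers")
    return out


def homozygous_rare_screen(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    gene_set,
    clinical: pd.DataFrame | None = None,
    maf_lt: float = 0.01,
) -> pd.DataFrame:
    """All (case sample, variant) pairs homozygous for a rare
    non-synonymous allele in the given genes; empty output is valid."""
    genes = set(getattr(gene_set, "genes", gene_set))
    if not genes:
        raise ValueError("empty gene set")
    variants = validate_variant_table(variants)
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)].reset_index()
    mask = (
        (v["maf"].to_numpy() < maf_lt)
        & _consequence_mask(v, "non-synonymous")
        & v["gene_id"].isin(genes).to_numpy()
    )
    d = np.where(genotypes.missing_mask, 0, genotypes.dosage)
    if clinical is not None:
        y = case_control_indicator(clinical, genotypes.sample_ids)
        sample_mask = y == 1
    else:
        sample_mask = np.ones(genotypes.n_samples, dtype=bool)
    rows, cols = np.nonzero((d[:, mask] == 2) & sample_mask[:, None])
    vids = v.loc[mask, "variant_id"].to_numpy()
    gids = v.loc[mask, "gene_id"].to_numpy()
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids[rows],
            "variant_id": vids[cols],
            "gene_id": gids[cols],
        }
    )
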