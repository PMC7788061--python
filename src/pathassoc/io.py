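"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (GT only) via cyvcf2, GMT gene sets, TSV variant/clinical tables,
BED-like gene regions and a plain-matrix TSV alternative to VCF.
Coordinates follow each format's native convention: VCF positions are
1-based inclusive, gene regions 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    validate_clinical_table,
    validate_variant_table,
    warn,
)

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotypes(path, sample_subset=None) -> tuple:
    """Read GT dosages from a VCF; returns (GenotypeMatrix, VariantTable).

    Dosage counts copies of the minor allele, determined from the combined
    cohort allele frequency (ties broken lexicographically by allele
    string).  Multi-allelic records are split into one bi-allelic variant
    per ALT.  Genotypes with any missing allele set the missing mask.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_subset is not None:
        subset = list(sample_subset)
        missing = [s for s in subset if s not in samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing[:5]}")
        keep_idx = [samples.index(s) for s in subset]
        samples = subset
    else:
        keep_idx = list(range(len(samples)))

    dosage_cols = []
    mask_cols = []
    meta = []
    seen = set()
    for record in vcf:
        gts = record.genotypes  # [a1, a2, phased] per sample
        alleles = np.array(
            [[g[0], g[1]] for g in gts], dtype=np.int16
        )[keep_idx]
        missing = (alleles < 0).any(axis=1)
        for k, alt in enumerate(record.ALT):
            alt_count = (alleles == k + 1).sum(axis=1).astype(np.int8)
            alt_count[missing] = 0
            n_obs = int((~missing).sum())
            if n_obs == 0:
                alt_freq = 0.0
            else:
                alt_freq = float(alt_count[~missing].sum()) / (2.0 * n_obs)
            ref = record.REF
            if alt_freq > 0.5 or (alt_freq == 0.5 and ref < alt):
                minor, maf = ref, 1.0 - alt_freq
                dos = np.where(missing, 0, 2 - alt_count).astype(np.int8)
            else:
                minor, maf = alt, alt_freq
                dos = alt_count
            vid = record.ID if record.ID not in (None, ".") else None
            if vid is None or len(record.ALT) > 1:
                vid = f"{record.CHROM}:{record.POS}:{ref}:{alt}"
            if vid in seen:
                raise ValueError(f"duplicated variant id after splitting: {vid!r}")
            seen.add(vid)
            dosage_cols.append(dos)
            mask_cols.append(missing.copy())
            meta.append((vid, str(record.CHROM), record.POS, ref, alt, minor, maf))
    if not meta:
        raise ValueError(f"no variants parsed from {path}")
    gm = GenotypeMatrix(
        sample_ids=np.asarray(samples, dtype=object),
        variant_ids=np.asarray([m[0] for m in meta], dtype=object),
        dosage=np.column_stack(dosage_cols),
        missing_mask=np.column_stack(mask_cols),
    )
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt", "minor_allele", "maf"]
    )
    return gm, validate_variant_table(variants)


def write_vcf(path, genotypes: GenotypeMatrix, variants: pd.DataFrame) -> None:
    """Minimal VCF 4.2 with GT only, unphased.  GT counts the ALT allele,
    so minor-oriented dosages are flipped back where minor == REF."""
    variants = validate_variant_table(variants)
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)]
    # written in matrix column order so that a round-trip through the
    # reader reproduces the object exactly
    order = range(len(v))
    gt_codes = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_ids))
            + "\n"
        )
        for j in order:
            row = v.iloc[j]
            dos = genotypes.dosage[:, j].astype(int)
            if row["minor_allele"] == row["ref"]:
                dos = 2 - dos
            gts = gt_codes[dos]
            gts = np.where(genotypes.missing_mask[:, j], "./.", gts)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{v.index[j]}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``; duplicate members are dropped
    with a warning."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_id, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warn(f"{path}:{lineno}: duplicate members in {set_id!r} deduplicated")
            provenance = "kegg_pathway" if set_id.startswith("hsa") else "literature_set"
            sets.append(
                GeneSet(
                    set_id=set_id,
                    display_name=description or set_id,
                    genes=tuple(unique),
                    provenance=provenance,
                )
            )
    return GeneSetCollection(sets)


def write_gmt(path, genesets: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.set_id, gs.display_name, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Clinical and annotation tables
# ---------------------------------------------------------------------------


def read_clinical_table(path) -> pd.DataFrame:
    """TSV with header; requires sample_id and status columns (case/control,
    case-insensitive), NA-tolerant damage index, boolean-ish flags; unknown
    columns are carried through untouched."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df = validate_clinical_table(df)
    if "damage_index" in df.columns:
        df["damage_index"] = pd.to_numeric(df["damage_index"], errors="coerce").astype(
            "Int64"
        )
    for col in df.columns:
        if df[col].dtype == object and col not in ("sample_id", "status"):
            low = df[col].astype(str).str.lower()
            if set(low.dropna()) <= {"true", "false", "nan"}:
                df[col] = low.map({"true": True, "false": False})
    return df


def read_variant_annotation(path) -> pd.DataFrame:
    """Variant annotation TSV as written by the fixture bundle."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    return validate_variant_table(df)


def read_gene_regions(path) -> pd.DataFrame:
    """BED-like gene regions: chrom, start (0-based), end (half-open), gene_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError("invalid gene regions (need 0 <= start < end)")
    return df


def assign_genes(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Annotate variants with gene_id by interval overlap.

    VCF positions are 1-based, regions 0-based half-open, so a variant is
    inside a region when ``start < pos <= end``.  Variants outside every
    region keep gene_id = NA (retained, excluded from gene/set tests).
    """
    variants = variants.copy()
    gene = pd.Series(pd.NA, index=variants.index, dtype=object)
    for chrom, group in variants.groupby(variants["chrom"].astype(str)):
        regs = regions[regions["chrom"].astype(str) == chrom]
        for _, r in regs.iterrows():
            inside = (group["pos"] > r["start"]) & (group["pos"] <= r["end"])
            gene.loc[group.index[inside]] = r["gene_id"]
    variants["gene_id"] = gene
    return variants


# ---------------------------------------------------------------------------
# Plain-matrix TSV alternative to VCF
# ---------------------------------------------------------------------------


def write_genotype_tsv(path, genotypes: GenotypeMatrix) -> None:
    """Samples x variants dosage matrix as TSV; missing entries as NA."""
    d = genotypes.dosage.astype(object)
    d[genotypes.missing_mask] = "NA"
    pd.DataFrame(d, index=genotypes.sample_ids, columns=genotypes.variant_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    mask = df.isna().to_numpy()
    dosage = df.fillna(0).to_numpy().astype(np.int8)
    return GenotypeMatrix(
        sample_ids=df.index.to_numpy(dtype=object),
        variant_ids=df.columns.to_numpy(dtype=object),
        dosage=dosage,
        missing_mask=mask,
    )
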