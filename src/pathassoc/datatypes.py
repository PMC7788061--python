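"""Canonical in-memory containers for the pipeline.

Genotypes are held as a dense individuals x variants minor-allele dosage
matrix with an explicit missingness mask.  Variant annotation, clinical data
and association results are plain :class:`pandas.DataFrame` objects with
documented schemas (validated by the helpers below), which keeps them easy
to slice, merge and write as TSV.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Controlled consequence vocabulary.
CONSEQUENCE_VOCAB = frozenset(
    {
        "missense",
        "stop-gained",
        "stop-lost",
        "start-lost",
        "frameshift",
        "splice-region",
        "synonymous",
        "non-coding",
    }
)

#: Protein-altering consequence class used for rare-variant screens.
NON_SYNONYMOUS = frozenset(
    {"missense", "stop-gained", "stop-lost", "start-lost", "frameshift", "splice-region"}
)

#: Columns every variant table must carry.  ``maf`` is the minor allele
#: frequency recomputed over non-missing calls of the combined sample.
VARIANT_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "minor_allele",
    "maf",
)


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix.

    Parameters
    ----------
    sample_ids, variant_ids
        Ordered, unique identifiers for rows and columns.
    dosage
        ``(n_samples, n_variants)`` array with values in ``{0, 1, 2}``
        counting copies of the minor allele.  Entries under the missing
        mask are arbitrary (conventionally 0) and ignored by all statistics.
    missing_mask
        Boolean array of the same shape; ``True`` marks a missing call.
    """

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosage = np.asarray(self.dosage)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.dosage.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if self.missing_mask.shape != self.dosage.shape:
            raise ValueError("missing_mask shape does not match dosage")
        for name, ids in (("sample", self.sample_ids), ("variant", self.variant_ids)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} ids")
        observed = self.dosage[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosage values must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant over non-missing calls.

        Because dosage counts the cohort-level minor allele this is simply
        the mean dosage divided by two; values may exceed 0.5 only for
        variants whose dosage was oriented externally.
        """
        d = np.where(self.missing_mask, 0, self.dosage).astype(float)
        n_obs = (~self.missing_mask).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = d.sum(axis=0) / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def imputed(self) -> np.ndarray:
        """Float dosage with missing entries replaced by the variant mean."""
        d = self.dosage.astype(float)
        if not self.missing_mask.any():
            return d
        d = np.where(self.missing_mask, np.nan, d)
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(self.missing_mask)
        d[idx] = col_mean[idx[1]]
        return d

    def variant_indexer(self) -> dict:
        return {v: i for i, v in enumerate(self.variant_ids)}

    def subset_variants(self, variant_ids: Iterable) -> "GenotypeMatrix":
        index = self.variant_indexer()
        ids = list(variant_ids)
        missing = [v for v in ids if v not in index]
        if missing:
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        cols = [index[v] for v in ids]
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            variant_ids=np.asarray(ids, dtype=object),
            dosage=self.dosage[:, cols].copy(),
            missing_mask=self.missing_mask[:, cols].copy(),
        )

    def subset_samples(self, sample_ids: Iterable) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        ids = list(sample_ids)
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=np.asarray(ids, dtype=object),
            variant_ids=self.variant_ids.copy(),
            dosage=self.dosage[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.variant_ids, other.variant_ids)
            and np.array_equal(
                np.where(self.missing_mask, -1, self.dosage),
                np.where(other.missing_mask, -1, other.dosage),
            )
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a provenance label."""

    set_id: str
    display_name: str
    genes: tuple
    provenance: str = "kegg_pathway"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no members")


class GeneSetCollection:
    """Ordered collection of :class:`GeneSet` objects keyed by id."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict = {}
        for s in sets:
            if s.set_id in self._sets:
                raise ValueError(f"duplicate gene set id {s.set_id!r}")
            self._sets[s.set_id] = s

    @classmethod
    def from_dict(
        cls,
        mapping: Mapping,
        provenance: str = "kegg_pathway",
        display_names: Mapping | None = None,
    ) -> "GeneSetCollection":
        names = display_names or {}
        return cls(
            GeneSet(
                set_id=str(sid),
                display_name=str(names.get(sid, sid)),
                genes=tuple(dict.fromkeys(genes)),
                provenance=provenance,
            )
            for sid, genes in mapping.items()
        )

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, set_id) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id) -> GeneSet:
        return self._sets[set_id]

    @property
    def ids(self) -> list:
        return list(self._sets)

    def genes_union(self) -> set:
        out: set = set()
        for s in self:
            out.update(s.genes)
        return out

    def drop_genes(self, genes: Iterable) -> "GeneSetCollection":
        """New collection with the given genes removed; empty sets dropped."""
        drop = set(genes)
        kept = []
        for s in self:
            remaining = tuple(g for g in s.genes if g not in drop)
            if remaining:
                kept.append(dataclasses.replace(s, genes=remaining))
        return GeneSetCollection(kept)


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if variants["variant_id"].duplicated().any():
        dups = variants.loc[variants["variant_id"].duplicated(), "variant_id"]
        raise ValueError(f"duplicate variant ids: {list(dups.head())}")
    if (variants["pos"] <= 0).any():
        raise ValueError("variant positions must be positive (1-based)")
    return variants


def validate_clinical_table(clinical: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in clinical.columns or "status" not in clinical.columns:
        raise ValueError("clinical table requires 'sample_id' and 'status' columns")
    if clinical["sample_id"].duplicated().any():
        dups = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicated sample rows: {list(dups.head())}")
    status = clinical["status"].astype(str).str.lower()
    bad = sorted(set(status) - {"case", "control"})
    if bad:
        raise ValueError(f"unknown status values: {bad}")
    clinical = clinical.copy()
    clinical["status"] = status
    return clinical


def case_control_indicator(clinical: pd.DataFrame, sample_ids: Iterable) -> np.ndarray:
    """0/1 case indicator aligned to ``sample_ids``; errors on absentees."""
    clinical = validate_clinical_table(clinical)
    status = clinical.set_index("sample_id")["status"]
    ids = list(sample_ids)
    missing = [s for s in ids if s not in status.index]
    if missing:
        raise ValueError(f"samples absent from clinical table: {missing[:5]}")
    y = (status.loc[ids] == "case").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    return y


def check_consequences(values: Iterable) -> None:
    offenders = sorted({str(v) for v in values} - set(CONSEQUENCE_VOCAB))
    if offenders:
        raise ValueError(f"unknown consequence values: {offenders}")


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=3)
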