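"""Synthetic case-control cohort generator.

Emulates a targeted-sequencing case-control study of immune pathway genes:
a configurable number of genes laid out on chromosomes and grouped into
pathways, per-variant minor allele frequencies drawn from a rare-skewed
spectrum, optional LD blocks generated by a Gaussian-copula haplotype
model, planted per-pathway log-odds effects, case/control labels from a
liability-threshold or logistic disease model, clinical covariates
(an organ-damage count and autoantibody flags) driven by the true genetic
burden, and case-only variant injection for catalogue tests.

All randomness flows from ``SimulationConfig.seed``; identical config and
seed reproduce identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection, GenotypeMatrix

_EXTERNAL_PANELS = ("swegen", "gnomad_nfe")


@dataclass
class ClinicalEffects:
    """Coefficients linking true genetic burden to clinical outcomes.

    The damage index is Poisson with a log link on the standardised true
    liability among cases; autoantibody flags are Bernoulli with a logit
    link.  Zero slopes give clinical variables independent of genotype.
    """

    damage_intercept: float = 0.0  # log scale; exp(0) = 1 expected count
    damage_slope: float = 0.35
    autoantibody: dict = field(
        default_factory=lambda: {"SSA_or_SSB": (-0.85, 0.5)}  # (logit intercept, slope)
    )


@dataclass
class CausalPathway:
    """Planted effect description for one pathway."""

    pathway_id: str
    lnor_mean: float = 0.3
    lnor_sd: float = 0.0
    fraction_causal: float = 0.2


@dataclass
class SimulationConfig:
    n_cases: int = 958
    n_controls: int = 1026
    n_genes: int = 100
    n_pathways: int = 10
    genes_per_pathway: dict | None = None  # pathway id -> gene id list
    variants_per_gene: int = 20
    maf_spectrum: tuple = ("beta", 0.3, 1.0)  # maf = 0.5 * Beta(a, b)
    min_maf: float = 5e-4
    ld_block_size: int = 1
    ld_r2: float = 0.0
    causal_pathways: tuple = ()
    disease_model: str = "liability"  # liability | logistic
    prevalence_or_intercept: float = 0.1
    rare_nonsyn_rate: float = 3.0  # expected rare non-synonymous sites per gene
    caseonly_injection: int = 0
    caseonly_carrier_counts: tuple | None = None
    clinical_model: ClinicalEffects = field(default_factory=ClinicalEffects)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_pathways", "variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must lie in [0, 1]")
        if not (0.0 < self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        self.causal_pathways = tuple(
            c if isinstance(c, CausalPathway) else CausalPathway(**c)
            for c in self.causal_pathways
        )
        if self.genes_per_pathway is None:
            self.genes_per_pathway = self._default_pathways()
        genes = self.gene_ids()
        known = set(genes)
        for pid, members in self.genes_per_pathway.items():
            bad = [g for g in members if g not in known]
            if bad:
                raise ValueError(f"pathway {pid!r} references undefined genes: {bad[:5]}")
        for c in self.causal_pathways:
            if c.pathway_id not in self.genes_per_pathway:
                raise ValueError(f"unknown causal pathway {c.pathway_id!r}")

    def gene_ids(self) -> list:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]

    def _default_pathways(self) -> dict:
        """Overlapping pathways covering the gene complement round-robin."""
        genes = self.gene_ids()
        per = max(2, int(np.ceil(len(genes) / self.n_pathways * 1.25)))
        out = {}
        for p in range(self.n_pathways):
            start = int(p * len(genes) / self.n_pathways)
            members = [genes[(start + k) % len(genes)] for k in range(per)]
            out[f"hsa{4000 + p:05d}"] = list(dict.fromkeys(members))
        return out

    @classmethod
    def reference_scale(cls, **overrides) -> "SimulationConfig":
        """Config at the scale of the motivating study design:
        958 cases / 1026 controls, 1832 genes in 35 pathways and roughly
        157 variants per gene (~287k variants in total)."""
        base = dict(
            n_cases=958,
            n_controls=1026,
            n_genes=1832,
            n_pathways=35,
            variants_per_gene=157,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    kind, *params = config.maf_spectrum
    if kind == "beta":
        a, b = params
        maf = 0.5 * rng.beta(a, b, size=n)
    elif kind == "fixed":
        maf = np.full(n, float(params[0]))
    else:
        raise ValueError(f"unknown maf_spectrum kind {kind!r}")
    return np.clip(maf, config.min_maf, 0.5)


def _latent_rho(target_phi: float, p: float) -> float:
    """Latent Gaussian correlation giving indicator correlation ~ target_phi
    for two equal-margin Bernoulli(p) thresholded variables."""
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal

    t = stats.norm.ppf(p)

    def phi_of(r: float) -> float:
        p11 = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([t, t])
        return (p11 - p * p) / (p * (1 - p))

    if target_phi <= 0:
        return 0.0
    hi = 1 - 1e-9
    if phi_of(hi) <= target_phi:
        return hi
    return float(brentq(lambda r: phi_of(r) - target_phi, 0.0, hi, xtol=1e-6))


def _simulate_block(
    rng: np.random.Generator, mafs: np.ndarray, n_ind: int, ld_r2: float
) -> np.ndarray:
    """Dosages for one LD block via two haplotypes per individual.

    Within a block the latent haplotype Gaussians follow an AR(1)
    correlation calibrated at the block's mean MAF so that adjacent
    variants have indicator (allele) correlation ~ sqrt(ld_r2)."""
    m = len(mafs)
    thresholds = stats.norm.ppf(mafs)
    if m == 1 or ld_r2 <= 0:
        haps = rng.random((2 * n_ind, m)) < mafs[None, :]
    else:
        r_lat = _latent_rho(np.sqrt(ld_r2), float(mafs.mean()))
        # AR(1) latent draws
        z = rng.standard_normal((2 * n_ind, m))
        for j in range(1, m):
            z[:, j] = r_lat * z[:, j - 1] + np.sqrt(1 - r_lat**2) * z[:, j]
        haps = z < thresholds[None, :]
    haps = haps.astype(np.int8)
    return haps[0::2] + haps[1::2]


def _assign_consequences(
    rng: np.random.Generator, config: SimulationConfig, true_maf: np.ndarray
) -> np.ndarray:
    """Consequence labels with the expected count of rare non-synonymous
    sites per gene equal to ``rare_nonsyn_rate``."""
    kind, *params = config.maf_spectrum
    if kind == "beta":
        a, b = params
        p_rare = float(stats.beta.cdf(2 * 0.01, a, b))
    else:
        p_rare = float(np.mean(true_maf < 0.01))
    expected_rare = config.variants_per_gene * max(p_rare, 1e-12)
    q_ns = min(1.0, config.rare_nonsyn_rate / expected_rare)
    cons = np.empty(len(true_maf), dtype=object)
    is_rare = true_maf < 0.01
    u = rng.random(len(true_maf))
    # rare sites: non-synonymous with probability q_ns
    rare_ns = is_rare & (u < q_ns)
    kinds = rng.choice(
        ["missense", "stop-gained", "splice-region"], p=[0.8, 0.1, 0.1], size=len(true_maf)
    )
    cons[rare_ns] = kinds[rare_ns]
    rest = ~rare_ns
    u2 = rng.random(len(true_maf))
    cons[rest & (u2 < 0.10)] = "missense"
    cons[rest & (u2 >= 0.10) & (u2 < 0.25)] = "synonymous"
    cons[rest & (u2 >= 0.25)] = "non-coding"
    return cons


def _sift_labels(rng: np.random.Generator, consequences: np.ndarray) -> np.ndarray:
    out = np.full(len(consequences), "-", dtype=object)
    mis = consequences == "missense"
    scores = rng.random(len(consequences))
    deleterious = mis & (scores < 0.4)
    tolerated = mis & ~deleterious
    out[deleterious] = [f"Deleterious({rng.uniform(0, 0.05):.2f})" for _ in range(int(deleterious.sum()))]
    out[tolerated] = [f"Tolerated({rng.uniform(0.06, 0.95):.2f})" for _ in range(int(tolerated.sum()))]
    return out


def _make_blueprint(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fixed per-variant properties drawn once per cohort: layout, target
    MAF, alleles, consequences, panel presence and planted ln-ORs (for
    the ALT allele, which carries the target MAF)."""
    genes = config.gene_ids()
    m_per = config.variants_per_gene
    m_total = len(genes) * m_per

    true_maf = _draw_mafs(config, rng, m_total)

    # genomic layout: genes round-robin over 22 chromosomes, 1 Mb apart,
    # variants 100 bp apart within the gene region
    chrom = np.empty(m_total, dtype=object)
    pos = np.empty(m_total, dtype=np.int64)
    gene_col = np.empty(m_total, dtype=object)
    for gi, gene in enumerate(genes):
        c = gi % 22 + 1
        gene_start = 1_000_000 * (gi // 22 + 1)
        sl = slice(gi * m_per, (gi + 1) * m_per)
        chrom[sl] = str(c)
        pos[sl] = gene_start + 100 * np.arange(m_per)
        gene_col[sl] = gene

    ref = rng.choice(_BASES, size=m_total)
    alt = np.array(
        [rng.choice([b for b in _BASES if b != r]) for r in ref], dtype=object
    )
    consequences = _assign_consequences(rng, config, true_maf)
    sift = _sift_labels(rng, consequences)

    # external control panel presence: common variants are almost always
    # seen in large panels, rare ones often but not always
    panel = {}
    for name in _EXTERNAL_PANELS:
        prob = np.where(true_maf >= 0.01, 0.995, 0.6)
        panel[f"panel_{name}"] = rng.random(m_total) < prob

    true_lnor = np.zeros(m_total)
    for causal in config.causal_pathways:
        member_genes = set(config.genes_per_pathway[causal.pathway_id])
        candidates = np.flatnonzero(np.isin(gene_col, list(member_genes)))
        k = int(round(causal.fraction_causal * len(candidates)))
        if k > 0:
            chosen = rng.choice(candidates, size=k, replace=False)
            effects = (
                rng.normal(causal.lnor_mean, causal.lnor_sd, size=k)
                if causal.lnor_sd > 0
                else np.full(k, causal.lnor_mean)
            )
            true_lnor[chosen] += effects

    return pd.DataFrame(
        {
            "variant_id": np.array(
                [f"v{i:07d}" for i in range(1, m_total + 1)], dtype=object
            ),
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene_id": gene_col,
            "consequence": consequences,
            "sift_label": sift,
            "true_maf": true_maf,
            "true_lnor": true_lnor,
            **panel,
        }
    )


def _draw_alt_dosage(
    config: SimulationConfig, blueprint: pd.DataFrame, n: int, rng: np.random.Generator
) -> tuple:
    """ALT-allele dosages (and missing mask) for ``n`` new individuals."""
    true_maf = blueprint["true_maf"].to_numpy()
    m_total = len(true_maf)
    m_per = config.variants_per_gene
    dosage = np.empty((n, m_total), dtype=np.int8)
    bs = config.ld_block_size
    for gi in range(config.n_genes):
        for start in range(gi * m_per, (gi + 1) * m_per, bs):
            end = min(start + bs, (gi + 1) * m_per)
            dosage[:, start:end] = _simulate_block(
                rng, true_maf[start:end], n, config.ld_r2
            )
    missing = np.zeros(dosage.shape, dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random(dosage.shape) < config.missing_rate
    return dosage, missing


def _orient_to_minor(gm: GenotypeMatrix, blueprint: pd.DataFrame) -> pd.DataFrame:
    """Flip ALT dosages to minor-allele dosages in place (cohort-level
    empirical frequency; 0.5 ties broken lexicographically, matching the
    VCF reader) and return the full variant table."""
    ref = blueprint["ref"].to_numpy()
    alt = blueprint["alt"].to_numpy()
    emp = gm.maf()
    flip = (emp > 0.5) | ((emp == 0.5) & (ref < alt))
    if flip.any():
        gm.dosage[:, flip] = np.where(
            gm.missing_mask[:, flip], gm.dosage[:, flip], 2 - gm.dosage[:, flip]
        )
    variants = blueprint.copy()
    variants.insert(5, "minor_allele", np.where(flip, ref, alt))
    variants.insert(6, "maf", gm.maf())
    variants["alt_flipped"] = flip
    ordered = [
        "variant_id", "chrom", "pos", "ref", "alt", "minor_allele", "maf",
        "gene_id", "consequence", "sift_label", "true_maf", "true_lnor",
        "alt_flipped",
    ] + [c for c in variants.columns if c.startswith("panel_")]
    return variants[ordered]


def simulate_genotypes(
    config: SimulationConfig, n_individuals: int | None = None
) -> tuple:
    """Genotype matrix and variant annotation table for ``n_individuals``
    (default cases + controls).

    Dosage counts the cohort minor allele; ``maf`` in the returned table
    is recomputed from the realised dosages (the sampling target is kept
    in ``true_maf``).  Causal ln-ORs are assigned in the blueprint
    (column ``true_lnor``, oriented to the ALT allele; ``alt_flipped``
    records where minor != ALT) so phenotype simulation sees a fixed
    causal set.
    """
    rng = np.random.default_rng(config.seed)
    blueprint = _make_blueprint(config, rng)
    n = int(n_individuals or (config.n_cases + config.n_controls))
    dosage, missing = _draw_alt_dosage(config, blueprint, n, rng)
    gm = GenotypeMatrix(
        sample_ids=np.array([f"tmp{i:06d}" for i in range(n)], dtype=object),
        variant_ids=blueprint["variant_id"].to_numpy(),
        dosage=dosage,
        missing_mask=missing,
    )
    variants = _orient_to_minor(gm, blueprint)
    return gm, variants


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _genetic_score(genotypes: GenotypeMatrix, variants: pd.DataFrame) -> np.ndarray:
    v = variants.set_index("variant_id").reindex(genotypes.variant_ids)
    beta = v["true_lnor"].to_numpy(dtype=float)
    nz = beta != 0
    if not nz.any():
        return np.zeros(genotypes.n_samples)
    d = genotypes.imputed()[:, nz]
    if "alt_flipped" in v.columns:  # ln-ORs are defined for the ALT allele
        flipped = v["alt_flipped"].to_numpy(dtype=bool)[nz]
        d = np.where(flipped[None, :], 2.0 - d, d)
    centred = d - d.mean(axis=0, keepdims=True)
    return centred @ beta[nz]


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Case/control status and clinical covariates for the given genotypes.

    Liability model: standard-normal polygenic noise plus the planted
    genetic score; the top fraction matching the requested case share
    becomes cases.  Logistic model: Bernoulli with logit equal to the
    population-prevalence intercept plus the genetic score (the dataset
    then has a random number of cases; orchestration resamples pools).
    The true liability is stored for recovery tests; the damage index and
    autoantibody flags are generated from ``clinical_model``.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    g = _genetic_score(genotypes, variants)
    n = genotypes.n_samples
    if config.disease_model == "liability":
        liability = g + rng.standard_normal(n)
        case_share = config.n_cases / (config.n_cases + config.n_controls)
        n_cases = int(round(case_share * n))
        order = np.argsort(-liability, kind="stable")
        status = np.full(n, "control", dtype=object)
        status[order[:n_cases]] = "case"
    elif config.disease_model == "logistic":
        intercept = np.log(
            config.prevalence_or_intercept / (1 - config.prevalence_or_intercept)
        )
        liability = intercept + g
        status = np.where(
            rng.random(n) < 1.0 / (1.0 + np.exp(-liability)), "case", "control"
        )
    else:
        raise ValueError(f"unknown disease_model {config.disease_model!r}")

    mdl = config.clinical_model
    scale = g.std()
    z = (g - g.mean()) / scale if scale > 0 else np.zeros(n)
    damage = rng.poisson(np.exp(mdl.damage_intercept + mdl.damage_slope * z))
    clinical = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "status": status,
            "damage_index": damage.astype(int),
            "true_liability": liability,
        }
    )
    for name, (intercept, slope) in mdl.autoantibody.items():
        p = 1.0 / (1.0 + np.exp(-(intercept + slope * z)))
        clinical[name] = rng.random(n) < p
    return clinical


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------


def _inject_case_only(
    rng: np.random.Generator,
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SimulationConfig,
) -> tuple:
    """Append rare non-synonymous variants carried exclusively by cases."""
    k = config.caseonly_injection
    if k <= 0:
        return genotypes, variants
    case_idx = np.flatnonzero((clinical["status"] == "case").to_numpy())
    counts = config.caseonly_carrier_counts or (1, 1, 2, 2, 2, 3, 4, 5)
    genes = config.gene_ids()
    new_cols = np.zeros((genotypes.n_samples, k), dtype=np.int8)
    rows = []
    gene_pos = variants.groupby("gene_id")["pos"].max()
    gene_chrom = variants.drop_duplicates("gene_id").set_index("gene_id")["chrom"]
    for i in range(k):
        cc = int(counts[i % len(counts)])
        carriers = rng.choice(case_idx, size=min(cc, len(case_idx)), replace=False)
        new_cols[carriers, i] = 1
        gene = genes[int(rng.integers(len(genes)))]
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        rows.append(
            {
                "variant_id": f"co{i + 1:05d}",
                "chrom": gene_chrom.loc[gene],
                "pos": int(gene_pos.loc[gene]) + 10 + i,
                "ref": ref,
                "alt": alt,
                "minor_allele": alt,
                "maf": len(carriers) / (2.0 * genotypes.n_samples),
                "gene_id": gene,
                "consequence": "missense",
                "sift_label": f"Deleterious({rng.uniform(0, 0.05):.2f})",
                "true_maf": 0.0,
                "true_lnor": 0.0,
                **{f"panel_{p}": False for p in _EXTERNAL_PANELS},
            }
        )
    gm = GenotypeMatrix(
        sample_ids=genotypes.sample_ids,
        variant_ids=np.concatenate(
            [genotypes.variant_ids, [r["variant_id"] for r in rows]]
        ),
        dosage=np.hstack([genotypes.dosage, new_cols]),
        missing_mask=np.hstack(
            [genotypes.missing_mask, np.zeros_like(new_cols, dtype=bool)]
        ),
    )
    vt = pd.concat([variants, pd.DataFrame(rows)], ignore_index=True)
    return gm, vt


def simulate_cohort(config: SimulationConfig, max_rounds: int = 20) -> dict:
    """Full synthetic cohort: genotypes, variants, gene sets and clinical.

    For the liability model a single pool of ``n_cases + n_controls``
    individuals is generated and labelled by liability rank.  For the
    logistic model, pools are drawn in rounds until both quotas are met;
    exceeding ``max_rounds`` raises.
    """
    if config.disease_model == "liability":
        gm, variants = simulate_genotypes(config)
        clinical = simulate_phenotypes(gm, variants, config)
    else:
        # one variant blueprint; ascertainment pools drawn from the same
        # generative process until both quotas are met
        rng = np.random.default_rng(config.seed)
        blueprint = _make_blueprint(config, rng)
        rng_pheno = np.random.default_rng(config.seed + 1)
        prev = config.prevalence_or_intercept
        pool_n = int(
            1.3 * max(config.n_cases / prev, config.n_controls / (1 - prev))
        )
        beta = blueprint["true_lnor"].to_numpy()
        true_maf = blueprint["true_maf"].to_numpy()
        intercept = np.log(prev / (1 - prev))
        parts_d: list = []
        parts_m: list = []
        parts_eta: list = []
        parts_case: list = []
        n_cases_seen = 0
        n_ctrls_seen = 0
        for _round in range(max_rounds):
            dosage, missing = _draw_alt_dosage(config, blueprint, pool_n, rng)
            g = (dosage.astype(float) - 2.0 * true_maf[None, :]) @ beta
            eta = intercept + g
            is_case = rng_pheno.random(pool_n) < 1.0 / (1.0 + np.exp(-eta))
            parts_d.append(dosage)
            parts_m.append(missing)
            parts_eta.append(eta)
            parts_case.append(is_case)
            n_cases_seen += int(is_case.sum())
            n_ctrls_seen += int((~is_case).sum())
            if n_cases_seen >= config.n_cases and n_ctrls_seen >= config.n_controls:
                break
        else:
            raise RuntimeError(
                f"disease model produced too few cases after {max_rounds} sampling rounds"
            )
        dosage = np.vstack(parts_d)
        missing = np.vstack(parts_m)
        eta = np.concatenate(parts_eta)
        is_case = np.concatenate(parts_case)
        keep = np.concatenate(
            [
                np.flatnonzero(is_case)[: config.n_cases],
                np.flatnonzero(~is_case)[: config.n_controls],
            ]
        )
        n_kept = len(keep)
        gm = GenotypeMatrix(
            sample_ids=np.array([f"tmp{i:06d}" for i in range(n_kept)], dtype=object),
            variant_ids=blueprint["variant_id"].to_numpy(),
            dosage=dosage[keep],
            missing_mask=missing[keep],
        )
        variants = _orient_to_minor(gm, blueprint)
        mdl = config.clinical_model
        g_kept = eta[keep] - intercept
        scale = g_kept.std()
        z = (g_kept - g_kept.mean()) / scale if scale > 0 else np.zeros(n_kept)
        clinical = pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "status": np.where(is_case[keep], "case", "control"),
                "damage_index": rng_pheno.poisson(
                    np.exp(mdl.damage_intercept + mdl.damage_slope * z)
                ).astype(int),
                "true_liability": eta[keep],
            }
        )
        for name, (b0, b1) in mdl.autoantibody.items():
            p = 1.0 / (1.0 + np.exp(-(b0 + b1 * z)))
            clinical[name] = rng_pheno.random(n_kept) < p

    # stable public sample ids, cases first
    order = np.argsort(
        (clinical["status"] != "case").to_numpy(), kind="stable"
    )
    gm = gm.subset_samples(clinical["sample_id"].to_numpy()[order])
    clinical = clinical.iloc[order].reset_index(drop=True)
    n_case = int((clinical["status"] == "case").sum())
    new_ids = np.array(
        [f"case{i + 1:05d}" for i in range(n_case)]
        + [f"ctrl{i + 1:05d}" for i in range(len(clinical) - n_case)],
        dtype=object,
    )
    gm.sample_ids = new_ids
    clinical["sample_id"] = new_ids

    rng_inj = np.random.default_rng(config.seed + 3)
    gm, variants = _inject_case_only(rng_inj, gm, variants, clinical, config)
    # refresh empirical MAF after subsetting/injection
    variants = variants.copy()
    variants["maf"] = gm.maf()

    genesets = GeneSetCollection.from_dict(
        config.genes_per_pathway, provenance="kegg_pathway"
    )
    return {
        "genotypes": gm,
        "variants": variants,
        "genesets": genesets,
        "clinical": clinical,
        "config": config,
    }


# ---------------------------------------------------------------------------
# Fixture bundle writer
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    genesets: GeneSetCollection,
    clinical: pd.DataFrame,
    outdir,
    config: SimulationConfig | None = None,
) -> dict:
    """Write the cohort as VCF + GMT + TSV tables (+ config); returns paths.

    Round-tripping through :mod:`pathassoc.io` readers reproduces the
    in-memory objects exactly.
    """
    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "gmt": outdir / "genesets.gmt",
        "variants": outdir / "variants.tsv",
        "clinical": outdir / "clinical.tsv",
        "gene_regions": outdir / "gene_regions.bed",
    }
    io_mod.write_vcf(paths["vcf"], genotypes, variants)
    io_mod.write_gmt(paths["gmt"], genesets)
    variants.to_csv(paths["variants"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    regions = (
        variants.dropna(subset=["gene_id"])
        .groupby("gene_id", sort=False)
        .agg(chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"))
        .reset_index()
    )
    # BED-like: 0-based half-open
    regions["start"] = regions["start"] - 1
    regions[["chrom", "start", "end", "gene_id"]].to_csv(
        paths["gene_regions"], sep="\t", index=False, header=False
    )
    if config is not None:
        import yaml

        paths["config"] = outdir / "config.yaml"
        cfg = dataclasses.asdict(config)
        cfg["clinical_model"] = dataclasses.asdict(config.clinical_model)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
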