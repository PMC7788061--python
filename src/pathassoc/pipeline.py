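"""End-to-end pipeline orchestration with a single config, deterministic
seeding, TSV stage outputs, a JSON-lines event log and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, association, io as io_mod, prs as prs_mod, rare, simulate, stratify
from .association import SetTestConfig
from .simulate import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "pathassoc_run"
    # input paths; when vcf is None the synthetic cohort is generated
    vcf: str | None = None
    gmt: str | None = None
    gene_regions: str | None = None
    clinical: str | None = None
    variant_annotation: str | None = None
    # stage parameters
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    maf_stratum: str = "all"
    fdr_threshold: float = 0.05
    prs_alpha: float = 0.05
    prs_orientation: str = "signed"
    ld_r2_threshold: float = 0.2
    ld_window_kb: float = 500.0
    positivity_percentile: float = 97.5
    n_clusters: int = 4
    cluster_linkage: str = "ward"
    clinical_variables: tuple = ("damage_index", "SSA_or_SSB")
    rare_maf_lt: float = 0.01
    monogenic_genes: tuple = ()
    stages: tuple = (
        "assoc",
        "pathways",
        "eliminate",
        "prs",
        "stratify",
        "rare",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("vcf", "gmt", "gene_regions", "clinical", "variant_annotation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def event(self, stage: str, **kw) -> None:
        rec = {"t": time.time(), "stage": stage, **kw}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()
        logger.info("stage %s: %s", stage, kw)

    def close(self) -> None:
        self._fh.close()


def _load_inputs(config: PipelineConfig, log: _RunLog) -> dict:
    if config.vcf is None:
        log.event("simulate", status="start")
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulate})
        data = simulate.simulate_cohort(sim_cfg)
        log.event(
            "simulate",
            status="done",
            n_samples=data["genotypes"].n_samples,
            n_variants=data["genotypes"].n_variants,
        )
        return data
    log.event("io", status="start")
    gm, vt = io_mod.read_vcf_genotypes(config.vcf)
    if config.variant_annotation:
        ann = io_mod.read_variant_annotation(config.variant_annotation)
        extra = [c for c in ann.columns if c not in vt.columns or c == "variant_id"]
        vt = vt.merge(ann[extra], on="variant_id", how="left")
    if config.gene_regions and "gene_id" not in vt.columns:
        vt = io_mod.assign_genes(vt, io_mod.read_gene_regions(config.gene_regions))
    if "gene_id" not in vt.columns:
        vt["gene_id"] = pd.NA
    genesets = io_mod.read_gmt(config.gmt) if config.gmt else None
    clinical = io_mod.read_clinical_table(config.clinical)
    log.event("io", status="done", n_samples=gm.n_samples, n_variants=gm.n_variants)
    return {"genotypes": gm, "variants": vt, "genesets": genesets, "clinical": clinical}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the output manifest.

    Any stage error aborts with the failing stage named; outputs written
    so far are retained on disk.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run_log.jsonl")
    outputs: dict = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = str(path)

    stage = "load"
    try:
        data = _load_inputs(config, log)
        gm, vt, genesets, clinical = (
            data["genotypes"],
            data["variants"],
            data["genesets"],
            data["clinical"],
        )
        if config.vcf is None:
            bundle = simulate.write_fixture_bundle(
                gm, vt, genesets, clinical, outdir / "cohort", data.get("config")
            )
            outputs.update({f"cohort_{k}": v for k, v in bundle.items()})
        set_cfg = SetTestConfig(maf_stratum=config.maf_stratum, seed=config.seed)

        single = None
        if "assoc" in config.stages:
            stage = "assoc"
            log.event(stage, status="start")
            single = association.single_variant_assoc(gm, clinical)
            save("single_variant", single)
            gene_res = association.gene_assoc(gm, vt, clinical, set_cfg)
            save("gene_assoc", gene_res)
            log.event(stage, status="done", n_tested=int((single["test"] != "skipped").sum()))

        pathway_res = None
        if "pathways" in config.stages and genesets is not None:
            stage = "pathways"
            log.event(stage, status="start")
            pathway_res = association.set_assoc(gm, vt, genesets, clinical, set_cfg)
            save("pathway_assoc", pathway_res)
            save(
                "pathway_assoc_strata",
                association.set_assoc_by_stratum(gm, vt, genesets, clinical, set_cfg),
            )
            log.event(stage, status="done")

        if "eliminate" in config.stages and genesets is not None:
            stage = "eliminate"
            log.event(stage, status="start")
            elim = association.sequential_elimination(
                gm, vt, genesets, clinical, set_cfg, fdr_threshold=config.fdr_threshold
            )
            save("sequential_elimination", elim)
            log.event(stage, status="done", n_selected=len(elim))

        scores = None
        if "prs" in config.stages and genesets is not None:
            stage = "prs"
            log.event(stage, status="start")
            if single is None:
                single = association.single_variant_assoc(gm, clinical)
            tested = single[single["test"] != "skipped"]
            pruned = prs_mod.ld_prune(
                gm,
                vt,
                tested.set_index("variant_id")["p_value"],
                r2_threshold=config.ld_r2_threshold,
                window_kb=config.ld_window_kb,
            )
            logger.warning(
                "PRS weights are estimated on the cohort being scored "
                "(in-sample); interpret positivity rates accordingly"
            )
            weights = prs_mod.build_prs_weights(
                tested, pruned, genesets, vt,
                alpha=config.prs_alpha, orientation=config.prs_orientation,
            )
            save("prs_weights", weights)
            scores = prs_mod.compute_pathway_prs(gm, weights, pathway_ids=genesets.ids)
            scores = prs_mod.classify_positivity(
                scores, clinical, percentile=config.positivity_percentile
            )
            save("prs_scores", scores.scores.reset_index())
            save("prs_positivity", scores.positive.reset_index())
            counts = scores.n_positive.rename("n_positive_pathways").reset_index()
            save("prs_positive_counts", counts)
            log.event(stage, status="done", n_weights=len(weights))

        if "stratify" in config.stages and scores is not None:
            stage = "stratify"
            log.event(stage, status="start")
            normalized = stratify.normalize_prs(scores.scores, clinical)
            case_ids = clinical.loc[clinical["status"] == "case", "sample_id"]
            clusters = stratify.cluster_patients(
                normalized.loc[case_ids],
                k=config.n_clusters,
                linkage_method=config.cluster_linkage,
            )
            save("clusters", clusters)
            variables = [v for v in config.clinical_variables if v in clinical.columns]
            if variables:
                groups = clusters.set_index("sample_id")["cluster"]
                save(
                    "cluster_clinical_tests",
                    stratify.compare_groups_clinical(groups, clinical, variables),
                )
            save("prs_case_control", stratify.prs_case_control_tests(scores.scores, clinical))
            log.event(stage, status="done")

        if "rare" in config.stages:
            stage = "rare"
            log.event(stage, status="start")
            if "consequence" in vt.columns:
                burden = rare.per_individual_burden(gm, vt, maf_lt=config.rare_maf_lt)
                save("rare_burden", burden.rename_axis("sample_id").reset_index())
                catalogue = rare.case_only_catalogue(gm, vt, clinical)
                save("case_only_catalogue", catalogue)
                genes = tuple(config.monogenic_genes) or tuple(
                    pd.unique(vt["gene_id"].dropna())[:5]
                )
                screen = rare.homozygous_rare_screen(gm, vt, genes, clinical)
                save("homozygous_rare", screen)
            log.event(stage, status="done")
    except Exception as exc:
        log.event(stage, status="error", error=str(exc))
        log.close()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
        },
        "outputs": {k: _sha256(Path(v)) for k, v in outputs.items() if Path(v).is_file()},
        "paths": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.event("manifest", status="done", n_outputs=len(outputs))
    log.close()
    return manifest
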