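"""End-to-end orchestration: simulate/load -> QC -> scans -> enrichment -> reports.

A :class:`PipelineConfig` (YAML-serializable) either names the input files
(genotypes as PLINK bed/bim/fam or VCF, phenotype/annotation/ranking/
control-pool TSVs) or carries a simulation block; :func:`run_pipeline`
executes every stage under one master seed and writes a deterministic
result tree — rerunning with the same config and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .assoc import ModelSpec, VariantScan, compute_pc1
from .containers import GeneSetRanking, GenotypeMatrix, validate_phenotypes
from .effects import bin_effect_sizes, export_gene_lists, overlap_table, top_centile_genes
from .enrich import EnrichmentScan
from .qc import QcThresholds, run_qc
from .simdata import SimConfig, config_from_dict, config_to_dict, simulate_study

logger = logging.getLogger("tbisig")

ALL_STAGES = ("qc", "assoc", "enrich", "report")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``inputs`` / ``simulate``."""

    seed: int = 0
    outdir: str = "results"
    inputs: dict | None = None          # genotypes, phenotypes, annotation, ranking, control_pool
    simulate: SimConfig | None = None
    outcomes: tuple = ("cbcl", "gec")
    models: tuple = ("interaction", "tbi")
    qc: QcThresholds = field(default_factory=QcThresholds)
    epoch_step: int = 5
    n_draws: int = 1000
    alpha: float = 0.05
    top_centile: float = 5.0

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        if self.inputs is not None:
            required = {"genotypes", "phenotypes", "annotation", "ranking", "control_pool"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing {sorted(missing)}")
            for key, path in self.inputs.items():
                probe = pathlib.Path(path)
                if key == "genotypes" and not str(path).endswith(".vcf"):
                    probe = probe.with_suffix(".bed")
                if not probe.exists():
                    raise FileNotFoundError(f"inputs.{key}: {probe} does not exist")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        d["qc"] = dataclasses.asdict(self.qc)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = config_from_dict(d["simulate"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcThresholds(**d["qc"])
        for key in ("outcomes", "models"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input loading
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig):
    """Load and reconcile the input files.

    Returns (genotypes, phenotypes, annotation, ranking, n_dropped) where
    ``n_dropped`` counts participants present in only one of the genotype
    and phenotype sources (dropped with a warning).
    """
    config.validate()
    paths = config.inputs
    gpath = str(paths["genotypes"])
    if gpath.endswith(".vcf"):
        genotypes = tio.read_vcf(gpath)
    else:
        genotypes = tio.read_plink(gpath)
    if "variant_metadata" in paths:
        meta = tio.read_variant_metadata(paths["variant_metadata"])
        genotypes.variants["rsq"] = meta["rsq"].reindex(genotypes.variant_ids).to_numpy()
        genotypes.variants["maf"] = meta["maf"].reindex(genotypes.variant_ids).to_numpy()
    else:
        # no imputation-quality source: treat variants as directly genotyped
        genotypes.variants["rsq"] = genotypes.variants["rsq"].fillna(1.0)
    phenotypes = tio.read_phenotypes(paths["phenotypes"], outcomes=config.outcomes)
    annotation = tio.read_annotation(paths["annotation"])
    ranking = tio.read_ranking(paths["ranking"], paths["control_pool"])

    common = genotypes.participants.intersection(phenotypes.index)
    n_dropped = (len(genotypes.participants) - len(common)) + (len(phenotypes.index) - len(common))
    if n_dropped:
        logger.warning("dropped %d participant records unmatched across genotype/phenotype "
                       "sources", n_dropped)
    genotypes = genotypes.subset(participants=common)
    phenotypes = phenotypes.loc[common]
    return genotypes, phenotypes, annotation, ranking, n_dropped


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: pathlib.Path
    qc_report: pd.DataFrame
    results_map: dict
    enrichment: object | None
    bin_tables: dict
    top_gene_sets: dict
    overlap: object | None
    manifest: dict


def _write_tsv(frame: pd.DataFrame, path, index=True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> PipelineResult:
    """Run the pipeline through the requested stages and write the result tree."""
    config.validate()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    n_dropped = 0

    if config.simulate is not None:
        bundle = simulate_study(config.simulate)
        genotypes, phenotypes = bundle.genotypes, bundle.phenotypes
        annotation, ranking = bundle.annotation, bundle.ranking
    else:
        genotypes, phenotypes, annotation, ranking, n_dropped = load_inputs(config)
    phenotypes = validate_phenotypes(phenotypes, outcomes=config.outcomes)
    logger.info("inputs ready: %d participants, %d variants (%.1fs)",
                genotypes.n_participants, genotypes.n_variants, time.perf_counter() - t0)

    # ---- QC ----
    t = time.perf_counter()
    qcres = run_qc(genotypes, annotation=annotation, thresholds=config.qc)
    gt = qcres.genotypes
    _write_tsv(qcres.report.to_frame(), outdir / "qc_report.tsv", index=False)
    (outdir / "variants_kept.txt").write_text(
        "".join(v + "\n" for v in gt.variant_ids))
    logger.info("qc: %d -> %d variants, %d participants removed (%.1fs)",
                qcres.report.input_variants, gt.n_variants,
                qcres.report.participants_removed, time.perf_counter() - t)

    # gene -> variant map restricted to surviving variants
    assignment = qcres.gene_assignment["assigned_gene"].reindex(gt.variant_ids)
    g2v: dict = {}
    for vid, gene in assignment.dropna().items():
        g2v.setdefault(gene, []).append(vid)
    ranking = GeneSetRanking(ranking.training_genes, ranking.ranked_genes,
                             ranking.control_genes, g2v)

    phenotypes = phenotypes.loc[phenotypes.index.intersection(gt.participants)]
    if "pc1" not in phenotypes.columns:
        phenotypes = phenotypes.join(compute_pc1(gt))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"tbisig": _version(), "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n_participants": int(gt.n_participants),
        "n_variants_post_qc": int(gt.n_variants),
        "participants_dropped_unmatched": int(n_dropped),
        "stages": list(stages),
    }
    result = PipelineResult(config, outdir, qcres.report.to_frame(), {}, None, {}, {}, None,
                            manifest)
    if "assoc" not in stages:
        _write_manifest(manifest, outdir)
        return result

    # ---- association scans ----
    maf = gt.variants["maf"]
    for outcome in config.outcomes:
        odir = outdir / outcome
        odir.mkdir(exist_ok=True)
        for model in config.models:
            t = time.perf_counter()
            spec = (ModelSpec(outcome=outcome) if model == "interaction"
                    else ModelSpec(outcome=outcome, subset="tbi", include_interaction=False))
            res = VariantScan(phenotypes, gt, spec, gene_assignment=assignment).fit()
            result.results_map[(outcome, model)] = res
            _write_tsv(res.frame, odir / f"association_{model}.tsv")
            logger.info("assoc %s/%s: %d hits (%.1fs)", outcome, model,
                        len(res.nominal_hits(config.alpha)), time.perf_counter() - t)
    if "enrich" in stages:
        t = time.perf_counter()
        scan = EnrichmentScan(result.results_map, ranking, maf, alpha=config.alpha)
        enr = scan.fit(step_percent=config.epoch_step, n_draws=config.n_draws,
                       seed=config.seed)
        result.enrichment = enr
        for outcome in config.outcomes:
            sub = enr.frame[enr.frame["name"].str.startswith(f"{outcome}/")]
            _write_tsv(sub, outdir / outcome / "enrichment.tsv", index=False)
        logger.info("enrichment scan done (%.1fs)", time.perf_counter() - t)

    if "report" in stages:
        for (outcome, model), res in result.results_map.items():
            table = bin_effect_sizes(res)
            result.bin_tables[(outcome, model)] = table
            _write_tsv(table.to_frame(), outdir / outcome / f"effect_bins_{model}.tsv")
            result.top_gene_sets[f"{outcome}_{model}"] = top_centile_genes(
                res, config.top_centile)
        if result.top_gene_sets:
            result.overlap = overlap_table(result.top_gene_sets)
            _write_tsv(result.overlap.to_frame(), outdir / "overlap.tsv", index=False)
            export_gene_lists(result.top_gene_sets, outdir / "gene_lists")

    _write_manifest(manifest, outdir)
    logger.info("pipeline complete (%.1fs total)", time.perf_counter() - t0)
    return result


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("tbisig")
    except PackageNotFoundError:
        return "unknown"


def _write_manifest(manifest: dict, outdir: pathlib.Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
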