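"""Synthetic genotype/phenotype/annotation generator.

Emulates the statistical structure the downstream analysis assumes: a
three-group injury cohort (orthopedic-injury comparison, moderate TBI,
severe TBI), biallelic common variants (MAF in [0.10, 0.50]) in
Hardy-Weinberg proportions, age/sex/PC1 covariate structure, and continuous
outcomes carrying group main effects plus variant and variant-by-group
effects concentrated in designated case genes.  Every draw is governed by a
single integer seed; a fixed seed reproduces the full fixture set
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUP_LEVELS, GeneSetRanking, GenotypeMatrix

_DEF_GROUP_FRACTIONS = (61 / 196, 49 / 196, 86 / 196)


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror a ~200-participant three-group cohort (61:49:86) with
    common variants, standardized effect sizes in the 0.2-0.5 range placed
    on a fraction of variants inside the top-ranked case genes, and two
    highly correlated continuous outcomes.
    """

    n_participants: int = 196
    group_fractions: tuple = _DEF_GROUP_FRACTIONS  # (OI, moderate, severe)
    n_training_genes: int = 18
    n_case_genes: int = 1000
    n_control_genes: int = 5000
    variants_per_gene: int | tuple = 8          # int, or (lo, hi) inclusive range
    maf_bounds: tuple = (0.10, 0.50)
    signal_fraction: float = 0.10               # causal fraction of signal-band variants
    signal_rank_band: tuple = (0.0, 5.0)        # percentile band of ranked genes carrying signal
    beta_main: float = 0.2                      # standardized variant main effect
    beta_interaction: float = 0.3               # standardized variant x TBI-group effect
    covariate_betas: dict = field(default_factory=lambda: {
        "age": 0.1, "sex": 0.1, "age_x_sex": 0.1, "pc1": 0.1})
    group_means: dict = field(default_factory=lambda: {
        "OI": 0.0, "moderate": 0.3, "severe": 0.6})
    outcomes: tuple = ("cbcl", "gec")
    outcome_corr: float = 0.8                   # noise correlation between outcomes
    age_range: tuple = (0.0, 17.0)
    missing_rate: float = 0.0
    gene_length: int = 10_000                   # bp per synthetic gene
    gene_gap: int = 20_000                      # bp between consecutive genes
    rsq_value: float = 1.0                      # imputation quality recorded per variant
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if abs(sum(self.group_fractions) - 1.0) > 1e-12:
            raise ValueError("group_fractions must sum to 1")
        lo, hi = self.maf_bounds
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_bounds must lie in (0, 0.5], got {self.maf_bounds}")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if isinstance(self.variants_per_gene, int):
            if self.variants_per_gene < 1:
                raise ValueError("variants_per_gene must be >= 1")
        else:
            lo, hi = self.variants_per_gene
            if not 1 <= lo <= hi:
                raise ValueError("variants_per_gene range invalid")
        if self.gene_gap <= 5000:
            raise ValueError("gene_gap must exceed the 5 kb intergenic rule")

    # deterministic child streams for each generation stage
    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SimTruth:
    """Ground-truth effects used to generate the phenotypes.

    ``true_betas`` maps causal variant id -> dict with keys ``beta_main``,
    ``beta_moderate``, ``beta_severe`` (interaction offsets relative to the
    OI reference slope); every other variant has all effects exactly 0.
    """

    causal_variant_ids: list
    true_betas: dict
    covariate_betas: dict
    group_means: dict

    def beta_of(self, variant_id: str) -> dict:
        zero = {"beta_main": 0.0, "beta_moderate": 0.0, "beta_severe": 0.0}
        return self.true_betas.get(variant_id, zero)


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    annotation: pd.DataFrame
    ranking: GeneSetRanking
    truth: SimTruth


# ---------------------------------------------------------------------------
# gene layout / ranking
# ---------------------------------------------------------------------------

def make_annotation_and_ranking(config: SimConfig):
    """Lay genes on one synthetic chromosome and build the ranked gene sets.

    Returns ``(annotation, ranking, variant_table)``: a BED-like annotation
    frame (chrom, start, end, gene; 1-based inclusive, non-overlapping),
    a :class:`GeneSetRanking` with case genes ranked 1..n_case_genes and a
    disjoint control pool, and a variant metadata frame with variants placed
    strictly inside gene bounds.
    """
    config.validate()
    rng = config._rng(0)
    names = (
        [f"TRN{i + 1:03d}" for i in range(config.n_training_genes)]
        + [f"CASE{i + 1:05d}" for i in range(config.n_case_genes)]
        + [f"CTRL{i + 1:05d}" for i in range(config.n_control_genes)]
    )
    n_genes = len(names)
    starts = 1 + np.arange(n_genes, dtype=np.int64) * (config.gene_length + config.gene_gap)
    ends = starts + config.gene_length - 1
    annotation = pd.DataFrame(
        {"chrom": "1", "start": starts, "end": ends, "gene": names})
    if ((annotation["start"].to_numpy()[1:] - annotation["end"].to_numpy()[:-1]) <= 0).any():
        raise ValueError("overlapping gene intervals in layout")

    if isinstance(config.variants_per_gene, int):
        counts = np.full(n_genes, config.variants_per_gene)
    else:
        lo, hi = config.variants_per_gene
        counts = rng.integers(lo, hi + 1, size=n_genes)

    rows = []
    g2v = {}
    for gene, start, end, k in zip(names, starts, ends, counts):
        # evenly spaced positions strictly inside the gene
        pos = np.linspace(start + 1, end - 1, int(k)).round().astype(np.int64)
        pos = np.unique(pos)
        vids = [f"{gene}:v{j + 1}" for j in range(len(pos))]
        g2v[gene] = vids
        for vid, p in zip(vids, pos):
            rows.append((vid, "1", int(p), "A", "G"))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    variants = variants.set_index("variant_id")
    lo, hi = config.maf_bounds
    variants["maf"] = rng.uniform(lo, hi, size=len(variants))
    variants["rsq"] = float(config.rsq_value)

    ranking = GeneSetRanking(
        training_genes=names[: config.n_training_genes],
        ranked_genes=names[config.n_training_genes: config.n_training_genes + config.n_case_genes],
        control_genes=names[config.n_training_genes + config.n_case_genes:],
        gene_to_variants=g2v,
    )
    return annotation, ranking, variants


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, layout=None) -> GenotypeMatrix:
    """Draw biallelic dosages under Hardy-Weinberg equilibrium.

    Each variant's dosage is the sum of two independent Bernoulli(MAF)
    allele draws per participant (so dosage ~ Binomial(2, MAF), counting
    the alternate = generating-minor allele); missing calls are introduced
    uniformly at ``missing_rate``.
    """
    config.validate()
    if layout is None:
        layout = make_annotation_and_ranking(config)
    _, _, variants = layout
    rng = config._rng(1)
    n, m = config.n_participants, len(variants)
    maf = variants["maf"].to_numpy()
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    if config.missing_rate > 0 and n * m:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
    participants = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="participant_id")
    return GenotypeMatrix(dosages, participants, variants.copy())


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_truth(config: SimConfig, ranking: GeneSetRanking) -> SimTruth:
    """Pick causal variants inside the configured rank band of case genes."""
    config.validate()
    rng = config._rng(2)
    lo, hi = config.signal_rank_band
    band_genes = [
        g for g in ranking.ranked_genes
        if lo < ranking.rank_percentile(g) <= hi
    ]
    band_variants = ranking.variants_of(band_genes)
    n_causal = int(round(config.signal_fraction * len(band_variants)))
    causal = sorted(rng.choice(band_variants, size=n_causal, replace=False)) if n_causal else []
    betas = {
        v: {"beta_main": config.beta_main,
            "beta_moderate": config.beta_interaction,
            "beta_severe": config.beta_interaction}
        for v in causal
    }
    return SimTruth(list(causal), betas, dict(config.covariate_betas), dict(config.group_means))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _group_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign groups with largest-remainder rounding of the target fractions."""
    n = config.n_participants
    raw = np.array(config.group_fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    labels = np.repeat(np.array(GROUP_LEVELS, dtype=object), base)
    return rng.permutation(labels)


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: SimTruth,
                        config: SimConfig) -> pd.DataFrame:
    """Generate the phenotype/covariate table.

    outcome = group mean + covariate effects + sum over causal variants of
    (beta_main + beta_int[group]) * standardized dosage + N(0, 1) noise.
    Dosages are standardized with their theoretical Hardy-Weinberg moments
    (mean 2p, SD sqrt(2p(1-p))) so the generating betas live on the same
    standardized scale the analysis reports; missing calls contribute 0
    (mean imputation).  With several outcomes configured, noise vectors are
    correlated at ``outcome_corr`` while the systematic part is shared.
    """
    config.validate()
    missing = set(truth.causal_variant_ids) - set(genotypes.variant_ids)
    if missing:
        raise ValueError(f"truth references unknown variants: {sorted(missing)[:5]}")
    rng = config._rng(3)
    n = genotypes.n_participants

    group = _group_labels(config, rng)
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    pc1 = rng.standard_normal(n)

    cb = truth.covariate_betas
    age_z = (age - np.mean(config.age_range)) / (np.ptp(config.age_range) / np.sqrt(12.0)) if n else age
    systematic = (
        np.array([truth.group_means[g] for g in group], dtype=float)
        + cb.get("age", 0.0) * age_z
        + cb.get("sex", 0.0) * sex
        + cb.get("age_x_sex", 0.0) * age_z * sex
        + cb.get("pc1", 0.0) * pc1
    )
    d_mod = (group == "moderate").astype(float)
    d_sev = (group == "severe").astype(float)
    for vid in truth.causal_variant_ids:
        j = genotypes.variant_ids.get_loc(vid)
        p = genotypes.variants["maf"].iloc[j]
        g = np.nan_to_num(genotypes.dosages[:, j], nan=2 * p)
        z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        b = truth.true_betas[vid]
        slope = b["beta_main"] + b["beta_moderate"] * d_mod + b["beta_severe"] * d_sev
        systematic = systematic + slope * z

    k = len(config.outcomes)
    noise = rng.standard_normal((n, k))
    if k > 1:
        r = config.outcome_corr
        cov = np.full((k, k), r) + (1 - r) * np.eye(k)
        noise = noise @ np.linalg.cholesky(cov).T

    table = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "group": group,
            "pc1": pc1,
            "cohort": np.where(group == "severe", "C1", "C2"),
        },
        index=genotypes.participants,
    )
    for i, name in enumerate(config.outcomes):
        table[name] = systematic + noise[:, i]
    return table


# ---------------------------------------------------------------------------
# one-call study generation
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate a complete, internally consistent study under one seed."""
    layout = make_annotation_and_ranking(config)
    annotation, ranking, _ = layout
    genotypes = simulate_genotypes(config, layout)
    truth = make_truth(config, ranking)
    phenotypes = simulate_phenotypes(genotypes, truth, config)
    return StudyBundle(config, genotypes, phenotypes, annotation, ranking, truth)


def write_fixture_set(bundle: StudyBundle, directory, genotype_format: str = "plink") -> dict:
    """Write the whole fixture set to ``directory``; returns name -> path.

    Emits PLINK bed/bim/fam (or an uncompressed VCF), phenotype TSV,
    BED-like annotation TSV, ranking TSV, control-pool TSV, and the
    ground-truth JSON.  Reading the files back reproduces the in-memory
    objects.
    """
    from . import io as tio  # local import: io pulls optional cyvcf2 lazily
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    if genotype_format == "plink":
        paths.update(tio.write_plink(bundle.genotypes, directory / "genotypes",
                                     phenotypes=bundle.phenotypes))
    elif genotype_format == "vcf":
        paths["vcf"] = tio.write_vcf(bundle.genotypes, directory / "genotypes.vcf")
    else:
        raise ValueError(f"unknown genotype_format {genotype_format!r}")
    paths["variant_metadata"] = tio.write_variant_metadata(
        bundle.genotypes, directory / "variant_metadata.tsv")
    paths["phenotypes"] = tio.write_phenotypes(bundle.phenotypes, directory / "phenotypes.tsv")
    paths["annotation"] = tio.write_annotation(bundle.annotation, directory / "annotation.tsv")
    rk = tio.write_ranking(bundle.ranking, directory / "ranking.tsv",
                           directory / "control_genes.tsv")
    paths.update(rk)
    paths["truth"] = tio.write_truth(bundle.truth, directory / "truth.json")
    paths["config"] = tio.write_sim_config(bundle.config, directory / "sim_config.json")
    return paths


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("group_fractions", "maf_bounds", "signal_rank_band", "age_range", "outcomes"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "variants_per_gene" in d and isinstance(d["variants_per_gene"], list):
        d["variants_per_gene"] = tuple(d["variants_per_gene"])
    return SimConfig(**d)
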