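"""File formats: PLINK bed/bim/fam, VCF, and the TSV/JSON sidecar files.

The PLINK codec implements the standard variant-major .bed layout (magic
``6c 1b 01``, two bits per call: 00 = two copies of allele A1, 10 = het,
11 = zero copies, 01 = missing).  A1 is written as the alternate (counted)
allele so that the dosage round-trips exactly.  VCF reading goes through
cyvcf2 when available.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GeneSetRanking, validate_phenotypes
from .simdata import SimConfig, SimTruth, config_to_dict, config_from_dict

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage (count of A1) -> 2-bit code, and back
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix, phenotypes: pd.DataFrame | None = None) -> dict:
    """Write a bed/bim/fam trio; returns {'bed':..., 'bim':..., 'fam':...}.

    fam sex codes follow the PLINK convention (1 = male, 2 = female) mapped
    from the phenotype table's 0/1 coding (1 = female there); unknown sex is
    written as 0 when no phenotype table is given.
    """
    prefix = pathlib.Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = genotypes.n_participants

    codes = np.full(genotypes.dosages.shape, 0b01, dtype=np.uint8)  # missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[genotypes.dosages == dosage] = code
    # pack 4 calls per byte, variant-major
    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, genotypes.n_variants), dtype=np.uint8)
    padded[:n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = np.zeros((n_bytes, genotypes.n_variants), dtype=np.uint8)
    for k in range(4):
        packed |= padded[k::4] << shifts[k]
    bed_path = prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # variant-major

    bim = pd.DataFrame({
        "chrom": genotypes.variants["chrom"].to_numpy(),
        "id": genotypes.variant_ids,
        "cm": 0,
        "pos": genotypes.variants["pos"].to_numpy(),
        "a1": genotypes.variants["alt"].to_numpy(),
        "a2": genotypes.variants["ref"].to_numpy(),
    })
    bim_path = prefix.with_suffix(".bim")
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    if phenotypes is not None:
        sex = phenotypes.reindex(genotypes.participants)["sex"]
        fam_sex = np.where(sex == 1, 2, 1)  # 0/1 female flag -> 2 female / 1 male
    else:
        fam_sex = np.zeros(n, dtype=int)
    fam = pd.DataFrame({
        "fid": genotypes.participants,
        "iid": genotypes.participants,
        "father": 0, "mother": 0,
        "sex": fam_sex, "phenotype": -9,
    })
    fam_path = prefix.with_suffix(".fam")
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}


def read_plink(prefix) -> GenotypeMatrix:
    """Read a bed/bim/fam trio written by :func:`write_plink` (or PLINK)."""
    prefix = pathlib.Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep="\t", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phenotype"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a variant-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != n_bytes * m:
        raise ValueError(f"{prefix}.bed: size mismatch ({len(body)} body bytes, "
                         f"expected {n_bytes * m})")
    packed = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([_CODE_TO_DOSAGE[c] for c in range(4)])
    dosages = lut[codes].T  # participants x variants, counts of A1 (= alt)
    variants = pd.DataFrame({
        "chrom": bim["chrom"].to_numpy(), "pos": bim["pos"].to_numpy(),
        "ref": bim["a2"].to_numpy(), "alt": bim["a1"].to_numpy(),
        "maf": np.nan, "rsq": np.nan,
    }, index=pd.Index(bim["id"], name="variant_id"))
    participants = pd.Index(fam["iid"].astype(str), name="participant_id")
    return GenotypeMatrix(dosages, participants, variants)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> pathlib.Path:
    """Write an uncompressed GT-only VCF (alt allele = counted allele)."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            sub = genotypes.variants[genotypes.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 10_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.participants)) + "\n")
        meta = genotypes.variants
        order = np.argsort(meta["pos"].to_numpy(), kind="stable")
        for j in order:
            row = meta.iloc[j]
            calls = [gt_map.get(d, "./.") for d in genotypes.dosages[:, j]]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{meta.index[j]}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    participants = pd.Index(vcf.samples, name="participant_id")
    rows, metas = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    lut = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: variant {var.ID} is not biallelic")
        rows.append(lut[var.gt_types])
        metas.append((var.ID, str(var.CHROM), var.POS, var.REF, var.ALT[0]))
    vcf.close()
    meta = pd.DataFrame(metas, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    meta = meta.set_index("variant_id")
    meta["maf"] = np.nan
    meta["rsq"] = np.nan
    dosages = np.array(rows).T if rows else np.empty((len(participants), 0))
    return GenotypeMatrix(dosages, participants, meta)


# ---------------------------------------------------------------------------
# TSV / JSON sidecars
# ---------------------------------------------------------------------------

def write_variant_metadata(genotypes: GenotypeMatrix, path) -> pathlib.Path:
    """Per-variant sidecar (generating MAF, imputation Rsq) that the PLINK
    and VCF carriers cannot hold."""
    path = pathlib.Path(path)
    genotypes.variants[["maf", "rsq"]].to_csv(path, sep="\t", index=True,
                                              index_label="variant_id",
                                              float_format="%.10g")
    return path


def read_variant_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="variant_id")
    missing = {"maf", "rsq"} - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: variant metadata missing columns {sorted(missing)}")
    return meta


def write_phenotypes(pheno: pd.DataFrame, path) -> pathlib.Path:
    path = pathlib.Path(path)
    pheno.to_csv(path, sep="\t", index=True, index_label="participant_id",
                 float_format="%.10g")
    return path


def read_phenotypes(path, outcomes=()) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", index_col="participant_id")
    pheno.index = pheno.index.astype(str)
    return validate_phenotypes(pheno, outcomes)


def write_annotation(annotation: pd.DataFrame, path) -> pathlib.Path:
    path = pathlib.Path(path)
    annotation[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "gene"} - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    return ann


def write_ranking(ranking: GeneSetRanking, ranking_path, control_path) -> dict:
    ranking_path = pathlib.Path(ranking_path)
    control_path = pathlib.Path(control_path)
    rows = [(g, 0, 1) for g in ranking.training_genes]
    rows += [(g, i + 1, 0) for i, g in enumerate(ranking.ranked_genes)]
    pd.DataFrame(rows, columns=["gene", "rank", "training"]).to_csv(
        ranking_path, sep="\t", index=False)
    pd.DataFrame({"gene": ranking.control_genes}).to_csv(control_path, sep="\t", index=False)
    return {"ranking": ranking_path, "control_pool": control_path}


def read_ranking(ranking_path, control_path, annotation=None,
                 variants: pd.DataFrame | None = None) -> GeneSetRanking:
    """Read ranking + control-pool TSVs; optionally build gene->variant map.

    When ``annotation`` and ``variants`` are given, variants are assigned to
    genes with the 5 kb intergenic rule of :func:`tbisig.qc.assign_variants_to_genes`.
    """
    rk = pd.read_csv(ranking_path, sep="\t")
    ctrl = pd.read_csv(control_path, sep="\t")
    training = rk.loc[rk["training"] == 1, "gene"].tolist()
    ranked = rk.loc[rk["training"] == 0].sort_values("rank")["gene"].tolist()
    g2v = {}
    if annotation is not None and variants is not None:
        from .qc import assign_variants_to_genes

        assigned = assign_variants_to_genes(variants, annotation)
        kept = assigned[assigned["assigned_gene"].notna()]
        for vid, gene in kept["assigned_gene"].items():
            g2v.setdefault(gene, []).append(vid)
    return GeneSetRanking(training, ranked, ctrl["gene"].tolist(), g2v)


def write_truth(truth: SimTruth, path) -> pathlib.Path:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimTruth(**d)


def write_sim_config(config: SimConfig, path) -> pathlib.Path:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))
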