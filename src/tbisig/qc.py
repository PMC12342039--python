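"""Variant and participant quality control, plus gene assignment.

The filter chain reproduces a common GWAS QC recipe for chip + imputed
data: participant call rate >= 90%, then per-variant SNP call rate >= 95%,
minor allele frequency >= 10%, Hardy-Weinberg exact-test p >= 1e-4,
imputation Rsq >= 0.95, and exclusion of intergenic variants more than
5,000 bp from the closest gene.  Filters are independent predicates, so the
surviving set does not depend on the stage order; the per-stage removal
counts do, and the default order is fixed and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import GenotypeMatrix

DEFAULT_FILTER_ORDER = ("call_rate", "maf", "hwe", "rsq", "gene_distance")


@dataclass
class QcThresholds:
    """Variant/participant QC thresholds (defaults = the standard recipe)."""

    maf_min: float = 0.10
    snp_call_rate_min: float = 0.95
    participant_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-4
    rsq_min: float = 0.95
    max_gene_distance: int = 5000  # "more than 5,000 bp" is excluded; == 5,000 kept


@dataclass
class QcReport:
    """Per-stage removal accounting; counts are conserved at every stage."""

    input_variants: int
    stages: list = field(default_factory=list)  # (stage, removed, remaining)
    input_participants: int = 0
    participants_removed: int = 0

    @property
    def surviving_variants(self) -> int:
        return self.stages[-1][2] if self.stages else self.input_variants

    def add_stage(self, name: str, removed: int) -> None:
        prev = self.surviving_variants
        self.stages.append((name, removed, prev - removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "removed", "remaining"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more likely than the observed one (the
    standard exact formulation).  Monomorphic input returns 1.0.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("total genotype count must be positive")
    nm = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)
    if nm == 0:
        return 1.0
    hs = np.arange(nm % 2, min(nm, 2 * n - nm) + 1, 2)
    n_rare_hom = (nm - hs) // 2
    n_common_hom = n - n_rare_hom - hs
    logp = (hs * np.log(2.0)
            - gammaln(n_rare_hom + 1) - gammaln(hs + 1) - gammaln(n_common_hom + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """1-df chi-squared Hardy-Weinberg test (offered as an alternative)."""
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_hom_major + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# per-variant statistics
# ---------------------------------------------------------------------------

def compute_variant_stats(genotypes: GenotypeMatrix, hwe_method: str = "exact") -> pd.DataFrame:
    """Per-variant MAF, call rate, HWE p and Rsq over the current sample.

    MAF uses the allele frequency over non-missing calls; a variant with all
    calls missing gets NaN MAF and zero call rate (and is removed by the
    call-rate filter).  HWE is computed on all participants pooled.
    """
    d = genotypes.dosages
    n_total = genotypes.n_participants
    present = ~np.isnan(d)
    n_called = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(d, axis=0) / (2 * np.maximum(n_called, 1))
    p_alt = np.where(n_called > 0, p_alt, np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)
    call_rate = n_called / n_total if n_total else np.zeros_like(n_called, dtype=float)

    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    test = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test
    hwe_p = np.array([
        test(int(a), int(b), int(c)) if (a + b + c) > 0 else np.nan
        for a, b, c in zip(n0, n1, n2)
    ])
    stats = pd.DataFrame({
        "maf": maf,
        "call_rate": call_rate,
        "hwe_p": hwe_p,
        "rsq": genotypes.variants["rsq"].to_numpy(),
    }, index=genotypes.variant_ids)
    return stats


def filter_participants(genotypes: GenotypeMatrix, min_call_rate: float = 0.90) -> pd.Index:
    """Participant ids whose genotype call rate meets the threshold."""
    if genotypes.n_variants == 0:
        return genotypes.participants
    rate = (~genotypes.missing_mask).mean(axis=1)
    return genotypes.participants[rate >= min_call_rate]


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_variants_to_genes(variants: pd.DataFrame, annotation: pd.DataFrame,
                             max_distance: int = 5000) -> pd.DataFrame:
    """Assign each variant to its nearest gene (1-based inclusive intervals).

    Returns a frame indexed like ``variants`` with ``assigned_gene`` (NaN if
    excluded), ``distance`` (0 inside a gene) and ``excluded``.  Variants
    more than ``max_distance`` bp from every gene are intergenic and
    excluded; equidistant ties go to the gene earlier in sorted order.
    Variants on chromosomes absent from the annotation are excluded with a
    warning.
    """
    out = pd.DataFrame(index=variants.index,
                       data={"assigned_gene": pd.Series(np.nan, index=variants.index, dtype=object),
                             "distance": np.iinfo(np.int64).max,
                             "excluded": True})
    ann = annotation.sort_values(["chrom", "start"])
    missing_chroms = set(variants["chrom"].astype(str)) - set(ann["chrom"].astype(str))
    if missing_chroms:
        warnings.warn(f"variants on chromosomes without annotation: {sorted(missing_chroms)}",
                      stacklevel=2)
    for chrom, genes in ann.groupby("chrom", sort=False):
        sel = variants["chrom"].astype(str) == str(chrom)
        if not sel.any():
            continue
        pos = variants.loc[sel, "pos"].to_numpy(dtype=np.int64)
        starts = genes["start"].to_numpy(dtype=np.int64)
        ends = genes["end"].to_numpy(dtype=np.int64)
        names = genes["gene"].to_numpy()

        idx_prev = np.searchsorted(starts, pos, side="right") - 1
        has_prev = idx_prev >= 0
        dist_prev = np.full(len(pos), np.iinfo(np.int64).max)
        ip = np.clip(idx_prev, 0, None)
        inside = has_prev & (pos <= ends[ip])
        dist_prev[has_prev] = np.maximum(pos[has_prev] - ends[ip[has_prev]], 0)
        idx_next = idx_prev + 1
        has_next = idx_next < len(starts)
        dist_next = np.full(len(pos), np.iinfo(np.int64).max)
        inx = np.clip(idx_next, None, len(starts) - 1)
        dist_next[has_next] = starts[inx[has_next]] - pos[has_next]

        # tie at equal distance -> earlier gene (prev) wins
        use_prev = has_prev & (dist_prev <= dist_next)
        best_idx = np.where(use_prev, ip, inx)
        best_dist = np.where(use_prev, dist_prev, dist_next)
        best_dist = np.where(inside, 0, best_dist)
        keep = best_dist <= max_distance
        out.loc[sel, "distance"] = best_dist
        gene_col = np.where(keep, names[best_idx], None)
        out.loc[sel, "assigned_gene"] = gene_col
        out.loc[sel, "excluded"] = ~keep
    return out


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def apply_variant_filters(stats: pd.DataFrame, thresholds: QcThresholds | None = None,
                          gene_assignment: pd.DataFrame | None = None,
                          order=DEFAULT_FILTER_ORDER) -> tuple[pd.Index, QcReport]:
    """Apply the variant filter chain; returns (kept ids, report).

    Predicates (a NaN statistic fails its filter):
    call_rate >= snp_call_rate_min, maf >= maf_min, hwe_p >= hwe_p_min,
    rsq >= rsq_min, and (when a gene assignment is supplied) not intergenic.
    Stage order only affects per-stage counts, never the surviving set.
    """
    thresholds = thresholds or QcThresholds()
    preds = {
        "call_rate": stats["call_rate"].to_numpy() >= thresholds.snp_call_rate_min,
        "maf": np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0) >= thresholds.maf_min,
        "hwe": np.nan_to_num(stats["hwe_p"].to_numpy(), nan=-1.0) >= thresholds.hwe_p_min,
        "rsq": np.nan_to_num(stats["rsq"].to_numpy(), nan=-1.0) >= thresholds.rsq_min,
    }
    if gene_assignment is not None:
        ga = gene_assignment.reindex(stats.index)
        preds["gene_distance"] = ~ga["excluded"].fillna(True).to_numpy()
    report = QcReport(input_variants=len(stats))
    alive = np.ones(len(stats), dtype=bool)
    for stage in order:
        if stage not in preds:
            continue
        removed = int((alive & ~preds[stage]).sum())
        alive &= preds[stage]
        report.add_stage(stage, removed)
    return stats.index[alive], report


@dataclass
class QcResult:
    genotypes: GenotypeMatrix
    stats: pd.DataFrame
    gene_assignment: pd.DataFrame
    report: QcReport


def run_qc(genotypes: GenotypeMatrix, annotation: pd.DataFrame | None = None,
           thresholds: QcThresholds | None = None, hwe_method: str = "exact") -> QcResult:
    """Full QC pass: participant filter, then variant stats and filters.

    MAF and the other variant statistics are recomputed after participant
    filtering so the filters reflect the analysis sample.
    """
    thresholds = thresholds or QcThresholds()
    kept_participants = filter_participants(genotypes, thresholds.participant_call_rate_min)
    n_removed = genotypes.n_participants - len(kept_participants)
    gt = genotypes.subset(participants=kept_participants) if n_removed else genotypes
    stats = compute_variant_stats(gt, hwe_method=hwe_method)
    assignment = None
    if annotation is not None:
        assignment = assign_variants_to_genes(gt.variants, annotation,
                                              thresholds.max_gene_distance)
        stats = stats.join(assignment[["assigned_gene", "distance"]])
    kept, report = apply_variant_filters(stats, thresholds, gene_assignment=assignment)
    report.input_participants = genotypes.n_participants
    report.participants_removed = n_removed
    gt = gt.subset(variants=kept)
    # carry the recomputed sample MAF on the surviving variants
    gt.variants = gt.variants.assign(maf=stats.loc[kept, "maf"].to_numpy())
    return QcResult(gt, stats, assignment if assignment is not None else pd.DataFrame(),
                    report)
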