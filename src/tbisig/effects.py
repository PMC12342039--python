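"""Effect-size binning, top-centile gene extraction, and overlap summaries.

Standardized coefficient magnitudes are binned at the conventional
small/medium/large landmarks into <0.2, [0.2, 0.3), [0.3, 0.4), [0.4, 0.5)
and >=0.5.  For the interaction model the binned magnitude of a variant is
the larger absolute value of its two variant-by-group coefficients; for the
TBI-only model it is the absolute main-effect coefficient.  A gene is
counted in every bin where it has at least one variant, so gene columns are
not a partition — only the SNP columns conserve the analyzed total.
"""

from __future__ import annotations

import itertools
import math
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssociationResults

BIN_EDGES = (0.2, 0.3, 0.4, 0.5)
BIN_LABELS = ("<0.2", "0.2", "0.3", "0.4", "0.5")  # "0.2" means [0.2, 0.3) etc.
#: Table-style row order: thresholds first, sub-small last
BIN_ROW_ORDER = ("0.2", "0.3", "0.4", "0.5", "<0.2")


def _unpack(results):
    """(frame, model, p-value column) from AssociationResults or DataFrame."""
    if isinstance(results, AssociationResults):
        return results.frame, results.model, results.hit_pvalue_column
    frame = results
    model = frame["model"].iloc[0] if len(frame) else "interaction"
    return frame, model, ("p_joint" if model == "interaction" else "p")


def effect_magnitudes(results, per_term: str | None = None) -> pd.Series:
    """Per-variant binned magnitude.

    For the interaction model, the max absolute value over the two
    variant-by-group coefficients (``per_term`` = "moderate"/"severe"
    forces one term); for the TBI-only model, the absolute main effect.
    """
    frame, model, _ = _unpack(results)
    if model == "interaction":
        if per_term is not None:
            return frame[f"beta_int_{per_term}"].abs()
        return pd.concat([frame["beta_int_moderate"].abs(),
                          frame["beta_int_severe"].abs()], axis=1).max(axis=1)
    return frame["beta"].abs()


def _bin_index(mag: np.ndarray) -> np.ndarray:
    """0 = <0.2; 1..4 = left-closed bins at 0.2 / 0.3 / 0.4 / >=0.5."""
    return np.searchsorted(BIN_EDGES, mag, side="right")


@dataclass
class EffectBinTable:
    """SNP and distinct-gene counts per effect-size magnitude bin."""

    table: pd.DataFrame        # index = bin labels; columns snps, genes
    total_snps: int
    total_genes: int
    n_unestimable: int
    model: str

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["Total"] = [self.total_snps, self.total_genes]
        return out


def bin_effect_sizes(results, per_term: str | None = None) -> EffectBinTable:
    """Bin every estimable variant by standardized effect magnitude.

    Each SNP lands in exactly one bin (SNP counts sum to the analyzed
    total); a gene is counted once per bin in which it has a SNP.
    Unestimable fits are excluded and reported separately.
    """
    frame, model, _ = _unpack(results)
    est = frame[frame["estimable"].astype(bool)] if len(frame) else frame
    n_unest = len(frame) - len(est)
    mag = effect_magnitudes(est, per_term) if len(est) else pd.Series(dtype=float)
    bins = _bin_index(mag.to_numpy()) if len(est) else np.array([], dtype=int)
    snp_counts = np.bincount(bins, minlength=5)
    genes = est["gene"] if "gene" in est.columns else pd.Series(index=est.index, dtype=object)
    gene_counts = np.array([genes[bins == b].dropna().nunique() for b in range(5)])
    order = [BIN_LABELS.index(lab) for lab in BIN_ROW_ORDER]
    table = pd.DataFrame(
        {"snps": snp_counts[order], "genes": gene_counts[order]},
        index=pd.Index(BIN_ROW_ORDER, name="effect_size"))
    return EffectBinTable(table, int(snp_counts.sum()),
                          int(genes.dropna().nunique()), int(n_unest), model)


def top_centile_genes(results, centile: float = 5.0) -> set:
    """Genes of the variants in the top ``centile`` % of effect magnitudes.

    Variants are ranked by magnitude descending, ties broken by smaller
    p-value then variant id (deterministic); the top ceil(centile/100 * m)
    variants are taken and their distinct genes returned.  Without a gene
    column the variant ids themselves are returned.
    """
    frame, _, pcol = _unpack(results)
    est = frame[frame["estimable"].astype(bool)] if len(frame) else frame
    m = len(est)
    if m == 0:
        return set()
    mag = effect_magnitudes(est)
    order = pd.DataFrame({
        "mag": -mag.to_numpy(),
        "p": est[pcol].to_numpy(),
        "vid": est.index.to_numpy(),
    }, index=est.index).sort_values(["mag", "p", "vid"], kind="mergesort")
    top = order.index[: math.ceil(centile / 100.0 * m)]
    if "gene" not in est.columns:
        return set(top)
    return set(est.loc[top, "gene"].dropna())


@dataclass
class OverlapSummary:
    """Venn-region sizes over named gene sets.

    ``regions`` has one row per subset of set names with both the plain
    intersection size and the exclusive (Venn-region) size; exclusive sizes
    satisfy inclusion-exclusion against the intersections exactly.
    """

    set_sizes: dict
    regions: pd.DataFrame
    common_all: int

    def to_frame(self) -> pd.DataFrame:
        return self.regions.copy()


def overlap_table(gene_sets) -> OverlapSummary:
    """All 2^k - 1 intersection / exclusive-region sizes for named sets.

    Accepts a mapping name -> set or an iterable of (name, set) pairs.
    """
    pairs = list(gene_sets.items()) if isinstance(gene_sets, dict) else list(gene_sets)
    names = [nm for nm, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    if not names:
        raise ValueError("no gene sets given")
    gene_sets = dict(pairs)
    universe = set().union(*gene_sets.values())
    membership = {g: frozenset(nm for nm in names if g in gene_sets[nm]) for g in universe}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            inter = sum(1 for pat in membership.values() if key <= pat)
            excl = sum(1 for pat in membership.values() if key == pat)
            rows.append({"sets": "&".join(combo), "degree": r,
                         "intersection": inter, "exclusive": excl})
    regions = pd.DataFrame(rows)
    common = len(set.intersection(*map(set, gene_sets.values())))
    return OverlapSummary({nm: len(s) for nm, s in gene_sets.items()}, regions, common)


def export_gene_lists(gene_sets: dict, directory) -> dict:
    """Write one plain-text symbol-per-line file per set (uppercased,
    deduplicated, sorted) for use with external pathway-enrichment tools."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, genes in gene_sets.items():
        path = directory / f"{name}.txt"
        symbols = sorted({str(g).upper() for g in genes})
        path.write_text("".join(s + "\n" for s in symbols))
        paths[name] = path
    return paths


def read_gene_list(path) -> set:
    return {line.strip() for line in pathlib.Path(path).read_text().splitlines()
            if line.strip()}
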