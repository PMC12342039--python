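"""Core in-memory containers shared across the pipeline.

Genotypes live in a dense participants x variants dosage matrix (float64,
NaN marks a missing call) with a variant-metadata DataFrame alongside;
phenotypes are a plain pandas DataFrame indexed by participant id. The gene
ranking bundles the training genes, the systems-biology-ranked case genes,
and the control gene pool together with the gene -> variant expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_LEVELS = ("OI", "moderate", "severe")

#: columns every variant-metadata frame carries
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "maf", "rsq")


@dataclass
class GenotypeMatrix:
    """Participants x variants additive-dosage matrix.

    Parameters
    ----------
    dosages : ndarray, shape (n_participants, n_variants)
        Count of the alternate allele in {0, 1, 2}; NaN encodes a missing
        call.
    participants : pd.Index
        Participant identifiers (rows).
    variants : pd.DataFrame
        Variant metadata indexed by variant id with at least the columns
        ``chrom, pos, ref, alt, maf, rsq``.  ``maf`` records the generating
        (or otherwise known) minor-allele frequency; empirical frequencies
        are recomputed by :mod:`tbisig.qc`.
    """

    dosages: np.ndarray
    participants: pd.Index
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.participants = pd.Index(self.participants)
        if self.dosages.shape != (len(self.participants), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.participants)} participants x {len(self.variants)} variants"
            )
        if self.variants.index.has_duplicates:
            raise ValueError("duplicate variant ids")
        if self.participants.has_duplicates:
            raise ValueError("duplicate participant ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a call is missing."""
        return np.isnan(self.dosages)

    # -- subsetting -----------------------------------------------------
    def subset(self, participants=None, variants=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given ids (order preserved)."""
        rows = slice(None)
        part = self.participants
        if participants is not None:
            part = pd.Index(participants)
            rows = self.participants.get_indexer(part)
            if (np.asarray(rows) < 0).any():
                missing = part[np.asarray(rows) < 0]
                raise KeyError(f"unknown participants: {list(missing)[:5]}")
        var_meta = self.variants
        cols = slice(None)
        if variants is not None:
            vids = pd.Index(variants)
            cols = self.variants.index.get_indexer(vids)
            if (np.asarray(cols) < 0).any():
                missing = vids[np.asarray(cols) < 0]
                raise KeyError(f"unknown variants: {list(missing)[:5]}")
            var_meta = self.variants.loc[vids]
        dos = self.dosages[rows][:, cols] if variants is not None else self.dosages[rows]
        return GenotypeMatrix(np.array(dos, copy=True), part, var_meta.copy())


@dataclass
class GeneSetRanking:
    """Training genes, ranked case genes, and the control gene pool.

    ``ranked_genes`` is ordered by systems-biology rank (best first,
    rank 1 = index 0) and excludes the training genes; ``control_genes``
    is disjoint from both.  ``gene_to_variants`` expands a gene symbol into
    the variant ids assigned to it (post-QC when built by the pipeline).
    """

    training_genes: list
    ranked_genes: list
    control_genes: list
    gene_to_variants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        case = set(self.training_genes) | set(self.ranked_genes)
        if case & set(self.control_genes):
            raise ValueError("control genes overlap case/training genes")
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError("duplicate ranked genes")

    @property
    def n_ranked(self) -> int:
        return len(self.ranked_genes)

    def rank_percentile(self, gene) -> float:
        """Percentile position of a ranked gene (rank / n_ranked * 100)."""
        rank = self.ranked_genes.index(gene) + 1
        return 100.0 * rank / self.n_ranked

    def variants_of(self, genes) -> list:
        out = []
        for g in genes:
            out.extend(self.gene_to_variants.get(g, ()))
        return out

    def restrict_variants(self, keep_ids) -> "GeneSetRanking":
        """Return a copy whose gene->variant map keeps only ``keep_ids``."""
        keep = set(keep_ids)
        g2v = {g: [v for v in vs if v in keep] for g, vs in self.gene_to_variants.items()}
        return GeneSetRanking(
            list(self.training_genes), list(self.ranked_genes),
            list(self.control_genes), g2v,
        )


def validate_phenotypes(pheno: pd.DataFrame, outcomes=()) -> pd.DataFrame:
    """Check the phenotype table contract and normalise dtypes.

    Requires columns ``age, sex, group`` (plus any outcome columns named);
    ``pc1`` is optional (the pipeline computes it from genotypes when
    absent).  ``sex`` is coerced to {0, 1}, ``group`` must take values in
    ``GROUP_LEVELS``.
    """
    pheno = pheno.copy()
    required = ["age", "sex", "group", *outcomes]
    for col in required:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    bad = set(pheno["group"].unique()) - set(GROUP_LEVELS)
    if bad:
        raise ValueError(f"unknown injury group labels: {sorted(bad)}")
    pheno["sex"] = pheno["sex"].astype(int)
    if not pheno["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0/1")
    return pheno
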