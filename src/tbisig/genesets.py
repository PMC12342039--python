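"""Centile-epoch case gene sets and MAF-band-matched control draws.

Case gene sets are built at nested "centile epochs": epoch 0 is the
training genes alone, epoch e adds the top e% of the systems-biology-ranked
case genes (cumulative mode), while incremental mode keeps only the slice
added between consecutive epochs.  The permutation null draws control-pool
variants matched exactly, band by band, to the case set's minor-allele-
frequency profile over the bands [0.10, 0.15), [0.15, 0.20), [0.20, 0.30),
[0.30, 0.50].
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetRanking

#: MAF band edges: left-closed, final band closed on both ends
MAF_BAND_EDGES = (0.10, 0.15, 0.20, 0.30, 0.50)
N_BANDS = len(MAF_BAND_EDGES) - 1
BAND_LABELS = tuple(
    f"[{lo:.2f},{hi:.2f}{']' if i == N_BANDS - 1 else ')'}"
    for i, (lo, hi) in enumerate(zip(MAF_BAND_EDGES, MAF_BAND_EDGES[1:]))
)


def assign_maf_band(maf: float) -> int:
    """1-based MAF band index; errors outside [0.10, 0.50] (a QC violation)."""
    if not (MAF_BAND_EDGES[0] <= maf <= MAF_BAND_EDGES[-1]):
        raise ValueError(f"MAF {maf} outside post-QC range "
                         f"[{MAF_BAND_EDGES[0]}, {MAF_BAND_EDGES[-1]}]")
    if maf == MAF_BAND_EDGES[-1]:
        return N_BANDS
    return int(np.searchsorted(MAF_BAND_EDGES, maf, side="right"))


def assign_maf_bands(mafs) -> np.ndarray:
    """Vectorized :func:`assign_maf_band`."""
    m = np.asarray(mafs, dtype=float)
    if ((m < MAF_BAND_EDGES[0]) | (m > MAF_BAND_EDGES[-1])).any():
        bad = m[(m < MAF_BAND_EDGES[0]) | (m > MAF_BAND_EDGES[-1])]
        raise ValueError(f"MAF outside post-QC range: {bad[:5]}")
    bands = np.searchsorted(MAF_BAND_EDGES, m, side="right")
    return np.where(m == MAF_BAND_EDGES[-1], N_BANDS, bands).astype(int)


def maf_band_profile(variant_ids, maf: pd.Series) -> np.ndarray:
    """Counts of variants per MAF band (length ``N_BANDS``)."""
    bands = assign_maf_bands(maf.loc[list(variant_ids)].to_numpy())
    return np.bincount(bands - 1, minlength=N_BANDS)


@dataclass
class EpochSet:
    """One case gene set at a centile epoch."""

    percent: int
    mode: str                 # "cumulative" | "incremental"
    genes: set
    variants: list

    @property
    def label(self) -> str:
        return f"{self.mode}_{self.percent}"

    def profile(self, maf: pd.Series) -> np.ndarray:
        return maf_band_profile(self.variants, maf)


def top_k(percent: float, n_ranked: int) -> int:
    """Number of ranked genes inside the top ``percent``: ceil(pct/100 * n)."""
    return math.ceil(percent / 100.0 * n_ranked)


def build_epochs(ranking: GeneSetRanking, step_percent: int = 5,
                 surviving_variants=None) -> list:
    """Build cumulative and incremental epoch sets at 0, step, ..., 100%.

    ``surviving_variants``, when given, restricts the gene -> variant
    expansion to post-QC variants.  Cumulative sets nest; incremental sets
    (epochs > 0) are pairwise disjoint and, united, give exactly the ranked
    genes; incremental epoch 0 is the training set.
    """
    if len(ranking.training_genes) < 1:
        raise ValueError("ranking must include at least one training gene")
    if step_percent <= 0 or 100 % step_percent != 0:
        raise ValueError("step_percent must divide 100")
    keep = set(surviving_variants) if surviving_variants is not None else None

    def expand(genes):
        vs = ranking.variants_of(sorted(genes))
        return [v for v in vs if v in keep] if keep is not None else list(vs)

    epochs = []
    training = set(ranking.training_genes)
    prev_genes = set()
    percents = [0] + ([] if not ranking.ranked_genes
                      else list(range(step_percent, 101, step_percent)))
    for pct in percents:
        ranked_top = set(ranking.ranked_genes[: top_k(pct, ranking.n_ranked)])
        cum_genes = training | ranked_top
        inc_genes = training if pct == 0 else (ranked_top - prev_genes)
        epochs.append(EpochSet(pct, "cumulative", cum_genes, expand(cum_genes)))
        epochs.append(EpochSet(pct, "incremental", inc_genes, expand(inc_genes)))
        prev_genes = ranked_top
    return epochs


@dataclass
class ControlDraw:
    """One matched control variant set."""

    index: int
    seed_key: tuple
    variant_ids: list
    band_counts: np.ndarray


def _draw_rng(master_seed: int, epoch_label: str, draw_index: int) -> np.random.Generator:
    """Counter-based per-draw stream: (master seed, epoch label, draw)."""
    key = zlib.crc32(epoch_label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(key, draw_index)))


def _pool_by_band(control_variants, maf: pd.Series):
    ids = np.asarray(list(control_variants), dtype=object)
    bands = assign_maf_bands(maf.loc[list(ids)].to_numpy())
    return [ids[bands == b + 1] for b in range(N_BANDS)]


def check_pool(case_profile: np.ndarray, pool_by_band) -> None:
    for b, (need, have) in enumerate(zip(case_profile, pool_by_band)):
        if len(have) < need:
            raise ValueError(
                f"control pool deficient in MAF band {BAND_LABELS[b]}: "
                f"need {need}, have {len(have)}")


def iter_control_draws(case_epoch: EpochSet, control_variants, maf: pd.Series,
                       n_draws: int = 10_000, seed: int = 0):
    """Yield matched control draws for one case epoch.

    Each draw samples, without replacement and independently within each
    MAF band, exactly the case set's per-band count from the control pool.
    Draw ``d`` depends only on (seed, epoch label, d).
    """
    case_profile = case_epoch.profile(maf)
    pool = _pool_by_band(control_variants, maf)
    check_pool(case_profile, pool)
    for d in range(n_draws):
        rng = _draw_rng(seed, case_epoch.label, d)
        picked = []
        for b in range(N_BANDS):
            k = int(case_profile[b])
            if k:
                idx = rng.choice(len(pool[b]), size=k, replace=False)
                picked.append(pool[b][idx])
        ids = np.concatenate(picked) if picked else np.array([], dtype=object)
        yield ControlDraw(d, (seed, case_epoch.label, d), list(ids), case_profile.copy())


def draw_control_sets(case_epoch: EpochSet, control_variants, maf: pd.Series,
                      n_draws: int = 10_000, seed: int = 0) -> list:
    """Materialized list form of :func:`iter_control_draws`."""
    return list(iter_control_draws(case_epoch, control_variants, maf, n_draws, seed))
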