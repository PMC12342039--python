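"""Permutation gene-set enrichment across centile epochs.

For each case epoch the number of nominally associated variants
(p < 0.05, uncorrected) is compared with the distribution of the same count
over MAF-matched control draws; the case set is called *enriched* when its
hit count strictly exceeds the 95th percentile of the permutation null.
The empirical p-value uses the (r + 1) / (B + 1) estimator, so it can never
be exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssociationResults
from .genesets import (EpochSet, _draw_rng, _pool_by_band, build_epochs,
                       check_pool, N_BANDS)

DEFAULT_ALPHA = 0.05
DEFAULT_N_DRAWS = 10_000


def count_nominal_hits(variant_ids, results, alpha: float = DEFAULT_ALPHA) -> int:
    """Count listed variants with an estimable model and p < alpha (strict).

    ``results`` is an :class:`AssociationResults` (its model picks the
    p-value column) or a DataFrame with ``p``/``estimable`` columns.  A
    variant id absent from the results is a pipeline-ordering bug and
    raises.
    """
    if isinstance(results, AssociationResults):
        frame, pcol = results.frame, results.hit_pvalue_column
    else:
        frame, pcol = results, "p"
    ids = pd.Index(variant_ids)
    pos = frame.index.get_indexer(ids)
    if (pos < 0).any():
        missing = ids[pos < 0]
        raise KeyError(f"variants absent from association results: {list(missing)[:5]}")
    p = frame[pcol].to_numpy()[pos]
    ok = frame["estimable"].to_numpy()[pos]
    with np.errstate(invalid="ignore"):
        return int((ok & (p < alpha)).sum())


def percentile95(null_counts: np.ndarray) -> int:
    """Type-1 discrete 95th percentile: smallest v with >= 95% of draws <= v."""
    s = np.sort(np.asarray(null_counts))
    idx = math.ceil(0.95 * len(s)) - 1
    return int(s[idx])


def enrichment_test(case_hits: int, null_hit_counts) -> dict:
    """Compare a case hit count against its permutation null.

    Returns percentile95, the strict-exceedance enrichment flag, the
    add-one-smoothed empirical p, and the box-and-whisker summary of the
    null (min, q1, median, q3, upper whisker, max).
    """
    null = np.asarray(list(null_hit_counts))
    if null.size == 0:
        raise ValueError("null hit-count distribution is empty")
    p95 = percentile95(null)
    b = null.size
    q1, med, q3 = np.percentile(null, [25, 50, 75])
    upper = null[null <= q3 + 1.5 * (q3 - q1)]
    return {
        "case_hits": int(case_hits),
        "n_draws": int(b),
        "percentile95": p95,
        "enriched": bool(case_hits > p95),
        "empirical_p": (int((null >= case_hits).sum()) + 1) / (b + 1),
        "null_min": int(null.min()),
        "null_q1": float(q1),
        "null_median": float(med),
        "null_q3": float(q3),
        "null_whisker_high": int(upper.max()) if upper.size else int(null.max()),
        "null_max": int(null.max()),
    }


def run_epoch_scan(results_map: dict, epochs, control_variants, maf: pd.Series,
                   n_draws: int = DEFAULT_N_DRAWS, seed: int = 0,
                   alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Enrichment test per epoch x mode for every result set in ``results_map``.

    ``results_map`` maps a name (e.g. ``("cbcl", "interaction")``) to an
    :class:`AssociationResults`; all result sets share the control draws of
    each epoch, which are identical to :func:`tbisig.genesets.iter_control_draws`
    under the same seed.  Returns a tidy frame, one row per name x epoch x
    mode, shaped like the cumulative/incremental enrichment readout (case
    dot plus null box-whisker summary).
    """
    names = list(results_map)
    # per result set: aligned hit indicator over its own index
    hit_arrays, indexes = {}, {}
    for name in names:
        res = results_map[name]
        f = res.frame
        with np.errstate(invalid="ignore"):
            hits = (f["estimable"].to_numpy()
                    & (f[res.hit_pvalue_column].to_numpy() < alpha))
        hit_arrays[name] = hits
        indexes[name] = f.index

    ctrl_ids = list(control_variants)
    pools = _pool_by_band(ctrl_ids, maf)
    # positions of each band's pool in each result frame (validates presence)
    pool_pos = {}
    for name in names:
        pos_bands = []
        for band in pools:
            pos = indexes[name].get_indexer(pd.Index(band))
            if (pos < 0).any():
                raise KeyError(f"control variants absent from results {name!r}")
            pos_bands.append(pos)
        pool_pos[name] = pos_bands

    rows = []
    for ep in epochs:
        profile = ep.profile(maf)
        check_pool(profile, pools)
        case_hits = {name: count_nominal_hits(ep.variants, results_map[name], alpha)
                     for name in names}
        null = {name: np.empty(n_draws, dtype=int) for name in names}
        for d in range(n_draws):
            rng = _draw_rng(seed, ep.label, d)
            picks = [rng.choice(len(pools[b]), size=int(profile[b]), replace=False)
                     if profile[b] else None for b in range(N_BANDS)]
            for name in names:
                total = 0
                hits = hit_arrays[name]
                for b, idx in enumerate(picks):
                    if idx is not None:
                        total += int(hits[pool_pos[name][b][idx]].sum())
                null[name][d] = total
        for name in names:
            row = {"name": name if isinstance(name, str) else "/".join(name),
                   "epoch": ep.percent, "mode": ep.mode,
                   "case_variants": len(ep.variants)}
            row.update(enrichment_test(case_hits[name], null[name]))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResults:
    """Results object for an epoch enrichment scan."""

    frame: pd.DataFrame
    alpha: float
    n_draws: int
    seed: int

    def summary(self) -> str:
        f = self.frame
        lines = [f"Epoch enrichment scan (alpha={self.alpha}, B={self.n_draws})"]
        for name, sub in f.groupby("name"):
            for mode, ss in sub.groupby("mode"):
                enriched = ss.loc[ss["enriched"], "epoch"].tolist()
                lines.append(f"  {name} [{mode}]: enriched epochs {enriched or 'none'}")
        return "\n".join(lines)

    def enriched_epochs(self, name=None, mode: str = "cumulative") -> list:
        f = self.frame
        if name is not None:
            label = name if isinstance(name, str) else "/".join(name)
            f = f[f["name"] == label]
        f = f[f["mode"] == mode]
        return f.loc[f["enriched"], "epoch"].tolist()

    def plot(self, name=None, mode: str = "cumulative", ax=None):
        """Box-and-whisker of the null per epoch with the case count as a dot."""
        import matplotlib.pyplot as plt

        f = self.frame
        if name is not None:
            label = name if isinstance(name, str) else "/".join(name)
            f = f[f["name"] == label]
        f = f[f["mode"] == mode].sort_values("epoch")
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(f))
        for i, (_, row) in enumerate(f.iterrows()):
            ax.vlines(i, row["null_min"], row["null_max"], color="0.6", lw=1)
            ax.add_patch(plt.Rectangle((i - 0.2, row["null_q1"]), 0.4,
                                       row["null_q3"] - row["null_q1"],
                                       fill=True, color="0.8"))
            ax.hlines(row["null_median"], i - 0.2, i + 0.2, color="0.3")
        ax.plot(x, f["case_hits"], "o", color="C3", label="case genes")
        ax.set_xticks(x, f["epoch"].astype(str))
        ax.set_xlabel("centile epoch (%)")
        ax.set_ylabel(f"variants with p < {self.alpha}")
        ax.set_title(f"{mode} enrichment")
        ax.legend()
        return ax


class EnrichmentScan:
    """Model object: permutation enrichment of association hits in ranked
    case genes against MAF-matched control draws.

    Parameters
    ----------
    results_map : dict name -> AssociationResults (or one AssociationResults)
    ranking : GeneSetRanking with the post-QC gene -> variant expansion
    maf : Series variant id -> post-QC minor allele frequency
    alpha : nominal significance threshold (default 0.05)
    """

    def __init__(self, results_map, ranking, maf: pd.Series,
                 alpha: float = DEFAULT_ALPHA):
        if isinstance(results_map, AssociationResults):
            r = results_map
            results_map = {(r.spec.outcome, r.model): r}
        self.results_map = results_map
        self.ranking = ranking
        self.maf = maf
        self.alpha = alpha

    def fit(self, step_percent: int = 5, n_draws: int = DEFAULT_N_DRAWS,
            seed: int = 0, epochs=None, modes=("cumulative", "incremental")) -> EnrichmentResults:
        if epochs is None:
            any_res = next(iter(self.results_map.values()))
            surviving = any_res.frame.index
            epochs = build_epochs(self.ranking, step_percent, surviving_variants=surviving)
        epochs = [ep for ep in epochs if ep.mode in modes]
        control_variants = [
            v for v in self.ranking.variants_of(self.ranking.control_genes)
            if v in self.maf.index
        ]
        frame = run_epoch_scan(self.results_map, epochs, control_variants,
                               self.maf, n_draws=n_draws, seed=seed, alpha=self.alpha)
        return EnrichmentResults(frame, self.alpha, n_draws, seed)
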