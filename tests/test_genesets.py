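"""Epoch construction, MAF banding, and matched control draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tbisig.containers import GeneSetRanking
from tbisig.genesets import (EpochSet, N_BANDS, assign_maf_band, assign_maf_bands,
                             build_epochs, draw_control_sets, iter_control_draws,
                             maf_band_profile, top_k)


@pytest.fixture()
def ranking():
    training = [f"T{i}" for i in range(3)]
    ranked = [f"R{i:03d}" for i in range(100)]
    control = [f"C{i:03d}" for i in range(50)]
    g2v = {g: [f"{g}:v{j}" for j in range(2)] for g in training + ranked + control}
    return GeneSetRanking(training, ranked, control, g2v)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def test_cumulative_epochs_nest_and_match_top_percent(ranking):
    epochs = build_epochs(ranking, step_percent=5)
    cum = {e.percent: e for e in epochs if e.mode == "cumulative"}
    assert cum[0].genes == set(ranking.training_genes)
    # 5% of 100 ranked genes -> training + 5
    assert cum[5].genes == set(ranking.training_genes) | set(ranking.ranked_genes[:5])
    for lo, hi in zip(sorted(cum), sorted(cum)[1:]):
        assert cum[lo].genes <= cum[hi].genes
    assert cum[100].genes == set(ranking.training_genes) | set(ranking.ranked_genes)


def test_incremental_epochs_partition_ranked_genes(ranking):
    epochs = build_epochs(ranking, step_percent=10)
    inc = [e for e in epochs if e.mode == "incremental" and e.percent > 0]
    union = set()
    for e in inc:
        assert not (e.genes & union), "incremental slices must be disjoint"
        union |= e.genes
    assert union == set(ranking.ranked_genes)
    inc0 = next(e for e in epochs if e.mode == "incremental" and e.percent == 0)
    assert inc0.genes == set(ranking.training_genes)


def test_top_k_uses_ceiling():
    assert top_k(5, 100) == 5
    assert top_k(5, 101) == 6
    assert top_k(1, 30) == 1


def test_epoch_variant_expansion_respects_qc_survivors(ranking):
    surviving = {f"R000:v0", f"T0:v1"}
    epochs = build_epochs(ranking, step_percent=50, surviving_variants=surviving)
    cum50 = next(e for e in epochs if e.mode == "cumulative" and e.percent == 50)
    assert set(cum50.variants) == surviving


def test_empty_ranked_list_gives_only_epoch_zero():
    rk = GeneSetRanking(["T0"], [], ["C0"], {"T0": ["T0:v0"], "C0": ["C0:v0"]})
    epochs = build_epochs(rk, step_percent=5)
    assert {e.percent for e in epochs} == {0}


def test_step_must_divide_100(ranking):
    with pytest.raises(ValueError, match="divide 100"):
        build_epochs(ranking, step_percent=7)


# ---------------------------------------------------------------------------
# MAF bands
# ---------------------------------------------------------------------------

def test_band_boundaries():
    assert assign_maf_band(0.12) == 1
    assert assign_maf_band(0.15) == 2      # left-closed
    assert assign_maf_band(0.20) == 3
    assert assign_maf_band(0.30) == 4
    assert assign_maf_band(0.50) == 4      # last band closed on the right
    assert assign_maf_band(0.10) == 1
    for bad in (0.05, 0.51):
        with pytest.raises(ValueError, match="outside post-QC range"):
            assign_maf_band(bad)


@given(st.floats(0.10, 0.50))
def test_band_assignment_scalar_vector_agree(maf):
    assert assign_maf_bands([maf])[0] == assign_maf_band(maf)


def test_profile_conserves_counts():
    maf = pd.Series([0.11, 0.16, 0.22, 0.45, 0.12],
                    index=[f"v{j}" for j in range(5)])
    profile = maf_band_profile(maf.index, maf)
    assert profile.sum() == 5
    np.testing.assert_array_equal(profile, [2, 1, 1, 1])


# ---------------------------------------------------------------------------
# control draws
# ---------------------------------------------------------------------------

def _case_and_pool(seed=0, n_pool=120):
    rng = np.random.default_rng(seed)
    case_ids = [f"case:v{j}" for j in range(30)]
    pool_ids = [f"ctrl:v{j}" for j in range(n_pool)]
    maf = pd.Series(rng.uniform(0.10, 0.50, len(case_ids) + len(pool_ids)),
                    index=case_ids + pool_ids)
    epoch = EpochSet(5, "cumulative", {"case"}, case_ids)
    return epoch, pool_ids, maf


def test_draws_match_case_band_profile_exactly():
    epoch, pool, maf = _case_and_pool()
    profile = epoch.profile(maf)
    for draw in draw_control_sets(epoch, pool, maf, n_draws=25, seed=3):
        np.testing.assert_array_equal(maf_band_profile(draw.variant_ids, maf), profile)
        assert set(draw.variant_ids) <= set(pool)
        assert len(set(draw.variant_ids)) == len(draw.variant_ids)  # without replacement


def test_draws_reproducible_from_seed_label_index():
    epoch, pool, maf = _case_and_pool()
    a = draw_control_sets(epoch, pool, maf, n_draws=5, seed=9)
    b = draw_control_sets(epoch, pool, maf, n_draws=5, seed=9)
    for da, db in zip(a, b):
        assert da.variant_ids == db.variant_ids
    # a different epoch label yields different draws under the same seed
    other = EpochSet(10, "cumulative", {"case"}, epoch.variants)
    c = draw_control_sets(other, pool, maf, n_draws=5, seed=9)
    assert any(da.variant_ids != dc.variant_ids for da, dc in zip(a, c))


def test_forced_draw_when_pool_exactly_matches():
    rng = np.random.default_rng(1)
    case_ids = [f"case:v{j}" for j in range(8)]
    pool_ids = [f"ctrl:v{j}" for j in range(8)]
    mafs = rng.uniform(0.10, 0.50, 8)
    maf = pd.Series(np.concatenate([mafs, mafs]), index=case_ids + pool_ids)
    epoch = EpochSet(0, "cumulative", {"case"}, case_ids)
    for draw in draw_control_sets(epoch, pool_ids, maf, n_draws=4, seed=2):
        assert sorted(draw.variant_ids) == sorted(pool_ids)


def test_deficient_band_raises_with_counts():
    case_ids = ["case:v0", "case:v1"]
    pool_ids = ["ctrl:v0"]
    maf = pd.Series([0.12, 0.13, 0.12], index=case_ids + pool_ids)
    epoch = EpochSet(0, "cumulative", {"case"}, case_ids)
    with pytest.raises(ValueError, match="need 2, have 1"):
        next(iter_control_draws(epoch, pool_ids, maf, n_draws=1, seed=0))


def test_within_band_inclusion_is_uniform():
    """Chi-squared goodness of fit over 2,000 draws on a 50-variant band."""
    case_ids = [f"case:v{j}" for j in range(10)]
    pool_ids = [f"ctrl:v{j}" for j in range(50)]
    maf = pd.Series(0.12, index=case_ids + pool_ids)  # everything in band 1
    epoch = EpochSet(0, "cumulative", {"case"}, case_ids)
    counts = {v: 0 for v in pool_ids}
    n_draws = 2000
    for draw in iter_control_draws(epoch, pool_ids, maf, n_draws=n_draws, seed=7):
        for v in draw.variant_ids:
            counts[v] += 1
    observed = np.array(list(counts.values()))
    expected = n_draws * len(case_ids) / len(pool_ids)
    # scale multinomial-style counts to a valid chi-square comparison
    stat = ((observed - expected) ** 2 / expected).sum()
    # inclusion indicators are without-replacement within a draw: variance is
    # slightly below multinomial, so the plain statistic is conservative here
    from scipy.stats import chi2
    assert chi2.sf(stat, len(pool_ids) - 1) > 0.01
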