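"""QC chain: variant statistics, exact HWE test, filters, gene assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from _oracles import hwe_oracle
from tbisig.containers import GenotypeMatrix
from tbisig.qc import (DEFAULT_FILTER_ORDER, QcThresholds, apply_variant_filters,
                       assign_variants_to_genes, compute_variant_stats,
                       filter_participants, hwe_chi2_test, hwe_exact_test, run_qc)


def _matrix(dosage_columns):
    d = np.array(dosage_columns, dtype=float).T
    n, m = d.shape
    meta = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A",
                         "alt": "G", "maf": np.nan, "rsq": 1.0},
                        index=pd.Index([f"v{j}" for j in range(m)], name="variant_id"))
    return GenotypeMatrix(d, [f"P{i}" for i in range(n)], meta)


def test_hwe_matches_enumeration_oracle_on_examples():
    # all-het with equal allele counts, and zero-het extremes
    for counts in [(0, 10, 0), (5, 0, 5), (0, 7, 0), (1, 2, 3), (12, 4, 1)]:
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)
    # monomorphic convention
    assert hwe_exact_test(9, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 4) == 1.0


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
def test_hwe_matches_enumeration_oracle_property(a, b, c):
    if a + b + c == 0:
        return
    assert hwe_exact_test(a, b, c) == pytest.approx(hwe_oracle(a, b, c), abs=1e-10)


def test_hwe_chi2_agrees_with_scipy_formulation():
    from scipy.stats import chi2

    a, b, c = 30, 30, 40
    p_alt = (2 * a + b) / (2 * (a + b + c))
    n = a + b + c
    exp = n * np.array([p_alt ** 2, 2 * p_alt * (1 - p_alt), (1 - p_alt) ** 2])
    stat = (((np.array([a, b, c]) - exp) ** 2) / exp).sum()
    assert hwe_chi2_test(a, b, c) == pytest.approx(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# variant statistics
# ---------------------------------------------------------------------------

def test_variant_stats_hand_counts():
    gt = _matrix([
        [0, 0, 1, 2],                     # alt freq 3/8 -> MAF 0.375
        [0, 0, 0, 0],                     # monomorphic -> MAF 0
        [np.nan, 1, 1, 1],                # 1 missing of 4 -> call rate 0.75
    ])
    stats = compute_variant_stats(gt)
    assert stats.loc["v0", "maf"] == pytest.approx(0.375)
    assert stats.loc["v1", "maf"] == 0.0
    assert stats.loc["v2", "call_rate"] == pytest.approx(0.75)


def test_all_missing_variant_flagged_for_removal():
    gt = _matrix([[np.nan] * 4, [0, 1, 1, 2]])
    stats = compute_variant_stats(gt)
    assert np.isnan(stats.loc["v0", "maf"])
    kept, report = apply_variant_filters(stats, QcThresholds())
    assert "v0" not in kept
    assert report.to_frame().set_index("stage").loc["call_rate", "removed"] == 1


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

@pytest.fixture()
def filter_stats():
    return pd.DataFrame({
        "maf": [0.09, 0.10, 0.30, 0.25, 0.40],
        "call_rate": [1.0, 1.0, 0.94, 1.0, 1.0],
        "hwe_p": [0.5, 0.5, 0.5, 1e-5, 0.5],
        "rsq": [1.0, 1.0, 1.0, 1.0, 0.90],
    }, index=pd.Index([f"v{j}" for j in range(5)], name="variant_id"))


def test_threshold_boundaries(filter_stats):
    kept, report = apply_variant_filters(filter_stats, QcThresholds())
    # MAF 0.09 removed, 0.10 kept; call rate 0.94 removed; HWE 1e-5 removed;
    # rsq 0.90 removed
    assert list(kept) == ["v1"]
    stages = report.to_frame().set_index("stage")
    assert stages.loc["maf", "removed"] == 1
    assert stages.loc["call_rate", "removed"] == 1
    assert stages.loc["hwe", "removed"] == 1
    assert stages.loc["rsq", "removed"] == 1


def test_counts_conserved_and_order_invariant(filter_stats):
    kept_default, report = apply_variant_filters(filter_stats)
    frame = report.to_frame()
    assert report.input_variants - frame["removed"].sum() == report.surviving_variants
    for i in range(len(frame)):
        prev = report.input_variants if i == 0 else frame["remaining"][i - 1]
        assert frame["remaining"][i] == prev - frame["removed"][i]
    for order in [DEFAULT_FILTER_ORDER[::-1], ("hwe", "rsq", "maf", "call_rate")]:
        kept, _ = apply_variant_filters(filter_stats, order=order)
        assert list(kept) == list(kept_default)


def test_all_passing_is_noop(filter_stats):
    ok = filter_stats.assign(maf=0.3, call_rate=1.0, hwe_p=0.5, rsq=1.0)
    kept, _ = apply_variant_filters(ok)
    assert list(kept) == list(ok.index)


def test_participant_call_rate_filter():
    # participant 0 misses 15% of calls -> removed; complete participants kept
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(3, 40)).astype(float)
    d[0, :6] = np.nan
    gt = _matrix(d.T)
    kept = filter_participants(gt, 0.90)
    assert list(kept) == ["P1", "P2"]
    complete = _matrix(rng.binomial(2, 0.3, size=(3, 40)).astype(float).T)
    assert list(filter_participants(complete)) == ["P0", "P1", "P2"]


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

@pytest.fixture()
def annotation():
    return pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "start": [1000, 20_000, 500],
        "end": [2000, 21_000, 900],
        "gene": ["GA", "GB", "GC"],
    })


def _variants(chrom_pos):
    return pd.DataFrame(
        {"chrom": [c for c, _ in chrom_pos], "pos": [p for _, p in chrom_pos]},
        index=pd.Index([f"v{j}" for j in range(len(chrom_pos))], name="variant_id"))


def test_gene_assignment_distances(annotation):
    res = assign_variants_to_genes(
        _variants([("1", 1500), ("1", 7000), ("1", 7001), ("1", 2100)]),
        annotation)
    assert res.loc["v0", "distance"] == 0 and res.loc["v0", "assigned_gene"] == "GA"
    # 5,000 bp past GA's end: kept (boundary inclusive); 5,001: excluded
    assert res.loc["v1", "distance"] == 5000 and not res.loc["v1", "excluded"]
    assert res.loc["v2", "excluded"] and res.loc["v2", "assigned_gene"] is None
    assert res.loc["v3", "assigned_gene"] == "GA" and res.loc["v3", "distance"] == 100


def test_gene_assignment_tie_goes_to_earlier_gene(annotation):
    # pos 11,000 is 9,000 bp from both GA's end and GB's start
    res = assign_variants_to_genes(_variants([("1", 11_000)]), annotation,
                                   max_distance=10_000)
    assert res.loc["v0", "assigned_gene"] == "GA"
    assert res.loc["v0", "distance"] == 9000


def test_gene_assignment_missing_chromosome_warns(annotation):
    with pytest.warns(UserWarning, match="chromosomes without annotation"):
        res = assign_variants_to_genes(_variants([("7", 100)]), annotation)
    assert res["excluded"].all()


def test_run_qc_recomputes_maf_after_participant_filter():
    # participant 0 has terrible call rate; removing it changes allele counts
    d = np.array([
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [2, 2, 2, 2, 2, 2, 2, 2, 2, 2],
        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    ], dtype=float)
    d[0, 1:] = np.nan
    gt = _matrix(d.T)
    res = run_qc(gt, thresholds=QcThresholds(hwe_p_min=0.0))
    assert res.report.participants_removed == 1
    # with P0 gone, alt freq = (1+2+1)/6 = 2/3 -> MAF 1/3 on every variant
    assert np.allclose(res.stats["maf"], 1 / 3)
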