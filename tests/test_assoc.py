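"""Association scan: coding, standardization, OLS oracles, PC1."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_for_variant
from tbisig import SimConfig, simulate_study
from tbisig.assoc import (ModelSpec, VariantScan, compute_pc1, encode_additive,
                          fit_interaction_model, fit_tbi_only_model,
                          standardize_continuous)
from tbisig.containers import GenotypeMatrix


def _phenotypes(n, seed=0, groups=("OI", "moderate", "severe")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.uniform(0, 17, n),
        "sex": rng.integers(0, 2, n),
        "group": rng.choice(groups, n),
        "pc1": rng.standard_normal(n),
        "y": rng.standard_normal(n),
    }, index=pd.Index([f"P{i}" for i in range(n)], name="participant_id"))


def _genotypes(n, m, seed=0, maf=0.3, missing=0.0):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, maf, size=(n, m)).astype(float)
    if missing:
        d[rng.random((n, m)) < missing] = np.nan
    meta = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A",
                         "alt": "G", "maf": maf, "rsq": 1.0},
                        index=pd.Index([f"v{j}" for j in range(m)], name="variant_id"))
    return GenotypeMatrix(d, [f"P{i}" for i in range(n)], meta)


# ---------------------------------------------------------------------------
# coding and standardization
# ---------------------------------------------------------------------------

def test_additive_coding_counts_minor_allele():
    # alt is minor: codes unchanged (0 = major homozygote ... 2 = minor hom)
    codes, flipped = encode_additive(np.array([0, 1, 2, 0.0]))
    assert not flipped and list(codes) == [0, 1, 2, 0]
    # alt is major: orientation flipped so the code still counts the minor allele
    codes, flipped = encode_additive(np.array([2, 2, 1, 2.0]))
    assert flipped and list(codes) == [0, 0, 1, 0]
    codes, _ = encode_additive(np.array([2.0, np.nan]))
    assert np.isnan(codes[1])


def test_standardize_closed_form_idempotent_and_zero_variance():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    out = standardize_continuous(df, ["a"])
    np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
    again = standardize_continuous(out, ["a"])
    np.testing.assert_allclose(again["a"], out["a"], atol=1e-12)
    with pytest.raises(ValueError, match="'b'"):
        standardize_continuous(df, ["b"])


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("subset", ["all", "tbi"])
def test_scan_matches_normal_equations_oracle(subset):
    """Coefficients and p-values agree with an explicit solve to 1e-8."""
    spec = (ModelSpec(outcome="y") if subset == "all"
            else ModelSpec(outcome="y", subset="tbi", include_interaction=False))
    rng_seeds = range(6)
    for seed in rng_seeds:
        n = 40 + 2 * seed
        pheno = _phenotypes(n, seed=seed)
        gt = _genotypes(n, 8, seed=100 + seed, missing=0.05)
        res = VariantScan(pheno, gt, spec).fit().frame
        for j, vid in enumerate(gt.variant_ids):
            row = res.loc[vid]
            if not row["estimable"]:
                continue
            beta, se, p_t, p_joint = oracle_for_variant(pheno, gt.dosages[:, j], spec)
            k = len(beta) - (3 if subset == "all" else 1)
            assert abs(row["beta"] - beta[k]) < 1e-8
            assert abs(row["se"] - se[k]) < 1e-8
            assert abs(row["p"] - p_t[k]) < 1e-8
            if subset == "all":
                assert abs(row["beta_int_moderate"] - beta[k + 1]) < 1e-8
                assert abs(row["beta_int_severe"] - beta[k + 2]) < 1e-8
                assert abs(row["p_joint"] - p_joint) < 1e-8


def test_perfect_fit_recovers_unit_coefficient():
    n = 60
    pheno = _phenotypes(n, seed=3)
    gt = _genotypes(n, 1, seed=3)
    z = gt.dosages[:, 0]
    pheno["y"] = (z - z.mean()) / z.std(ddof=1)  # outcome == standardized dosage
    row = fit_interaction_model(gt.dosages[:, 0], pheno, ModelSpec(outcome="y"))
    assert row["beta"] == pytest.approx(1.0, abs=1e-8)


def test_tbi_model_excludes_oi_and_matches_direct_subset_fit():
    n = 120
    pheno = _phenotypes(n, seed=4)
    gt = _genotypes(n, 1, seed=4)
    tbi_spec = ModelSpec(outcome="y", subset="tbi", include_interaction=False)
    row = fit_tbi_only_model(gt.dosages[:, 0], pheno, tbi_spec)
    n_tbi = (pheno["group"] != "OI").sum()
    assert row["n_used"] == n_tbi
    # independent refit on the pre-subset data matches to 1e-10
    sub = pheno[pheno["group"] != "OI"]
    gt_sub = gt.subset(participants=sub.index)
    row2 = fit_tbi_only_model(gt_sub.dosages[:, 0], sub, tbi_spec)
    assert row["beta"] == pytest.approx(row2["beta"], abs=1e-10)
    assert row["p"] == pytest.approx(row2["p"], abs=1e-10)


def test_variant_constant_within_group_flagged_unestimable():
    n = 90
    pheno = _phenotypes(n, seed=5)
    gt = _genotypes(n, 1, seed=5)
    d = gt.dosages.copy()
    d[(pheno["group"] == "severe").to_numpy(), 0] = 1.0  # no variation in one group
    d[(pheno["group"] == "moderate").to_numpy(), 0] = 1.0
    gt2 = GenotypeMatrix(d, gt.participants, gt.variants)
    res = VariantScan(pheno, gt2, ModelSpec(outcome="y")).fit().frame
    assert not res["estimable"].iloc[0]
    assert np.isnan(res["p_joint"].iloc[0])


def test_complete_case_handling_matches_row_drop():
    n = 80
    pheno = _phenotypes(n, seed=6)
    gt = _genotypes(n, 4, seed=6, missing=0.2)
    res = VariantScan(pheno, gt, ModelSpec(outcome="y")).fit().frame
    for j, vid in enumerate(gt.variant_ids):
        present = ~np.isnan(gt.dosages[:, j])
        assert res.loc[vid, "n_used"] == present.sum()


def test_null_interaction_pvalues_nominally_calibrated():
    cfg = SimConfig(n_participants=400, n_case_genes=100, n_control_genes=150,
                    variants_per_gene=5, signal_fraction=0.0, beta_main=0.0,
                    beta_interaction=0.0, outcomes=("y",), seed=17)
    bundle = simulate_study(cfg)
    res = VariantScan(bundle.phenotypes, bundle.genotypes, ModelSpec(outcome="y")).fit()
    frac = (res.frame["p_joint"] < 0.05).mean()
    m = len(res.frame)
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)


# ---------------------------------------------------------------------------
# PC1
# ---------------------------------------------------------------------------

def test_pc1_separates_two_populations():
    rng = np.random.default_rng(8)
    n_half, m = 60, 300
    d = np.vstack([
        rng.binomial(2, 0.15, size=(n_half, m)),
        rng.binomial(2, 0.45, size=(n_half, m)),
    ]).astype(float)
    meta = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A",
                         "alt": "G", "maf": 0.3, "rsq": 1.0},
                        index=pd.Index([f"v{j}" for j in range(m)], name="variant_id"))
    gt = GenotypeMatrix(d, [f"P{i}" for i in range(2 * n_half)], meta)
    pc1 = compute_pc1(gt)
    a, b = pc1[:n_half], pc1[n_half:]
    # clusters well separated along PC1 (between-variance dominates within)
    assert (a.mean() - b.mean()) ** 2 > 4 * (a.var() + b.var())
    # permutation equivariance
    perm = rng.permutation(2 * n_half)
    gt_perm = GenotypeMatrix(d[perm], [f"P{i}" for i in perm], meta)
    pc1_perm = compute_pc1(gt_perm)
    np.testing.assert_allclose(pc1_perm.to_numpy(), pc1.to_numpy()[perm], atol=1e-8)


def test_pc1_degenerate_inputs_error():
    meta = pd.DataFrame({"chrom": "1", "pos": [1], "ref": "A", "alt": "G",
                         "maf": 0.3, "rsq": 1.0},
                        index=pd.Index(["v0"], name="variant_id"))
    with pytest.raises(ValueError, match="at least 2"):
        compute_pc1(GenotypeMatrix(np.ones((1, 1)), ["P0"], meta))
    with pytest.raises(ValueError, match="monomorphic"):
        compute_pc1(GenotypeMatrix(np.ones((4, 1)), [f"P{i}" for i in range(4)], meta))
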