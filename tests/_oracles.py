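"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the code paths they check: the HWE oracle uses
exact integer/rational arithmetic over an explicit enumeration of
heterozygote counts; the regression oracle solves the normal equations
directly and takes p-values from the classical t/F distributions.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps

from tbisig.assoc import _build_design


def hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Exact two-sided HWE p by rational enumeration of het counts."""
    n = n_hom_major + n_het + n_hom_minor
    nm = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)
    if nm == 0:
        return 1.0

    def weight(h):  # integer count of genotype orderings at het count h
        r = (nm - h) // 2
        return Fraction(comb(n, h) * comb(n - h, r) * 2 ** h)

    hs = range(nm % 2, min(nm, 2 * n - nm) + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return float(sum(w for w in weights.values() if w / total <= p_obs) / total)


def normal_equations_oracle(y, X, joint_cols=None):
    """Explicit (X'X)^-1 X'y solve with classical t/F p-values."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    p_t = 2 * sps.t.sf(np.abs(beta / se), df)
    p_joint = None
    if joint_cols:
        bi = beta[list(joint_cols)]
        Vii = cov[np.ix_(joint_cols, joint_cols)]
        F = bi @ np.linalg.solve(Vii, bi) / len(joint_cols)
        p_joint = sps.f.sf(F, len(joint_cols), df)
    return beta, se, p_t, p_joint


def oracle_for_variant(pheno, dosage, spec):
    """Fit one variant's model by the explicit route (complete case, flip,
    standardize, solve)."""
    rows, y, C, names, inter = _build_design(pheno, spec)
    g = np.asarray(dosage, dtype=float)[pheno.index.get_indexer(rows)]
    keep = ~np.isnan(g)
    gk = g[keep]
    if gk.mean() / 2 > 0.5:
        gk = 2 - gk
    z = (gk - gk.mean()) / gk.std(ddof=1)
    cols = [C[keep], z[:, None]]
    joint = None
    if inter is not None:
        cols.append(z[:, None] * inter[keep])
        pcols = C.shape[1] + 1 + inter.shape[1]
        joint = [pcols - 2, pcols - 1]
    X = np.hstack(cols)
    return normal_equations_oracle(y[keep], X, joint)
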