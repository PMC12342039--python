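"""Per-variant standardized linear models.

Two model families are fitted per variant, both by ordinary least squares
on standardized data:

* the **interaction model** on all participants — outcome ~ age + sex +
  age:sex + PC1 + injury group (3 levels, orthopedic-injury reference) +
  variant + variant:group, where a 2-df joint F-test on the two
  variant-by-group terms asks whether the variant's association with the
  outcome differs by injury group; and
* the **TBI-only model** on the moderate + severe subset — outcome ~
  covariates + severity dummy + variant, reporting the variant main effect.

The outcome, the continuous covariates and the additive genotype coding are
standardized (mean 0, sample SD 1, denominator n-1), so every coefficient
is on the standardized-effect scale.  Missing genotype calls are handled
complete-case per variant, as genome-scan tools conventionally do.

The scan is implemented as batched weighted least squares: the fixed
covariate block is shared, per-variant Gram matrices are assembled with
dense matrix products and solved as a stacked array, which makes a scan of
tens of thousands of variants take seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GROUP_LEVELS, GenotypeMatrix

_EIG_RTOL = 1e-9  # relative eigenvalue cutoff flagging a rank-deficient design


@dataclass
class ModelSpec:
    """What to regress on what.

    ``subset`` is ``"all"`` (interaction model over the three groups) or
    ``"tbi"`` (moderate + severe participants only, severity dummy, no
    interaction).
    """

    outcome: str = "cbcl"
    covariates: tuple = ("age", "sex", "age_x_sex", "pc1")
    group_col: str = "group"
    reference: str = "OI"
    include_interaction: bool = True
    subset: str = "all"

    @property
    def model_name(self) -> str:
        return "tbi" if self.subset == "tbi" else "interaction"


# ---------------------------------------------------------------------------
# small building blocks
# ---------------------------------------------------------------------------

def encode_additive(dosages: np.ndarray, alt_freq: float | None = None):
    """Return (codes, flipped): dosage re-oriented to count the minor allele.

    ``dosages`` counts the alternate allele; if the alternate allele is the
    major one (frequency > 0.5 over non-missing calls), the coding is
    flipped to ``2 - dosage`` so that 0 = major homozygote, 1 = het,
    2 = minor homozygote.  NaN (missing) propagates.
    """
    d = np.asarray(dosages, dtype=float)
    if alt_freq is None:
        with np.errstate(invalid="ignore"):
            alt_freq = float(np.nanmean(d) / 2.0)
    flipped = bool(alt_freq > 0.5)
    return (2.0 - d if flipped else d), flipped


def standardize_continuous(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Standardize the named columns to mean 0, SD 1 (sample SD, n-1).

    Idempotent on already-standardized columns; a zero-variance column is an
    error naming the column.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def compute_pc1(genotypes: GenotypeMatrix) -> pd.Series:
    """First principal component of the column-standardized dosage matrix.

    Missing calls are imputed to the column mean; monomorphic columns are
    dropped.  Sign convention: PC1 correlates positively with the first
    retained variant's dosage.
    """
    if genotypes.n_participants < 2:
        raise ValueError("PC1 requires at least 2 participants")
    d = genotypes.dosages.copy()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(mu, idx[1])
    sd = d.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variants monomorphic; PC1 undefined")
    z = (d[:, keep] - mu[keep]) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    r = float(scores @ z[:, 0])
    if r < 0:
        scores = -scores
    return pd.Series(scores, index=genotypes.participants, name="pc1")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _build_design(pheno: pd.DataFrame, spec: ModelSpec):
    """Complete-case covariate design for the requested subset.

    Returns (row index, y standardized, C fixed design, column names,
    interaction dummies or None).  Standardization of the outcome and the
    continuous covariates happens here, once, on the analysis subset; the
    age-by-sex product is formed from the standardized age.
    """
    df = pheno
    if spec.subset == "tbi":
        df = df[df[spec.group_col].isin(["moderate", "severe"])]
    elif spec.subset != "all":
        raise ValueError(f"unknown subset {spec.subset!r}")
    if spec.subset == "all" and spec.reference not in set(df[spec.group_col]):
        raise ValueError(f"reference group {spec.reference!r} absent from data")

    base_cols = [spec.outcome] + [c for c in spec.covariates if c != "age_x_sex"]
    df = df.dropna(subset=base_cols + [spec.group_col])
    if df.empty:
        raise ValueError("no complete-case rows for the requested model")
    continuous = [spec.outcome] + [
        c for c in spec.covariates if c not in ("sex", "age_x_sex")
    ]
    df = standardize_continuous(df, continuous)

    cols, names = [np.ones(len(df))], ["intercept"]
    for c in spec.covariates:
        if c == "age_x_sex":
            cols.append(df["age"].to_numpy() * df["sex"].to_numpy())
        else:
            cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    group = df[spec.group_col].to_numpy()
    inter = None
    if spec.subset == "tbi":
        cols.append((group == "severe").astype(float))
        names.append("severe")
    else:
        others = [g for g in GROUP_LEVELS if g != spec.reference and g in set(group)]
        dummies = []
        for g in others:
            dummy = (group == g).astype(float)
            cols.append(dummy)
            names.append(f"group_{g}")
            dummies.append(dummy)
        if spec.include_interaction:
            inter = np.column_stack(dummies) if dummies else None
    C = np.column_stack(cols)
    y = df[spec.outcome].to_numpy(dtype=float)
    return df.index, y, C, names, inter


# ---------------------------------------------------------------------------
# batched scan core
# ---------------------------------------------------------------------------

def _scan_chunk(y, C, G, inter):
    """Complete-case OLS for a block of variants at once.

    y: (n,) standardized outcome; C: (n, k) fixed design; G: (n, m) raw
    dosages with NaN missing; inter: (n, q) interaction dummies or None.
    Returns a dict of per-variant arrays.
    """
    n, k = C.shape
    m = G.shape[1]
    q = inter.shape[1] if inter is not None else 0
    p = k + 1 + q

    w = (~np.isnan(G)).astype(float)
    nv = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(G, axis=0) / (2 * np.maximum(nv, 1))
    flip = p_alt > 0.5
    Gm = np.where(flip[None, :], 2.0 - G, G)
    s1 = np.nansum(Gm, axis=0)
    s2 = np.nansum(Gm * Gm, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / nv
        var = (s2 - nv * mean ** 2) / np.maximum(nv - 1, 1)
    poly = (var > 0) & (nv >= 2)
    sd = np.sqrt(np.where(poly, var, 1.0))
    Z = np.nan_to_num((Gm - mean[None, :]) / sd[None, :]) * w

    # Gram pieces shared across variants
    iu = np.triu_indices(k)
    P = C[:, iu[0]] * C[:, iu[1]]                    # (n, k(k+1)/2)
    CWC_flat = P.T @ w                               # (kk2, m)
    CWy = (C * y[:, None]).T @ w                     # (k, m)
    yWy = (y * y) @ w                                # (m,)

    zcols = [Z]
    if inter is not None:
        zcols += [Z * inter[:, j][:, None] for j in range(q)]
    CtZ = [C.T @ zc for zc in zcols]                 # each (k, m)
    zz = np.empty((m, 1 + q, 1 + q))
    sz = [(zc * Z).sum(axis=0) for zc in zcols]      # Z'Z, Z'(Z dj)...
    zz[:, 0, 0] = sz[0]
    for a in range(1, 1 + q):
        zz[:, 0, a] = zz[:, a, 0] = sz[a]
        zz[:, a, a] = sz[a]                          # dj^2 = dj
        for b in range(a + 1, 1 + q):
            zz[:, a, b] = zz[:, b, a] = 0.0          # disjoint dummies
    zy = np.array([y @ zc for zc in zcols]).T        # (m, 1+q)

    XtX = np.empty((m, p, p))
    XtX[:, iu[0], iu[1]] = CWC_flat.T
    XtX[:, iu[1], iu[0]] = CWC_flat.T
    for a in range(1 + q):
        XtX[:, :k, k + a] = CtZ[a].T
        XtX[:, k + a, :k] = CtZ[a].T
    XtX[:, k:, k:] = zz
    Xty = np.empty((m, p))
    Xty[:, :k] = CWy.T
    Xty[:, k:] = zy

    df_resid = nv - p
    eig = np.linalg.eigvalsh(XtX)
    ok = poly & (df_resid >= 1) & (eig[:, 0] > _EIG_RTOL * np.maximum(eig[:, -1], 1.0))
    XtX_safe = np.where(ok[:, None, None], XtX, np.eye(p)[None, :, :])
    beta = np.linalg.solve(XtX_safe, Xty[:, :, None])[:, :, 0]
    rss = np.maximum(yWy - np.einsum("mp,mp->m", beta, Xty), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / np.maximum(df_resid, 1)
        cov = np.linalg.inv(XtX_safe) * sigma2[:, None, None]
        se = np.sqrt(np.einsum("mpp->mp", cov))
        tstat = beta / se
        p_t = 2 * sps.t.sf(np.abs(tstat), np.maximum(df_resid, 1)[:, None])
        p_t = np.where(se == 0, 0.0, p_t)
    p_joint = np.full(m, np.nan)
    if q:
        bi = beta[:, k + 1:]
        Vii = cov[:, k + 1:, k + 1:]
        Vii_safe = np.where(ok[:, None, None] & (sigma2 > 0)[:, None, None],
                            Vii, np.eye(q)[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            fstat = np.einsum(
                "mq,mq->m", bi, np.linalg.solve(Vii_safe, bi[:, :, None])[:, :, 0]) / q
        p_joint = sps.f.sf(fstat, q, np.maximum(df_resid, 1))
        p_joint = np.where(sigma2 == 0, 0.0, p_joint)
    bad = ~ok
    for arr in (beta, se, p_t):
        arr[bad] = np.nan
    p_joint[bad] = np.nan
    return {
        "beta": beta, "se": se, "p_t": p_t, "p_joint": p_joint,
        "n_used": nv.astype(int), "estimable": ok, "flipped": flip,
    }


@dataclass
class AssociationResults:
    """Per-variant fit results; thin wrapper around a DataFrame.

    The frame is indexed by variant id with columns ``model, gene, beta,
    se, p`` (variant main effect) and, for the interaction model,
    ``beta_int_moderate/severe``, their SEs and Wald p-values, and the
    joint 2-df interaction p-value ``p_joint``; plus ``n_used, estimable,
    flipped``.
    """

    frame: pd.DataFrame
    spec: ModelSpec
    covariate_names: list = field(default_factory=list)

    @property
    def model(self) -> str:
        return self.spec.model_name

    @property
    def hit_pvalue_column(self) -> str:
        """p-value column the enrichment stage counts (joint interaction p
        for the interaction model, main-effect p for the TBI-only model)."""
        return "p_joint" if self.model == "interaction" else "p"

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def pvalues(self) -> pd.Series:
        return self.frame[self.hit_pvalue_column]

    def nominal_hits(self, alpha: float = 0.05) -> pd.Index:
        f = self.frame
        if "estimable" not in f.columns:  # zero-variant scan
            return f.index[:0]
        ok = f["estimable"] & (f[self.hit_pvalue_column] < alpha)
        return f.index[ok]

    def summary(self, top: int = 10) -> str:
        f = self.frame
        est = f[f["estimable"]]
        lines = [
            f"Variant scan [{self.model}] outcome={self.spec.outcome}",
            f"  variants: {len(f)} ({len(f) - len(est)} unestimable)",
            f"  nominal hits (p < 0.05): {len(self.nominal_hits())}",
            "",
            est.nsmallest(top, self.hit_pvalue_column)[
                [c for c in ("gene", "beta", "beta_int_moderate", "beta_int_severe",
                             self.hit_pvalue_column, "n_used") if c in est.columns]
            ].to_string(),
        ]
        return "\n".join(lines)


class VariantScan:
    """Model object: a per-variant OLS scan of one outcome.

    Parameters
    ----------
    phenotypes : DataFrame indexed by participant id (outcome, covariates,
        group; ``pc1`` either present or supplied via ``extra_covariates``).
    genotypes : GenotypeMatrix (post-QC).
    spec : ModelSpec
    gene_assignment : optional Series variant id -> gene symbol carried into
        the results.
    """

    def __init__(self, phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                 spec: ModelSpec | None = None, gene_assignment: pd.Series | None = None):
        self.spec = spec or ModelSpec()
        common = phenotypes.index.intersection(genotypes.participants)
        if len(common) == 0:
            raise ValueError("no participants shared by phenotype and genotype tables")
        self.phenotypes = phenotypes.loc[common]
        self.genotypes = genotypes.subset(participants=common) \
            if len(common) != genotypes.n_participants else genotypes
        self.gene_assignment = gene_assignment

    def fit(self, chunk_size: int = 8192) -> AssociationResults:
        spec = self.spec
        rows, y, C, names, inter = _build_design(self.phenotypes, spec)
        ridx = self.genotypes.participants.get_indexer(rows)
        G_all = self.genotypes.dosages[ridx]
        m = self.genotypes.n_variants
        parts = []
        for lo in range(0, m, chunk_size):
            hi = min(lo + chunk_size, m)
            parts.append(_scan_chunk(y, C, G_all[:, lo:hi], inter))
        res = {key: np.concatenate([p[key] for p in parts], axis=0)
               for key in parts[0]} if parts else None
        k = C.shape[1]
        vids = self.genotypes.variant_ids
        if res is None:
            frame = pd.DataFrame(index=vids)
        else:
            frame = pd.DataFrame(index=vids, data={
                "model": spec.model_name,
                "beta": res["beta"][:, k],
                "se": res["se"][:, k],
                "p": res["p_t"][:, k],
                "n_used": res["n_used"],
                "estimable": res["estimable"],
                "flipped": res["flipped"],
            })
            if inter is not None:
                for j, g in enumerate(("moderate", "severe")):
                    frame[f"beta_int_{g}"] = res["beta"][:, k + 1 + j]
                    frame[f"se_int_{g}"] = res["se"][:, k + 1 + j]
                    frame[f"p_int_{g}"] = res["p_t"][:, k + 1 + j]
                frame["p_joint"] = res["p_joint"]
        if self.gene_assignment is not None:
            frame.insert(0, "gene", self.gene_assignment.reindex(vids))
        frame.index.name = "variant_id"
        return AssociationResults(frame, spec, names)


# ---------------------------------------------------------------------------
# single-variant conveniences (spec operations)
# ---------------------------------------------------------------------------

def _single_variant_matrix(dosages, phenotypes: pd.DataFrame) -> GenotypeMatrix:
    meta = pd.DataFrame({"chrom": ["1"], "pos": [1], "ref": ["A"], "alt": ["G"],
                         "maf": [np.nan], "rsq": [1.0]},
                        index=pd.Index(["v1"], name="variant_id"))
    d = np.asarray(dosages, dtype=float).reshape(-1, 1)
    return GenotypeMatrix(d, phenotypes.index, meta)


def fit_interaction_model(dosages, phenotypes: pd.DataFrame,
                          spec: ModelSpec | None = None) -> pd.Series:
    """Fit the interaction model for one variant; returns its result row."""
    spec = spec or ModelSpec()
    if spec.subset != "all" or not spec.include_interaction:
        raise ValueError("interaction model requires subset='all', include_interaction=True")
    gt = _single_variant_matrix(dosages, phenotypes)
    return VariantScan(phenotypes, gt, spec).fit().frame.iloc[0]


def fit_tbi_only_model(dosages, phenotypes: pd.DataFrame,
                       spec: ModelSpec | None = None) -> pd.Series:
    """Fit the TBI-only main-effect model for one variant."""
    spec = spec or ModelSpec(subset="tbi", include_interaction=False)
    if spec.subset != "tbi":
        raise ValueError("TBI-only model requires subset='tbi'")
    gt = _single_variant_matrix(dosages, phenotypes)
    return VariantScan(phenotypes, gt, spec).fit().frame.iloc[0]
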