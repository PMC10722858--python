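"""Mixed-linear-model association engine and related quantitative genetics.

The association model is the standard single-marker MLM

    y = Q alpha + x beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with a centered (VanRaden-style) genomic relationship matrix K and genotype
principal components Q as structure covariates. Variance components are
estimated once by REML on the null model (no marker) through the
eigendecomposition of K and a 1-D search over the ratio delta = se^2/sg^2;
each marker is then tested by generalized least squares with the null
components held fixed (the P3D shortcut), which reduces to ordinary least
squares on the decorrelated scale and is fully vectorized over markers.

Broad-sense heritability uses the replicate one-way ANOVA estimator
H^2 = var(G) / (var(G) + var(E)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import MISSING, GenotypeMatrix, MetaboliteMatrix

# ---------------------------------------------------------------- QC


@dataclass
class QcReport:
    maf: np.ndarray  # per input SNP; NaN where undefined (all calls missing)
    mcf: np.ndarray
    passed: np.ndarray  # bool per input SNP


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.05, mcf_max: float = 0.1
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep SNPs with MAF strictly > maf_min and MCF strictly < mcf_max.

    MAF is computed on non-missing calls; a SNP with every call missing has
    undefined MAF and is excluded.
    """
    x = g.calls
    miss = x == MISSING
    n_called = (~miss).sum(axis=0)
    mcf = miss.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(miss, 0, x).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    passed = (maf > maf_min) & (mcf < mcf_max) & (n_called > 0)
    return g.subset_snps(passed), QcReport(maf=maf, mcf=mcf, passed=passed)


# ---------------------------------------------------------------- kinship / structure


def compute_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Centered genomic relationship K = W W' / c, c = sum_j 2 p_j (1 - p_j).

    W is the column-centered mean-imputed dosage matrix. Symmetric and
    numerically PSD by construction.
    """
    x = g.dosage(impute=True)
    p = x.mean(axis=0) / 2.0
    w = x - 2.0 * p
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("no polymorphic SNPs: kinship undefined")
    k = (w @ w.T) / c
    return (k + k.T) / 2.0


def compute_structure(g: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k genotype principal components (n × k), columns centered.

    Deterministic up to machine precision: each PC's sign is fixed so that its
    largest-magnitude sample loading is positive.
    """
    if k == 0:
        return np.zeros((g.n_samples, 0))
    if k >= g.n_samples:
        raise ValueError(f"k={k} must be < n_samples={g.n_samples}")
    x = g.dosage(impute=True)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(pcs.shape[1]):
        i = int(np.argmax(np.abs(pcs[:, j])))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------- REML null model


@dataclass
class NullModelFit:
    """REML variance components plus the cached spectrum used by the scan."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # se^2 / sg^2
    loglik: float
    eigvals: np.ndarray  # eigenvalues of K
    eigvecs: np.ndarray  # eigenvectors of K (columns)
    covariates: np.ndarray  # fixed-effect design [1, Q], original scale
    degenerate: bool = False


def _reml_neg2ll(log_delta: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """-2 x REML log-likelihood profile over delta (sg^2 profiled out)."""
    delta = np.exp(log_delta)
    w = lam + delta
    n, p = xt.shape
    xtw = xt / w[:, None]
    xx = xt.T @ xtw
    try:
        beta = np.linalg.solve(xx, xtw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - xt @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    sg2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(xx)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(sg2) + float(np.sum(np.log(w))) + logdet_xx


def fit_null_mlm(
    y: np.ndarray,
    K: np.ndarray,
    Q: np.ndarray | None = None,
    grid_size: int = 100,
    log_delta_bounds: tuple[float, float] = (-11.5, 11.5),
) -> NullModelFit:
    """REML fit of y = Q alpha + u + e via eigendecomposition of K.

    The profile -2 log-likelihood is evaluated on a grid over log delta and
    refined by bounded 1-D optimization around the grid minimum.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if Q is None:
        Q = np.zeros((n, 0))
    X = np.column_stack([np.ones(n), Q])
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    xt = U.T @ X
    if np.var(y) == 0:
        return NullModelFit(0.0, 0.0, 1.0, 0.0, lam, U, X, degenerate=True)

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, grid_size)
    vals = np.array([_reml_neg2ll(g_, lam, yt, xt) for g_ in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        _reml_neg2ll, bounds=(a, b), args=(lam, yt, xt), method="bounded",
        options={"xatol": 1e-10},
    )
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    neg2ll = min(float(res.fun), float(vals[i]))
    if not np.isfinite(neg2ll):
        raise RuntimeError("REML optimization produced non-finite likelihood")
    delta = float(np.exp(log_delta))
    w = lam + delta
    p = xt.shape[1]
    xtw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xtw, xtw.T @ yt)
    r = yt - xt @ beta
    sg2 = float(r @ (r / w)) / (n - p)
    # boundary collapse: delta at either bound means one component vanishes
    if log_delta >= hi - 1e-6:
        se2, sg2 = sg2 * delta, 0.0
        se2 = float(se2)
    else:
        se2 = sg2 * delta
    return NullModelFit(
        sigma_g2=max(sg2, 0.0),
        sigma_e2=max(se2, 0.0),
        delta=delta,
        loglik=-0.5 * neg2ll,
        eigvals=lam,
        eigvecs=U,
        covariates=X,
    )


# ---------------------------------------------------------------- association scan


@dataclass
class AssociationResult:
    """Per-SNP marker test results for one trait."""

    snp_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray  # Wald t statistic
    p: np.ndarray
    var_explained: np.ndarray
    collinear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.collinear is None:
            self.collinear = np.zeros(len(self.snp_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "id": self.snp_ids,
                "beta": self.beta,
                "se": self.se,
                "stat": self.stat,
                "p": self.p,
                "var_explained": self.var_explained,
            }
        )


def scan_associations(
    g: GenotypeMatrix,
    y: np.ndarray,
    null: NullModelFit,
) -> AssociationResult:
    """GLS marker scan with null-model variance components held fixed (P3D).

    On the decorrelated scale (rotate by the eigenvectors of K, whiten by
    sqrt(eigenvalue + delta)) the model is OLS of y on [1, Q, x_snp]; the Wald
    t statistic uses the per-model residual variance, so with K = I and no
    covariates the P-values equal the ordinary 1-df F-test exactly.

    ``var_explained`` is the squared partial correlation of the marker given
    the covariates on the decorrelated scale, i.e. the proportional reduction
    in residual sum of squares when the marker enters the model.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    w = np.sqrt(null.eigvals + null.delta)
    Ut = null.eigvecs.T
    yt = (Ut @ y) / w
    Xt = (Ut @ null.covariates) / w[:, None]
    Gt = (Ut @ g.dosage(impute=True)) / w[:, None]

    # project covariates out of y and every marker column
    qx, _ = np.linalg.qr(Xt)
    y_res = yt - qx @ (qx.T @ yt)
    G_res = Gt - qx @ (qx.T @ Gt)

    p_cov = Xt.shape[1]
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough samples for the marker test")

    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    rss0 = float(y_res @ y_res)
    collinear = gg <= 1e-12 * max(np.max(gg), 1.0)
    gg_safe = np.where(collinear, 1.0, gg)
    beta = gy / gg_safe
    rss1 = np.maximum(rss0 - gy * beta, 0.0)
    sigma2 = rss1 / df
    se = np.sqrt(np.maximum(sigma2 / gg_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    ve = np.where(rss0 > 0, (rss0 - rss1) / rss0, 0.0)
    beta = np.where(collinear, 0.0, beta)
    se = np.where(collinear, np.nan, se)
    tstat = np.where(collinear, 0.0, tstat)
    pvals = np.where(collinear, 1.0, pvals)
    ve = np.where(collinear, 0.0, ve)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    return AssociationResult(
        snp_ids=[s.id for s in g.snps],
        chroms=g.chroms,
        positions=g.positions,
        beta=beta,
        se=se,
        stat=tstat,
        p=pvals,
        var_explained=np.clip(ve, 0.0, 1.0),
        collinear=collinear,
    )


def run_gwas(
    g: GenotypeMatrix,
    y: np.ndarray,
    structure_k: int = 3,
    K: np.ndarray | None = None,
    Q: np.ndarray | None = None,
) -> AssociationResult:
    """Convenience wrapper: kinship + PCs + null REML + scan in one call."""
    if K is None:
        K = compute_kinship(g)
    if Q is None:
        Q = compute_structure(g, structure_k)
    null = fit_null_mlm(y, K, Q)
    return scan_associations(g, y, null)


# ---------------------------------------------------------------- heritability


@dataclass
class HeritabilityEstimate:
    metabolite: str
    var_g: float
    var_e: float
    h2: float


def estimate_heritability(m: MetaboliteMatrix) -> list[HeritabilityEstimate]:
    """Replicate one-way ANOVA broad-sense heritability per metabolite.

    var(E) = MS_within; var(G) = max(0, (MS_between - MS_within)/r);
    H^2 = var(G)/(var(G)+var(E)), defined as 0 when both components vanish.
    Requires r >= 2 biological replicates.
    """
    r = m.n_replicates
    if r < 2:
        raise ValueError("heritability needs >= 2 replicates")
    out = []
    v = m.values  # (n, m, r)
    n = v.shape[0]
    means = v.mean(axis=2)  # accession means
    grand = means.mean(axis=0)
    ms_between = r * ((means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_within = ((v - means[:, :, None]) ** 2).sum(axis=(0, 2)) / (n * (r - 1))
    var_g = np.maximum((ms_between - ms_within) / r, 0.0)
    var_e = ms_within
    denom = var_g + var_e
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(denom > 0, var_g / denom, 0.0)
    for j, name in enumerate(m.metabolites):
        out.append(
            HeritabilityEstimate(name, float(var_g[j]), float(var_e[j]), float(h2[j]))
        )
    return out
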