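"""Mixed linear model association with a genomic relationship matrix.

The model is y = Xb + g*beta + u + e with u ~ N(0, sigma2_g * G) and
e ~ N(0, sigma2_e * I), where G is the realised genomic relationship
matrix (VanRaden/Yang form). Variance components are estimated once by
REML on the null model (no candidate variant) and reused across variants
— the standard MLMA economy — and each variant is then tested by
generalised least squares under the fitted covariance, with a two-sided
p-value from the normal approximation to the Wald statistic. For
genome-wide trait scans a leave-one-chromosome-out (LOCO) variant is
provided: variants on chromosome c are tested against a GRM built from
all other chromosomes, avoiding proximal contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .data_io import GenotypeMatrix

ASSOC_COLUMNS = ["chrom", "pos", "ref", "alt", "tested_allele", "effect",
                 "se", "z", "p", "n", "phenotype_id", "flag"]


@dataclass
class Grm:
    """Realised genomic relationships between individuals."""

    individuals: list
    values: np.ndarray
    n_variants_used: int

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class VarianceComponents:
    """REML estimates of the genetic and residual variances."""

    sigma2_g: float
    sigma2_e: float
    loglik: float

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def build_grm(gm: GenotypeMatrix, variant_idx=None) -> Grm:
    """Genomic relationship matrix from centred, MAF-scaled dosages.

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    over the m informative subset variants, with x the (mean-imputed)
    alternate-allele dosage and p its frequency. Monomorphic variants are
    skipped.
    """
    if variant_idx is None:
        variant_idx = np.arange(gm.n_variants)
    variant_idx = np.asarray(variant_idx)
    if variant_idx.size == 0:
        raise ValueError("empty variant subset for GRM")
    x = gm.dosage_float()[variant_idx]
    p = x.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all GRM variants are monomorphic")
    x, p = x[poly], p[poly]
    z = (x - 2 * p[:, None]) / np.sqrt(2 * p[:, None] * (1 - p[:, None]))
    m = z.shape[0]
    return Grm(individuals=list(gm.individuals["id"]),
               values=z.T @ z / m, n_variants_used=m)


def reml_fit(y: np.ndarray, X: np.ndarray, grm: Grm,
             tol: float = 1e-8) -> VarianceComponents:
    """REML variance components via eigendecomposition of the GRM.

    After rotating the model by the GRM's eigenvectors, the restricted
    likelihood is profiled down to a scalar function of the variance
    ratio gamma = sigma2_g / sigma2_e and maximised by bounded scalar
    optimisation on log(gamma); gamma = 0 (no genetic variance) is
    evaluated explicitly so boundary optima are exact.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    if n < p + 2:
        raise ValueError("too few observations for REML")
    d, u = np.linalg.eigh(grm.values)
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ X

    def neg2_reml(log_gamma: float) -> tuple:
        gamma = np.exp(log_gamma) if np.isfinite(log_gamma) else 0.0
        w = gamma * d + 1.0
        xw = xt / w[:, None]
        xtx = xt.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ yt)
        r = yt - xt @ beta
        rss = float(np.sum(r * r / w))
        sigma2_e = rss / (n - p)
        val = ((n - p) * np.log(sigma2_e) + np.sum(np.log(w))
               + np.linalg.slogdet(xtx)[1] + (n - p))
        return val, sigma2_e

    res = minimize_scalar(lambda lg: neg2_reml(lg)[0], bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": tol})
    val0, s2e0 = neg2_reml(-np.inf)
    if val0 <= res.fun:
        return VarianceComponents(0.0, s2e0, -0.5 * val0)
    gamma = float(np.exp(res.x))
    val, s2e = neg2_reml(res.x)
    return VarianceComponents(gamma * s2e, s2e, -0.5 * val)


def _whiten(grm_values: np.ndarray, vc: VarianceComponents):
    """Return a transform T with T V T' = I for V = s2g*G + s2e*I."""
    d, u = np.linalg.eigh(grm_values)
    d = np.clip(d, 0.0, None)
    w = vc.sigma2_g * d + vc.sigma2_e
    return (u / np.sqrt(w)).T  # rows scaled: T = diag(w^-1/2) U'


def mlma_scan(y: np.ndarray, X: np.ndarray, gm: GenotypeMatrix, grm: Grm,
              vc: VarianceComponents | None = None, variant_idx=None,
              phenotype_id: str = "trait") -> pd.DataFrame:
    """Per-variant mixed-model association scan.

    Variance components come from one null-model REML fit (without the
    candidate variant) and are reused; each variant's dosage is appended
    to the fixed effects and tested by GLS under the fitted covariance.
    The tested allele is always the alternate allele, so effect signs are
    directly comparable across scans. Variants with zero dosage variance
    after mean imputation are emitted with p = 1 and flag
    ``zero_variance``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if vc is None:
        vc = reml_fit(y, X, grm)
    if variant_idx is None:
        variant_idx = np.arange(gm.n_variants)
    variant_idx = np.asarray(variant_idx)

    t = _whiten(grm.values, vc)
    yt = t @ y
    xt = t @ X
    # residualise against fixed effects in the whitened space
    q, _ = np.linalg.qr(xt)
    y_res = yt - q @ (q.T @ yt)
    dos = gm.dosage_float()[variant_idx]
    gt = dos @ t.T                        # (n_variants, n)
    g_res = gt - (gt @ q) @ q.T
    gg = np.einsum("ij,ij->i", g_res, g_res)
    gy = g_res @ y_res
    zero = gg <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(zero, 0.0, gy / np.maximum(gg, 1e-300))
        se = np.where(zero, np.nan, 1.0 / np.sqrt(np.maximum(gg, 1e-300)))
        zstat = np.where(zero, 0.0, effect / se)
    pvals = np.where(zero, 1.0, 2.0 * norm.sf(np.abs(zstat)))
    pvals = np.maximum(pvals, np.finfo(float).tiny)
    v = gm.variants.iloc[variant_idx]
    return pd.DataFrame({
        "chrom": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
        "ref": v["ref"].to_numpy(), "alt": v["alt"].to_numpy(),
        "tested_allele": v["alt"].to_numpy(),
        "effect": effect, "se": se, "z": zstat, "p": pvals,
        "n": y.size, "phenotype_id": phenotype_id,
        "flag": np.where(zero, "zero_variance", ""),
    })


def loco_scan(y: np.ndarray, X: np.ndarray, gm: GenotypeMatrix,
              phenotype_id: str = "trait") -> pd.DataFrame:
    """Leave-one-chromosome-out mixed-model scan.

    Variants on chromosome c are tested with a GRM built from all other
    chromosomes (variance components re-estimated per left-out
    chromosome). Requires at least two chromosomes.
    """
    chroms = pd.unique(gm.variants["chrom"])
    if len(chroms) < 2:
        raise ValueError("LOCO needs >= 2 chromosomes; use mlma_scan")
    parts = []
    chrom_arr = gm.variants["chrom"].to_numpy()
    for c in chroms:
        test_idx = np.flatnonzero(chrom_arr == c)
        grm_idx = np.flatnonzero(chrom_arr != c)
        grm = build_grm(gm, grm_idx)
        parts.append(mlma_scan(y, X, gm, grm, vc=None, variant_idx=test_idx,
                               phenotype_id=phenotype_id))
    out = pd.concat(parts, ignore_index=True)
    order = np.lexsort((out["pos"].to_numpy(),
                        out["chrom"].to_numpy().astype(str)))
    return out.iloc[order].reset_index(drop=True)


def write_assoc(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_assoc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
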