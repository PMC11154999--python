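"""Cis-eQTL scans and the dual allele-specific-expression (ASE) test.

Cis scans test every variant within 1 Mb of a feature (gene, exon or
intron cluster) against its expression phenotype with the mixed-model
machinery (age as covariate, GRM random effect). ASE works on pairs of a
transcript SNP (tSNP, the heterozygous exonic site whose allele counts
form the phenotype) and a driver SNP (dSNP, a nearby variant tested for
association with the allelic imbalance), using only individuals
heterozygous at both sites. Two tests are run per pair — a linear
regression of the allele-count phenotype on the phase coding, and a
counts-based Z-test — and a pair is called significant only when both
pass the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .data_io import MISSING, GenotypeMatrix, compute_maf
from .expression_phenotypes import allele_count_phenotype
from .gwas_engine import Grm, VarianceComponents, mlma_scan

ASE_CALL_COLUMNS = ["tSNP_chrom", "tSNP_pos", "dSNP_chrom", "dSNP_pos",
                    "n_doublehet", "b", "p_linear", "Z", "p_z", "significant"]


def cis_window_variants(gm: GenotypeMatrix, chrom, start: int, end: int,
                        window_bp: int = 1_000_000) -> np.ndarray:
    """Indices of variants within ``window_bp`` of [start, end] on
    ``chrom`` (bounds inclusive, 1-based)."""
    v = gm.variants
    mask = ((v["chrom"] == chrom)
            & (v["pos"] >= start - window_bp)
            & (v["pos"] <= end + window_bp))
    return np.flatnonzero(mask.to_numpy())


def cis_scan(feature: pd.Series, gm: GenotypeMatrix, phenotype: np.ndarray,
             grm: Grm, covariates: np.ndarray | None = None,
             window_bp: int = 1_000_000,
             vc: VarianceComponents | None = None) -> pd.DataFrame:
    """Mixed-model association of one expression feature against its cis
    window.

    ``feature`` needs ``feature_id, kind, chrom, start, end``; the result
    is the standard association table labelled geQTL/eeQTL/sQTL by
    feature kind. An empty window yields an empty table.
    """
    idx = cis_window_variants(gm, feature["chrom"], int(feature["start"]),
                              int(feature["end"]), window_bp)
    label = {"gene": "geQTL", "exon": "eeQTL", "intron": "sQTL"}.get(
        feature.get("kind", "gene"), "eQTL")
    pid = f"{label}:{feature['feature_id']}"
    n = gm.n_individuals
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    if idx.size == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "tested_allele",
                                     "effect", "se", "z", "p", "n",
                                     "phenotype_id", "flag"])
    return mlma_scan(phenotype, X, gm, grm, vc=vc, variant_idx=idx,
                     phenotype_id=pid)


def phase_code(gm: GenotypeMatrix, t_idx: int, d_idx: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Phase coding of the dSNP relative to the tSNP.

    Only individuals heterozygous and phased at both sites are returned.
    x = +1 when the dSNP alternate allele lies on the same haplotype as
    the tSNP reference allele ("same phase"), -1 otherwise. The
    orientation is a convention; flipping it only changes the sign of the
    linear-model effect.
    """
    th = gm.haplotypes[t_idx]
    dh = gm.haplotypes[d_idx]
    het_t = (gm.dosage[t_idx] == 1) & (th[:, 0] != MISSING) & (th[:, 1] != MISSING)
    het_d = (gm.dosage[d_idx] == 1) & (dh[:, 0] != MISSING) & (dh[:, 1] != MISSING)
    keep = np.flatnonzero(het_t & het_d)
    if keep.size == 0:
        return np.empty(0), keep
    ref_hap = (th[keep, 0] == 1).astype(int)   # haplotype index carrying tSNP ref
    d_on_ref_hap = dh[keep, ref_hap]
    x = np.where(d_on_ref_hap == 1, 1.0, -1.0)
    return x, keep


def ase_linear_test(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of the allele-count phenotype on the phase
    coding (intercept included), two-sided p from t with n-2 df.

    Returns (nan, nan) — flagged undefined — when there are fewer than
    three double-heterozygotes or the coding is constant.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 3 or np.all(x == x[0]):
        return np.nan, np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    b = float(xc @ yc) / sxx
    resid = yc - b * xc
    s2 = float(resid @ resid) / (n - 2)
    if s2 <= 0:
        return b, float(np.finfo(float).tiny)
    se = np.sqrt(s2 / sxx)
    p = 2.0 * t_dist.sf(abs(b) / se, df=n - 2)
    return b, max(float(p), float(np.finfo(float).tiny))


def ase_z_test(n_ref: np.ndarray, n_alt: np.ndarray, x: np.ndarray
               ) -> tuple[float, float]:
    """Counts-based ASE Z-test.

    With M/P the tSNP reference/alternate counts of same-phase
    individuals (x = +1) and N/Q those of alternate-phase individuals
    (x = -1), the statistic is Z = (A/T - 0.5) * sqrt(4T) with
    A = sum(M) + sum(Q) and T the grand total — the score statistic of
    Binomial(T, 1/2). Returns (nan, nan) when T = 0.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    same = x > 0
    a = n_ref[same].sum() + n_alt[~same].sum()
    t = n_ref.sum() + n_alt.sum()
    if t <= 0:
        return np.nan, np.nan
    z = (a / t - 0.5) * np.sqrt(4.0 * t)
    p = 2.0 * norm.sf(abs(z))
    return float(z), max(float(p), float(np.finfo(float).tiny))


@dataclass
class AseCall:
    """Outcome of the dual ASE test for one tSNP/dSNP pair."""

    t_idx: int
    d_idx: int
    n_doublehet: int
    b: float
    p_linear: float
    z: float
    p_z: float
    significant: bool


def ase_dual_call(t_idx: int, d_idx: int, n_doublehet: int, b: float,
                  p_linear: float, z: float, p_z: float,
                  threshold: float = 1e-6) -> AseCall:
    """Declare a pair significant only when BOTH tests have p <= threshold;
    an undefined (NaN) test can never be significant."""
    ok = (np.isfinite(p_linear) and np.isfinite(p_z)
          and p_linear <= threshold and p_z <= threshold)
    return AseCall(t_idx, d_idx, n_doublehet, b, p_linear, z, p_z, bool(ok))


def ase_scan(gm: GenotypeMatrix, ase_table: pd.DataFrame,
             window_bp: int = 1_000_000, maf_min: float = 0.05,
             threshold: float = 1e-6) -> pd.DataFrame:
    """Dual ASE test of every dSNP within 1 Mb of every tSNP in the table.

    ``ase_table`` must have passed QC and carry chrom, pos, individual,
    nRef, nAlt. Both the tSNP and the dSNP must have MAF >= ``maf_min``
    (the sample shrinks to double-heterozygotes, so rare variants are
    uninformative). Returns one row per pair in the shared call layout.
    """
    maf = compute_maf(gm)
    key_to_idx = {(c, p): i for i, (c, p) in
                  enumerate(zip(gm.variants["chrom"], gm.variants["pos"]))}
    ind_pos = {iid: j for j, iid in enumerate(gm.individuals["id"])}
    rows = []
    for (chrom, pos), sub in ase_table.groupby(["chrom", "pos"], sort=True):
        t_idx = key_to_idx.get((chrom, pos))
        if t_idx is None or maf[t_idx] < maf_min:
            continue
        counts = np.zeros((gm.n_individuals, 2))
        for r in sub.itertuples(index=False):
            j = ind_pos.get(r.individual)
            if j is not None:
                counts[j] = (r.nRef, r.nAlt)
        d_candidates = cis_window_variants(gm, chrom, pos, pos, window_bp)
        for d_idx in d_candidates:
            if d_idx == t_idx or maf[d_idx] < maf_min:
                continue
            x, keep = phase_code(gm, t_idx, int(d_idx))
            covered = counts[keep].sum(axis=1) > 0
            x, keep = x[covered], keep[covered]
            y = allele_count_phenotype(counts[keep, 0], counts[keep, 1])
            b, p_lin = ase_linear_test(y, x)
            z, p_z = ase_z_test(counts[keep, 0], counts[keep, 1], x)
            call = ase_dual_call(t_idx, int(d_idx), keep.size, b, p_lin, z,
                                 p_z, threshold)
            rows.append((chrom, pos, gm.variants.at[d_idx, "chrom"],
                         gm.variants.at[d_idx, "pos"], call.n_doublehet,
                         call.b, call.p_linear, call.z, call.p_z,
                         call.significant))
    return pd.DataFrame(rows, columns=ASE_CALL_COLUMNS)
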