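"""Turn raw RNA-seq count matrices and allele-count tables into
analysis-ready expression phenotypes.

Three feature kinds are handled: gene counts, exon counts and intron
(splicing) counts grouped into clusters. Between-sample normalisation uses
the trimmed mean of M-values (TMM); gene/exon phenotypes for association
scans are log2 counts-per-million on effective library sizes; intron
phenotypes are within-cluster usage proportions. Allele-specific
expression works from per-individual reference/alternate read counts at
heterozygous transcript SNPs, with the allele-count phenotype
log((nRef + 10)/(nAlt + 10)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ["feature_id", "kind", "chrom", "start", "end"]

ASE_COLUMNS = ["chrom", "pos", "ref", "alt", "individual",
               "nRef", "nAlt", "depth", "top2_match"]


@dataclass
class ExpressionMatrix:
    """Feature-by-individual count matrix with library-size bookkeeping.

    ``features`` has columns ``feature_id, kind, chrom, start, end`` (kind
    in {gene, exon, intron}) plus ``parent`` for exons (gene id) and
    ``cluster`` for introns. ``counts`` is float64 (n_features,
    n_individuals); ``norm_factors`` holds TMM factors once computed.
    """

    features: pd.DataFrame
    individuals: list
    counts: np.ndarray
    norm_factors: np.ndarray | None = None

    def __post_init__(self):
        if self.counts.shape != (len(self.features), len(self.individuals)):
            raise ValueError("counts shape must be (n_features, n_individuals)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def lib_size(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def effective_lib_size(self) -> np.ndarray:
        f = self.norm_factors if self.norm_factors is not None else 1.0
        return self.lib_size * f

    def take_features(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(self, features=self.features.iloc[idx].reset_index(drop=True),
                       counts=self.counts[idx])

    def cpm(self) -> np.ndarray:
        """Counts per million on effective library sizes."""
        lib = self.effective_lib_size
        if (lib <= 0).any():
            bad = [self.individuals[j] for j in np.flatnonzero(lib <= 0)]
            raise ValueError(f"zero library size for individuals: {bad}")
        return self.counts / lib * 1e6

    def log_cpm(self, prior: float = 0.5) -> np.ndarray:
        """log2 CPM with a small prior count, the association phenotype
        for gene and exon features."""
        lib = self.effective_lib_size
        return np.log2((self.counts + prior) / (lib + 2 * prior) * 1e6)

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [self.features,
             pd.DataFrame(self.counts, columns=list(self.individuals))], axis=1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = [c for c in df.columns
                     if c in FEATURE_COLUMNS + ["parent", "cluster"]]
        inds = [c for c in df.columns if c not in meta_cols]
        return cls(features=df[meta_cols], individuals=inds,
                   counts=df[inds].to_numpy(dtype=np.float64))


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
                     lib_ref: float, trim_m: float, trim_a: float) -> float:
    """TMM factor of one column against the reference column."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o, r = obs[pos], ref[pos]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # precision weights: inverse asymptotic (delta-method) variance of M
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], 1.0 / v[finite]
    n = m.size
    if n == 0:
        return 1.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_normalise(em: ExpressionMatrix, trim_m: float = 0.30,
                  trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference column is the one whose 75th-percentile
    count-fraction is closest to the sample mean of those fractions; each
    column's factor is the weighted trimmed mean of gene-wise log-ratios
    against the reference (trim ``trim_m`` on M, ``trim_a`` on A,
    precision weights from the delta method). Factors are rescaled so
    their geometric mean is 1 and stored on ``em.norm_factors``.
    """
    if len(em.individuals) < 2:
        raise ValueError("TMM needs at least two individuals")
    lib = em.lib_size
    if (lib <= 0).any():
        bad = [em.individuals[j] for j in np.flatnonzero(lib <= 0)]
        raise ValueError(f"column of all zeros for individuals: {bad}")
    uq = np.quantile(em.counts / lib, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_pair_factor(em.counts[:, j], em.counts[:, ref_j],
                         lib[j], lib[ref_j], trim_m, trim_a)
        for j in range(len(em.individuals))
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    em.norm_factors = factors
    return factors


def cpm_filter(em: ExpressionMatrix, min_cpm: float = 3.0,
               min_frac_samples: float = 0.5) -> ExpressionMatrix:
    """Keep features with >= ``min_cpm`` counts-per-million (inclusive)
    in at least ``min_frac_samples`` of the individuals.

    CPM uses effective library sizes when TMM factors are present.
    """
    cpm = em.cpm()
    frac = (cpm >= min_cpm).mean(axis=1)
    return em.take_features(np.flatnonzero(frac >= min_frac_samples))


def intron_usage(em: ExpressionMatrix) -> np.ndarray:
    """Within-cluster usage proportion of each intron (0 where the whole
    cluster has zero counts in an individual)."""
    if "cluster" not in em.features.columns:
        raise ValueError("intron matrix needs a 'cluster' feature column")
    cluster = em.features["cluster"].to_numpy()
    totals = pd.DataFrame(em.counts).groupby(cluster).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = np.where(totals > 0, em.counts / np.maximum(totals, 1e-300), 0.0)
    return usage


def intron_cluster_filter(em: ExpressionMatrix, min_presence: float = 0.60,
                          var_eps: float = 1e-8) -> ExpressionMatrix:
    """Drop introns observed in < ``min_presence`` of individuals or with
    usage variance <= ``var_eps`` (almost no variation)."""
    present = (em.counts > 0).mean(axis=1)
    usage = intron_usage(em)
    var = usage.var(axis=1)
    keep = (present >= min_presence) & (var > var_eps)
    return em.take_features(np.flatnonzero(keep))


def ase_qc(table: pd.DataFrame, min_sum: int = 10,
           max_depth_mismatch: float = 0.20) -> pd.DataFrame:
    """Apply the three allele-count QC rules.

    Rows are removed when the allele-count sum is below ``min_sum``, when
    the gap between read depth and the allele-count sum exceeds
    ``max_depth_mismatch`` of the depth, or when the site's two most
    prevalent alleles do not match REF/ALT (``top2_match`` false).
    Surviving rows are returned unchanged.
    """
    s = table["nRef"] + table["nAlt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        mismatch = (table["depth"] - s) / table["depth"].replace(0, np.nan)
    keep = (s >= min_sum) & (mismatch.fillna(1.0) <= max_depth_mismatch)
    if "top2_match" in table.columns:
        keep &= table["top2_match"].astype(bool)
    return table.loc[keep].reset_index(drop=True)


def allele_count_phenotype(n_ref, n_alt, pseudo: float = 10.0):
    """Allele-count phenotype ln((nRef + 10)/(nAlt + 10)).

    Natural log; antisymmetric under swapping the two allele counts; the
    pseudocount keeps it defined at zero coverage.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    return np.log((n_ref + pseudo) / (n_alt + pseudo))


def read_ase_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    return df


def write_ase_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
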