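"""Genotype and phenotype I/O plus array-genotyping QC rules.

Genotypes live in a :class:`GenotypeMatrix`: phased haplotypes (variant x
individual x 2), derived dosages, per-call quality scores (GenCall-style,
0-1) and per-variant imputation quality. All coordinates are 1-based
inclusive, the VCF convention; downstream window arithmetic is stated in
those units. Only biallelic sites are supported: multi-allelic records are
rejected with an explicit error because the allele-specific expression QC
requires the two most prevalent alleles to match REF and ALT.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1  # sentinel for missing haplotype alleles / dosages

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "impute_r2"]


class VcfParseError(ValueError):
    """Malformed or unsupported VCF content."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Phased diploid genotypes with per-call QC and variant metadata.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt,
        impute_r2`` in input order.
    individuals : pandas.DataFrame
        One row per individual with columns ``id, stratum, line``.
    haplotypes : ndarray of int8, shape (n_variants, n_individuals, 2)
        0/1 allele indicators; ``MISSING`` marks a missing or unphased
        allele call (unphased genotypes keep their dosage but carry no
        phase information).
    dosage : ndarray of int8, shape (n_variants, n_individuals)
        Alternate-allele count 0/1/2, ``MISSING`` when the genotype is
        unknown.
    qc : ndarray of float32 or None
        Per-call quality score in [0, 1] (GenCall analogue).
    """

    variants: pd.DataFrame
    individuals: pd.DataFrame
    haplotypes: np.ndarray
    dosage: np.ndarray
    qc: np.ndarray | None = None

    def __post_init__(self):
        n_var, n_ind = len(self.variants), len(self.individuals)
        if self.haplotypes.shape != (n_var, n_ind, 2):
            raise ValueError("haplotypes must have shape (n_variants, n_individuals, 2)")
        if self.dosage.shape != (n_var, n_ind):
            raise ValueError("dosage must have shape (n_variants, n_individuals)")
        phased = np.all(self.haplotypes >= 0, axis=2)
        hap_sum = self.haplotypes.sum(axis=2)
        ok = self.dosage[phased] == hap_sum[phased]
        if not np.all(ok):
            raise ValueError("dosage inconsistent with phased haplotypes")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def variant_keys(self) -> pd.MultiIndex:
        v = self.variants
        return pd.MultiIndex.from_arrays([v["chrom"], v["pos"], v["ref"], v["alt"]])

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[idx],
            dosage=self.dosage[idx],
            qc=None if self.qc is None else self.qc[idx],
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            individuals=self.individuals.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[:, idx],
            dosage=self.dosage[:, idx],
            qc=None if self.qc is None else self.qc[:, idx],
        )

    def dosage_float(self, mean_impute: bool = True) -> np.ndarray:
        """Dosage as float with missing entries mean-imputed per variant."""
        d = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if mean_impute and miss.any():
            with np.errstate(invalid="ignore"):
                d[miss] = np.nan
                means = np.nanmean(d, axis=1)
            means = np.where(np.isnan(means), 0.0, means)
            d = np.where(np.isnan(d), means[:, None], d)
        return d


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency over non-missing calls.

    MAF = min(p, 1-p) with p the alternate-allele frequency; invariant to
    swapping the REF/ALT labels. Variants where every call is missing get
    NaN.
    """
    d = gm.dosage
    nonmiss = d != MISSING
    n_alleles = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, d, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def alt_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant alternate-allele frequency over non-missing calls."""
    d = gm.dosage
    nonmiss = d != MISSING
    n_alleles = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


def read_genotypes(path: str | os.PathLike, r2_key: str = "R2",
                   qc_key: str = "GC") -> GenotypeMatrix:
    """Read phased genotypes from a VCF file.

    Haplotype order is preserved exactly as written (``first|second``).
    Unphased genotypes keep their dosage but both haplotype slots are set
    to missing. Multi-allelic sites raise :class:`VcfParseError`.

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped).
    r2_key : str
        INFO key carrying per-variant imputation quality.
    qc_key : str
        FORMAT key carrying per-call quality scores, if present.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps, dosages, qcs = [], [], [], []
    any_qc = False
    for var in vcf:
        if len(var.ALT) != 1:
            raise VcfParseError(
                f"multi-allelic site at {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT)}); split or drop it first"
            )
        r2 = var.INFO.get(r2_key)
        rows.append((var.CHROM, var.POS, var.ID or ".", var.REF, var.ALT[0],
                     float(r2) if r2 is not None else np.nan))
        h = np.full((len(samples), 2), MISSING, dtype=np.int8)
        d = np.full(len(samples), MISSING, dtype=np.int8)
        for j, call in enumerate(var.genotypes):
            a0, a1, phased = call[0], call[1], call[2]
            if a0 >= 0 and a1 >= 0:
                d[j] = a0 + a1
                if phased:
                    h[j, 0], h[j, 1] = a0, a1
        haps.append(h)
        dosages.append(d)
        if qc_key in (var.FORMAT or []):
            any_qc = True
            qcs.append(np.asarray(var.format(qc_key), dtype=np.float32).ravel())
        else:
            qcs.append(np.full(len(samples), np.nan, dtype=np.float32))
    vcf.close()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dup = variants.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        i = int(np.flatnonzero(dup.values)[0])
        raise VcfParseError(
            f"duplicate variant record {variants.loc[i, 'chrom']}:{variants.loc[i, 'pos']}"
        )
    individuals = pd.DataFrame({"id": samples, "stratum": "", "line": ""})
    n_var = len(variants)
    return GenotypeMatrix(
        variants=variants,
        individuals=individuals,
        haplotypes=(np.stack(haps) if n_var else np.zeros((0, len(samples), 2), np.int8)),
        dosage=(np.stack(dosages) if n_var else np.zeros((0, len(samples)), np.int8)),
        qc=(np.stack(qcs) if any_qc and n_var else None),
    )


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike,
                    r2_key: str = "R2", qc_key: str = "GC") -> None:
    """Write a :class:`GenotypeMatrix` as a VCF v4.2 text file.

    Phased calls are written ``a|b`` preserving haplotype order; unphased
    known genotypes as ``a/b`` (alleles in ascending order); unknown as
    ``./.``. Round-trip through :func:`read_genotypes` is the identity on
    haplotypes, positions and alleles.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f'##INFO=<ID={r2_key},Number=1,Type=Float,'
              'Description="Imputation accuracy (r-squared)">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    write_qc = gm.qc is not None
    if write_qc:
        buf.write(f'##FORMAT=<ID={qc_key},Number=1,Type=Float,'
                  'Description="Per-call quality score">\n')
    for chrom in pd.unique(gm.variants["chrom"]):
        buf.write(f"##contig=<ID={chrom}>\n")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    buf.write("\t".join(cols + list(gm.individuals["id"])) + "\n")
    fmt = f"GT:{qc_key}" if write_qc else "GT"
    for i, v in enumerate(gm.variants.itertuples(index=False)):
        info = f"{r2_key}={v.impute_r2:.6g}" if np.isfinite(v.impute_r2) else "."
        fields = [str(v.chrom), str(v.pos), v.id, v.ref, v.alt, ".", "PASS", info, fmt]
        for j in range(gm.n_individuals):
            a0, a1 = gm.haplotypes[i, j]
            d = gm.dosage[i, j]
            if a0 != MISSING and a1 != MISSING:
                gt = f"{a0}|{a1}"
            elif d != MISSING:
                gt = "/".join(["0"] * (2 - d) + ["1"] * d)
            else:
                gt = "./."
            if write_qc:
                gt += f":{gm.qc[i, j]:.4g}"
            fields.append(gt)
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def gencall_filter(gm: GenotypeMatrix, score_min: float = 0.6,
                   max_low_frac: float = 0.10) -> GenotypeMatrix:
    """Drop individuals/variants with too many low-quality calls.

    Individuals, then variants, with strictly more than ``max_low_frac``
    of their calls scoring below ``score_min`` are removed; low-scoring
    calls that survive are set to missing. Idempotent: a second
    application changes nothing because surviving low calls are blanked.
    """
    if gm.qc is None:
        raise ValueError("gencall_filter requires per-call qc scores")
    low = gm.qc < score_min  # NaN compares False: unscored calls never count as low
    keep_ind = low.mean(axis=0) <= max_low_frac
    gm = gm.take_individuals(np.flatnonzero(keep_ind))
    low = gm.qc < score_min
    keep_var = low.mean(axis=1) <= max_low_frac
    gm = gm.take_variants(np.flatnonzero(keep_var))
    low = gm.qc < score_min
    if low.any():
        haps = gm.haplotypes.copy()
        dos = gm.dosage.copy()
        qc = gm.qc.copy()
        haps[low] = MISSING
        dos[low] = MISSING
        qc[low] = 1.0  # blanked calls carry no remaining low-quality evidence
        gm = replace(gm, haplotypes=haps, dosage=dos, qc=qc)
    return gm


def variant_qc(gm: GenotypeMatrix, maf_min: float,
               r2_min: float = 0.40) -> GenotypeMatrix:
    """Remove variants failing the MAF or imputation-r2 thresholds.

    A variant is kept when ``maf >= maf_min`` and ``impute_r2 >= r2_min``;
    genotype values are never altered, only membership. Missing r2 is
    treated as failing.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    maf = compute_maf(gm)
    r2 = gm.variants["impute_r2"].to_numpy(dtype=float)
    keep = (maf >= maf_min) & (r2 >= r2_min)
    keep &= ~np.isnan(maf)
    return gm.take_variants(np.flatnonzero(keep))


def intersect_variants(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix
                       ) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Restrict two genotype sets to their shared variants.

    Variants match on (chrom, pos, ref, alt); both outputs carry the
    shared variants in the same order (the order of ``gm_a``).
    Allele-swapped sites (REF/ALT exchanged between datasets) are not
    merged; they are returned in the third element so the caller can
    decide how to handle them.
    """
    keys_a, keys_b = gm_a.variant_keys, gm_b.variant_keys
    common = keys_a.intersection(keys_b, sort=False)
    ia = np.flatnonzero(keys_a.isin(common))
    pos_b = pd.Series(np.arange(len(keys_b)), index=keys_b)
    ib = pos_b.loc[keys_a[ia]].to_numpy()
    swapped_keys = pd.MultiIndex.from_arrays(
        [gm_a.variants["chrom"], gm_a.variants["pos"],
         gm_a.variants["alt"], gm_a.variants["ref"]]
    )
    swap_mask = swapped_keys.isin(keys_b) & ~keys_a.isin(common)
    swapped = gm_a.variants.loc[swap_mask, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return gm_a.take_variants(ia), gm_b.take_variants(ib), swapped


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a phenotype/covariate table (TSV with header).

    Expected columns: ``individual, trait, value, stratum`` plus any
    number of covariate columns. Binary traits must be coded 0/1.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["individual", "trait"]).any():
        raise ValueError("an individual appears more than once for a trait")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
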