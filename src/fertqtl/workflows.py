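"""End-to-end assemblies of the pipeline stages.

These are the glue runs a user would script: per-stratum mixed-model
GWAS combined by weighted Z-score meta-analysis, and cis scans over all
expression features of one kind. They contain no statistics of their
own — everything is delegated to the stage modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix
from .eqtl_ase import cis_scan
from .expression_phenotypes import ExpressionMatrix, intron_usage
from .gwas_engine import build_grm, loco_scan, mlma_scan, reml_fit
from .meta_analysis import align_alleles, weighted_z_meta


def design_matrix(pheno: pd.DataFrame, covariates=("calving_age",
                                                   "calving_month",
                                                   "synchronisation")) -> np.ndarray:
    """Fixed-effect design from a phenotype table slice: intercept,
    continuous covariates as-is, calving month as categorical indicators;
    all-missing covariates are dropped."""
    cols = [np.ones(len(pheno))]
    for c in covariates:
        if c not in pheno.columns or pheno[c].isna().all():
            continue
        if c == "calving_month":
            d = pd.get_dummies(pheno[c].astype(int), drop_first=True)
            cols.append(d.to_numpy(dtype=float))
        else:
            cols.append(pheno[c].to_numpy(dtype=float)[:, None])
    return np.column_stack(cols)


def trait_meta_gwas(gm: GenotypeMatrix, pheno: pd.DataFrame, trait: str,
                    loco: bool = True) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Per-stratum mixed-model GWAS of one trait, combined by weighted
    Z-score meta-analysis. Returns (meta table, per-stratum scans)."""
    sub_all = pheno.loc[pheno["trait"] == trait]
    scans = []
    for s in pd.unique(sub_all["stratum"]):
        sub = sub_all.loc[sub_all["stratum"] == s]
        j = gm.individuals["id"].isin(sub["individual"]).to_numpy()
        gms = gm.take_individuals(np.flatnonzero(j))
        sub = sub.set_index("individual").loc[gms.individuals["id"]]
        y = sub["value"].to_numpy(dtype=float)
        X = design_matrix(sub)
        if loco and gms.variants["chrom"].nunique() > 1:
            scans.append(loco_scan(y, X, gms, phenotype_id=trait))
        else:
            grm = build_grm(gms)
            scans.append(mlma_scan(y, X, gms, grm, phenotype_id=trait))
    meta = weighted_z_meta(align_alleles(scans))
    return meta, scans


def expression_cis_scans(gm: GenotypeMatrix, em: ExpressionMatrix,
                         age: np.ndarray | None = None,
                         window_bp: int = 1_000_000,
                         grm=None) -> pd.DataFrame:
    """Cis mixed-model scan of every feature in an expression matrix.

    Gene/exon features are scanned on log2 CPM (TMM-effective library
    sizes); intron features on within-cluster usage. Age enters as a
    covariate when provided; one whole-genome GRM is shared across
    features.
    """
    if grm is None:
        grm = build_grm(gm)
    kinds = em.features["kind"].unique()
    values = (intron_usage(em) if set(kinds) == {"intron"} else em.log_cpm())
    parts = []
    for i in range(em.n_features):
        feat = em.features.iloc[i]
        scan = cis_scan(feat, gm, values[i], grm,
                        covariates=None if age is None else age,
                        window_bp=window_bp)
        if len(scan):
            scan = scan.assign(feature_id=feat["feature_id"],
                               kind=feat["kind"])
            parts.append(scan)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
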