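"""Weighted Z-score meta-analysis of per-stratum association scans.

Strata (breed-by-sex subsets analysed separately) are combined with the
sample-size-weighted Z-score scheme: z_meta = sum(w_s z_s) /
sqrt(sum(w_s^2)) with w_s = sqrt(n_s). A variant absent from some strata
is combined over the strata that carry it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

KEY = ["chrom", "pos", "ref", "alt"]


def align_alleles(scans: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Re-sign every stratum's effects so the tested allele is ALT.

    Scans whose ``tested_allele`` equals REF at a variant have effect and
    z negated. Rows where the tested allele matches neither REF nor ALT
    are dropped (strand problems are for the caller to resolve).
    """
    out = []
    for scan in scans:
        scan = scan.copy()
        on_ref = scan["tested_allele"] == scan["ref"]
        on_alt = scan["tested_allele"] == scan["alt"]
        scan.loc[on_ref, ["effect", "z"]] *= -1.0
        scan.loc[on_ref, "tested_allele"] = scan.loc[on_ref, "alt"]
        out.append(scan.loc[on_ref | on_alt].reset_index(drop=True))
    return out


def weighted_z_meta(scans: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine aligned per-stratum scans into one weighted Z-score scan.

    Returns one row per variant present in at least one stratum with
    columns ``z_meta, p, direction, n_strata, total_n`` alongside the
    variant key; the result is invariant to the order of the input scans.
    """
    pieces = []
    for scan in scans:
        w = np.sqrt(scan["n"].to_numpy(dtype=float))
        pieces.append(pd.DataFrame({
            **{k: scan[k] for k in KEY},
            "wz": w * scan["z"].to_numpy(), "w2": w * w, "n": scan["n"],
        }))
    allp = pd.concat(pieces, ignore_index=True)
    grouped = allp.groupby(KEY, sort=True).agg(
        wz=("wz", "sum"), w2=("w2", "sum"),
        n_strata=("wz", "size"), total_n=("n", "sum")).reset_index()
    z = grouped["wz"] / np.sqrt(grouped["w2"])
    p = np.maximum(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny)
    out = grouped[KEY + ["n_strata", "total_n"]].copy()
    out["z_meta"] = z
    out["p"] = p
    out["direction"] = np.sign(z).astype(int)
    return out
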