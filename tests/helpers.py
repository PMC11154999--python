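"""Small constructors shared by the test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from fertqtl.data_io import MISSING, GenotypeMatrix


def make_gm(haplotypes, chrom=None, pos=None, qc=None, ref="A", alt="G",
            stratum=None, line=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an explicit (n_var, n_ind, 2) array.

    Entries of MISSING (-1) in a haplotype pair mark a missing call
    (dosage missing too unless only unphased: pass dosage via a tuple
    (haps, dosage) if needed).
    """
    if isinstance(haplotypes, tuple):
        haps, dosage = haplotypes
        haps = np.asarray(haps, dtype=np.int8)
        dosage = np.asarray(dosage, dtype=np.int8)
    else:
        haps = np.asarray(haplotypes, dtype=np.int8)
        dosage = np.where((haps >= 0).all(axis=2), haps.sum(axis=2),
                          MISSING).astype(np.int8)
    n_var, n_ind, _ = haps.shape
    if pos is None:
        pos = np.arange(1, n_var + 1) * 1000
    if chrom is None:
        chrom = ["chr1"] * n_var
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "id": [f"v{i}" for i in range(n_var)],
        "ref": ref, "alt": alt, "impute_r2": 1.0,
    })
    individuals = pd.DataFrame({
        "id": [f"i{j}" for j in range(n_ind)],
        "stratum": stratum if stratum is not None else "",
        "line": line if line is not None else "",
    })
    return GenotypeMatrix(variants=variants, individuals=individuals,
                          haplotypes=haps, dosage=dosage,
                          qc=None if qc is None else np.asarray(qc, np.float32))


def dosage_gm(dosages, **kw) -> GenotypeMatrix:
    """GenotypeMatrix from a (n_var, n_ind) dosage array, arbitrary phase
    (alt alleles put on the first haplotype)."""
    d = np.asarray(dosages)
    h1 = (d >= 1).astype(np.int8)
    h2 = (d == 2).astype(np.int8)
    haps = np.stack([h1, h2], axis=2)
    return make_gm(haps, **kw)
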