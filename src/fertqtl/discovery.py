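"""Significance thresholding, expected-FDR estimation and QTL clumping.

A variant is significant at p <= threshold (1e-6 by default). The FDR of
such a call set is estimated as Q_e = E(V)/R with E(V) = n_tests *
threshold, the expected count of false positives among R declared
significant. Significant variants are then clumped into QTL regions:
variants are processed from smallest to largest p-value and a variant
within 1 Mb of an existing region on the same chromosome joins it
(single-linkage chaining, so regions can span several Mb); otherwise it
founds a new region with itself as top variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FdrEstimate:
    """Expected false discovery rate of a fixed-threshold call set."""

    n_tests: int
    threshold: float
    n_sig: int
    expected_false: float
    q_e: float


@dataclass
class QtlRegion:
    """A clumped run of significant variants around a top signal."""

    chrom: str
    start: int
    end: int
    top_pos: int
    top_p: float
    members: list = field(default_factory=list)  # row indices into the input

    @property
    def n_members(self) -> int:
        return len(self.members)


def significant_set(results: pd.DataFrame, threshold: float = 1e-6,
                    p_col: str = "p") -> pd.DataFrame:
    """Rows with p <= threshold (inclusive)."""
    return results.loc[results[p_col] <= threshold].reset_index(drop=True)


def estimate_fdr(n_tests: int, threshold: float, n_sig: int) -> FdrEstimate:
    """Q_e = (n_tests * threshold) / n_sig.

    With no significant calls the estimate is undefined (NaN); values
    above 1 are reported as-is.
    """
    if n_tests < 0 or n_sig < 0 or threshold < 0:
        raise ValueError("n_tests, threshold and n_sig must be non-negative")
    if n_sig > n_tests:
        raise ValueError("n_sig cannot exceed n_tests")
    ev = n_tests * threshold
    q_e = ev / n_sig if n_sig > 0 else np.nan
    return FdrEstimate(n_tests, threshold, n_sig, ev, q_e)


def define_qtl_regions(sig: pd.DataFrame, window_bp: int = 1_000_000,
                       mode: str = "chain", p_col: str = "p") -> list[QtlRegion]:
    """Clump significant variants into QTL regions.

    Variants are ranked from smallest to largest p (ties broken by
    position, then alleles, so the output is order-invariant). In
    ``chain`` mode a variant joins a region when it is within
    ``window_bp`` of any current member (single-linkage, allowing
    multi-megabase regions); in ``top`` mode only when it is within
    ``window_bp`` of the region's top variant.
    """
    if mode not in ("chain", "top"):
        raise ValueError("mode must be 'chain' or 'top'")
    if len(sig) == 0:
        return []
    df = sig.reset_index(drop=True)
    sort_cols = [p_col, "pos"] + [c for c in ("ref", "alt") if c in df.columns]
    p_order = df.sort_values(sort_cols, kind="mergesort").index.to_numpy()
    regions: list[QtlRegion] = []
    if mode == "chain":
        # single-linkage on positions: runs with consecutive gaps <= window
        for chrom in pd.unique(df["chrom"]):
            rows = np.flatnonzero((df["chrom"] == chrom).to_numpy())
            rows = rows[np.argsort(df["pos"].to_numpy()[rows], kind="mergesort")]
            pos = df["pos"].to_numpy()[rows]
            breaks = np.flatnonzero(np.diff(pos) > window_bp) + 1
            for run in np.split(np.arange(rows.size), breaks):
                members = rows[run]
                regions.append(_make_region(df, chrom, members, p_col))
    else:
        # greedy clumping: each unassigned top captures variants within window
        assigned = np.zeros(len(df), dtype=bool)
        for i in p_order:
            if assigned[i]:
                continue
            chrom = df.at[i, "chrom"]
            pos = int(df.at[i, "pos"])
            near = ((df["chrom"] == chrom).to_numpy()
                    & (np.abs(df["pos"].to_numpy() - pos) <= window_bp)
                    & ~assigned)
            members = np.flatnonzero(near)
            assigned[members] = True
            regions.append(_make_region(df, chrom, members, p_col))
    regions.sort(key=lambda r: (str(r.chrom), r.start))
    return regions


def _make_region(df: pd.DataFrame, chrom, members: np.ndarray,
                 p_col: str) -> QtlRegion:
    sub = df.iloc[members]
    sort_cols = [p_col, "pos"] + [c for c in ("ref", "alt") if c in df.columns]
    top = sub.sort_values(sort_cols, kind="mergesort").iloc[0]
    return QtlRegion(chrom=chrom, start=int(sub["pos"].min()),
                     end=int(sub["pos"].max()), top_pos=int(top["pos"]),
                     top_p=float(top[p_col]), members=[int(m) for m in members])


def regions_to_frame(regions: list[QtlRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_members": r.n_members, "top_pos": r.top_pos, "top_p": r.top_p,
    } for r in regions])


def regions_to_bed(regions: list[QtlRegion], path) -> None:
    """BED export: 0-based half-open, so start-1 and end unchanged."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                     f"top={r.top_pos};p={r.top_p:.3g}\n")
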