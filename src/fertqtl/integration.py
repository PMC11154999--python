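"""Divergent-line differential expression, eQTL enrichment of trait
signals, cross-population direction concordance and the candidate
overlap report.

Differential expression between the POS (high-fertility) and NEG
(low-fertility) lines uses a negative-binomial exact test with a common
dispersion estimated by conditional maximum likelihood on
quantile-adjusted pseudo-counts, Benjamini-Hochberg control at
FDR < 0.05. Enrichment of trait-significant variants for eQTL is a fold
(perc_eQTL_sig / perc_eQTL_all) with a 2x2 chi-square test. Direction
concordance summarises, for a set of variants, how often the allele
favourable for one trait is also favourable for another. The overlap
report combines everything per QTL region and flags variants whose
directions agree across all available evidence: trait effect, cis
expression effect, line differential expression, line allele-frequency
difference and secondary-trait directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import nbinom, norm, poisson
from statsmodels.stats.multitest import multipletests

from .data_io import MISSING, GenotypeMatrix
from .discovery import QtlRegion
from .expression_phenotypes import ExpressionMatrix

KEY = ["chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# differential expression: NB exact test with common dispersion
# ---------------------------------------------------------------------------

def _q2qnbinom(x: np.ndarray, mu_in: np.ndarray, mu_out: float,
               dispersion: float) -> np.ndarray:
    """Quantile-to-quantile map of NB counts from one mean to another.

    Each observation is carried to the output library size by matching
    cumulative probabilities, averaging a normal and a gamma
    approximation of the NB distribution (both with the same mean and
    variance), which is accurate over the whole count range.
    """
    x = np.asarray(x, dtype=float)
    mu_in = np.broadcast_to(np.asarray(mu_in, dtype=float), x.shape).copy()
    mu_out = np.broadcast_to(np.asarray(mu_out, dtype=float), x.shape).copy()
    eps = 1e-14
    zero = (mu_in < eps) | (mu_out < eps)
    mu_in[zero] += 0.25
    mu_out[zero] += 0.25
    from scipy.stats import gamma as gamma_dist
    ri = 1.0 + dispersion * mu_in
    vi = mu_in * ri
    ro = 1.0 + dispersion * mu_out
    vo = mu_out * ro
    out = np.empty_like(x)
    upper = x >= mu_in
    for mask, tail in ((upper, True), (~upper, False)):
        if not mask.any():
            continue
        xm, mi, mo = x[mask], mu_in[mask], mu_out[mask]
        vim, vom = vi[mask], vo[mask]
        rim, rom = ri[mask], ro[mask]
        if tail:
            p1 = norm.sf(xm, loc=mi, scale=np.sqrt(vim))
            p2 = gamma_dist.sf(xm, a=mi / rim, scale=rim)
            q1 = norm.isf(p1, loc=mo, scale=np.sqrt(vom))
            q2 = gamma_dist.isf(p2, a=mo / rom, scale=rom)
        else:
            p1 = norm.cdf(xm, loc=mi, scale=np.sqrt(vim))
            p2 = gamma_dist.cdf(xm, a=mi / rim, scale=rim)
            q1 = norm.ppf(p1, loc=mo, scale=np.sqrt(vom))
            q2 = gamma_dist.ppf(p2, a=mo / rom, scale=rom)
        out[mask] = 0.5 * (q1 + q2)
    return np.clip(out, 0.0, None)


def _cond_loglik(counts: np.ndarray, dispersion: float) -> float:
    """Conditional NB log-likelihood of one group's (pseudo) counts given
    their total, summed over genes; the common-dispersion objective."""
    r = 1.0 / dispersion
    n = counts.shape[1]
    z = counts.sum(axis=1)
    ll = (gammaln(counts + r).sum(axis=1) - n * gammaln(r)
          + gammaln(n * r) - gammaln(z + n * r))
    return float(ll.sum())


def estimate_common_dispersion(em: ExpressionMatrix, line_labels: np.ndarray,
                               n_iter: int = 2) -> float:
    """Common NB dispersion by conditional maximum likelihood on
    quantile-adjusted pseudo-counts, alternating pseudo-count update and
    1-D likelihood maximisation."""
    groups = [np.flatnonzero(line_labels == g) for g in ("NEG", "POS")]
    lib = em.effective_lib_size
    disp = 0.1
    for _ in range(n_iter):
        pseudo, _ = _pseudo_counts(em.counts, lib, groups, disp)
        def neg(ld):
            d = float(np.exp(ld))
            return -sum(_cond_loglik(pseudo[:, g], d) for g in groups)
        res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(5.0)),
                              method="bounded", options={"xatol": 1e-6})
        disp = float(np.exp(res.x))
    return disp


def _pseudo_counts(counts: np.ndarray, lib: np.ndarray, groups: list,
                   dispersion: float) -> tuple[np.ndarray, float]:
    """Counts mapped to a common (geometric-mean) library size."""
    used = np.concatenate(groups)
    lib_common = float(np.exp(np.mean(np.log(lib[used]))))
    # per-gene abundance under the null (all used samples)
    lam = counts[:, used].sum(axis=1) / lib[used].sum()
    pseudo = np.zeros_like(counts, dtype=float)
    for j in used:
        pseudo[:, j] = _q2qnbinom(counts[:, j], lam * lib[j],
                                  lam * lib_common, dispersion)
    return pseudo, lib_common


def nb_exact_pvalue(y1: float, y2: float, n1: int, n2: int,
                    dispersion: float) -> float:
    """Exact two-sided NB test of two group sums at equalised library
    sizes.

    Conditional on the total t = y1 + y2, sums the probabilities of all
    splits as or less likely than the observed one, with
    Y1 ~ NB(mean n1*mu, size n1/dispersion) and Y2 likewise (Poisson in
    the dispersion -> 0 limit, where this reduces to the conditional
    binomial exact test).
    """
    y1, y2 = float(np.round(y1)), float(np.round(y2))
    t = int(y1 + y2)
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    a = np.arange(t + 1)
    if dispersion <= 1e-12:
        logp = (poisson.logpmf(a, n1 * mu)
                + poisson.logpmf(t - a, n2 * mu))
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        logp = (nbinom.logpmf(a, r1, r1 / (r1 + n1 * mu))
                + nbinom.logpmf(t - a, r2, r2 / (r2 + n2 * mu)))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[int(y1)]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-10)].sum()))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_exact_test(em: ExpressionMatrix, line_labels,
                  dispersion: float | None = None,
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Differential expression between the NEG and POS lines.

    Per gene: common-dispersion NB exact test on quantile-adjusted
    pseudo-count group sums, BH adjustment across genes, log2 fold change
    (positive = upregulated in POS) from prior-damped normalised group
    means. Individuals outside both lines are ignored.
    """
    line_labels = np.asarray(line_labels)
    g_neg = np.flatnonzero(line_labels == "NEG")
    g_pos = np.flatnonzero(line_labels == "POS")
    if g_neg.size == 0 or g_pos.size == 0:
        raise ValueError("both POS and NEG lines must be non-empty")
    lib = em.effective_lib_size
    if dispersion is None:
        dispersion = estimate_common_dispersion(em, line_labels)
    pseudo, lib_common = _pseudo_counts(em.counts, lib, [g_neg, g_pos],
                                        dispersion)
    y_neg = pseudo[:, g_neg].sum(axis=1)
    y_pos = pseudo[:, g_pos].sum(axis=1)
    pvals = np.array([
        nb_exact_pvalue(y_neg[i], y_pos[i], g_neg.size, g_pos.size, dispersion)
        for i in range(em.n_features)])
    cpm = em.cpm()
    mean_neg = cpm[:, g_neg].mean(axis=1)
    mean_pos = cpm[:, g_pos].mean(axis=1)
    prior_cpm = prior_count / lib_common * 1e6
    logfc = np.log2((mean_pos + prior_cpm) / (mean_neg + prior_cpm))
    fdr = bh_fdr(pvals)
    return pd.DataFrame({
        "gene": em.features["feature_id"], "logFC": logfc,
        "mean_neg": mean_neg, "mean_pos": mean_pos,
        "p": pvals, "fdr": fdr, "significant": fdr < 0.05,
        "dispersion": dispersion,
    })


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """eQTL enrichment among trait-significant variants."""

    set_label: str
    n_total: int
    n_eqtl: int
    n_sig_trait: int
    n_both: int
    perc_eqtl_all: float
    perc_eqtl_sig: float
    enrichment: float
    chi2: float
    p_enrichment: float


def enrichment_from_counts(set_label: str, n_total: int, n_eqtl: int,
                           n_sig_trait: int, n_both: int,
                           continuity: bool = False) -> EnrichmentResult:
    """Enrichment fold and 2x2 chi-square from the four counts.

    Fold = (100 * n_both / n_sig_trait) / (100 * n_eqtl / n_total); the
    chi-square tests independence of eQTL status and trait significance
    (no continuity correction unless requested).
    """
    if n_both > min(n_eqtl, n_sig_trait):
        raise ValueError("intersection larger than its parent sets")
    perc_all = 100.0 * n_eqtl / n_total
    perc_sig = (100.0 * n_both / n_sig_trait) if n_sig_trait > 0 else np.nan
    fold = perc_sig / perc_all if (n_sig_trait > 0 and perc_all > 0) else np.nan
    table = np.array([
        [n_both, n_sig_trait - n_both],
        [n_eqtl - n_both, n_total - n_eqtl - n_sig_trait + n_both],
    ], dtype=float)
    chi2, p = chi2_2x2(table, continuity=continuity)
    return EnrichmentResult(set_label, n_total, n_eqtl, n_sig_trait, n_both,
                            perc_all, perc_sig, fold, chi2, p)


def chi2_2x2(table: np.ndarray, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square of independence for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return np.nan, np.nan
    expected = rows @ cols / total
    diff = np.abs(table - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def enrichment(set_label: str, eqtl_variants: pd.DataFrame,
               trait_sig: pd.DataFrame, universe: pd.DataFrame,
               continuity: bool = False) -> EnrichmentResult:
    """Set-based wrapper: counts memberships on the (chrom, pos, ref,
    alt) key and delegates to :func:`enrichment_from_counts`."""
    uni = pd.MultiIndex.from_frame(universe[KEY])
    eq = pd.MultiIndex.from_frame(eqtl_variants[KEY]).intersection(uni)
    sig = pd.MultiIndex.from_frame(trait_sig[KEY]).intersection(uni)
    both = eq.intersection(sig)
    return enrichment_from_counts(set_label, len(uni), len(eq), len(sig),
                                  len(both), continuity=continuity)


def enrichment_grid(set_label: str, eqtl_scan: pd.DataFrame,
                    trait_scan: pd.DataFrame, universe: pd.DataFrame,
                    thresholds=(1e-4, 1e-6, 1e-8)) -> pd.DataFrame:
    """Enrichment over a grid of significance thresholds applied to both
    the trait scan and the eQTL scan."""
    rows = []
    for thr_trait in thresholds:
        for thr_eqtl in thresholds:
            eq = eqtl_scan.loc[eqtl_scan["p"] <= thr_eqtl]
            sig = trait_scan.loc[trait_scan["p"] <= thr_trait]
            res = enrichment(set_label, eq, sig, universe)
            rows.append({"set": set_label, "threshold_trait": thr_trait,
                         "threshold_eqtl": thr_eqtl,
                         **res.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direction concordance
# ---------------------------------------------------------------------------

def direction_concordance(trait_scan: pd.DataFrame, other_scan: pd.DataFrame,
                          trait_polarity: int, other_polarity: int,
                          variant_set: pd.DataFrame | None = None,
                          label: str = "ALL",
                          trait_effect_col: str = "z_meta",
                          other_effect_col: str = "effect") -> dict:
    """Percent of variants whose effect direction is favourable (or
    unfavourable) for both traits.

    ``*_polarity`` is +1 when a positive effect on the trait is
    favourable and -1 otherwise (for a calving-interval-like trait the
    favourable sign is -1). Only the sign of each effect is used.
    Variants missing from either scan are excluded and counted.
    """
    merged = trait_scan.merge(other_scan, on=KEY, suffixes=("_a", "_b"))
    if variant_set is not None:
        keys = pd.MultiIndex.from_frame(variant_set[KEY])
        merged = merged.loc[pd.MultiIndex.from_frame(merged[KEY]).isin(keys)]
    ca = trait_effect_col + ("_a" if trait_effect_col + "_a" in merged else "")
    cb = other_effect_col + ("_b" if other_effect_col + "_b" in merged else "")
    sa = np.sign(merged[ca].to_numpy()) * trait_polarity
    sb = np.sign(merged[cb].to_numpy()) * other_polarity
    defined = (sa != 0) & (sb != 0)
    n = int(defined.sum())
    pct = 100.0 * float((sa[defined] == sb[defined]).mean()) if n else np.nan
    n_requested = len(variant_set) if variant_set is not None else len(trait_scan)
    return {"variant_set": label, "n_variants": n,
            "n_missing": int(n_requested - n), "percent_consistent": pct}


def group_allele_freq(gm: GenotypeMatrix, lines=("POS", "NEG")) -> pd.DataFrame:
    """Alternate-allele frequency per selection line over non-missing
    calls."""
    out = gm.variants[KEY].copy()
    labels = gm.individuals["line"].to_numpy()
    for line in lines:
        j = np.flatnonzero(labels == line)
        if j.size == 0:
            raise ValueError(f"line {line!r} is empty")
        d = gm.dosage[:, j]
        ok = d != MISSING
        denom = 2 * ok.sum(axis=1)
        alt = np.where(ok, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[f"freq_{line}"] = np.where(denom > 0, alt / np.maximum(denom, 1),
                                           np.nan)
    return out


# ---------------------------------------------------------------------------
# overlap report (candidate concordance)
# ---------------------------------------------------------------------------

def overlap_report(regions: list[QtlRegion], trait_sig: pd.DataFrame,
                   eqtl_calls: dict[str, pd.DataFrame],
                   de_results: pd.DataFrame, line_freqs: pd.DataFrame,
                   trait_polarity: int = -1,
                   secondary_scans: dict[str, tuple[pd.DataFrame, int]] | None = None,
                   ) -> pd.DataFrame:
    """Per-region candidate records with an all-directions-concordant flag.

    For each QTL region and each eQTL kind, lists the region's variants
    that are significant for both the trait and that eQTL. A variant is
    flagged concordant when every defined piece of evidence points the
    same way for its trait-favourable allele: the cis expression
    direction matches the differential-expression sign between the
    high- and low-fertility lines, the favourable allele is more frequent
    in the POS line, and its direction on each secondary fertility trait
    is favourable. Any undefined component leaves the flag undetermined
    (None) rather than False.

    ``eqtl_calls`` maps a kind label (GE/EE/S/ASE) to a table of
    significant eQTL variants with columns ``chrom, pos, ref, alt,
    effect`` plus ``feature_id`` (and ``gene`` for the DE link).
    ``trait_sig`` needs the variant key plus a signed ``z_meta`` (or
    ``effect``) column. ``secondary_scans`` maps trait name to (aligned
    scan, polarity).
    """
    eff_col = "z_meta" if "z_meta" in trait_sig.columns else "effect"
    trait_idx = trait_sig.set_index(KEY)
    freq_idx = line_freqs.set_index(KEY)
    de_idx = de_results.set_index("gene") if len(de_results) else None
    records = []
    for ri, region in enumerate(regions):
        for kind, calls in eqtl_calls.items():
            if len(calls) == 0:
                continue
            in_region = calls.loc[
                (calls["chrom"] == region.chrom)
                & (calls["pos"] >= region.start)
                & (calls["pos"] <= region.end)]
            for row in in_region.itertuples(index=False):
                key = (row.chrom, row.pos, row.ref, row.alt)
                if key not in trait_idx.index:
                    continue
                t_eff = float(trait_idx.loc[key, eff_col])
                # sign of the trait-favourable allele on the ALT coding
                s_fav = trait_polarity * np.sign(t_eff)
                components: list = []
                expr_dir = s_fav * np.sign(getattr(row, "effect", np.nan))
                gene = getattr(row, "gene", None)
                de_sign = np.nan
                if de_idx is not None and gene in de_idx.index:
                    de_sign = np.sign(float(de_idx.loc[gene, "logFC"]))
                components.append(_agree(expr_dir, de_sign))
                if key in freq_idx.index:
                    fp = float(freq_idx.loc[key, "freq_POS"])
                    fn = float(freq_idx.loc[key, "freq_NEG"])
                    d = s_fav * (fp - fn)
                    components.append(None if (np.isnan(d) or d == 0 or s_fav == 0)
                                      else bool(d > 0))
                else:
                    components.append(None)
                for name, (scan, pol) in (secondary_scans or {}).items():
                    sc_idx = scan.set_index(KEY)
                    if key in sc_idx.index:
                        sec = float(sc_idx.loc[key, "effect"])
                        d = s_fav * pol * np.sign(sec)
                        components.append(None if d == 0 else bool(d > 0))
                    else:
                        components.append(None)
                if any(c is False for c in components):
                    concordant: bool | None = False
                elif any(c is None for c in components):
                    concordant = None
                else:
                    concordant = True
                records.append({
                    "region": ri, "region_chrom": region.chrom,
                    "region_start": region.start, "region_end": region.end,
                    "eqtl_kind": kind, "feature_id": getattr(row, "feature_id", ""),
                    "chrom": row.chrom, "pos": row.pos, "ref": row.ref,
                    "alt": row.alt, "trait_effect": t_eff,
                    "expression_effect": float(getattr(row, "effect", np.nan)),
                    "de_logfc_sign": de_sign,
                    "freq_POS": float(freq_idx.loc[key, "freq_POS"])
                    if key in freq_idx.index else np.nan,
                    "freq_NEG": float(freq_idx.loc[key, "freq_NEG"])
                    if key in freq_idx.index else np.nan,
                    "concordant": concordant,
                })
    out = pd.DataFrame(records)
    if len(out):
        # keep tri-state semantics: Python True/False/None, not numpy bools
        out["concordant"] = pd.Series([r["concordant"] for r in records],
                                      dtype=object)
    return out


def _agree(a: float, b: float) -> bool | None:
    """Do two signed directions agree? None when either is undefined."""
    if not np.isfinite(a) or not np.isfinite(b) or a == 0 or b == 0:
        return None
    return bool(a == b)
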