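"""Synthetic genotype, fertility-trait, expression and allele-count data.

The generator targets the statistical structure every downstream stage
consumes, not cattle-genome realism: phased diploid haplotypes built as
founder mosaics (local LD decaying with distance), a Beta minor-allele
frequency spectrum, divergent selection lines obtained by truncation on
true genetic merit, a continuous calving-interval-like trait plus binary
secondary fertility traits measured in independent strata,
negative-binomial expression counts with planted cis effects at gene,
exon and intron-cluster level, and phase-linked allele-specific read
counts at heterozygous transcript SNPs. Every output is a deterministic
function of the seed; the realised causal configuration is recorded in a
:class:`GroundTruth` for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data_io import MISSING, GenotypeMatrix, write_genotypes, write_phenotypes
from .expression_phenotypes import ExpressionMatrix, write_ase_table

# fixed stream offsets so each stage draws from its own child generator
_STREAM = {"population": 0, "lines": 1, "traits": 2, "expression": 3, "ase": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(_STREAM[stage],)))


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines every output.

    Sizes default to a desk-scale version of a two-population dairy-cattle
    study: two strata (breed/sex analogues) of 300 cows simulated from a
    shared founder pool, two chromosomes of 10 Mb with 500 variants each,
    divergent POS/NEG lines split by truncation on true genetic merit,
    lowly heritable fertility traits (h2 = 0.25 for the continuous
    calving-interval analogue), moderately overdispersed counts
    (NB dispersion 0.1) and 30x mean allele-specific read depth.
    """

    seed: int = 0
    # population
    n_individuals: int = 300           # per stratum
    n_strata: int = 2
    n_founder_haplotypes: int = 30
    n_chromosomes: int = 2
    n_variants_per_chrom: int = 500
    chrom_length_bp: int = 10_000_000
    maf_beta: tuple = (0.8, 0.8)       # Beta shape of the allele-frequency spectrum
    maf_floor: float = 0.02
    switch_rate_per_bp: float = 1e-6   # founder-mosaic switch rate
    ld_decay_bp: float = 200_000.0     # founder-haplotype LD decay length
    # fertility traits
    trait_name: str = "calving_interval"
    trait_qtl: list = field(default_factory=list)   # [(variant_idx, effect), ...]
    trait_h2: float = 0.25
    trait_polygenic: bool = True
    binary_traits: list = field(default_factory=lambda: [
        # (name, prevalence, favourable_sign, after six weeks of mating?)
        ("sm3wk", 0.7, +1, False),
        ("co6wk", 0.6, +1, False),
        ("ttconc_long", 0.5, -1, True),
    ])
    covariate_effects: dict = field(default_factory=lambda: {
        "calving_age": 0.1, "calving_month": 0.3, "synchronisation": 0.5})
    # divergent lines (fractions of the ranking tails labelled POS / NEG)
    line_frac: float = 0.5
    trait_favourable_sign: int = -1    # lower calving interval is favourable
    # expression
    n_genes: int = 60
    exons_per_gene: int = 4
    n_intron_clusters: int = 20
    introns_per_cluster: int = 3
    base_mean: float = 100.0
    nb_dispersion: float = 0.1
    lib_size_log2_range: float = 0.75  # half-range; >= 2-fold spread overall
    ge_qtl: list = field(default_factory=list)   # [(gene_idx, variant_idx, beta)]
    ee_qtl: list = field(default_factory=list)   # [(gene_idx, exon_idx, variant_idx, shift)]
    s_qtl: list = field(default_factory=list)    # [(cluster_idx, intron_idx, variant_idx, shift)]
    de_genes: list = field(default_factory=list)  # [(gene_idx, log2fc)] + = up in POS
    # allele-specific expression
    ase_qtl: list = field(default_factory=list)  # [(tsnp_idx, dsnp_idx, theta)]
    ase_mean_depth: float = 30.0

    def validate(self) -> None:
        if self.n_founder_haplotypes < 1 or self.n_variants_per_chrom < 1:
            raise ValueError("need at least one founder haplotype and one variant")
        if not 0.0 < self.trait_h2 < 1.0 and self.trait_h2 != 0.0:
            raise ValueError("trait_h2 must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.ase_mean_depth <= 0:
            raise ValueError("mean ASE depth must be positive")
        if not 0.0 < self.line_frac <= 0.5:
            raise ValueError("line_frac must be in (0, 0.5]")

    @property
    def n_variants(self) -> int:
        return self.n_chromosomes * self.n_variants_per_chrom


@dataclass
class GroundTruth:
    """Realised causal configuration of one simulated dataset."""

    trait_qtl: list = field(default_factory=list)
    line_allele_freq: dict = field(default_factory=dict)  # variant_idx -> {POS, NEG}
    ge_qtl: list = field(default_factory=list)
    ee_qtl: list = field(default_factory=list)
    s_qtl: list = field(default_factory=list)
    ase_qtl: list = field(default_factory=list)
    de_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def simulate_population(cfg: SimConfig) -> GenotypeMatrix:
    """Phased genotypes by mosaic copying from shared founder haplotypes.

    Founder haplotypes carry alleles thresholded from an AR(1) latent
    Gaussian along each chromosome (correlation exp(-d/ld_decay_bp)), so
    LD decays with distance even within founders; individual haplotypes
    copy founder segments with Poisson switch points
    (rate ``switch_rate_per_bp``). Strata are independent populations
    drawn from the same founder pool.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "population")
    n_ind_total = cfg.n_individuals * cfg.n_strata
    n_haps = 2 * n_ind_total
    k = cfg.n_founder_haplotypes

    chrom_blocks, var_rows = [], []
    for c in range(cfg.n_chromosomes):
        m = cfg.n_variants_per_chrom
        pos = np.sort(rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=m, replace=False))
        p_alt = cfg.maf_floor + (1 - 2 * cfg.maf_floor) * rng.beta(*cfg.maf_beta, size=m)
        # founder haplotypes: thresholded AR(1) Gaussian
        gaps = np.diff(pos)
        r = np.exp(-gaps / cfg.ld_decay_bp)
        z = np.empty((k, m))
        z[:, 0] = rng.standard_normal(k)
        eps = rng.standard_normal((k, m - 1)) if m > 1 else None
        for i in range(1, m):
            z[:, i] = r[i - 1] * z[:, i - 1] + np.sqrt(1 - r[i - 1] ** 2) * eps[:, i - 1]
        founders = (z < norm.ppf(p_alt)[None, :]).astype(np.int8)  # (k, m)

        # mosaic copying: per-variant switch indicator, forward-filled paths
        p_switch = 1.0 - np.exp(-cfg.switch_rate_per_bp * gaps)
        start = rng.integers(0, k, size=n_haps)
        new_id = rng.integers(0, k, size=(m - 1, n_haps)) if m > 1 else None
        path = np.empty((m, n_haps), dtype=np.int32)
        path[0] = start
        if m > 1:
            do_switch = rng.random((m - 1, n_haps)) < p_switch[:, None]
            for i in range(1, m):
                path[i] = np.where(do_switch[i - 1], new_id[i - 1], path[i - 1])
        haps = founders[path, np.arange(m)[:, None]]  # (m, n_haps)
        chrom_blocks.append(haps)
        var_rows.append(pd.DataFrame({
            "chrom": f"chr{c + 1}", "pos": pos,
            "id": [f"chr{c + 1}:{p}" for p in pos],
            "ref": "A", "alt": "G", "impute_r2": 1.0,
        }))

    hap_flat = np.concatenate(chrom_blocks, axis=0)  # (n_var, n_haps)
    haplotypes = hap_flat.reshape(hap_flat.shape[0], n_ind_total, 2)
    dosage = haplotypes.sum(axis=2).astype(np.int8)
    individuals = pd.DataFrame({
        "id": [f"ind{j:04d}" for j in range(n_ind_total)],
        "stratum": np.repeat([f"S{s + 1}" for s in range(cfg.n_strata)],
                             cfg.n_individuals),
        "line": "",
    })
    return GenotypeMatrix(variants=pd.concat(var_rows, ignore_index=True),
                          individuals=individuals,
                          haplotypes=haplotypes.astype(np.int8),
                          dosage=dosage)


def true_genetic_values(gm: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Sum of planted trait-QTL effects over alternate-allele dosages."""
    g = np.zeros(gm.n_individuals)
    for v_idx, eff in cfg.trait_qtl:
        g += eff * gm.dosage[int(v_idx)].astype(float)
    return g


def simulate_divergent_lines(gm: GenotypeMatrix, cfg: SimConfig
                             ) -> tuple[GenotypeMatrix, GroundTruth]:
    """Assign POS/NEG line labels by truncation selection on genetic merit.

    Merit is ``trait_favourable_sign`` times the true genetic value (for a
    calving-interval-like trait a lower value is favourable). Within each
    stratum the top ``line_frac`` of the merit ranking becomes POS, the
    bottom ``line_frac`` NEG, anything between OTHER; ties are broken by a
    seeded random jitter so the labels partition the individuals. The
    realised per-line allele frequencies at the causal variants go into
    the returned :class:`GroundTruth`.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "lines")
    merit = cfg.trait_favourable_sign * true_genetic_values(gm, cfg)
    merit = merit + 1e-9 * rng.standard_normal(gm.n_individuals)
    labels = np.full(gm.n_individuals, "OTHER", dtype=object)
    for s in gm.individuals["stratum"].unique():
        idx = np.flatnonzero((gm.individuals["stratum"] == s).to_numpy())
        order = idx[np.argsort(merit[idx])]
        n_tail = max(1, int(round(cfg.line_frac * len(idx))))
        labels[order[:n_tail]] = "NEG"
        labels[order[-n_tail:]] = "POS"
    gm.individuals["line"] = labels
    truth = GroundTruth(trait_qtl=[(int(v), float(e)) for v, e in cfg.trait_qtl])
    for v_idx, _ in cfg.trait_qtl:
        v_idx = int(v_idx)
        freqs = {}
        for line in ("POS", "NEG"):
            j = np.flatnonzero(labels == line)
            d = gm.dosage[v_idx, j]
            ok = d != MISSING
            freqs[line] = float(d[ok].sum() / (2 * ok.sum())) if ok.any() else np.nan
        truth.line_allele_freq[v_idx] = freqs
    return gm, truth


def simulate_fertility_traits(gm: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Continuous and binary fertility traits with covariates, per stratum.

    The continuous trait is causal effects + a GRM-consistent polygenic
    term + Gaussian noise scaled so the genetic fraction of variance is
    ``trait_h2`` within each stratum. Binary traits are thresholded from
    an independent liability sharing the same genetic values, oriented by
    each trait's favourable sign. Covariates (calving age, calving month,
    synchronisation for post-six-week traits) carry known nuisance
    effects.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "traits")
    n = gm.n_individuals
    causal = true_genetic_values(gm, cfg)
    if cfg.trait_polygenic and cfg.trait_h2 > 0:
        z = _standardised_dosage(gm)
        a = rng.standard_normal(z.shape[0]) / np.sqrt(z.shape[0])
        poly = z.T @ a
    else:
        poly = np.zeros(n)
    genetic = causal + poly

    age = rng.normal(36.0, 4.0, size=n)
    month = rng.integers(1, 13, size=n)
    sync = rng.integers(0, 2, size=n)
    month_eff = rng.normal(0.0, cfg.covariate_effects.get("calving_month", 0.0), size=12)
    nuisance_base = cfg.covariate_effects.get("calving_age", 0.0) * (age - age.mean())
    nuisance_base = nuisance_base + month_eff[month - 1]
    sync_eff = cfg.covariate_effects.get("synchronisation", 0.0) * (sync - 0.5)

    rows = []
    strata = gm.individuals["stratum"].to_numpy()
    ids = gm.individuals["id"].to_numpy()
    for s in pd.unique(strata):
        j = np.flatnonzero(strata == s)
        g = genetic[j]
        var_g = g.var()
        if cfg.trait_h2 > 0 and var_g > 0:
            sd_e = np.sqrt(var_g * (1 - cfg.trait_h2) / cfg.trait_h2)
        else:
            g = np.zeros_like(g)
            sd_e = 1.0
        y = g + nuisance_base[j] + sd_e * rng.standard_normal(len(j))
        rows.append(pd.DataFrame({
            "individual": ids[j], "trait": cfg.trait_name, "value": y,
            "stratum": s, "calving_age": age[j], "calving_month": month[j],
            "synchronisation": np.nan,
        }))
        for name, prevalence, fav_sign, post6wk in cfg.binary_traits:
            liab = fav_sign * g
            sd_l = np.sqrt(liab.var() * (1 - cfg.trait_h2) / cfg.trait_h2) \
                if cfg.trait_h2 > 0 and liab.var() > 0 else 1.0
            liab = liab + nuisance_base[j] + sd_l * rng.standard_normal(len(j))
            if post6wk:
                liab = liab + sync_eff[j]
            thresh = np.quantile(liab, 1 - prevalence)
            val = (liab > thresh).astype(float)
            rows.append(pd.DataFrame({
                "individual": ids[j], "trait": name, "value": val,
                "stratum": s, "calving_age": age[j], "calving_month": month[j],
                "synchronisation": sync[j].astype(float) if post6wk else np.nan,
            }))
    return pd.concat(rows, ignore_index=True)


def _standardised_dosage(gm: GenotypeMatrix) -> np.ndarray:
    d = gm.dosage_float()
    p = d.mean(axis=1) / 2.0
    ok = (p > 0) & (p < 1)
    z = (d[ok] - 2 * p[ok, None]) / np.sqrt(2 * p[ok, None] * (1 - p[ok, None]))
    return z


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with mean ``mean`` and variance mean(1+disp*mean)."""
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def gene_features(gm: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Deterministic gene placement: genes alternate across chromosomes
    and spread evenly over each chromosome's variant span."""
    chroms = pd.unique(gm.variants["chrom"])
    genes = []
    for g in range(cfg.n_genes):
        c = chroms[g % len(chroms)]
        cpos = gm.variants.loc[gm.variants["chrom"] == c, "pos"].to_numpy()
        lo, hi = cpos.min(), cpos.max()
        start = int(lo + (hi - lo) * ((g // len(chroms)) + 0.5)
                    / max(1, (cfg.n_genes + len(chroms) - 1) // len(chroms)))
        genes.append((f"gene{g:03d}", "gene", c, start, start + 5000))
    return pd.DataFrame(genes, columns=["feature_id", "kind", "chrom",
                                        "start", "end"])


def simulate_expression(gm: GenotypeMatrix, cfg: SimConfig
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                   ExpressionMatrix, GroundTruth]:
    """Gene, exon and intron-cluster counts with planted cis effects.

    Gene counts are negative binomial with log-mean = baseline +
    beta * dosage(cis variant) + line effect (DE genes) + log library
    offset; library sizes vary at least two-fold. Exon counts partition
    each gene's count multinomially, with eeQTL shifting one exon's
    proportion on the logit scale per dosage; intron clusters follow the
    same scheme with sQTL shifting intron usage.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "expression")
    n = gm.n_individuals
    lines = gm.individuals["line"].to_numpy()
    lib = 2.0 ** rng.uniform(-cfg.lib_size_log2_range, cfg.lib_size_log2_range, size=n)

    gene_feats = gene_features(gm, cfg)
    chroms = pd.unique(gm.variants["chrom"])

    def resolve(v_idx, chrom, start):
        """A negative variant index means: nearest variant to the feature."""
        if v_idx >= 0:
            return int(v_idx)
        on_chrom = np.flatnonzero((gm.variants["chrom"] == chrom).to_numpy())
        pos = gm.variants["pos"].to_numpy()[on_chrom]
        return int(on_chrom[np.argmin(np.abs(pos - start))])

    base = cfg.base_mean * np.exp(rng.normal(0.0, 0.7, size=cfg.n_genes))
    log_mu = np.log(base)[:, None] + np.log(lib)[None, :]
    ge_resolved = []
    for g_idx, v_idx, beta in cfg.ge_qtl:
        row = gene_feats.iloc[int(g_idx)]
        v_idx = resolve(v_idx, row["chrom"], row["start"])
        ge_resolved.append((int(g_idx), v_idx, float(beta)))
        log_mu[int(g_idx)] += beta * gm.dosage_float()[v_idx]
    for g_idx, l2fc in cfg.de_genes:
        eff = np.where(lines == "POS", 0.5, np.where(lines == "NEG", -0.5, 0.0))
        log_mu[int(g_idx)] += np.log(2.0) * l2fc * eff
    gene_counts = _nb_draw(rng, np.exp(log_mu), cfg.nb_dispersion).astype(np.float64)

    # exon partition of each gene's count
    e_per = cfg.exons_per_gene
    exon_feats, exon_counts = [], np.zeros((cfg.n_genes * e_per, n))
    ee_by_gene, ee_resolved = {}, []
    for g_idx, e_idx, v_idx, shift in cfg.ee_qtl:
        row = gene_feats.iloc[int(g_idx)]
        v_idx = resolve(v_idx, row["chrom"], row["start"])
        ee_by_gene.setdefault(int(g_idx), []).append((int(e_idx), v_idx, shift))
        ee_resolved.append((int(g_idx), int(e_idx), v_idx, float(shift)))
    for g in range(cfg.n_genes):
        props = rng.dirichlet(np.full(e_per, 5.0))
        logit = np.log(props / (1 - props))
        logits = np.tile(logit[:, None], (1, n))
        for e_idx, v_idx, shift in ee_by_gene.get(g, []):
            logits[e_idx] += shift * gm.dosage_float()[v_idx]
        pr = expit(logits)
        pr /= pr.sum(axis=0, keepdims=True)
        exon_counts[g * e_per:(g + 1) * e_per] = rng.multinomial(
            gene_counts[g].astype(np.int64), pr.T).T
        row = gene_feats.iloc[g]
        span = (row["end"] - row["start"]) // e_per
        for e in range(e_per):
            exon_feats.append((f"gene{g:03d}_ex{e}", "exon", row["chrom"],
                               row["start"] + e * span,
                               row["start"] + (e + 1) * span - 1, f"gene{g:03d}"))
    exon_feats = pd.DataFrame(exon_feats, columns=["feature_id", "kind", "chrom",
                                                   "start", "end", "parent"])

    # intron clusters
    i_per = cfg.introns_per_cluster
    intr_feats, intr_counts = [], np.zeros((cfg.n_intron_clusters * i_per, n))
    sq_by_cluster, sq_resolved = {}, []
    cluster_starts = {}
    for c in range(cfg.n_intron_clusters):
        chrom = chroms[c % len(chroms)]
        cpos = gm.variants.loc[gm.variants["chrom"] == chrom, "pos"].to_numpy()
        cluster_starts[c] = (chrom, int(
            cpos.min() + (cpos.max() - cpos.min()) * ((c // len(chroms)) + 0.25)
            / max(1, (cfg.n_intron_clusters + len(chroms) - 1) // len(chroms))))
    for c_idx, i_idx, v_idx, shift in cfg.s_qtl:
        chrom, start = cluster_starts[int(c_idx)]
        v_idx = resolve(v_idx, chrom, start)
        sq_by_cluster.setdefault(int(c_idx), []).append((int(i_idx), v_idx, shift))
        sq_resolved.append((int(c_idx), int(i_idx), v_idx, float(shift)))
    for c in range(cfg.n_intron_clusters):
        chrom, start = cluster_starts[c]
        total = _nb_draw(rng, np.full(n, 80.0) * lib, cfg.nb_dispersion)
        props = rng.dirichlet(np.full(i_per, 4.0))
        logit = np.log(props / (1 - props))
        logits = np.tile(logit[:, None], (1, n))
        for i_idx, v_idx, shift in sq_by_cluster.get(c, []):
            logits[i_idx] += shift * gm.dosage_float()[v_idx]
        pr = expit(logits)
        pr /= pr.sum(axis=0, keepdims=True)
        intr_counts[c * i_per:(c + 1) * i_per] = rng.multinomial(
            total.astype(np.int64), pr.T).T
        for i in range(i_per):
            intr_feats.append((f"clu{c:02d}_in{i}", "intron", chrom,
                               start + i * 300, start + i * 300 + 299, f"clu{c:02d}"))
    intr_feats = pd.DataFrame(intr_feats, columns=["feature_id", "kind", "chrom",
                                                   "start", "end", "cluster"])

    inds = list(gm.individuals["id"])
    truth = GroundTruth(
        ge_qtl=ge_resolved, ee_qtl=ee_resolved, s_qtl=sq_resolved,
        de_genes=[(int(g), float(f)) for g, f in cfg.de_genes],
    )
    return (ExpressionMatrix(gene_feats, inds, gene_counts),
            ExpressionMatrix(exon_feats, inds, exon_counts),
            ExpressionMatrix(intr_feats, inds, intr_counts),
            truth)


def simulate_allele_counts(gm: GenotypeMatrix, cfg: SimConfig
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Phase-linked allele-specific read counts at transcript SNPs.

    For each configured (tSNP, dSNP, theta) and each individual
    heterozygous at the tSNP: total depth ~ Poisson(mean depth) and
    reference reads ~ Binomial(depth, pi) with logit(pi) = theta * s,
    where s = +1 if the dSNP alternate allele is in phase with the tSNP
    reference allele and -1 otherwise (s set by the realised haplotypes;
    pi = 0.5 for individuals homozygous at the dSNP). Individuals
    homozygous at the tSNP are emitted with monoallelic counts so the
    downstream double-heterozygote rule has something to filter.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "ase")
    rows = []
    truth = GroundTruth(ase_qtl=[(int(t), int(d), float(th))
                                 for t, d, th in cfg.ase_qtl])
    ids = gm.individuals["id"].to_numpy()
    for t_idx, d_idx, theta in cfg.ase_qtl:
        t_idx, d_idx = int(t_idx), int(d_idx)
        tv = gm.variants.iloc[t_idx]
        th = gm.haplotypes[t_idx]
        dh = gm.haplotypes[d_idx]
        depth = rng.poisson(cfg.ase_mean_depth, size=gm.n_individuals)
        for j in range(gm.n_individuals):
            if gm.dosage[t_idx, j] == MISSING:
                continue
            if gm.dosage[t_idx, j] == 1 and th[j, 0] != MISSING:
                if gm.dosage[d_idx, j] == 1 and dh[j, 0] != MISSING:
                    # s = +1 when dSNP alt shares a haplotype with tSNP ref
                    ref_hap = int(th[j, 0] == 1)   # haplotype carrying tSNP ref
                    s = 1.0 if dh[j, ref_hap] == 1 else -1.0
                else:
                    s = 0.0
                pi = expit(theta * s)
                n_ref = rng.binomial(depth[j], pi)
            elif gm.dosage[t_idx, j] == 0:
                n_ref = depth[j]
            elif gm.dosage[t_idx, j] == 2:
                n_ref = 0
            else:
                continue  # unphased heterozygote: no usable allele counts
            rows.append((tv["chrom"], int(tv["pos"]), tv["ref"], tv["alt"],
                         ids[j], int(n_ref), int(depth[j] - n_ref),
                         int(depth[j]), True))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "individual",
                                        "nRef", "nAlt", "depth", "top2_match"])
    return table, truth


def write_fixtures(cfg: SimConfig, out_dir) -> dict:
    """Run every simulation stage and write the fixture files.

    Emits ``genotypes.vcf``, ``genes.tsv``/``exons.tsv``/``introns.tsv``,
    ``phenotypes.tsv``, ``allele_counts.tsv`` and ``ground_truth.json``;
    returns the paths. Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = simulate_population(cfg)
    gm, truth_lines = simulate_divergent_lines(gm, cfg)
    pheno = simulate_fertility_traits(gm, cfg)
    genes, exons, introns, truth_expr = simulate_expression(gm, cfg)
    ase, truth_ase = simulate_allele_counts(gm, cfg)
    truth = GroundTruth(
        trait_qtl=truth_lines.trait_qtl,
        line_allele_freq=truth_lines.line_allele_freq,
        ge_qtl=truth_expr.ge_qtl, ee_qtl=truth_expr.ee_qtl,
        s_qtl=truth_expr.s_qtl, de_genes=truth_expr.de_genes,
        ase_qtl=truth_ase.ase_qtl,
    )
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "genes": out / "genes.tsv",
        "exons": out / "exons.tsv",
        "introns": out / "introns.tsv",
        "allele_counts": out / "allele_counts.tsv",
        "lines": out / "lines.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_genotypes(gm, paths["vcf"])
    write_phenotypes(pheno, paths["phenotypes"])
    genes.to_tsv(paths["genes"])
    exons.to_tsv(paths["exons"])
    introns.to_tsv(paths["introns"])
    write_ase_table(ase, paths["allele_counts"])
    gm.individuals.to_csv(paths["lines"], sep="\t", index=False)
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


def small_preset(seed: int = 0) -> SimConfig:
    """A <1-minute fixture: 2 strata x 150 cows, 2 chromosomes x 400
    variants, 40 genes, planted effects of every kind."""
    return SimConfig(
        seed=seed, n_individuals=150, n_strata=2, n_chromosomes=2,
        n_variants_per_chrom=400, n_genes=40, n_intron_clusters=10,
        trait_qtl=[(50, 0.8), (520, -0.6)],
        ge_qtl=[(0, -1, 0.6), (5, -1, 0.5)],
        ee_qtl=[(2, 1, -1, 0.8)],
        s_qtl=[(1, 0, -1, 0.9)],
        de_genes=[(0, 2.0), (7, -1.5)],
        ase_qtl=[(50, 60, 1.0), (200, 210, 0.0)],
    )


def medium_preset(seed: int = 0) -> SimConfig:
    """A larger end-to-end configuration (still desk scale)."""
    cfg = small_preset(seed)
    cfg.n_individuals = 300
    cfg.n_variants_per_chrom = 1000
    cfg.n_genes = 100
    cfg.n_intron_clusters = 25
    return cfg
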