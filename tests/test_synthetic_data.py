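import json

import numpy as np
import pandas as pd
import pytest

from fertqtl import data_io, synthetic_data as sd
from fertqtl.expression_phenotypes import ExpressionMatrix


class TestSimulatePopulation:
    def test_deterministic_under_seed(self, small_cfg):
        a = sd.simulate_population(small_cfg)
        b = sd.simulate_population(small_cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_zero_switch_rate_gives_pure_founder_copies(self):
        cfg = sd.SimConfig(seed=3, n_individuals=30, n_strata=1,
                           n_chromosomes=1, n_variants_per_chrom=200,
                           n_founder_haplotypes=8, switch_rate_per_bp=0.0)
        gm = sd.simulate_population(cfg)
        haps = gm.haplotypes.reshape(gm.n_variants, -1).T  # one row per haplotype
        founders = {tuple(h) for h in haps}
        assert len(founders) <= 8

    def test_ld_decays_with_distance(self, population):
        gm, _ = population
        chr1 = np.flatnonzero((gm.variants["chrom"] == "chr1").to_numpy())
        pos = gm.variants["pos"].to_numpy()[chr1]
        x = gm.dosage_float()[chr1]
        x = x - x.mean(axis=1, keepdims=True)
        sd_ = x.std(axis=1)
        keep = sd_ > 0
        cc = np.corrcoef(x[keep])
        pos = pos[keep]
        adj = np.array([cc[i, i + 1] ** 2 for i in range(len(pos) - 1)])
        far = []
        for i in range(0, len(pos), 7):
            j = np.flatnonzero(pos > pos[i] + 1_000_000)
            if j.size:
                far.append(cc[i, j[0]] ** 2)
        assert np.nanmean(adj) > np.nanmean(far)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_population(sd.SimConfig(n_founder_haplotypes=0))
        with pytest.raises(ValueError):
            sd.simulate_population(sd.SimConfig(n_variants_per_chrom=0))


class TestDivergentLines:
    def test_partition(self, population):
        gm, _ = population
        lines = gm.individuals["line"]
        assert set(lines.unique()) <= {"POS", "NEG", "OTHER"}
        assert lines.isin(["POS", "NEG", "OTHER"]).all()
        assert (lines == "POS").sum() > 0 and (lines == "NEG").sum() > 0

    def test_selection_shifts_causal_allele_frequency(self, population):
        gm, truth = population
        cfg_effects = dict(truth.trait_qtl)
        for v_idx, eff in truth.trait_qtl:
            freqs = truth.line_allele_freq[v_idx]
            # favourable sign -1: POS selected for low trait values, so the
            # trait-increasing (positive-effect) alt allele is rarer in POS
            if eff > 0:
                assert freqs["POS"] < freqs["NEG"]
            else:
                assert freqs["POS"] > freqs["NEG"]

    def test_null_effects_give_no_systematic_divergence(self):
        cfg = sd.SimConfig(seed=5, n_individuals=200, n_strata=1,
                           n_chromosomes=1, n_variants_per_chrom=400,
                           trait_qtl=[(0, 0.0)])
        gm = sd.simulate_population(cfg)
        gm, _ = sd.simulate_divergent_lines(gm, cfg)
        lines = gm.individuals["line"].to_numpy()
        d = gm.dosage_float()
        diff = (d[:, lines == "POS"].mean(axis=1)
                - d[:, lines == "NEG"].mean(axis=1)) / 2
        n = (lines == "POS").sum()
        maf = data_io.compute_maf(gm)
        # diffs across variants are correlated (one random split, LD), so
        # the bound is 3 binomial SEs of a single variant's frequency diff
        se = np.sqrt(np.nanmean(2 * maf * (1 - maf)) / (2 * n))
        assert abs(np.nanmean(diff)) < 3 * se


class TestFertilityTraits:
    def test_noiseless_single_variant_limit_is_affine(self):
        cfg = sd.SimConfig(seed=9, n_individuals=100, n_strata=1,
                           n_chromosomes=1, n_variants_per_chrom=50,
                           trait_qtl=[(10, 1.0)], trait_h2=0.999999,
                           trait_polygenic=False,
                           covariate_effects={},
                           binary_traits=[])
        gm = sd.simulate_population(cfg)
        gm, _ = sd.simulate_divergent_lines(gm, cfg)
        ph = sd.simulate_fertility_traits(gm, cfg)
        y = ph.set_index("individual").loc[gm.individuals["id"], "value"].to_numpy()
        d = gm.dosage_float()[10]
        resid = y - d  # effect 1.0, intercept 0
        assert np.std(resid - resid.mean()) < 0.05

    def test_binary_prevalence(self, small_cfg, population):
        gm, _ = population
        ph = sd.simulate_fertility_traits(gm, small_cfg)
        for name, prevalence, _, _ in small_cfg.binary_traits:
            sub = ph.loc[ph["trait"] == name, "value"]
            se = np.sqrt(prevalence * (1 - prevalence) / len(sub))
            assert abs(sub.mean() - prevalence) <= 3 * se + 1.0 / len(sub)
        ci = ph.loc[ph["trait"] == small_cfg.trait_name]
        assert len(ci) == gm.n_individuals


class TestExpression:
    def test_exon_counts_partition_gene_counts(self, expression):
        genes, exons, _, _ = expression
        sums = pd.DataFrame(exons.counts).groupby(
            exons.features["parent"].to_numpy()).sum()
        gene_order = genes.features["feature_id"].to_numpy()
        np.testing.assert_allclose(sums.loc[gene_order].to_numpy(), genes.counts)

    def test_planted_de_fold_change(self):
        cfg = sd.SimConfig(seed=21, n_individuals=150, n_strata=2,
                           n_chromosomes=2, n_variants_per_chrom=100,
                           n_genes=20, trait_qtl=[(5, 0.5)],
                           de_genes=[(3, 2.0)])
        gm = sd.simulate_population(cfg)
        gm, _ = sd.simulate_divergent_lines(gm, cfg)
        genes, _, _, _ = sd.simulate_expression(gm, cfg)
        lines = gm.individuals["line"].to_numpy()
        ratio = (genes.counts[3, lines == "POS"].mean()
                 / genes.counts[3, lines == "NEG"].mean())
        assert 2.0 <= ratio <= 8.0

    def test_null_config_centred_fold_changes(self):
        cfg = sd.SimConfig(seed=22, n_individuals=200, n_strata=1,
                           n_chromosomes=1, n_variants_per_chrom=50,
                           n_genes=40, trait_qtl=[(5, 0.0)])
        gm = sd.simulate_population(cfg)
        gm, _ = sd.simulate_divergent_lines(gm, cfg)
        genes, _, _, _ = sd.simulate_expression(gm, cfg)
        lines = gm.individuals["line"].to_numpy()
        lfc = np.log2(genes.counts[:, lines == "POS"].mean(axis=1)
                      / genes.counts[:, lines == "NEG"].mean(axis=1))
        assert abs(lfc.mean()) < 3 * lfc.std() / np.sqrt(len(lfc))

    def test_library_sizes_vary_at_least_twofold(self, expression):
        genes, _, _, _ = expression
        lib = genes.lib_size
        assert lib.max() / lib.min() >= 2.0


class TestAlleleCounts:
    def test_null_theta_balanced(self):
        cfg = sd.SimConfig(seed=30, n_individuals=300, n_strata=1,
                           n_chromosomes=1, n_variants_per_chrom=100,
                           ase_qtl=[(10, 20, 0.0)])
        gm = sd.simulate_population(cfg)
        tab, _ = sd.simulate_allele_counts(gm, cfg)
        het = tab.loc[(tab["nRef"] > 0) & (tab["nAlt"] > 0)]
        total = (het["nRef"] + het["nAlt"]).sum()
        frac = het["nRef"].sum() / total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_homozygous_counts_monoallelic(self, small_cfg, population):
        gm, _ = population
        tab, _ = sd.simulate_allele_counts(gm, small_cfg)
        t_idx = small_cfg.ase_qtl[0][0]
        pos = gm.variants.iloc[t_idx]["pos"]
        sub = tab[tab["pos"] == pos].set_index("individual")
        hom_ref = gm.individuals.loc[gm.dosage[t_idx] == 0, "id"]
        assert (sub.loc[sub.index.intersection(hom_ref), "nAlt"] == 0).all()


class TestWriteFixtures:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = sd.SimConfig(seed=4, n_individuals=40, n_strata=1,
                           n_chromosomes=2, n_variants_per_chrom=60,
                           n_genes=10, n_intron_clusters=4,
                           trait_qtl=[(10, 0.7)], ge_qtl=[(0, -1, 0.5)],
                           de_genes=[(1, 1.5)], ase_qtl=[(10, 12, 0.8)])
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths1 = sd.write_fixtures(cfg, d1)
        paths2 = sd.write_fixtures(cfg, d2)
        for k in paths1:
            assert (d1 / k).parent.exists()
            b1 = open(paths1[k], "rb").read()
            b2 = open(paths2[k], "rb").read()
            assert b1 == b2, f"fixture {k} not byte-identical"
        gm = data_io.read_genotypes(paths1["vcf"])
        ref = sd.simulate_population(cfg)
        np.testing.assert_array_equal(gm.haplotypes, ref.haplotypes)
        genes = ExpressionMatrix.from_tsv(paths1["genes"])
        assert genes.counts.shape == (10, 40)
        truth = json.load(open(paths1["ground_truth"]))
        assert [tuple(t) for t in truth["trait_qtl"]] == [(10, 0.7)]
        assert len(truth["ge_qtl"]) == 1 and truth["ge_qtl"][0][0] == 0
        assert truth["ase_qtl"] == [[10, 12, 0.8]]
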