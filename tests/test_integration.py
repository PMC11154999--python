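import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from fertqtl import integration
from fertqtl.discovery import QtlRegion
from test_expression_phenotypes import em_from_counts


class TestNbExactPvalue:
    def test_identical_group_sums_give_p_one(self):
        assert integration.nb_exact_pvalue(50, 50, 5, 5, 0.1) == pytest.approx(1.0)

    def test_poisson_limit_matches_conditional_binomial(self):
        # dispersion -> 0: the conditional distribution is Binomial(t, n1/(n1+n2))
        for y1, y2, n1, n2 in [(12, 30, 3, 5), (4, 4, 2, 2), (0, 9, 4, 4),
                               (25, 5, 6, 2)]:
            ours = integration.nb_exact_pvalue(y1, y2, n1, n2, 0.0)
            oracle = binomtest(y1, y1 + y2, n1 / (n1 + n2)).pvalue
            assert ours == pytest.approx(oracle, abs=1e-6), (y1, y2, n1, n2)

    def test_more_extreme_split_smaller_p(self):
        p_mild = integration.nb_exact_pvalue(45, 55, 5, 5, 0.05)
        p_strong = integration.nb_exact_pvalue(20, 80, 5, 5, 0.05)
        assert p_strong < p_mild


class TestBhFdr:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(integration.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_identity_and_saturation(self):
        assert integration.bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(integration.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        adj = integration.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = rng.permutation(100)
        np.testing.assert_allclose(integration.bh_fdr(p[perm]), adj[perm])

    def test_dominates_raw_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert (integration.bh_fdr(p) >= p - 1e-12).all()


class TestDeExactTest:
    def test_identical_counts_null(self):
        counts = np.tile(np.array([[30.0], [200.0], [7.0]]), (1, 8))
        em = em_from_counts(counts)
        lines = np.array(["NEG"] * 4 + ["POS"] * 4)
        de = integration.de_exact_test(em, lines, dispersion=0.1)
        np.testing.assert_allclose(de["logFC"], 0.0, atol=1e-9)
        np.testing.assert_allclose(de["p"], 1.0)

    def test_planted_fold_change_detected_with_correct_sign(self):
        rng = np.random.default_rng(3)
        n = 60
        mu = np.full((40, n), 100.0)
        lines = np.array(["NEG"] * (n // 2) + ["POS"] * (n // 2))
        mu[0, lines == "POS"] *= 4.0   # log2FC = 2 up in POS
        mu[1, lines == "POS"] /= 4.0
        size = 1 / 0.05
        counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
        de = integration.de_exact_test(em_from_counts(counts), lines)
        assert de.loc[0, "significant"] and de.loc[0, "logFC"] > 1
        assert de.loc[1, "significant"] and de.loc[1, "logFC"] < -1
        assert not de.loc[5:, "significant"].any()

    def test_common_dispersion_estimate_near_truth(self):
        rng = np.random.default_rng(4)
        true_disp = 0.15
        size = 1 / true_disp
        mu = np.exp(rng.normal(4, 1, size=(150, 1))) * np.ones((150, 80))
        counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
        em = em_from_counts(counts)
        lines = np.array(["NEG"] * 40 + ["POS"] * 40)
        est = integration.estimate_common_dispersion(em, lines)
        assert 0.5 * true_disp <= est <= 2.0 * true_disp

    def test_requires_both_lines(self):
        em = em_from_counts(np.ones((2, 4)))
        with pytest.raises(ValueError, match="POS"):
            integration.de_exact_test(em, np.array(["NEG"] * 4))


class TestEnrichment:
    def test_reported_study_scale_ge_row(self):
        res = integration.enrichment_from_counts(
            "GE", n_total=13_710_843, n_eqtl=1_196_131,
            n_sig_trait=3412, n_both=1719)
        assert res.perc_eqtl_all == pytest.approx(8.72, abs=0.005)
        assert res.perc_eqtl_sig == pytest.approx(50.38, abs=0.005)
        assert res.enrichment == pytest.approx(5.78, abs=0.01)
        assert res.p_enrichment < 1e-100

    def test_independence_gives_fold_one(self):
        res = integration.enrichment_from_counts("x", 10_000, 1000, 500, 50)
        assert res.enrichment == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_chi2_hand_values(self):
        stat, p = integration.chi2_2x2(np.array([[10, 90], [100, 900]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        stat, _ = integration.chi2_2x2(np.array([[30, 70], [100, 900]]))
        assert stat == pytest.approx(34.89, abs=0.01)

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency
        table = np.array([[37, 1463], [260, 98240]])
        stat, p = integration.chi2_2x2(table)
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_intersection_bounds_checked(self):
        with pytest.raises(ValueError):
            integration.enrichment_from_counts("x", 100, 10, 5, 7)

    def test_set_based_wrapper(self):
        uni = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100),
                            "ref": "A", "alt": "G"})
        eq = uni.iloc[:20]
        sig = uni.iloc[10:30]
        res = integration.enrichment("GE", eq, sig, uni)
        assert (res.n_total, res.n_eqtl, res.n_sig_trait, res.n_both) == \
            (100, 20, 20, 10)


class TestDirectionConcordance:
    def _scans(self, z_a, eff_b):
        k = len(z_a)
        key = {"chrom": "chr1", "pos": np.arange(1, k + 1), "ref": "A", "alt": "G"}
        a = pd.DataFrame({**key, "z_meta": z_a})
        b = pd.DataFrame({**key, "effect": eff_b})
        return a, b

    def test_fully_consistent_is_100(self):
        # trait: lower favourable (polarity -1); other: higher favourable (+1)
        a, b = self._scans([-1.0, -2.0, 1.5], [1.0, 3.0, -0.5])
        out = integration.direction_concordance(a, b, -1, +1)
        assert out["percent_consistent"] == pytest.approx(100.0)

    def test_eight_of_ten(self):
        z = np.ones(10)
        eff = -np.ones(10)
        eff[:2] = 1.0  # two inconsistent under opposite polarities
        a, b = self._scans(z, eff)
        out = integration.direction_concordance(a, b, -1, +1)
        assert out["percent_consistent"] == pytest.approx(80.0)

    def test_null_scans_near_50(self):
        rng = np.random.default_rng(0)
        a, b = self._scans(rng.standard_normal(1000), rng.standard_normal(1000))
        out = integration.direction_concordance(a, b, -1, +1)
        se = 100 * np.sqrt(0.25 / 1000)
        assert abs(out["percent_consistent"] - 50.0) <= 3 * se

    def test_missing_variants_excluded_and_counted(self):
        a, b = self._scans([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        b = b.iloc[:2]
        out = integration.direction_concordance(a, b, +1, +1)
        assert out["n_variants"] == 2
        assert out["n_missing"] == 1


class TestGroupAlleleFreq:
    def test_single_het_individual(self):
        from helpers import dosage_gm
        gm = dosage_gm(np.array([[1, 0]]), line=["POS", "NEG"])
        out = integration.group_allele_freq(gm)
        assert out.loc[0, "freq_POS"] == pytest.approx(0.5)
        assert out.loc[0, "freq_NEG"] == pytest.approx(0.0)

    def test_identical_distributions_equal_freqs(self):
        from helpers import dosage_gm
        d = np.array([[0, 1, 2, 0, 1, 2]])
        gm = dosage_gm(d, line=["POS"] * 3 + ["NEG"] * 3)
        out = integration.group_allele_freq(gm)
        assert out.loc[0, "freq_POS"] == out.loc[0, "freq_NEG"]


class TestOverlapReport:
    def _inputs(self, trait_z=-3.0, expr_eff=1.0, logfc=1.0,
                freq_pos=0.8, freq_neg=0.2, sec_eff=None):
        key = {"chrom": "chr1", "pos": 500, "ref": "A", "alt": "G"}
        region = QtlRegion(chrom="chr1", start=400, end=600, top_pos=500,
                           top_p=1e-9, members=[0])
        trait_sig = pd.DataFrame([{**key, "z_meta": trait_z, "p": 1e-9}])
        eqtl = {"GE": pd.DataFrame([{**key, "effect": expr_eff, "p": 1e-8,
                                     "feature_id": "geneX", "gene": "geneX"}])}
        de = pd.DataFrame([{"gene": "geneX", "logFC": logfc, "p": 1e-4,
                            "fdr": 1e-3, "significant": True}])
        freqs = pd.DataFrame([{**key, "freq_POS": freq_pos, "freq_NEG": freq_neg}])
        sec = None
        if sec_eff is not None:
            sec = {"sm3wk": (pd.DataFrame([{**key, "effect": sec_eff}]), +1)}
        return [region], trait_sig, eqtl, de, freqs, sec

    def test_fully_concordant_variant_flagged(self):
        # alt decreases CI (favourable), increases expression, gene up in POS,
        # alt more frequent in POS
        regions, sig, eqtl, de, freqs, _ = self._inputs()
        rep = integration.overlap_report(regions, sig, eqtl, de, freqs)
        assert len(rep) == 1
        assert rep.loc[0, "concordant"] is True

    def test_direction_flip_breaks_concordance(self):
        # same but the gene is DOWN-regulated in the high-fertility line
        regions, sig, eqtl, de, freqs, _ = self._inputs(logfc=-1.0)
        rep = integration.overlap_report(regions, sig, eqtl, de, freqs)
        assert rep.loc[0, "concordant"] is False

    def test_frequency_flip_breaks_concordance(self):
        regions, sig, eqtl, de, freqs, _ = self._inputs(freq_pos=0.2,
                                                        freq_neg=0.8)
        rep = integration.overlap_report(regions, sig, eqtl, de, freqs)
        assert rep.loc[0, "concordant"] is False

    def test_undefined_component_leaves_flag_undetermined(self):
        regions, sig, eqtl, de, freqs, _ = self._inputs()
        de_missing = de.iloc[:0]  # gene absent from the DE table
        rep = integration.overlap_report(regions, sig, eqtl, de_missing, freqs)
        assert rep.loc[0, "concordant"] is None

    def test_secondary_trait_direction_enters_flag(self):
        # favourable allele must act favourably on the secondary trait
        regions, sig, eqtl, de, freqs, sec = self._inputs(sec_eff=1.0)
        rep = integration.overlap_report(regions, sig, eqtl, de, freqs,
                                         secondary_scans=sec)
        assert rep.loc[0, "concordant"] is True
        regions, sig, eqtl, de, freqs, sec = self._inputs(sec_eff=-1.0)
        rep = integration.overlap_report(regions, sig, eqtl, de, freqs,
                                         secondary_scans=sec)
        assert rep.loc[0, "concordant"] is False

    def test_invariant_to_global_allele_relabelling(self):
        regions, sig, eqtl, de, freqs, _ = self._inputs()
        flipped_sig = sig.copy()
        flipped_sig[["ref", "alt"]] = sig[["alt", "ref"]].to_numpy()
        flipped_sig["z_meta"] *= -1
        eqtl_f = {"GE": eqtl["GE"].copy()}
        eqtl_f["GE"][["ref", "alt"]] = eqtl["GE"][["alt", "ref"]].to_numpy()
        eqtl_f["GE"]["effect"] *= -1
        freqs_f = freqs.copy()
        freqs_f[["ref", "alt"]] = freqs[["alt", "ref"]].to_numpy()
        freqs_f[["freq_POS", "freq_NEG"]] = 1.0 - freqs[["freq_POS", "freq_NEG"]]
        rep = integration.overlap_report(regions, flipped_sig, eqtl_f, de,
                                         freqs_f)
        assert rep.loc[0, "concordant"] is True

    def test_region_with_no_overlapping_eqtl(self):
        regions, sig, eqtl, de, freqs, _ = self._inputs()
        eqtl_far = {"GE": eqtl["GE"].assign(pos=999_999)}
        rep = integration.overlap_report(regions, sig, eqtl_far, de, freqs)
        assert len(rep) == 0
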