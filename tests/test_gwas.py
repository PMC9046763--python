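"""Association-scan tests: PCA structure, OLS equivalence, calibration under
a polygenic null, thresholds, per-SNP variance explained, gene windows."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aquags import (
    GRM,
    SimConfig,
    candidate_windows,
    genotype_pca,
    lmm_gwas,
    significance_thresholds,
    simulate_genotypes,
    simulate_phenotypes,
    snp_pve,
    vanraden_grm,
)
from aquags.gwas import GwasError

from conftest import make_panel


def _sim(seed, n=455, m=2000, h2=0.4, n_qtl=None):
    cfg = SimConfig(n_individuals=n, n_snps=m, heritabilities=[h2], trait_names=["T"],
                    trait_means=[0.0], trait_sds=[1.0], n_qtl=n_qtl or m // 2, seed=seed)
    panel = simulate_genotypes(cfg)
    y, truth = simulate_phenotypes(panel, cfg)
    return panel, y[:, 0], truth


class TestPca:
    def test_scores_orthogonal(self, hwe_panel):
        scores, ev = genotype_pca(hwe_panel, k=3)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(ev) <= 1e-12)

    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        m = 400
        p1 = rng.uniform(0.1, 0.4, m)
        p2 = np.clip(p1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
        pop1 = rng.binomial(2, p1, size=(100, m)).astype(float)
        pop2 = rng.binomial(2, p2, size=(100, m)).astype(float)
        panel = make_panel(np.vstack([pop1, pop2]))
        scores, _ = genotype_pca(panel, k=2)
        a, b = scores[:100, 0], scores[100:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
               max(b.min(), a.min()) > min(b.max(), a.max())
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_rank_limit(self):
        panel = make_panel(np.random.default_rng(1).binomial(2, 0.5, (5, 50)).astype(float))
        with pytest.raises(GwasError, match="rank"):
            genotype_pca(panel, k=5)


class TestLmm:
    def test_identity_grm_equals_ols(self):
        panel, y, _ = _sim(seed=50, n=200, m=50)
        gi = GRM(values=np.eye(200), individual_ids=panel.individual_ids,
                 denominator=1.0, allele_freqs=np.zeros(0))
        res = lmm_gwas(y, panel, gi)
        for j in range(50):
            x = panel.dosages[:, j]
            X = np.column_stack([np.ones_like(x), x])
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = 200 - 2
            sigma2 = float(res_ss[0]) / dof
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * xtx_inv[1, 1])
            p_ols = stats.chi2.sf((beta[1] / se) ** 2, 1)
            assert res.table["p"].iloc[j] == pytest.approx(p_ols, abs=1e-6)

    def test_single_qtl_is_top_hit(self):
        # one QTL explaining a quarter of the phenotypic variance
        panel, y, truth = _sim(seed=51, n=455, m=1000, h2=0.25, n_qtl=1)
        res = lmm_gwas(y, panel, vanraden_grm(panel))
        assert int(np.argmin(res.table["p"].to_numpy())) == truth.qtl_indices[0]

    def test_scale_and_shift_invariance(self):
        panel, y, _ = _sim(seed=52, n=200, m=100)
        g = vanraden_grm(panel)
        p1 = lmm_gwas(y, panel, g).table["p"].to_numpy()
        p2 = lmm_gwas(3.7 * y + 42.0, panel, g).table["p"].to_numpy()
        assert np.allclose(p1, p2, atol=1e-8)

    def test_null_pvalues_uniform(self):
        # polygenic null at m = 10,000: KS distance to uniform < 0.02
        panel, y, _ = _sim(seed=53, n=455, m=10_000, h2=0.4, n_qtl=10_000)
        res = lmm_gwas(y, panel, vanraden_grm(panel))
        ks = stats.kstest(res.table["p"].to_numpy(), "uniform").statistic
        assert ks < 0.02
        assert 0.9 < res.lambda_gc < 1.1

    def test_table_has_one_row_per_snp(self):
        panel, y, _ = _sim(seed=54, n=100, m=60)
        res = lmm_gwas(y, panel, vanraden_grm(panel))
        assert len(res.table) == res.n_tests == 60

    def test_zero_variance_snp_flagged(self):
        panel, y, _ = _sim(seed=55, n=100, m=30)
        dos = panel.dosages.copy()
        dos[:, 4] = 1.0  # constant column
        panel2 = panel.with_dosages(dos)
        gi = GRM(values=np.eye(100), individual_ids=panel.individual_ids,
                 denominator=1.0, allele_freqs=np.zeros(0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmm_gwas(y, panel2, gi)
        assert res.table["p"].iloc[4] == 1.0
        assert bool(res.table["zero_var"].iloc[4])


class TestThresholdsAndPve:
    def test_bonferroni_at_study_scale(self):
        bonf, sugg = significance_thresholds(16162, alpha=0.05, suggestive_neglog10=4.0)
        assert bonf == pytest.approx(0.05 / 16162)
        assert bonf == pytest.approx(3.0937e-6, rel=1e-4)
        assert sugg == pytest.approx(1e-4)

    def test_single_test_equals_alpha(self):
        bonf, _ = significance_thresholds(1, alpha=0.05)
        assert bonf == 0.05

    def test_pve_values(self):
        assert snp_pve(0.0, 0.3, 1.0) == 0.0
        assert snp_pve(1.0, 0.5, 2.0) == pytest.approx(0.25)
        assert snp_pve(100.0, 0.5, 1.0) == 1.0  # clipped

    def test_pve_domain(self):
        with pytest.raises(GwasError):
            snp_pve(1.0, 0.6, 1.0)
        with pytest.raises(GwasError):
            snp_pve(1.0, 0.3, 0.0)


class TestCandidateWindows:
    GENES = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [399_000, 700_000, 100],
        "end": [401_000, 710_000, 200],
        "strand": ["+", "-", "+"],
        "gene_id": ["g1", "g2", "g3"],
        "name": ["growth1", "other", "tiny"],
    })

    def _hit(self, chrom="chr1", pos=500_000):
        return pd.DataFrame({"snp": ["s1"], "chrom": [chrom], "pos": [pos]})

    def test_window_arithmetic(self):
        w = candidate_windows(self._hit(), self.GENES)[0]
        assert (w.start, w.end) == (400_000, 600_000)

    def test_start_clipped_at_one(self):
        w = candidate_windows(self._hit(pos=40_000), self.GENES)[0]
        assert w.start == 1

    def test_one_bp_overlap_reported(self):
        w = candidate_windows(self._hit(), self.GENES)[0]
        assert [g["gene_id"] for g in w.genes] == ["g1"]

    def test_unknown_chromosome_warns_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            w = candidate_windows(self._hit(chrom="chrX"), self.GENES)[0]
        assert w.genes == []

    def test_end_clipped_to_chromosome(self):
        w = candidate_windows(self._hit(), self.GENES,
                              chrom_lengths={"chr1": 550_000})[0]
        assert w.end == 550_000
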