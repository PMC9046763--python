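"""Generator tests: allele-frequency behaviour, determinism, heritability
and correlation structure of the simulated cohort."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquags import SimConfig, SimConfigError, simulate_genotypes, simulate_phenotypes


def _cfg(**kw):
    kw.setdefault("trait_names", ["T"])
    kw.setdefault("trait_means", [0.0])
    kw.setdefault("trait_sds", [1.0])
    kw.setdefault("heritabilities", [0.4])
    return SimConfig(**kw)


class TestGenotypes:
    def test_mean_dosage_at_half_frequency(self):
        cfg = _cfg(n_individuals=2000, n_snps=1, maf_range=(0.5, 0.5), seed=1)
        panel = simulate_genotypes(cfg)
        assert abs(panel.dosages.mean() - 1.0) < 0.05

    def test_observed_freqs_track_drawn_freqs(self):
        cfg = _cfg(n_individuals=500, n_snps=200, maf_range=(0.05, 0.5), seed=2)
        panel = simulate_genotypes(cfg)
        # binomial sampling error at n=500: |p_hat - p| < 0.06 for >= 95% SNPs
        rng = np.random.default_rng(cfg.seed)
        drawn = rng.uniform(0.05, 0.5, size=200)
        close = np.abs(panel.allele_freqs() - drawn) < 0.06
        assert close.mean() >= 0.95

    def test_determinism(self):
        cfg = _cfg(n_individuals=100, n_snps=300, seed=7)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.positions_bp, b.positions_bp)

    def test_missing_rate_knob(self):
        cfg = _cfg(n_individuals=300, n_snps=200, missing_rate=0.1, seed=3)
        panel = simulate_genotypes(cfg)
        assert abs(panel.missing_mask.mean() - 0.1) < 0.02

    def test_ld_blocks_create_correlation(self):
        cfg = _cfg(n_individuals=400, n_snps=100, n_chromosomes=1,
                   ld_blocks=True, ld_r=0.95, seed=5)
        panel = simulate_genotypes(cfg)
        X = panel.dosages - panel.dosages.mean(axis=0)
        r = np.corrcoef(X.T)
        adjacent = np.array([r[j, j + 1] for j in range(99)])
        assert np.nanmean(adjacent**2) > 0.5

    @pytest.mark.parametrize("maf_range", [(0.0, 0.5), (0.1, 0.05), (0.05, 0.6)])
    def test_bad_maf_range_rejected(self, maf_range):
        with pytest.raises(SimConfigError):
            _cfg(maf_range=maf_range)

    def test_non_psd_correlation_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(
                heritabilities=[0.4, 0.4, 0.4], trait_names=list("abc"),
                trait_means=[0] * 3, trait_sds=[1] * 3,
                genetic_correlation=[[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
                phenotypic_correlation_target=None,
            )


class TestPhenotypes:
    def test_zero_heritability_has_no_genetic_signal(self):
        cfg = _cfg(n_individuals=455, n_snps=500, heritabilities=[0.0], seed=11)
        panel = simulate_genotypes(cfg)
        y, truth = simulate_phenotypes(panel, cfg)
        assert np.allclose(truth.true_breeding_values, 0.0)
        assert truth.realized_h2[0] == 0.0

    def test_full_heritability_is_exact(self):
        cfg = _cfg(n_individuals=200, n_snps=400, heritabilities=[1.0],
                   trait_means=[50.0], seed=12)
        panel = simulate_genotypes(cfg)
        y, truth = simulate_phenotypes(panel, cfg)
        assert np.allclose(y[:, 0], 50.0 + truth.true_breeding_values[:, 0])

    def test_realized_h2_recovers_target(self):
        # Monte Carlo over replicate seeds at the cohort's size
        vals = []
        for seed in range(20):
            cfg = _cfg(n_individuals=455, n_snps=2000, heritabilities=[0.38],
                       n_qtl=500, seed=100 + seed)
            panel = simulate_genotypes(cfg)
            _, truth = simulate_phenotypes(panel, cfg)
            vals.append(truth.realized_h2[0])
        assert abs(np.mean(vals) - 0.38) < 0.04

    def test_h2_concentrates_at_large_n(self):
        cfg = _cfg(n_individuals=2000, n_snps=1000, heritabilities=[0.4],
                   n_qtl=250, seed=13)
        panel = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(panel, cfg)
        assert abs(truth.realized_h2[0] - 0.4) < 0.03

    def test_identity_genetic_correlation_gives_independent_bvs(self):
        # null SD of the BV correlation is ~1/sqrt(n_qtl); 0.1 is >3 sigma
        cfg = SimConfig(
            n_individuals=2000, n_snps=2000, n_qtl=2000,
            heritabilities=[0.4, 0.4], trait_names=["a", "b"],
            trait_means=[0, 0], trait_sds=[1, 1],
            genetic_correlation=np.eye(2), phenotypic_correlation_target=None, seed=14,
        )
        panel = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(panel, cfg)
        r = np.corrcoef(truth.true_breeding_values.T)[0, 1]
        assert abs(r) < 0.1

    def test_requested_genetic_correlation_recovered(self):
        cfg = SimConfig(
            n_individuals=2000, n_snps=1000, n_qtl=500,
            heritabilities=[0.4, 0.3], trait_names=["a", "b"],
            trait_means=[0, 0], trait_sds=[1, 1],
            genetic_correlation=[[1, 0.8], [0.8, 1]],
            phenotypic_correlation_target=None, seed=15,
        )
        panel = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(panel, cfg)
        r = np.corrcoef(truth.true_breeding_values.T)[0, 1]
        assert abs(r - 0.8) < 0.08

    def test_phenotypic_correlation_target_approached(self):
        cfg = SimConfig(n_individuals=2000, n_snps=1000, n_qtl=250, seed=16)
        panel = simulate_genotypes(cfg)
        y, _ = simulate_phenotypes(panel, cfg)
        r = np.corrcoef(y.T)
        target = np.asarray(cfg.phenotypic_correlation_target)
        assert np.abs(r - target).max() < 0.08

    def test_infeasible_phenotypic_target_names_pair(self):
        cfg = SimConfig(
            n_individuals=300, n_snps=500, n_qtl=100,
            heritabilities=[0.9, 0.9], trait_names=["BW", "TL"],
            trait_means=[0, 0], trait_sds=[1, 1],
            genetic_correlation=[[1, -0.9], [-0.9, 1]],
            phenotypic_correlation_target=[[1, 0.9], [0.9, 1]], seed=17,
        )
        panel = simulate_genotypes(cfg)
        with pytest.raises(SimConfigError, match="BW/TL"):
            simulate_phenotypes(panel, cfg)

    def test_phenotypes_deterministic(self):
        cfg = _cfg(n_individuals=120, n_snps=300, seed=18)
        panel = simulate_genotypes(cfg)
        y1, t1 = simulate_phenotypes(panel, cfg)
        y2, t2 = simulate_phenotypes(panel, cfg)
        assert np.array_equal(y1, y2)
        assert np.array_equal(t1.true_effects, t2.true_effects)


@given(seed=st.integers(0, 2**20), n=st.integers(20, 60), m=st.integers(5, 40))
@settings(max_examples=15, deadline=None)
def test_simulation_determinism_property(seed, n, m):
    """Identical config (incl. seed) yields bit-identical panels/phenotypes."""
    cfg = _cfg(n_individuals=n, n_snps=m, n_chromosomes=2, n_qtl=min(5, m), seed=seed)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    ya, _ = simulate_phenotypes(a, cfg)
    yb, _ = simulate_phenotypes(b, cfg)
    assert np.array_equal(ya, yb)
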