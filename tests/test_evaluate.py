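"""Cross-validation machinery: fold plans, predictability, SNP-subset
selection strategies and the density experiment contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquags import (
    SimConfig,
    density_experiment,
    make_folds,
    predictability,
    run_cv,
    select_snps,
    simulate_genotypes,
    simulate_phenotypes,
)
from aquags.evaluate import EvalError

from conftest import make_panel


class TestFoldPlan:
    def test_study_design_sizes(self):
        plan = make_folds(455, 5, n_repeats=3, base_seed=0)
        for r in range(3):
            for f in range(5):
                assert plan.test_indices(r, f).size == 91
                assert plan.train_indices(r, f).size == 364

    def test_folds_partition_individuals(self):
        plan = make_folds(103, 5, n_repeats=4, base_seed=1)
        for r in range(4):
            all_idx = np.concatenate([plan.test_indices(r, f) for f in range(5)])
            assert np.array_equal(np.sort(all_idx), np.arange(103))
            sizes = [plan.test_indices(r, f).size for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_deterministic_given_seed(self):
        a = make_folds(100, 5, 10, base_seed=7)
        b = make_folds(100, 5, 10, base_seed=7)
        assert np.array_equal(a.assignments, b.assignments)

    def test_too_few_individuals(self):
        with pytest.raises(EvalError):
            make_folds(3, 5)

    @given(n=st.integers(10, 200), k=st.integers(2, 8), seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_partition_property(self, n, k, seed):
        if n < k:
            return
        plan = make_folds(n, k, n_repeats=2, base_seed=seed)
        for r in range(2):
            assert np.array_equal(
                np.sort(np.concatenate([plan.test_indices(r, f) for f in range(k)])),
                np.arange(n),
            )


class TestPredictability:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictability(y, y) == pytest.approx(1.0)
        assert predictability(-y, y) == pytest.approx(-1.0)

    def test_permutation_null_centered_at_zero(self):
        rng = np.random.default_rng(0)
        gebv = rng.standard_normal(91)
        y = rng.standard_normal(91)
        rs = [predictability(gebv, rng.permutation(y)) for _ in range(200)]
        assert abs(np.mean(rs)) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(EvalError):
            predictability(np.ones(5), np.arange(5.0))


def _sim(seed, n=300, m=800, h2=0.4, n_qtl=None, **kw):
    cfg = SimConfig(n_individuals=n, n_snps=m, heritabilities=[h2], trait_names=["T"],
                    trait_means=[0.0], trait_sds=[1.0], n_qtl=n_qtl or m // 4,
                    seed=seed, **kw)
    panel = simulate_genotypes(cfg)
    y, truth = simulate_phenotypes(panel, cfg)
    return panel, y[:, 0], truth


class TestRunCv:
    def test_null_trait_mean_r_near_zero(self):
        panel, y, _ = _sim(seed=60, n=250, m=500, h2=0.0)
        plan = make_folds(250, 5, n_repeats=8, base_seed=2)
        report = run_cv(y, panel, ["GBLUP"], plan)
        assert abs(report.mean_r()) <= 0.05

    def test_heritable_trait_predicts(self):
        # h2=1 with many causal markers in strong LD: r >= 0.5
        panel, y, _ = _sim(seed=61, n=300, m=1200, h2=1.0, n_qtl=1200,
                           ld_blocks=True, ld_r=0.93)
        plan = make_folds(300, 5, n_repeats=1, base_seed=3)
        report = run_cv(y, panel, ["GBLUP"], plan)
        assert report.mean_r() >= 0.5

    def test_models_share_exact_folds(self):
        plan = make_folds(100, 5, n_repeats=2, base_seed=4)
        a = [plan.train_indices(r, f) for r in range(2) for f in range(5)]
        b = [plan.train_indices(r, f) for r in range(2) for f in range(5)]
        for x, z in zip(a, b):
            assert np.array_equal(x, z)

    def test_summary_matches_cells(self):
        panel, y, _ = _sim(seed=62, n=120, m=200, h2=0.5)
        plan = make_folds(120, 4, n_repeats=2, base_seed=5)
        report = run_cv(y, panel, ["GBLUP"], plan)
        manual = report.cells.dropna(subset=["r"]).groupby("model")["r"].mean()
        assert report.summary["mean_r"].iloc[0] == pytest.approx(manual.iloc[0])
        assert len(report.cells) == 4 * 2


class TestSelectSnps:
    def test_evenly_spaced_rule(self, hwe_panel):
        panel = hwe_panel.subset(snps=np.arange(10))
        idx = select_snps(panel, "evenly_spaced", 5)
        assert idx.tolist() == [0, 2, 4, 6, 9]

    def test_random_subsets_nested(self, hwe_panel):
        s100 = select_snps(hwe_panel, "random", 100, seed=9)
        s150 = select_snps(hwe_panel, "random", 150, seed=9)
        assert set(s100).issubset(set(s150))

    def test_ranked_full_size_is_identity(self, hwe_panel):
        ranking = np.random.default_rng(1).permutation(hwe_panel.n_snps)
        idx = select_snps(hwe_panel, "gwas_ranked", hwe_panel.n_snps, ranking=ranking)
        assert np.array_equal(idx, np.arange(hwe_panel.n_snps))

    def test_evenly_spaced_pads_duplicates(self, hwe_panel):
        panel = hwe_panel.subset(snps=np.arange(7))
        idx = select_snps(panel, "evenly_spaced", 7)
        assert np.array_equal(idx, np.arange(7))

    def test_size_bounds(self, hwe_panel):
        with pytest.raises(EvalError):
            select_snps(hwe_panel, "random", 0)
        with pytest.raises(EvalError):
            select_snps(hwe_panel, "random", hwe_panel.n_snps + 1)


class TestDensity:
    def test_full_size_matches_full_panel_cv(self):
        panel, y, _ = _sim(seed=63, n=200, m=400, h2=0.5)
        plan = make_folds(200, 5, n_repeats=1, base_seed=6)
        full = run_cv(y, panel, ["GBLUP"], plan)
        curve = density_experiment(y, panel, plan, "random", sizes=[400], seed=1)
        assert curve.mean_r[0] == pytest.approx(full.mean_r(), abs=1e-10)

    def test_ranked_beats_random_on_sparse_architecture(self):
        # 50 QTL: GWAS-informed subsets find signal that random ones dilute
        panel, y, _ = _sim(seed=64, n=400, m=2000, h2=0.5, n_qtl=50)
        plan = make_folds(400, 5, n_repeats=2, base_seed=7)
        ranked = density_experiment(y, panel, plan, "gwas_ranked", sizes=[200])
        rand = density_experiment(y, panel, plan, "random", sizes=[200], seed=8)
        assert ranked.mean_r[0] > rand.mean_r[0]

    def test_noisy_monotonicity(self):
        panel, y, _ = _sim(seed=65, n=300, m=3000, h2=0.4, n_qtl=750,
                           ld_blocks=True, ld_r=0.9)
        plan = make_folds(300, 5, n_repeats=1, base_seed=9)
        for strategy in ("random", "evenly_spaced"):
            curve = density_experiment(y, panel, plan, strategy,
                                       sizes=[100, 3000], seed=10)
            assert curve.mean_r[1] >= curve.mean_r[0] - 0.02
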