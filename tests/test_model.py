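"""Animal-model construction, solving, REML/Gibbs fitting, ratio statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from pedsel.model import (
    AnimalModel,
    ChainConfig,
    MMESystem,
    TraitSpec,
    genetic_correlation,
    heritability,
    hpd_interval,
    solve_mme,
)
from pedsel.pedigree import PedigreeRecord, topo_sort
from pedsel.simulate import SimConfig, simulate_program

from conftest import random_pedigree


def unrelated(n):
    return topo_sort([PedigreeRecord(f"a{i}") for i in range(n)])


class TestRatioStatistics:
    @pytest.mark.parametrize("va,ve,expected", [
        (2.625, 0.626, 0.81),     # high-heritability ordinal hip score
        (0.0148, 0.0046, 0.76),   # distraction index
        (1.0, 1.0, 0.50),
    ])
    def test_heritability_reference_pairs(self, va, ve, expected):
        assert round(heritability(va, ve), 2) == expected

    def test_heritability_bad_total_raises(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)

    @pytest.mark.parametrize("cov,v1,v2,expected", [
        (-0.0777, 2.625, 0.0062, -0.61),
        (-0.1244, 1.766, 0.0148, -0.77),
        (0.0, 1.0, 2.0, 0.0),
    ])
    def test_genetic_correlation_reference_pairs(self, cov, v1, v2, expected):
        assert round(genetic_correlation(cov, v1, v2), 2) == expected

    def test_genetic_correlation_zero_variance_raises(self):
        with pytest.raises(ValueError):
            genetic_correlation(0.1, 0.0, 1.0)


class TestHpdInterval:
    def test_constant_draws_zero_width(self):
        lo, hi = hpd_interval(np.full(100, 3.7))
        assert lo == hi == 3.7

    def test_standard_normal_hits_closed_form(self, rng):
        lo, hi = hpd_interval(rng.standard_normal(10_000))
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_matches_exhaustive_window_search(self, rng):
        x = np.sort(rng.gamma(2.0, 1.0, size=200))
        m = int(np.ceil(0.95 * 200))
        widths = [(x[i + m - 1] - x[i], x[i], x[i + m - 1])
                  for i in range(200 - m + 1)]
        _, lo_b, hi_b = min(widths)
        lo, hi = hpd_interval(x, 0.95)
        assert (lo, hi) == (lo_b, hi_b)

    def test_too_few_draws_raises(self):
        with pytest.raises(ValueError, match="50"):
            hpd_interval(np.arange(10.0))


class TestBuildSolveMME:
    def test_identity_system_returns_rhs(self):
        rhs = np.array([1.0, -2.0, 3.0])
        sys_ = MMESystem(sparse.identity(3, format="csr"), rhs, [0], [1], 1, [[]])
        assert np.allclose(solve_mme(sys_), rhs)

    def test_unrelated_single_records_shrink_by_h2(self, rng):
        # intercept-only model, A = I: EBV_i = h2 * (y_i - ybar)
        n, h2 = 40, 0.36
        ped = unrelated(n)
        y = rng.normal(5.0, 1.0, n)
        df = pd.DataFrame({"animal_id": ped.ids, "y": y})
        am = AnimalModel(df, ped, [TraitSpec("y", "y")])
        theta = solve_mme(am.build_mme([[h2]], [[1 - h2]]))
        ebv = theta[am.off_u[0]:]
        assert np.allclose(ebv, h2 * (y - y.mean()), atol=1e-8)
        # monotone shrinkage of the phenotype deviations
        assert np.all(np.diff(ebv[np.argsort(y)]) > 0)

    def test_matches_dense_solve_on_toy_pedigree(self, rng):
        ped = topo_sort(random_pedigree(rng, 30, n_founders=6))
        y1 = rng.normal(0, 1, 30)
        y2 = rng.normal(0, 0.1, 30)
        y2[rng.choice(30, 8, replace=False)] = np.nan  # trait-wise missing
        df = pd.DataFrame({"animal_id": ped.ids, "y1": y1, "y2": y2,
                           "sex": rng.choice(["male", "female"], 30)})
        am = AnimalModel(df, ped, [TraitSpec("t1", "y1", ("sex",)),
                                   TraitSpec("t2", "y2")])
        G0 = np.array([[0.5, -0.02], [-0.02, 0.01]])
        R0 = np.array([[0.5, -0.01], [-0.01, 0.008]])
        sys_ = am.build_mme(G0, R0)
        theta = solve_mme(sys_)
        dense = np.linalg.solve(sys_.C.toarray(), sys_.rhs)
        assert np.allclose(theta, dense, atol=1e-8)

    def test_solution_invariant_to_record_order(self, rng):
        ped = topo_sort(random_pedigree(rng, 25, n_founders=5))
        y = rng.normal(size=25)
        df = pd.DataFrame({"animal_id": ped.ids, "y": y})
        am1 = AnimalModel(df, ped, [TraitSpec("y", "y")])
        am2 = AnimalModel(df.sample(frac=1, random_state=1), ped,
                          [TraitSpec("y", "y")])
        t1 = solve_mme(am1.build_mme([[0.3]], [[0.7]]))
        t2 = solve_mme(am2.build_mme([[0.3]], [[0.7]]))
        assert np.allclose(t1[am1.off_u[0]:], t2[am2.off_u[0]:], atol=1e-9)

    def test_all_missing_second_trait_reduces_to_single_trait(self, rng):
        ped = topo_sort(random_pedigree(rng, 20, n_founders=5))
        y = rng.normal(size=20)
        df2 = pd.DataFrame({"animal_id": ped.ids, "y1": y, "y2": np.nan})
        with pytest.warns(UserWarning):
            am2 = AnimalModel(df2, ped, [TraitSpec("t1", "y1"),
                                         TraitSpec("t2", "y2")])
        # diagonal G0 decouples the traits: trait-1 block must match the
        # plain single-trait assembly
        am1 = AnimalModel(pd.DataFrame({"animal_id": ped.ids, "y1": y}), ped,
                          [TraitSpec("t1", "y1")])
        t2 = solve_mme(am2.build_mme(np.diag([0.4, 0.01]), np.diag([0.6, 0.02])))
        t1 = solve_mme(am1.build_mme([[0.4]], [[0.6]]))
        assert np.allclose(t2[am2.off_u[0]: am2.off_u[0] + am2.q],
                           t1[am1.off_u[0]:], atol=1e-9)

    def test_confounded_fixed_effects_raise(self, rng):
        ped = unrelated(12)
        grp = np.repeat(["a", "b"], 6)
        df = pd.DataFrame({"animal_id": ped.ids, "y": rng.normal(size=12),
                           "g1": grp, "g2": grp})
        with pytest.raises(ValueError, match="confounded|singular"):
            AnimalModel(df, ped, [TraitSpec("y", "y", ("g1", "g2"))])


class TestChainConfig:
    def test_retained_draw_count_reference_chain(self):
        assert ChainConfig.paper_scale().n_retained == 900

    def test_inconsistent_chain_raises(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimConfig(n_founders=60, litters_per_generation=12,
                    litter_size_mean=5, n_generations=3,
                    criterion="random", sex_effect_di=0.0,
                    inbreeding_slope=(0.0, 0.0), seed=3)
    pop = simulate_program(cfg)
    return cfg, pop.phenotypes(), pop.pedigree()


class TestFitting:
    def test_reml_shift_invariance(self, small_sim):
        cfg, df, ped = small_sim
        am = AnimalModel(df, ped, [TraitSpec("DI", "di")])
        r1 = am.fit_reml(tol=1e-7, max_rounds=300, compute_se=False)
        df_shift = df.assign(di=df["di"] + 10.0)
        am2 = AnimalModel(df_shift, ped, [TraitSpec("DI", "di")])
        r2 = am2.fit_reml(tol=1e-7, max_rounds=300, compute_se=False)
        assert np.allclose(r1.G0, r2.G0, rtol=1e-4)
        assert np.allclose(r1.R0, r2.R0, rtol=1e-4)

    def test_reml_null_genetic_variance(self):
        cfg = SimConfig(n_founders=80, litters_per_generation=25,
                        litter_size_mean=5, n_generations=2, criterion="random",
                        G0=np.zeros((2, 2)), inbreeding_slope=(0.0, 0.0), seed=11)
        pop = simulate_program(cfg)
        am = AnimalModel(pop.phenotypes(), pop.pedigree(),
                         [TraitSpec("DI", "di", ("sex",))])
        res = am.fit_reml(tol=5e-3, max_rounds=150, compute_se=False)
        assert res.h2[0] < 0.1

    def test_gibbs_deterministic_given_seed(self, small_sim):
        cfg, df, ped = small_sim
        am = AnimalModel(df.head(120), ped,
                         [TraitSpec("HES", "hes_latent"), TraitSpec("DI", "di")])
        chain = ChainConfig(iterations=300, burn_in=100, thin=20)
        a = am.fit_gibbs(chain=chain, seed=42)
        b = am.fit_gibbs(chain=chain, seed=42)
        assert np.array_equal(a.draws_G, b.draws_G)
        assert np.array_equal(a.draws_R, b.draws_R)
        c = am.fit_gibbs(chain=chain, seed=43)
        assert not np.array_equal(a.draws_G, c.draws_G)

    def test_draw_statistics_respect_ranges(self, small_sim):
        cfg, df, ped = small_sim
        am = AnimalModel(df.head(150), ped,
                         [TraitSpec("HES", "hes_latent"), TraitSpec("DI", "di")])
        res = am.fit_gibbs(chain=ChainConfig(1500, 500, 10), seed=9)
        assert res.n_draws == 100
        for t in range(2):
            h2d = res.h2_draws(t)
            assert np.all((h2d > 0) & (h2d < 1))
        assert np.all(np.abs(res.r_a_draws()) <= 1)

    def test_reml_summary_and_report(self, small_sim):
        cfg, df, ped = small_sim
        am = AnimalModel(df, ped, [TraitSpec("HES", "hes_latent"),
                                   TraitSpec("DI", "di")])
        res = am.fit_reml(tol=1e-5, max_rounds=300)
        assert not res.pd_bent
        assert 0 < res.h2[0] < 1 and 0 < res.h2[1] < 1
        assert -1 <= res.r_a <= 1
        rep = res.to_report()
        assert rep["method"] == "EM-REML"
        assert "rA" in res.summary() or "genetic correlation" in res.summary()
        lo, hi = res.h2_interval(1)
        assert lo < res.h2[1] < hi
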