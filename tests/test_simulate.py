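"""Generative checks on the breeding-program simulator."""

import numpy as np
import pytest
from scipy import stats

from pedsel.simulate import SimConfig, advance_generation, simulate_founders, simulate_program


class TestFounders:
    def test_zero_genetic_variance_means_zero_bv(self):
        cfg = SimConfig(n_founders=30, G0=np.zeros((2, 2)), seed=1)
        pop = simulate_founders(cfg)
        assert np.all(pop.bv == 0.0)

    def test_bv_sample_covariance_matches_g0(self):
        cfg = SimConfig(n_founders=10_000, seed=4)
        pop = simulate_founders(cfg)
        C = np.cov(pop.bv.T)
        assert np.allclose(np.diag(C), np.diag(cfg.G0), rtol=0.10)
        assert C[0, 1] == pytest.approx(cfg.G0[0, 1], rel=0.35)

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_founders=50, seed=7)
        a = simulate_founders(cfg).phenotypes()
        b = simulate_founders(SimConfig(n_founders=50, seed=7)).phenotypes()
        assert a.equals(b)

    def test_founders_have_zero_f_and_g(self):
        pop = simulate_founders(SimConfig(n_founders=20, seed=2))
        ped = pop.pedigree()
        assert np.all(ped.F == 0)
        assert np.all(ped.g == 0)


class TestAdvanceGeneration:
    def test_zero_generations_founders_only(self):
        cfg = SimConfig(n_founders=25, n_generations=0, seed=3)
        pop = simulate_program(cfg)
        assert pop.n == 25
        assert max(pop.gen) == 0

    def test_mendelian_sampling_variance_halves(self):
        # one fixed non-inbred pair, thousands of offspring:
        # var(offspring BV | parents) ~= 0.5 * G0
        cfg = SimConfig(n_founders=2, litters_per_generation=800,
                        litter_size_mean=6, n_generations=0,
                        proportion_selected={"male": 1.0, "female": 1.0},
                        avoid_full_sib_matings=False, seed=9)
        pop = simulate_founders(cfg)
        advance_generation(pop)
        kids = np.array(pop.gen) == 1
        C = np.cov(pop.bv[kids].T)
        assert np.allclose(np.diag(C), 0.5 * np.diag(cfg.G0), rtol=0.10)

    @staticmethod
    def _replicate_slopes(make_cfg, key, n_reps=20):
        """Per-generation-mean regression slopes over independent replicates.

        A single run's slope is dominated by genetic drift (the means are a
        random walk), so flatness is asserted on the replicate average.
        """
        slopes = []
        for seed in range(n_reps):
            pop = simulate_program(make_cfg(seed))
            gens = np.array([g["gen"] for g in pop.gen_log])
            means = np.array([g[key] for g in pop.gen_log])
            slopes.append(stats.linregress(gens, means).slope)
        return np.asarray(slopes)

    def test_random_mating_no_trend_in_bv(self):
        slopes = self._replicate_slopes(
            lambda s: SimConfig(n_founders=80, litters_per_generation=30,
                                litter_size_mean=6, n_generations=6,
                                criterion="random", inbreeding_slope=(0.0, 0.0),
                                seed=100 + s),
            "mean_bv_di")
        sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 3.0 * sem

    def test_zero_correlation_no_correlated_response(self):
        G0 = np.diag([1.7, 0.0096])
        slopes_hes = self._replicate_slopes(
            lambda s: SimConfig(n_founders=80, litters_per_generation=30,
                                litter_size_mean=6, n_generations=6, G0=G0,
                                selection_trait="DI", criterion="phenotype",
                                inbreeding_slope=(0.0, 0.0), seed=200 + s),
            "mean_bv_hes")
        sem = slopes_hes.std(ddof=1) / np.sqrt(len(slopes_hes))
        assert abs(slopes_hes.mean()) < 3.0 * sem  # rA = 0: no correlated response
        slopes_di = self._replicate_slopes(
            lambda s: SimConfig(n_founders=80, litters_per_generation=30,
                                litter_size_mean=6, n_generations=6, G0=G0,
                                selection_trait="DI", criterion="phenotype",
                                inbreeding_slope=(0.0, 0.0), seed=200 + s),
            "mean_bv_di", n_reps=5)
        assert slopes_di.mean() < -0.005  # direct response is clearly downward

    def test_mean_inbreeding_nondecreasing(self):
        cfg = SimConfig(n_founders=40, litters_per_generation=15,
                        litter_size_mean=5, n_generations=5, seed=14)
        pop = simulate_program(cfg)
        mean_f = [g["mean_F"] for g in pop.gen_log]
        assert np.all(np.diff(mean_f) >= -1e-12)

    def test_selection_improves_hes(self):
        cfg = SimConfig(n_founders=60, litters_per_generation=20,
                        litter_size_mean=6, n_generations=5,
                        selection_trait="HES", criterion="phenotype", seed=15)
        pop = simulate_program(cfg)
        bv = [g["mean_bv_hes"] for g in pop.gen_log]
        assert bv[-1] > bv[0] + 0.5  # clear upward genetic trend


class TestRealizedParameters:
    def test_realized_h2_matches_config(self):
        cfg = SimConfig(n_founders=8000, litters_per_generation=0,
                        n_generations=0, sex_effect_di=0.0,
                        inbreeding_slope=(0.0, 0.0), seed=16)
        pop = simulate_founders(cfg)
        df = pop.phenotypes()
        h2_real = np.var(pop.bv[:, 1]) / np.var(df["di"])
        assert h2_real == pytest.approx(cfg.h2[1], abs=0.05)

    def test_ebv_selection_produces_ordered_hesc_trend(self):
        from pedsel.trend import jonckheere_terpstra

        cfg = SimConfig(n_founders=60, litters_per_generation=20,
                        litter_size_mean=6, n_generations=6,
                        selection_trait="HES", criterion="index_ebv", seed=17)
        pop = simulate_program(cfg)
        df = pop.phenotypes()
        res = jonckheere_terpstra(df["hes"], df["gen"], alternative="increasing",
                                  exact=False)
        assert res.pvalue < 0.05


class TestConfigValidation:
    def test_bad_covariance_raises(self):
        with pytest.raises(ValueError):
            SimConfig(G0=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_bad_proportion_raises(self):
        with pytest.raises(ValueError):
            SimConfig(proportion_selected={"male": 0.0, "female": 0.5})

    def test_nonmonotone_thresholds_raise(self):
        with pytest.raises(ValueError):
            SimConfig(hes_thresholds=(2.0, 1.0))
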