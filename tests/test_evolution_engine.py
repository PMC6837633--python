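import numpy as np
import pandas as pd
import pytest

from episwitch.circuit_models import PARAM_BOUNDS, Genotype, solution_k
from episwitch.environments import ENV_HIGH, ENV_LOW
from episwitch.evolution_engine import (EnvironmentSchedule, EvolutionConfig,
                                        MutationDraw, advance_environment,
                                        control_phenotype, cycle_summary,
                                        mutate_genotype, run_evolution,
                                        select_next_generation)


class TestFitness:
    # examples straight from the Lorentzian definition
    @pytest.mark.parametrize("A, env, expected", [
        (80.0, ENV_HIGH, 1.0),
        (84.0, ENV_HIGH, 0.5),  # eps^2 = 16, deviation^2 = 16
        (80.0, ENV_LOW, 4.0 / 3604.0),
    ])
    def test_lorentzian_values(self, A, env, expected):
        from episwitch.environments import fitness_score
        assert fitness_score(A, env) == pytest.approx(expected, rel=1e-12)

    def test_variants_peak_and_width(self):
        from episwitch.environments import fitness_score
        for shape in ("gaussian", "step"):
            assert fitness_score(80.0, ENV_HIGH, shape) == 1.0
        # gaussian matched to the Lorentzian FWHM: value 0.5 at A_opt +/- eps
        eps = np.sqrt(ENV_HIGH.eps_sq)
        assert fitness_score(80.0 + eps, ENV_HIGH, "gaussian") == pytest.approx(0.5)
        assert fitness_score(80.0 + 2 * eps, ENV_HIGH, "step") == 1.0
        assert fitness_score(80.0 + 2.1 * eps, ENV_HIGH, "step") == 1e-6


class TestMutation:
    def test_zero_radius_identity(self):
        g = Genotype(80, 4, 30)
        out = mutate_genotype(g, 1.1, draw=MutationDraw(r=0, phi1=0.3, phi2=1.0))
        assert (out.k, out.n_H, out.K_D) == (g.k, g.n_H, g.K_D)

    def test_polar_axis_moves_only_KD(self):
        g = Genotype(80, 4, 30)
        out = mutate_genotype(g, 1.5,
                              draw=MutationDraw(r=0.7, phi1=1.0, phi2=0.4))
        assert out.k == g.k and out.n_H == g.n_H
        assert out.K_D == pytest.approx(30 * 1.5 ** 0.7)

    def test_displacement_norm_equals_radius(self, rng):
        """In log-M coordinates the spherical displacement norm is exactly r,
        hence <= 1 and uniform on (0, 1)."""
        g = Genotype(80, 4, 30)
        M = 1.5
        rs = []
        for _ in range(5000):
            draw = MutationDraw(r=rng.uniform(0, 1), phi1=rng.uniform(-1, 1),
                                phi2=rng.uniform(0, 2 * np.pi))
            out = mutate_genotype(g, M, draw=draw)
            disp = np.array([np.log(out.k / g.k), np.log(out.n_H / g.n_H),
                             np.log(out.K_D / g.K_D)]) / np.log(M)
            norm = np.linalg.norm(disp)
            assert norm == pytest.approx(draw.r, abs=1e-12)
            rs.append(norm)
        rs = np.asarray(rs)
        assert rs.max() <= 1.0
        # uniformity: compare deciles
        hist, _ = np.histogram(rs, bins=10, range=(0, 1))
        assert hist.min() > 0.7 * 500 and hist.max() < 1.3 * 500

    def test_clamped_to_physiological_box(self, rng):
        g = Genotype(999, 15.9, 119.0)
        for scheme in ("spherical", "homogeneous_spherical", "cubic", "1d"):
            for _ in range(200):
                out = mutate_genotype(g, 5.0, scheme, rng)
                assert PARAM_BOUNDS["k"][0] <= out.k <= PARAM_BOUNDS["k"][1]
                assert PARAM_BOUNDS["n_H"][0] <= out.n_H <= PARAM_BOUNDS["n_H"][1]
                assert PARAM_BOUNDS["K_D"][0] <= out.K_D <= PARAM_BOUNDS["K_D"][1]

    def test_invalid_M(self, rng):
        with pytest.raises(ValueError):
            mutate_genotype(Genotype(80, 4, 30), 1.0, rng=rng)


class TestSelection:
    def test_drift_limit_is_uniform(self, rng):
        fit = rng.random(50)
        counts = np.zeros(50)
        for _ in range(400):
            parents = select_next_generation(fit, 1, rng)
            counts += np.bincount(parents, minlength=50)
        freq = counts / counts.sum()
        assert abs(freq - 1 / 50).max() < 0.01

    def test_elitist_limit_clones_fittest(self, rng):
        fit = rng.random(64)
        parents = select_next_generation(fit, 64, rng)
        assert np.all(parents == np.argmax(fit))

    def test_two_cell_tournament_enumeration(self, rng):
        # with N = s_t = 2 every tournament contains both cells
        parents = select_next_generation(np.array([1.0, 0.1]), 2, rng)
        assert np.all(parents == 0)

    def test_selected_mean_fitness_monotone_in_st(self, rng):
        fit = rng.random(100)
        means = []
        for s_t in (1, 2, 5, 20, 100):
            sampled = [fit[select_next_generation(fit, s_t, rng)].mean()
                       for _ in range(50)]
            means.append(np.mean(sampled))
        assert np.all(np.diff(means) > -1e-3)

    def test_truncation_and_proportional(self, rng):
        fit = np.array([0.9, 0.5, 0.1, 0.05])
        # s_t = N keeps only the top cell
        parents = select_next_generation(fit, 4, rng, scheme="truncation")
        assert np.all(parents == 0)
        # proportional: frequencies track fitness shares
        draws = np.concatenate([
            select_next_generation(fit, 2, rng, scheme="proportional")
            for _ in range(500)])
        freq = np.bincount(draws, minlength=4) / draws.size
        assert np.allclose(freq, fit / fit.sum(), atol=0.03)

    def test_oversized_tournament_rejected(self, rng):
        with pytest.raises(ValueError):
            select_next_generation(np.ones(5), 6, rng)


class TestSchedule:
    def test_500_cycles_at_nu_01(self):
        sched = EnvironmentSchedule(nu=0.1)
        labels, epoch_ends = sched.sequence(10_000)
        assert len(epoch_ends[1::2]) == 500  # complete LOW+HIGH cycles
        assert sched.epoch_length == 10

    def test_epoch_length_inverse_nu(self):
        assert EnvironmentSchedule(nu=0.01).epoch_length == 100

    def test_periodic_alternation(self):
        labels, _ = EnvironmentSchedule(nu=0.5, start_env="LOW").sequence(8)
        assert list(labels) == ["LOW", "LOW", "HIGH", "HIGH"] * 2
        env = advance_environment(EnvironmentSchedule(nu=0.5), 2)
        assert env.label == "HIGH"

    def test_non_integer_period_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentSchedule(nu=0.3)

    def test_stochastic_epoch_lengths_geometric(self, rng):
        sched = EnvironmentSchedule(nu=0.1, mode="stochastic")
        labels, epoch_ends = sched.sequence(100_000, rng)
        lengths = np.diff(np.concatenate([[-1], epoch_ends]))
        mean = lengths.mean()
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(mean - 10.0) < 3 * se


class TestControlPhenotype:
    def test_monostable_unique(self):
        g = Genotype(80, 1, 10)
        target = (70 + np.sqrt(5700)) / 2
        for A0 in (0.0, 20.0, 500.0):
            assert control_phenotype(g, A0) == pytest.approx(target, abs=1e-5)

    def test_hysteresis_basins(self, bistable_center):
        lo = control_phenotype(bistable_center, 30.0)
        hi = control_phenotype(bistable_center, 60.0)
        assert round(lo) == 20 and round(hi) == 80


class TestCycleSummary:
    def test_idempotent_on_constant_fitness(self):
        rec = pd.DataFrame({"w": [0.6] * 10, "mean_nH": [2.0] * 10,
                            "mean_KD": [30.0] * 10, "f_B": [0.1] * 10})
        s = cycle_summary(rec, 3)
        assert s["W_cycle"] == pytest.approx(0.6)
        rec["w"] = 1.0
        assert cycle_summary(rec, 0)["W_cycle"] == pytest.approx(1.0)

    def test_geometric_mean_arithmetic(self):
        rec = pd.DataFrame({"w": [0.25, 1, 1, 1], "mean_nH": [1] * 4,
                            "mean_KD": [1] * 4, "f_B": [0] * 4})
        assert cycle_summary(rec, 0)["W_cycle"] == pytest.approx(0.25 ** 0.25)


class TestRunEvolution:
    def test_no_mutation_no_new_genotypes(self):
        cfg = EvolutionConfig(N=30, s_t=1, u=0.0, generations=40, nu=0.25,
                              master_seed=5)
        res = run_evolution(cfg)
        assert len(res.genotype_table.genotypes) == 1
        assert np.all(res.final_genotype_ids == 0)

    def test_bit_reproducible(self):
        cfg = lambda: EvolutionConfig(N=40, generations=60, nu=0.25,
                                      master_seed=9)
        r1, r2 = run_evolution(cfg()), run_evolution(cfg())
        assert r1.generations.equals(r2.generations)
        assert r1.cycles.equals(r2.cycles)
        assert np.array_equal(r1.final_genotype_ids, r2.final_genotype_ids)

    def test_fitness_bounded_and_genotypes_in_box(self):
        cfg = EvolutionConfig(N=60, generations=80, nu=0.25, M=3.0, u=0.2,
                              master_seed=2)
        res = run_evolution(cfg)
        assert res.generations["w"].between(0, 1).all()
        for g in res.genotype_table.genotypes:
            assert g.within_bounds()

    def test_control_hysteresis_no_spontaneous_switching(self):
        """Without mutation a bistable CONTROL population never changes
        phenotype: every cell stays at the inherited stable state."""
        k_star, _ = solution_k(20, 16, 50)
        cfg = EvolutionConfig(N=30, s_t=10, u=0.0, generations=30, nu=0.25,
                              theta0=Genotype(k_star, 16, 50),
                              control_mode=True, start_env="LOW",
                              master_seed=4)
        res = run_evolution(cfg)
        # phenotype stays at the LOW stable state; mean fitness constant
        w = res.generations["w"].to_numpy()
        low_gens = res.generations["env"] == "LOW"
        assert np.allclose(w[low_gens.to_numpy()], w[0])

    def test_time_average_phenotype_mode_runs(self):
        cfg = EvolutionConfig(N=20, s_t=5, generations=20, nu=0.25,
                              phenotype_mode="time_average", master_seed=1)
        res = run_evolution(cfg)
        assert len(res.generations) == 20
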