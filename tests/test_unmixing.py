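import math

import numpy as np
import pytest
from scipy import integrate as sp_integrate
from scipy import stats

from n2osource.unmixing import (
    SIGNALS,
    EndmemberTable,
    McmcConfig,
    MixingObservation,
    apportion_dataset,
    forward_model,
    grid_posterior_oracle,
    log_posterior,
    sample_posterior,
)

from .conftest import ANALYTICAL_SIGMAS

F_EQUAL = (0.25, 0.25, 0.25, 0.25)


def obs_at(values, sigmas=None):
    return MixingObservation(values, sigmas or dict(ANALYTICAL_SIGMAS))


class TestForwardModel:
    def test_pure_source_identity(self, default_table):
        out = forward_model((1, 0, 0, 0), 1.0, default_table)
        for s in SIGNALS:
            assert out[s] == pytest.approx(default_table.means[s][0], abs=1e-12)

    def test_equal_mix_mean(self, default_table):
        out = forward_model(F_EQUAL, 1.0, default_table)
        for s in SIGNALS:
            assert out[s] == pytest.approx(
                float(np.mean(default_table.means[s])), abs=1e-12
            )

    def test_rayleigh_shift_closed_form(self):
        # mixture value 10.0, mu = -5.0, r = 0.5 -> 10 - 5 ln(0.5) = 13.4657...
        table = EndmemberTable(
            pathways=("a", "b", "c", "d"),
            means={s: np.full(4, 10.0) for s in SIGNALS},
            sds={s: np.zeros(4) for s in SIGNALS},
            mu_mean={s: -5.0 for s in SIGNALS},
            mu_sd={s: 0.0 for s in SIGNALS},
        )
        out = forward_model(F_EQUAL, 0.5, table)
        expected = 10.0 + (-5.0) * math.log(0.5)
        for s in SIGNALS:
            assert out[s] == pytest.approx(expected, abs=1e-10)
            assert out[s] == pytest.approx(13.4657359, abs=1e-6)

    def test_off_simplex_rejected(self, default_table):
        with pytest.raises(ValueError):
            forward_model((0.5, 0.6, -0.1, 0.0), 1.0, default_table)
        with pytest.raises(ValueError):
            forward_model((0.5, 0.2, 0.2, 0.2), 1.0, default_table)

    def test_r_out_of_range(self, default_table):
        for r in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                forward_model(F_EQUAL, r, default_table)

    def test_rayleigh_sensitivity(self, default_table):
        # finite-difference dF/dln r equals mu
        r0, eps = 0.6, 1e-6
        hi = forward_model(F_EQUAL, math.exp(math.log(r0) + eps), default_table)
        lo = forward_model(F_EQUAL, math.exp(math.log(r0) - eps), default_table)
        for s in SIGNALS:
            deriv = (hi[s] - lo[s]) / (2 * eps)
            assert deriv == pytest.approx(default_table.mu_mean[s], abs=1e-8)


class TestLogPosterior:
    def test_out_of_support(self, default_table):
        obs = obs_at(forward_model(F_EQUAL, 1.0, default_table))
        assert log_posterior((0.5, 0.6, -0.1, 0.0), 1.0, obs, default_table) == -math.inf
        assert log_posterior(F_EQUAL, 0.05, obs, default_table) == -math.inf
        assert log_posterior(F_EQUAL, 1.2, obs, default_table) == -math.inf

    def test_pure_source_likelihood_maximal(self, default_table):
        obs = obs_at(forward_model((1, 0, 0, 0), 1.0, default_table))
        k = default_table.n_pathways
        vals = [
            log_posterior(tuple(np.eye(k)[i]), 1.0, obs, default_table)
            for i in range(k)
        ]
        assert np.argmax(vals) == 0

    def test_term_by_term_oracle(self, default_table):
        # difference of log densities at two points equals independently
        # summed Gaussian log-density differences (scipy oracle)
        obs = obs_at({"d15n_bulk": -3.0, "d18o": 38.0, "sp": 25.0})
        latent1 = {
            "E": {s: np.asarray(default_table.means[s]) + 0.5 for s in SIGNALS},
            "mu": {s: default_table.mu_mean[s] + 0.2 for s in SIGNALS},
        }
        latent2 = {
            "E": {s: np.asarray(default_table.means[s]) - 1.0 for s in SIGNALS},
            "mu": {s: default_table.mu_mean[s] - 0.3 for s in SIGNALS},
        }
        p1 = (0.5, 0.2, 0.2, 0.1), 0.8
        p2 = (0.4, 0.3, 0.1, 0.2), 0.95

        def oracle(f, r, latent):
            f = np.asarray(f)
            total = 0.0
            for s in SIGNALS:
                pred = float(f @ latent["E"][s] + latent["mu"][s] * math.log(r))
                total += stats.norm.logpdf(obs.values[s], pred, obs.sigmas[s])
                total += stats.norm.logpdf(
                    latent["E"][s], default_table.means[s], default_table.sds[s]
                ).sum()
                total += stats.norm.logpdf(
                    latent["mu"][s], default_table.mu_mean[s], default_table.mu_sd[s]
                )
            return total  # Dirichlet(1)/uniform-r terms are constant

        got = log_posterior(
            p1[0], p1[1], obs, default_table, latent=latent1
        ) - log_posterior(p2[0], p2[1], obs, default_table, latent=latent2)
        want = oracle(*p1, latent1) - oracle(*p2, latent2)
        assert got == pytest.approx(want, abs=1e-10)

    def test_marginal_matches_latent_at_zero_uncertainty(self, collapsed_table):
        obs = obs_at({"d15n_bulk": -3.0, "d18o": 38.0, "sp": 25.0})
        f, r = (0.5, 0.2, 0.2, 0.1), 0.8
        latent = {
            "E": {s: np.asarray(collapsed_table.means[s]) for s in SIGNALS},
            "mu": dict(collapsed_table.mu_mean),
        }
        a = log_posterior(f, r, obs, collapsed_table)
        b = log_posterior(f, r, obs, collapsed_table, latent=latent)
        assert a == pytest.approx(b, abs=1e-10)


class TestSampler:
    def test_determinism(self, default_table):
        obs = obs_at(forward_model((0.6, 0.2, 0.1, 0.1), 1.0, default_table))
        cfg = McmcConfig(seed=11, n_iter=2000, n_chains=2)
        a = sample_posterior(obs, default_table, cfg)
        b = sample_posterior(obs, default_table, cfg)
        assert np.array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_pure_source_limit(self, default_table):
        obs = obs_at(
            forward_model((1, 0, 0, 0), 1.0, default_table),
            sigmas={s: 0.1 for s in SIGNALS},
        )
        post = sample_posterior(obs, default_table, McmcConfig(seed=3, n_iter=6000))
        assert post.summaries.loc["f_aN", "mean"] > 0.8

    def test_simplex_closure_and_r_support(self, default_table):
        obs = obs_at(forward_model((0.4, 0.3, 0.2, 0.1), 0.8, default_table))
        post = sample_posterior(obs, default_table, McmcConfig(seed=5, n_iter=3000))
        f = post.draws[:, :4]
        r = post.draws[:, 4]
        assert np.abs(f.sum(axis=1) - 1.0).max() <= 1e-12
        assert np.all(f >= 0)
        assert np.all((r > 0) & (r <= 1))

    def test_diagnostics_reported(self, default_table):
        obs = obs_at(forward_model(F_EQUAL, 1.0, default_table))
        post = sample_posterior(obs, default_table, McmcConfig(seed=9, n_iter=4000))
        assert 0.05 < post.acceptance_rate < 0.9
        assert set(post.rhat) == {"f_aN", "f_bN", "f_nD", "f_bD", "r"}
        assert all(math.isfinite(v) for v in post.rhat.values())


class TestGridOracle:
    def test_grid_too_coarse(self, collapsed_table):
        obs = obs_at(forward_model(F_EQUAL, 1.0, collapsed_table))
        with pytest.raises(ValueError):
            grid_posterior_oracle(obs, collapsed_table, 0.1)

    def test_uncollapsed_rejected(self, default_table):
        obs = obs_at(forward_model(F_EQUAL, 1.0, default_table))
        with pytest.raises(ValueError):
            grid_posterior_oracle(obs, default_table, 0.02)

    def test_symmetry_two_equidistant_sources(self):
        # obs at the exact midpoint of A and B, with C/D mirror images of
        # each other about the obs, r fixed at 1: swapping (A,B) and (C,D)
        # leaves the likelihood invariant, so marginals must match
        table = EndmemberTable(
            pathways=("A", "B", "C", "D"),
            means={
                "d15n_bulk": np.array([-10.0, 10.0, 60.0, -60.0]),
                "d18o": np.array([30.0, 50.0, 100.0, -20.0]),
                "sp": np.array([5.0, 15.0, 80.0, -60.0]),
            },
            sds={s: np.zeros(4) for s in SIGNALS},
            mu_mean={s: -5.0 for s in SIGNALS},
            mu_sd={s: 0.0 for s in SIGNALS},
        )
        obs = obs_at({"d15n_bulk": 0.0, "d18o": 40.0, "sp": 10.0})
        g = grid_posterior_oracle(obs, table, 0.02, fix_r=1.0)
        assert g["f_A"] == pytest.approx(g["f_B"], abs=0.01)
        assert g["f_C"] == pytest.approx(g["f_D"], abs=0.01)

    def test_two_source_quadrature(self):
        # r fixed at 1: grid matches 1-D quadrature posterior on 2 sources
        table = EndmemberTable(
            pathways=("A", "B"),
            means={
                "d15n_bulk": np.array([0.0, -25.0]),
                "d18o": np.array([42.0, 30.0]),
                "sp": np.array([30.0, -2.0]),
            },
            sds={s: np.zeros(2) for s in SIGNALS},
            mu_mean={s: -5.0 for s in SIGNALS},
            mu_sd={s: 0.0 for s in SIGNALS},
        )
        f_true = 0.65
        obs_vals = {
            s: f_true * table.means[s][0] + (1 - f_true) * table.means[s][1]
            for s in SIGNALS
        }
        obs = obs_at(obs_vals)

        def like(fa):
            ll = 0.0
            for s in SIGNALS:
                pred = fa * table.means[s][0] + (1 - fa) * table.means[s][1]
                ll += -0.5 * ((obs.values[s] - pred) / obs.sigmas[s]) ** 2
            return math.exp(ll)

        z, _ = sp_integrate.quad(like, 0, 1)
        mean_quad, _ = sp_integrate.quad(lambda fa: fa * like(fa) / z, 0, 1)
        g = grid_posterior_oracle(obs, table, 0.01, fix_r=1.0)
        assert g["f_A"] == pytest.approx(mean_quad, abs=0.005)

    def test_mcmc_matches_grid_three_pathways(self, collapsed_table):
        sub = collapsed_table.subset(["aN", "nD", "bD"])
        obs = obs_at(forward_model((0.5, 0.3, 0.2), 0.95, sub))
        g = grid_posterior_oracle(obs, sub, 0.02)
        post = sample_posterior(obs, sub, McmcConfig(seed=2, n_iter=10_000))
        for name, want in g.items():
            assert post.summaries.loc[name, "mean"] == pytest.approx(want, abs=0.02)

    def test_label_permutation_equivariance(self, collapsed_table):
        obs = obs_at(forward_model((0.55, 0.25, 0.12, 0.08), 0.9, collapsed_table))
        g = grid_posterior_oracle(obs, collapsed_table, 0.02)
        perm = [2, 0, 3, 1]
        gp = grid_posterior_oracle(obs, collapsed_table.permute(perm), 0.02)
        for p in collapsed_table.pathways:
            assert gp[f"f_{p}"] == pytest.approx(g[f"f_{p}"], abs=1e-12)


class TestApportionDataset:
    def test_empty_input(self, default_table):
        with pytest.raises(ValueError):
            apportion_dataset([], default_table, McmcConfig())

    def test_single_record(self, default_table):
        obs = obs_at(forward_model((0.6, 0.2, 0.1, 0.1), 1.0, default_table))
        cfg = McmcConfig(seed=21, n_iter=3000)
        result = apportion_dataset([obs], default_table, cfg)
        post = sample_posterior(obs, default_table, cfg)
        assert result.overall_mean["aN"] == pytest.approx(
            post.summaries.loc["f_aN", "mean"]
        )
        assert result.overall_sd["aN"] == 0.0

    def test_shared_truth_recovery(self, default_table, rng):
        truth = (0.7, 0.1, 0.1, 0.1)
        clean = forward_model(truth, 1.0, default_table)
        observations = [
            obs_at(
                {
                    s: clean[s] + ANALYTICAL_SIGMAS[s] * rng.standard_normal()
                    for s in SIGNALS
                }
            )
            for _ in range(4)
        ]
        result = apportion_dataset(
            observations, default_table, McmcConfig(seed=31, n_iter=6000)
        )
        assert result.overall_mean["aN"] == pytest.approx(0.7, abs=0.1)
        assert len(result.per_sample) == 4
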