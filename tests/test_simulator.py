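"""Simulator: effect planting bookkeeping, design synthesis, agreement of the
two sampling routes with each other and with the closed-form negative-binomial
marginal, and fidelity reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, ks_2samp, nbinom

from meripower import (
    RegionParams,
    SimulationConfig,
    SizeFactors,
    assign_effects,
    simulate_counts,
    synthesize_design,
    validate_against_pilot,
)
from meripower.containers import ValidationError
from meripower.simulate import expected_counts


def _params(m, alpha=-0.4, beta=0.0, phi=0.1, theta=10.0, beta_hat=None):
    return RegionParams(pd.DataFrame(
        {"region_id": [f"r{i}" for i in range(m)],
         "alpha": alpha,
         "beta": beta if beta_hat is None else beta_hat,
         "phi": phi, "theta": theta,
         "is_dmr": False}
    ))


def _samples(n_per_group):
    return pd.DataFrame(
        {"sample": [f"s{j}" for j in range(2 * n_per_group)],
         "condition": ["A"] * n_per_group + ["B"] * n_per_group,
         "pair": list(range(1, n_per_group + 1)) * 2}
    )


class TestAssignEffects:
    def test_exact_dmr_count(self, rng):
        planted = assign_effects(_params(100), SimulationConfig(dmr_prop=0.1), rng)
        assert planted.is_dmr.sum() == 10
        assert (planted.beta[~planted.is_dmr] == 0).all()

    def test_zero_proportion(self, rng):
        planted = assign_effects(_params(50), SimulationConfig(dmr_prop=0.0), rng)
        assert planted.is_dmr.sum() == 0 and (planted.beta == 0).all()

    def test_rounding_rule_over_seeds(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            planted = assign_effects(_params(37), SimulationConfig(dmr_prop=0.1), rng)
            assert planted.is_dmr.sum() == round(0.1 * 37)

    def test_uniform_component_magnitudes_in_range(self, rng):
        # all beta_hat = 0: nothing exceeds the median, every DMR effect is
        # drawn from the uniform component
        planted = assign_effects(_params(200), SimulationConfig(dmr_prop=0.5), rng)
        mags = np.abs(planted.beta[planted.is_dmr])
        assert ((mags >= 1.0) & (mags <= 2.0)).all()
        assert (planted.beta[planted.is_dmr] < 0).any()  # signs randomised

    def test_large_estimates_reused_with_sign(self, rng):
        beta_hat = np.linspace(-4, 4, 101)
        planted = assign_effects(
            _params(101, beta_hat=beta_hat), SimulationConfig(dmr_prop=1.0), rng
        )
        cut = np.median(np.abs(beta_hat))
        reused = np.abs(beta_hat) > cut
        np.testing.assert_allclose(planted.beta[reused], beta_hat[reused])

    def test_empty_region_set_errors(self, rng):
        with pytest.raises(ValidationError):
            assign_effects(_params(0), SimulationConfig(), rng)


class TestSynthesizeDesign:
    def test_identity_at_pilot_size(self, rng):
        pilot = SizeFactors(np.array([0.8, 1.0, 1.2]), np.array([1.1, 0.9, 1.0]))
        sf, samples = synthesize_design(pilot, SimulationConfig(n_per_group=3), rng)
        np.testing.assert_allclose(sf.sx, np.tile(pilot.sx, 2))
        np.testing.assert_allclose(sf.sy, np.tile(pilot.sy, 2))
        assert list(samples["condition"]) == ["A"] * 3 + ["B"] * 3

    def test_depth_factor_scales_everything(self, rng):
        pilot = SizeFactors(np.array([0.8, 1.2]), np.array([1.1, 0.9]))
        sf, _ = synthesize_design(
            pilot, SimulationConfig(n_per_group=2, depth_factor=2.0), rng
        )
        np.testing.assert_allclose(sf.sx, np.tile(pilot.sx * 2, 2))

    def test_oversampling_draws_from_pilot_multiset(self, rng):
        pilot = SizeFactors(np.array([0.7, 1.0, 1.3]), np.array([0.9, 1.0, 1.1]))
        sf, samples = synthesize_design(pilot, SimulationConfig(n_per_group=10), rng)
        assert len(sf) == 20
        assert set(np.round(sf.sx, 12)) <= set(np.round(pilot.sx, 12))
        assert set(np.round(sf.sy, 12)) <= set(np.round(pilot.sy, 12))


class TestSimulateCounts:
    def test_reproducible_given_seed(self):
        params = _params(30)
        sf = SizeFactors(np.ones(4), np.ones(4))
        a = simulate_counts(params, sf, _samples(2), np.random.default_rng(3))
        b = simulate_counts(params, sf, _samples(2), np.random.default_rng(3))
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)

    def test_monte_carlo_mean_matches_closed_form(self):
        # one parameter cell replicated many times -> iid draws down a column
        m = 20000
        mu, phi, theta, s = 0.35, 0.12, 8.0, 1.4
        alpha = np.log(mu / (1 - mu))
        params = _params(m, alpha=alpha, phi=phi, theta=theta)
        sf = SizeFactors(np.full(4, s), np.full(4, s))
        sim = simulate_counts(params, sf, _samples(2), np.random.default_rng(0))
        ex, ey = expected_counts(params, sf, _samples(2))
        r_x = (1 - mu) * (1 / phi - 1)
        var_x = ex[0, 0] * (1 + s * theta)
        se = np.sqrt(var_x / m)
        assert abs(sim.X[:, 0].mean() - ex[0, 0]) < 3 * se
        assert ex[0, 0] == pytest.approx(s * r_x * theta)

    def test_gamma_poisson_and_nb_marginal_agree(self):
        m = 10000
        params = _params(m, alpha=0.2, phi=0.08, theta=12.0)
        sf = SizeFactors(np.ones(4) * 1.3, np.ones(4) * 0.7)
        gp = simulate_counts(params, sf, _samples(2), np.random.default_rng(1),
                             mode="gamma_poisson")
        nb = simulate_counts(params, sf, _samples(2), np.random.default_rng(2),
                             mode="nb")
        assert ks_2samp(gp.X[:, 0], nb.X[:, 0]).pvalue > 0.01
        assert ks_2samp(gp.Y[:, 1], nb.Y[:, 1]).pvalue > 0.01

    def test_marginal_law_is_printed_negative_binomial(self):
        # chi-square goodness of fit of simulated X against the NB marginal
        rng = np.random.default_rng(42)
        rejections = 0
        cells = 20
        for c in range(cells):
            mu = rng.uniform(0.2, 0.7)
            phi = rng.uniform(0.03, 0.3)
            theta = rng.uniform(3.0, 25.0)
            s = rng.uniform(0.6, 1.6)
            m = 3000
            params = _params(m, alpha=np.log(mu / (1 - mu)), phi=phi, theta=theta)
            sf = SizeFactors(np.full(2, s), np.full(2, s))
            sim = simulate_counts(params, sf, _samples(1), rng)
            draws = sim.X[:, 0]
            r = (1 - mu) * (1 / phi - 1)
            p = 1.0 / (1.0 + s * theta)
            # greedy integer bins, each with expected count >= 8, plus a tail
            edges, acc, k = [], 0.0, 0
            while (1 - nbinom.cdf(k, r, p)) * m >= 8:
                acc += nbinom.pmf(k, r, p)
                if acc * m >= 8:
                    edges.append(k)
                    acc = 0.0
                k += 1
            cdf = nbinom.cdf(np.asarray(edges), r, p)
            probs = np.diff(np.concatenate([[0.0], cdf]))
            probs = np.append(probs, 1.0 - cdf[-1])
            obs = np.bincount(
                np.searchsorted(edges, draws, side="left"), minlength=len(probs)
            )
            exp = probs * m
            stat, pval = chisquare(obs, exp * obs.sum() / exp.sum())
            rejections += pval < 0.05
        assert (cells - rejections) / cells >= 0.94

    def test_vanishing_dispersion_concentrates_methylation(self):
        m = 4000
        mu = 0.4
        params = _params(m, alpha=np.log(mu / (1 - mu)), phi=1e-6, theta=200.0)
        sf = SizeFactors(np.ones(2), np.ones(2))
        sim = simulate_counts(params, sf, _samples(1), np.random.default_rng(4))
        ratio = sim.Y[:, 0] / np.maximum(sim.X[:, 0] + sim.Y[:, 0], 1)
        tot = (sim.X[:, 0] + sim.Y[:, 0]).mean()
        binom_sd = np.sqrt(mu * (1 - mu) / tot)
        beta_sd = np.sqrt(mu * (1 - mu) * 1e-6)  # residual beta-layer floor
        assert abs(ratio.mean() - mu) < 0.02
        assert ratio.std() < binom_sd + 2.0 * beta_sd

    def test_invalid_phi_rejected_before_sampling(self):
        with pytest.raises(ValidationError):
            _params(3, phi=1.2)


class TestValidateAgainstPilot:
    def test_pilot_against_itself_is_zero_divergence(self, small_pilot):
        rc = small_pilot.to_region_counts()
        from meripower.containers import SimulatedDataset

        sim = SimulatedDataset(
            X=rc.X.copy(), Y=rc.Y.copy(), samples=rc.samples,
            size_factors=small_pilot.size_factors,
            truth=pd.DataFrame(
                {"region_id": rc.region_ids, "beta": 0.0, "is_dmr": False}
            ),
        )
        rep = validate_against_pilot(sim, rc)
        assert (rep["kl_pooled_counts"] == 0).all()
        assert (rep["ks_methylation"] == 0).all()
        assert (rep["log2_fc_mean_total"] == 0).all()

    def test_matched_better_than_permuted(self, small_pilot, rng):
        rc = small_pilot.to_region_counts()
        params = RegionParams(small_pilot.truth)
        sim = simulate_counts(params, small_pilot.size_factors,
                              small_pilot.samples, rng)
        matched = validate_against_pilot(sim, rc)
        perm = rng.permutation(rc.n_regions)
        from meripower.containers import RegionCounts

        shuffled = RegionCounts(
            regions=rc.regions.iloc[perm].reset_index(drop=True),
            X=rc.X[perm], Y=rc.Y[perm], samples=rc.samples,
        )
        mismatched = validate_against_pilot(sim, shuffled)
        assert matched["kl_pooled_counts"].median() < mismatched["kl_pooled_counts"].median()
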