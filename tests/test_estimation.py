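"""Parameter estimation: size factors, beta-binomial and negative-binomial
recovery on self-generated data, baseline/theta samplers, KL-divergence
dispersion arbitration, and theta rescaling closure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import ks_2samp

from meripower import (
    RegionCounts,
    RegionParams,
    SizeFactors,
    estimate_baseline_distribution,
    estimate_size_factors,
    fit_beta_binomial_region,
    fit_negative_binomial_region,
    normalize_counts,
    rescale_theta,
    select_dispersion_by_kl,
    simulate_counts,
)
from meripower.containers import ValidationError
from meripower.estimation import estimate_region_params, estimate_theta_distribution


def _region_counts(x, y, samples=None):
    x = np.atleast_2d(x)
    n = x.shape[1]
    if samples is None:
        half = n // 2
        samples = pd.DataFrame(
            {"sample": [f"s{j}" for j in range(n)],
             "condition": ["A"] * half + ["B"] * (n - half),
             "pair": list(range(n))}
        )
    regions = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(x.shape[0]) * 100,
         "end": np.arange(x.shape[0]) * 100 + 100, "strand": "+",
         "region_id": [f"r{i}" for i in range(x.shape[0])]}
    )
    return RegionCounts(regions=regions, X=x, Y=np.atleast_2d(y), samples=samples)


def _two_group_samples(n_per_group):
    return pd.DataFrame(
        {"sample": [f"s{j}" for j in range(2 * n_per_group)],
         "condition": ["A"] * n_per_group + ["B"] * n_per_group,
         "pair": list(range(1, n_per_group + 1)) * 2}
    )


def _sim_regions(m, alpha, beta, phi, theta, n_per_group, rng):
    params = RegionParams(pd.DataFrame(
        {"region_id": [f"r{i}" for i in range(m)],
         "alpha": alpha, "beta": beta, "phi": phi, "theta": theta,
         "is_dmr": np.asarray(beta) != 0}
    ))
    n = 2 * n_per_group
    sf = SizeFactors(np.ones(n), np.ones(n))
    samples = _two_group_samples(n_per_group)
    sim = simulate_counts(params, sf, samples, rng)
    return params, sf, samples, sim


class TestSizeFactors:
    def test_hand_computed_single_pair(self):
        rc = _region_counts([[100]], [[400]])
        sf = estimate_size_factors(rc)
        assert sf.sx[0] == pytest.approx(0.4)
        assert sf.sy[0] == pytest.approx(1.6)

    def test_equal_libraries_give_unit_factors(self):
        rc = _region_counts([[10, 10], [20, 20]], [[10, 10], [20, 20]])
        sf = estimate_size_factors(rc)
        np.testing.assert_allclose(sf.sx, 1.0)
        np.testing.assert_allclose(sf.sy, 1.0)

    def test_global_rescaling_leaves_factors_unchanged(self):
        x = np.array([[10, 30], [5, 15]])
        y = np.array([[40, 20], [10, 5]])
        sf1 = estimate_size_factors(_region_counts(x, y))
        sf2 = estimate_size_factors(_region_counts(7 * x, 7 * y))
        np.testing.assert_allclose(sf1.sx, sf2.sx)
        np.testing.assert_allclose(sf1.sy, sf2.sy)

    def test_relabeling_equivariance(self):
        x = np.array([[10, 30], [5, 15]])
        y = np.array([[40, 20], [10, 5]])
        sf = estimate_size_factors(_region_counts(x, y))
        sf_rev = estimate_size_factors(_region_counts(x[:, ::-1], y[:, ::-1]))
        np.testing.assert_allclose(sf.sx, sf_rev.sx[::-1])

    def test_all_zero_library_errors(self):
        with pytest.raises(ValidationError):
            estimate_size_factors(_region_counts([[0, 5]], [[3, 4]]))


class TestBetaBinomialFit:
    def test_symmetric_no_effect(self, rng):
        t = np.full(10, 200)
        y = rng.binomial(200, 0.5, size=10)
        z = np.repeat([0, 1], 5)
        fit = fit_beta_binomial_region(y, t, z)
        assert abs(fit.alpha) < 0.25
        assert abs(fit.beta) < 0.35

    def test_effect_recovery_on_own_sampler(self):
        rng = np.random.default_rng(77)
        m = 200
        params, sf, samples, sim = _sim_regions(
            m, alpha=np.full(m, logit(0.4)), beta=np.full(m, 1.0),
            phi=np.full(m, 0.1), theta=np.full(m, 20.0),
            n_per_group=10, rng=rng,
        )
        z = np.repeat([0, 1], 10)
        betas = []
        for i in range(m):
            t = sim.X[i] + sim.Y[i]
            fit = fit_beta_binomial_region(sim.Y[i].astype(float), t.astype(float), z)
            betas.append(fit.beta)
        assert abs(np.mean(betas) - 1.0) < 0.1

    def test_single_observation_per_group_flagged(self):
        fit = fit_beta_binomial_region(
            np.array([5.0, 9.0]), np.array([10.0, 12.0]), np.array([0, 1])
        )
        assert not fit.converged
        assert fit.phi == pytest.approx(1e-6)

    def test_no_usable_sample_in_group_errors(self):
        with pytest.raises(ValidationError):
            fit_beta_binomial_region(
                np.array([5.0, 0.0]), np.array([10.0, 0.0]), np.array([0, 1])
            )


class TestNegativeBinomialFit:
    def test_symmetric_counts_give_alpha_near_zero(self, rng):
        x = rng.poisson(100, size=10)
        fit = fit_negative_binomial_region(
            x, x, np.ones(10), np.ones(10), np.repeat([0, 1], 5)
        )
        assert abs(fit.alpha) < 0.2

    def test_parameter_recovery_on_own_sampler(self):
        rng = np.random.default_rng(5)
        m = 200
        params, sf, samples, sim = _sim_regions(
            m, alpha=np.full(m, logit(0.4)), beta=np.zeros(m),
            phi=np.full(m, 0.15), theta=np.full(m, 5.0),
            n_per_group=10, rng=rng,
        )
        z = np.repeat([0, 1], 10)
        phis, thetas = [], []
        for i in range(m):
            fit = fit_negative_binomial_region(sim.X[i], sim.Y[i], sf.sx, sf.sy, z)
            phis.append(fit.phi)
            thetas.append(fit.theta)
        assert abs(np.median(thetas) - 5.0) / 5.0 < 0.2
        assert abs(np.median(phis) - 0.15) < 0.05

    def test_zero_variance_hits_lower_clamp(self):
        fit = fit_negative_binomial_region(
            np.full(6, 50), np.full(6, 50), np.ones(6), np.ones(6),
            np.repeat([0, 1], 3),
        )
        assert not fit.converged
        assert fit.phi == pytest.approx(1e-6)


class TestBaselineAndThetaSamplers:
    def test_empirical_point_mass(self, rng):
        s = estimate_baseline_distribution(np.array([-0.3]), mode="empirical")
        assert (s.sample(50, rng) == -0.3).all()

    def test_parametric_moments(self, rng):
        s = estimate_baseline_distribution(np.array([-1.0, 1.0]), mode="parametric")
        assert s.mean == 0.0 and s.sd == 1.0

    def test_empirical_ecdf_converges(self, rng):
        src = rng.normal(size=300)
        s = estimate_baseline_distribution(src, mode="empirical")
        draws = s.sample(6000, rng)
        assert ks_2samp(draws, src).statistic < 0.05

    def test_empty_estimates_error(self):
        with pytest.raises(ValidationError):
            estimate_baseline_distribution(np.array([]))

    def test_theta_parametric_tracks_phi(self, rng):
        phi = np.exp(rng.normal(-2.5, 0.4, size=200))
        theta = 2.0 / phi  # exact power law, no noise
        s = estimate_theta_distribution(theta, phi, mode="parametric")
        draws = s.sample(np.full(500, 0.1), rng)
        assert np.median(draws) == pytest.approx(20.0, rel=0.15)


class TestDispersionArbitration:
    def _base(self, m, phi, theta=15.0, alpha=-0.4):
        return pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(m)],
             "alpha": alpha, "beta": 0.0, "phi": phi, "theta": theta,
             "is_dmr": False}
        )

    def test_identical_phis_default_to_nb(self, rng):
        m = 30
        base = self._base(m, 0.1)
        sf = SizeFactors(np.ones(6), np.ones(6))
        samples = _two_group_samples(3)
        real = simulate_counts(RegionParams(base), sf, samples, rng)
        rc = _region_counts(real.X, real.Y, samples)
        phi = np.full(m, 0.1)
        _, source, _ = select_dispersion_by_kl(rc, base, phi, phi, sf, rng, nsim_kl=2)
        assert source == "NB"

    def test_planted_bb_truth_selected(self):
        hits = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            m = 60
            phi_true = np.full(m, 0.05)
            base = self._base(m, 0.05)
            sf = SizeFactors(np.ones(8), np.ones(8))
            samples = _two_group_samples(4)
            real = simulate_counts(RegionParams(base), sf, samples, rng)
            rc = _region_counts(real.X, real.Y, samples)
            _, source, _ = select_dispersion_by_kl(
                rc, base, phi_nb=np.clip(phi_true * 10, 0, 0.95),
                phi_bb=phi_true, sf=sf, rng=rng, nsim_kl=3,
            )
            hits += source == "BB"
        assert hits / reps > 0.9

    def test_single_region_falls_back_to_direct_comparison(self, rng):
        base = self._base(1, 0.1)
        sf = SizeFactors(np.ones(6), np.ones(6))
        samples = _two_group_samples(3)
        real = simulate_counts(RegionParams(base), sf, samples, rng)
        rc = _region_counts(real.X, real.Y, samples)
        phi = np.full(1, 0.1)
        _, source, _ = select_dispersion_by_kl(rc, base, phi, phi, sf, rng, nsim_kl=2)
        assert source == "NB"  # tie prefers NB


class TestRescaleTheta:
    def test_identity_when_means_match(self):
        theta = np.array([2.0, 5.0])
        totals = np.array([[10, 20], [30, 50]], dtype=float)
        np.testing.assert_allclose(rescale_theta(theta, totals, totals), theta)

    def test_halved_simulation_doubles_theta(self):
        theta = np.array([2.0, 5.0])
        real = np.array([[10, 20], [30, 50]], dtype=float)
        np.testing.assert_allclose(
            rescale_theta(theta, real, real / 2), theta * 2
        )

    def test_second_round_closure(self, rng):
        # enough samples that per-region Monte-Carlo noise in the mean total
        # is well below the 10% closure band being checked
        m = 80
        base = pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(m)],
             "alpha": -0.4, "beta": 0.0,
             "phi": np.full(m, 0.08),
             "theta": np.full(m, 12.0), "is_dmr": False}
        )
        sf = SizeFactors(np.ones(100), np.ones(100))
        samples = _two_group_samples(50)
        real = simulate_counts(RegionParams(base), sf, samples, rng)
        real_totals = real.X + real.Y
        # start from badly distorted theta, rescale once, resimulate
        distorted = base.assign(theta=base["theta"] * 3.0)
        first = simulate_counts(RegionParams(distorted), sf, samples, rng)
        theta2 = rescale_theta(
            distorted["theta"].to_numpy(), real_totals, first.X + first.Y
        )
        second = simulate_counts(
            RegionParams(base.assign(theta=theta2)), sf, samples, rng
        )
        ratio = (second.X + second.Y).mean(axis=1) / real_totals.mean(axis=1)
        assert (np.abs(np.log(ratio)) < np.log(1.10)).mean() >= 0.9


def test_estimation_pipeline_end_to_end(small_region_counts):
    params, sf = estimate_region_params(
        small_region_counts, rng=np.random.default_rng(0), nsim_kl=2
    )
    assert len(params) == small_region_counts.n_regions
    assert set(params.table["dispersion_source"]) <= {"NB", "BB"}
    assert (params.phi > 0).all() and (params.phi < 1).all()
    assert (params.theta > 0).all()
    # second-round totals should track the pilot after rescaling
    sim = simulate_counts(
        params, sf, small_region_counts.samples, np.random.default_rng(1)
    )
    fc = (sim.X + sim.Y).mean(axis=1) / np.maximum(
        (small_region_counts.X + small_region_counts.Y).mean(axis=1), 1.0
    )
    assert np.median(np.abs(np.log2(fc))) < 0.35
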