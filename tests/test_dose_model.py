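"""Dose-inefficacy model: curve, standardisation, likelihood, quadrature posterior."""
import math

import numpy as np
import pytest
from scipy.special import expit, logit

from crmineff import (
    DoseGrid,
    ModelSpec,
    PosteriorSummary,
    TrialHistory,
    backward_fit_standardised_dose,
    credible_interval,
    inefficacy_probability,
    log_likelihood,
    posterior_update,
)


class TestCurve:
    @pytest.mark.parametrize(
        "beta, d, expected",
        [
            (1.0, 5.0, 0.5),
            (0.0, 8.0, expit(5.0)),
            (1.0, 5.0 - logit(0.05), 0.05),  # inverted analytically
        ],
    )
    def test_curve_values(self, beta, d, expected):
        assert inefficacy_probability(beta, d) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            inefficacy_probability(1.0, -0.1)

    def test_decreasing_in_dose_and_slope(self, grid):
        d = np.array(grid.standardised)
        for beta in (0.2, 1.0, 4.0, 9.5):
            p = inefficacy_probability(beta, d)
            assert np.all(np.diff(p) < 0)
        p_at = [inefficacy_probability(b, 3.0) for b in (0.5, 1.0, 2.0)]
        assert p_at[0] > p_at[1] > p_at[2]


class TestBackwardFit:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.95, 5.0 - math.log(0.95 / 0.05)), (0.5, 5.0), (0.05, 5.0 - math.log(0.05 / 0.95))],
    )
    def test_values(self, p, expected):
        assert backward_fit_standardised_dose(p) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_about_half(self):
        lo = backward_fit_standardised_dose(0.95)
        hi = backward_fit_standardised_dose(0.05)
        assert (lo + hi) / 2 == pytest.approx(5.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_probability_rejected(self, p):
        with pytest.raises(ValueError):
            backward_fit_standardised_dose(p)

    def test_inverts_the_curve_at_unit_slope(self, grid):
        for d in grid.standardised:
            p = inefficacy_probability(1.0, d)
            assert backward_fit_standardised_dose(p) == pytest.approx(d, abs=1e-9)


class TestLogLikelihood:
    def test_empty_history_is_zero(self, grid):
        assert log_likelihood(TrialHistory(), 1.3, grid) == 0.0

    def test_single_record(self, grid):
        h = TrialHistory()
        h.append(50, 1, 1)  # standardised dose 5, logit argument 0
        assert log_likelihood(h, 1.0, grid) == pytest.approx(math.log(0.5))

    def test_additivity(self, grid):
        rng = np.random.default_rng(7)
        records = [(int(rng.choice(grid.actual_mg)), int(rng.random() < 0.5)) for _ in range(8)]
        full = TrialHistory()
        total = 0.0
        for dose, y in records:
            single = TrialHistory()
            single.append(dose, y, 1)
            total += log_likelihood(single, 0.8, grid)
            full.append(dose, y, 1)
        assert log_likelihood(full, 0.8, grid) == pytest.approx(total, rel=1e-12)

    def test_off_grid_dose_rejected(self, grid):
        h = TrialHistory()
        h.append(35, 1, 1)
        with pytest.raises(ValueError):
            log_likelihood(h, 1.0, grid)


class TestPosterior:
    def test_weights_normalised(self, grid, model, random_history):
        rng = np.random.default_rng(0)
        for _ in range(10):
            post = posterior_update(random_history(rng, int(rng.integers(0, 21))), model, grid)
            assert post.beta_weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_history_returns_vague_prior(self, grid, model):
        post = posterior_update(TrialHistory(), model, grid)
        # uniform prior: flat weights, median at the middle of the support
        assert post.beta_median == pytest.approx(5.0, abs=1e-6)
        wide = sum(
            1
            for d in grid.actual_mg
            if (lambda iv: iv[0] < 0.06 and iv[1] > 0.70)(credible_interval(post, d, 0.90))
        )
        assert wide >= 6  # 90% bands span nearly the whole range at most doses

    def test_all_ineffective_flattens_curve(self, grid, model):
        h = TrialHistory()
        for dose in grid.actual_mg:
            for _ in range(2):
                h.append(dose, 1, 1)
        h.append(40, 1, 2)
        h.append(80, 1, 2)  # 18 ineffective responses in total
        post = posterior_update(h, model, grid)
        assert post.beta_median < 0.2
        assert post.estimate_at(80) > 0.9
        # independent oracle: same quadrature at 10x resolution
        fine = posterior_update(h, ModelSpec(n_beta=40010), grid)
        assert post.beta_median == pytest.approx(fine.beta_median, abs=1e-4)
        np.testing.assert_allclose(post.p_plugin, fine.p_plugin, atol=1e-4)

    def test_effective_response_pulls_slope_up(self, grid, model, random_history):
        rng = np.random.default_rng(42)
        for _ in range(100):
            h = random_history(rng, int(rng.integers(1, 16)))
            before = posterior_update(h, model, grid).beta_median
            h.append(int(rng.choice(grid.actual_mg)), 0, 2)
            after = posterior_update(h, model, grid).beta_median
            assert after >= before - 1e-9

    def test_point_estimates_strictly_decreasing(self, grid, model, random_history):
        rng = np.random.default_rng(3)
        for _ in range(20):
            post = posterior_update(random_history(rng, 12), model, grid)
            assert np.all(np.diff(post.p_plugin) < 0)
            assert np.all(np.diff(post.p_mean) < 0)

    def test_quadrature_refinement_stable(self, grid, random_history):
        rng = np.random.default_rng(11)
        coarse, fine = ModelSpec(n_beta=4001), ModelSpec(n_beta=8002)
        for _ in range(20):
            h = random_history(rng, int(rng.integers(0, 21)))
            a = posterior_update(h, coarse, grid)
            b = posterior_update(h, fine, grid)
            assert abs(a.beta_median - b.beta_median) < 1e-4
            assert np.max(np.abs(a.p_plugin - b.p_plugin)) < 1e-4
            assert np.max(np.abs(a.p_mean - b.p_mean)) < 1e-4

    def test_serialisable(self, grid, model):
        post = posterior_update(TrialHistory(), model, grid)
        payload = post.to_dict()
        assert len(payload["per_dose"]) == len(grid.actual_mg)
        assert post.to_json()


class TestCredibleInterval:
    def test_point_mass_collapses(self):
        post = PosteriorSummary(
            beta_support=np.array([1.0]),
            beta_weights=np.array([1.0]),
            beta_median=1.0,
            doses_mg=(50,),
            standardised=(5.0,),
            p_plugin=np.array([0.5]),
            p_mean=np.array([0.5]),
            ci_level=0.9,
            ci_lo=np.array([0.5]),
            ci_hi=np.array([0.5]),
        )
        lo, hi = credible_interval(post, 50, 0.9)
        assert lo == hi == pytest.approx(0.5)

    def test_wide_level_approaches_support_image(self, grid, model):
        post = posterior_update(TrialHistory(), model, grid)
        lo, hi = credible_interval(post, 50, 0.9999)
        assert lo == pytest.approx(float(expit(5.0 - 10.0 * 5.0)), abs=1e-3)
        assert hi == pytest.approx(float(expit(5.0)), abs=1e-2)

    def test_prior_interval_reaches_lower_at_high_dose(self, grid, model):
        post = posterior_update(TrialHistory(), model, grid)
        lo10, hi10 = credible_interval(post, 10, 0.9)
        lo80, hi80 = credible_interval(post, 80, 0.9)
        assert lo80 < lo10 and hi80 < hi10

    def test_level_validated(self, grid, model):
        post = posterior_update(TrialHistory(), model, grid)
        with pytest.raises(ValueError):
            credible_interval(post, 10, 1.0)


def _metropolis_posterior_means(history, spec, grid, seed, n_iter=60000, burn=5000):
    """Independent random-walk Metropolis sampler over beta (test oracle)."""
    rng = np.random.default_rng(seed)
    from scipy.special import log_expit

    n1, n0 = history.response_counts(grid.actual_mg)
    d = np.array(grid.standardised)

    def log_target(beta):
        if not 0.0 < beta < spec.support_upper():
            return -np.inf
        eta = 5.0 - beta * d
        return float(
            spec.prior_logpdf(np.array([beta]))[0] + n1 @ log_expit(eta) + n0 @ log_expit(-eta)
        )

    beta = 2.0
    lt = log_target(beta)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        prop = beta + rng.normal(0.0, 0.8)
        lt_prop = log_target(prop)
        if math.log(rng.random()) < lt_prop - lt:
            beta, lt = prop, lt_prop
        draws[i] = beta
    draws = draws[burn:]
    d = np.array(grid.standardised)
    return expit(5.0 - draws[:, None] * d[None, :]).mean(axis=0)


@pytest.mark.parametrize("pattern", ["mixed", "mostly_effective"])
def test_mcmc_cross_check(grid, model, pattern):
    """An independent MCMC sampler agrees with quadrature per-dose means."""
    h = TrialHistory()
    if pattern == "mixed":
        for dose, y in [(10, 1), (10, 1), (20, 1), (20, 0), (40, 0), (40, 0), (80, 0), (80, 0)]:
            h.append(dose, y, 1)
    else:
        for dose in (10, 20, 40, 80):
            h.append(dose, 0, 1)
            h.append(dose, 0, 1)
        for _ in range(4):
            h.append(40, 0, 2)
    quad = posterior_update(h, model, grid)
    mcmc = _metropolis_posterior_means(h, model, grid, seed=123)
    np.testing.assert_allclose(quad.p_mean, mcmc, atol=0.01)
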