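"""Multivariate birth-death: covariate links, horseshoe shrinkage,
thermodynamic integration."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from paleorates.birth_death import LineageTimes, RateProfile, bd_loglik
from paleorates.env_mbd import (
    CovariateSeries,
    MBDParams,
    TimeGrid,
    align_to_grid,
    bayes_factor,
    gridded_covariates,
    make_beta_schedule,
    mbd_loglik,
    mbd_rate,
    rescale_01,
    run_mbd,
    shrinkage_weight,
    thermodynamic_logml,
)


class TestRescale:
    def test_linear_map_to_unit_interval(self):
        s = CovariateSeries("x", np.array([30.0, 20.0, 10.0]),
                            np.array([10.0, 20.0, 30.0]))
        out = rescale_01(s)
        assert list(out.values) == [0.0, 0.5, 1.0]
        assert out.rescaled

    def test_idempotent(self):
        s = CovariateSeries("x", np.array([9.0, 3.0]), np.array([0.0, 1.0]))
        once = rescale_01(s)
        twice = rescale_01(once)
        assert np.array_equal(once.values, twice.values)

    def test_constant_series_rejected(self):
        s = CovariateSeries("x", np.array([9.0, 3.0]), np.array([2.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            rescale_01(s)

    def test_ascending_ages_rejected(self):
        with pytest.raises(ValueError):
            CovariateSeries("x", np.array([1.0, 5.0]), np.array([0.0, 1.0]))


class TestGridAlignment:
    def test_linear_interpolation(self):
        s = rescale_01(
            CovariateSeries("x", np.array([10.0, 0.0]), np.array([0.0, 1.0]))
        )
        assert align_to_grid(s, np.array([5.0]))[0] == pytest.approx(0.5)

    def test_nearest_value_extrapolation(self):
        s = rescale_01(
            CovariateSeries("x", np.array([10.0, 5.0]), np.array([0.0, 1.0]))
        )
        assert align_to_grid(s, np.array([15.0]))[0] == 0.0  # older end
        assert align_to_grid(s, np.array([1.0]))[0] == 1.0  # younger end

    def test_exact_age_returns_exact_value(self):
        s = rescale_01(
            CovariateSeries("x", np.array([10.0, 4.0, 0.0]),
                            np.array([0.0, 3.0, 1.0]))
        )
        assert align_to_grid(s, np.array([4.0]))[0] == 1.0  # rescaled max

    def test_unrescaled_series_rejected(self):
        s = CovariateSeries("x", np.array([10.0, 0.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="rescaled"):
            align_to_grid(s, np.array([5.0]))

    def test_empty_grid_rejected(self):
        s = rescale_01(
            CovariateSeries("x", np.array([10.0, 0.0]), np.array([0.0, 1.0]))
        )
        with pytest.raises(ValueError):
            align_to_grid(s, np.array([]))


class TestRateLink:
    def test_zero_g_gives_baseline_both_forms(self):
        x = np.array([0.7])
        for form in ("linear", "exponential"):
            assert mbd_rate(0.5, np.array([0.0]), x, form) == pytest.approx(
                0.5
            )

    def test_linear_arithmetic(self):
        assert mbd_rate(0.5, np.array([-0.5]), np.array([1.0]),
                        "linear") == pytest.approx(0.25)

    def test_linear_floors_at_zero(self):
        assert mbd_rate(0.5, np.array([-3.0]), np.array([1.0]),
                        "linear") == 0.0

    def test_exponential_arithmetic(self):
        assert mbd_rate(0.5, np.array([math.log(2)]), np.array([1.0]),
                        "exponential") == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            mbd_rate(0.0, np.array([1.0]), np.array([1.0]), "linear")


class TestShrinkageWeight:
    @pytest.mark.parametrize(
        "local2tau2,expected", [(1.0, 0.5), (3.0, 0.75)]
    )
    def test_weight_values(self, local2tau2, expected):
        w = shrinkage_weight(math.sqrt(local2tau2), 1.0)
        assert w == pytest.approx(expected)

    def test_full_shrinkage_limit(self):
        assert shrinkage_weight(1.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_weight(-1.0, 1.0)


@pytest.fixture
def toy_lineages():
    return LineageTimes(
        ["Genus a", "Genus b", "Genus c"],
        ts=np.array([9.5, 7.0, 4.0]),
        te=np.array([3.0, 1.5, 0.0]),
        extant=np.array([False, False, True]),
    )


class TestMBDLoglik:
    def test_reduces_to_constant_rate_bd_when_g_zero(self, toy_lineages):
        grid = TimeGrid(10.0, 0.1)
        X = np.zeros((grid.n_bins, 2))
        p = MBDParams(0.3, 0.2, [0.0, 0.0], [0.0, 0.0], "linear")
        got = mbd_loglik(toy_lineages, p, X, grid)
        expected = bd_loglik(
            toy_lineages,
            RateProfile(np.array([]), np.array([0.3])),
            RateProfile(np.array([]), np.array([0.2])),
        )
        assert got == pytest.approx(expected, abs=1e-6)

    def test_two_lineage_two_bin_hand_computation(self):
        lin = LineageTimes(["Genus a", "Genus b"],
                           np.array([1.8, 1.2]), np.array([0.6, 0.2]))
        grid = TimeGrid(2.0, 1.0)  # bins (1,2] and (0,1]
        X = np.array([[0.0], [1.0]])  # covariate on in the young bin only
        p = MBDParams(0.4, 0.3, [0.5], [-0.2], "exponential")
        lam = 0.4 * np.exp(np.array([0.0, 0.5]))
        mu = 0.3 * np.exp(np.array([0.0, -0.2]))
        # exposure: a covers (0.6,1.8) -> 0.8 in old bin, 0.4 in young;
        # b covers (0.2,1.2) -> 0.2 old, 0.8 young
        T = np.array([0.8 + 0.2, 0.4 + 0.8])
        # birth of b at 1.2 (old bin), deaths at 0.6 and 0.2 (young bin)
        expected = (
            math.log(lam[0]) + 2 * math.log(mu[1])
            - np.sum(T * (lam + mu))
        )
        assert mbd_loglik(lin, p, X, grid) == pytest.approx(expected,
                                                            abs=1e-10)

    def test_linear_floor_with_event_gives_neg_inf(self, toy_lineages):
        grid = TimeGrid(10.0, 0.1)
        X = np.ones((grid.n_bins, 1))
        p = MBDParams(0.3, 0.2, [-2.0], [0.0], "linear")
        assert mbd_loglik(toy_lineages, p, X, grid) == -np.inf


class TestRunMBD:
    def test_same_seed_gives_identical_posterior(self, toy_lineages):
        cov = rescale_01(
            CovariateSeries("x", np.array([10.0, 5.0, 0.0]),
                            np.array([1.0, 3.0, 2.0]))
        )
        kw = dict(form="exponential", generations=2000, sampling_freq=20,
                  seed=9, ts_cutoff=None, grid_step=0.5)
        a = run_mbd([toy_lineages], [cov], **kw)
        b = run_mbd([toy_lineages], [cov], **kw)
        assert a.draws.equals(b.draws)

    def test_zero_covariates_reduces_to_constant_rate_estimation(
        self, toy_lineages
    ):
        post = run_mbd([toy_lineages], [], generations=2000,
                       sampling_freq=20, seed=1, ts_cutoff=None,
                       grid_step=0.5)
        assert {"l0", "m0"} <= set(post.draws.columns)
        assert not any(c.startswith("Gi_") for c in post.draws.columns)

    def test_unrescaled_covariate_rejected(self, toy_lineages):
        cov = CovariateSeries("x", np.array([10.0, 0.0]),
                              np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="rescaled"):
            run_mbd([toy_lineages], [cov], generations=100)

    def test_pure_noise_covariates_rarely_called_signal(self):
        # with no true covariate effect, <= 20% of shrinkage weights
        # may exceed 0.5 across seeds
        from paleorates.preservation import PreservationKind, PreservationModel
        from paleorates.synthetic_fossils import (
            SimScenario,
            conditioned_on_size,
            generate_covariate_series,
            simulate_bd_lineages,
        )

        grid_ages = np.arange(25.0, -0.01, -0.5)
        covs = [
            rescale_01(generate_covariate_series("sinusoid", grid_ages,
                                                 {"period": 11.0}, seed=51)),
            rescale_01(generate_covariate_series("random-walk", grid_ages,
                                                 seed=52)),
        ]
        flagged = total = 0
        for seed in range(1, 11):
            scen = SimScenario(seed=seed, lam=0.3, mu=0.2, origin=25,
                               n_cap=2000)
            lin = conditioned_on_size(
                simulate_bd_lineages, scen, 100, 800
            )
            post = run_mbd([lin], covs, form="exponential",
                           generations=40_000, sampling_freq=40, seed=seed,
                           ts_cutoff=None, grid_step=0.1)
            s = post.summary()
            w = np.concatenate([s["w_Gi"].values, s["w_Gm"].values])
            flagged += int(np.sum(w > 0.5))
            total += len(w)
        assert flagged / total <= 0.20


def _poisson_gamma_toy():
    rng = np.random.default_rng(5)
    x = rng.poisson(3.0, size=30)
    a, b = 2.0, 1.0
    n, sx = len(x), int(x.sum())
    closed = (
        a * math.log(b) - gammaln(a) + gammaln(a + sx)
        - (a + sx) * math.log(b + n) - gammaln(x + 1).sum()
    )

    def sampler(beta, n_draws=4000):
        rg = np.random.default_rng(77 + int(beta * 1e6))
        theta = rg.gamma(a + beta * sx, 1.0 / (b + beta * n), size=n_draws)
        return sx * np.log(theta) - n * theta - gammaln(x + 1).sum()

    return sampler, float(closed)


class TestThermodynamicIntegration:
    def test_conjugate_toy_within_tolerance(self):
        sampler, closed = _poisson_gamma_toy()
        ml = thermodynamic_logml(sampler, make_beta_schedule(16), "toy")
        assert abs(ml.logml - closed) <= 0.1

    def test_denser_schedules_improve_on_average(self):
        sampler, closed = _poisson_gamma_toy()
        errs = [
            abs(thermodynamic_logml(sampler, make_beta_schedule(k)).logml
                - closed)
            for k in (8, 32)
        ]
        assert errs[1] < errs[0]

    def test_one_point_schedule_is_degenerate_mean_loglik(self):
        sampler, _ = _poisson_gamma_toy()
        ml = thermodynamic_logml(sampler, [1.0])
        assert ml.degenerate
        assert ml.logml == pytest.approx(float(np.mean(sampler(1.0))),
                                         rel=1e-12)

    def test_schedule_missing_zero_rejected(self):
        sampler, _ = _poisson_gamma_toy()
        with pytest.raises(ValueError):
            thermodynamic_logml(sampler, [0.5, 1.0])

    def test_unsorted_schedule_rejected(self):
        sampler, _ = _poisson_gamma_toy()
        with pytest.raises(ValueError):
            thermodynamic_logml(sampler, [0.0, 0.8, 0.4, 1.0])

    def test_beta_schedule_shape(self):
        b = make_beta_schedule(16, 0.3)
        assert b[0] == 0.0 and b[-1] == 1.0
        assert np.all(np.diff(b) > 0)
        assert np.median(b) < 0.5  # dense near zero


class TestBayesFactor:
    def test_equal_marginals_give_zero(self):
        from paleorates.env_mbd import MarginalLikelihood

        a = MarginalLikelihood("a", -50.0, np.array([0.0, 1.0]))
        b = MarginalLikelihood("b", -50.0, np.array([0.0, 1.0]))
        assert bayes_factor(a, b)["log_bf"] == 0.0

    def test_subtraction_and_scales(self):
        from paleorates.env_mbd import MarginalLikelihood

        a = MarginalLikelihood("a", -100.0, np.array([0.0, 1.0]))
        b = MarginalLikelihood("b", -102.0, np.array([0.0, 1.0]))
        out = bayes_factor(a, b)
        assert out["log_bf"] == pytest.approx(2.0)
        assert out["two_log_bf"] == pytest.approx(4.0)
        assert out["favours"] == "a"

    def test_infinite_marginal_rejected(self):
        from paleorates.env_mbd import MarginalLikelihood

        a = MarginalLikelihood("a", float("-inf"), np.array([0.0, 1.0]))
        b = MarginalLikelihood("b", -1.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            bayes_factor(a, b)
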