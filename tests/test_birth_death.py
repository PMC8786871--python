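"""Birth-death likelihood, RJMCMC machinery, and posterior summaries."""

import math

import numpy as np
import pytest

from paleorates.birth_death import (
    ChainSample,
    LineageTimes,
    MCMCConfig,
    RateProfile,
    bd_loglik,
    combine_replicates,
    diversity_trajectory,
    effective_sample_size,
    rates_through_time,
    rjmcmc_run,
)


def brute_force_bd_loglik(lineages, lam, mu, n_grid=200_001):
    """Independent oracle: Riemann-sum interval splitter."""
    ts, te = lineages.ts, lineages.te
    oldest = int(np.argmax(ts))
    ll = 0.0
    for i in range(len(ts)):
        if i != oldest:
            ll += math.log(float(lam.rate_at(np.array([ts[i]]))[0]))
        if not lineages.extant[i]:
            ll += math.log(float(mu.rate_at(np.array([te[i]]))[0]))
        grid = np.linspace(te[i], ts[i], n_grid)
        mid = 0.5 * (grid[:-1] + grid[1:])
        dt = grid[1] - grid[0]
        ll -= float(np.sum((lam.rate_at(mid) + mu.rate_at(mid)) * dt))
    return ll


class TestRateProfile:
    def test_rate_lookup_and_interval_assignment(self):
        prof = RateProfile(np.array([20.0, 10.0]), np.array([0.1, 0.2, 0.3]))
        ages = np.array([25.0, 20.0, 15.0, 10.0, 5.0])
        # an age equal to a shift time belongs to the older interval
        assert list(prof.rate_at(ages)) == [0.1, 0.1, 0.2, 0.2, 0.3]

    def test_integral_matches_riemann_sum(self):
        prof = RateProfile(np.array([18.0, 7.5]), np.array([0.4, 0.15, 0.6]))
        lo, hi = 3.0, 22.0
        x = np.linspace(lo, hi, 400_001)
        mid = 0.5 * (x[:-1] + x[1:])
        riemann = float(np.sum(prof.rate_at(mid)) * (x[1] - x[0]))
        # Riemann error is dominated by the cells containing the two
        # rate discontinuities (~ |dr| * dx / 2 each)
        assert float(prof.integral(np.array([lo]), np.array([hi]))[0]) == (
            pytest.approx(riemann, abs=1e-4)
        )

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            RateProfile(np.array([5.0]), np.array([0.1]))  # wrong length
        with pytest.raises(ValueError):
            RateProfile(np.array([]), np.array([-0.1]))  # negative rate
        with pytest.raises(ValueError):
            RateProfile(np.array([3.0, 8.0]), np.array([1.0, 1.0, 1.0]))


class TestBDLoglik:
    def test_single_interval_closed_form(self):
        # B=3, D=1, total lineage time 50, lam=.1, mu=.02
        lin = LineageTimes(
            ["a", "b", "c", "d"],
            ts=np.array([20.0, 15.0, 12.0, 13.0]),
            te=np.array([0.0, 0.0, 0.0, 10.0]),
            extant=np.array([True, True, True, False]),
        )
        lam = RateProfile(np.array([]), np.array([0.1]))
        mu = RateProfile(np.array([]), np.array([0.02]))
        expected = 3 * math.log(0.1) + math.log(0.02) - 0.12 * 50
        assert bd_loglik(lin, lam, mu) == pytest.approx(expected, abs=1e-10)

    def test_no_events_contributes_only_exposure(self):
        lin = LineageTimes(["a"], np.array([10.0]), np.array([0.0]),
                           np.array([True]))
        lam = RateProfile(np.array([]), np.array([0.3]))
        mu = RateProfile(np.array([]), np.array([0.2]))
        assert bd_loglik(lin, lam, mu) == pytest.approx(-0.5 * 10, abs=1e-12)

    def test_multi_interval_matches_brute_force(self):
        rng = np.random.default_rng(4)
        ts = rng.uniform(10, 30, size=12)
        te = rng.uniform(0, 1, size=12) * (ts - 0.5)
        lin = LineageTimes([f"s{i}" for i in range(12)], ts, te)
        lam = RateProfile(np.array([22.0, 9.0]), np.array([0.05, 0.3, 0.12]))
        mu = RateProfile(np.array([15.0]), np.array([0.08, 0.25]))
        assert bd_loglik(lin, lam, mu) == pytest.approx(
            brute_force_bd_loglik(lin, lam, mu), abs=5e-4
        )

    def test_lineage_invariants_enforced(self):
        with pytest.raises(ValueError):
            LineageTimes(["a"], np.array([5.0]), np.array([5.0]))
        with pytest.raises(ValueError):
            LineageTimes(["a"], np.array([5.0]), np.array([1.0]),
                         np.array([True]))  # extant must have te = 0


@pytest.fixture(scope="module")
def small_chain():
    from paleorates.preservation import PreservationKind, PreservationModel
    from paleorates.synthetic_fossils import (
        SimScenario,
        conditioned_on_size,
        simulate_bd_lineages,
        simulate_preservation,
    )

    scen = SimScenario(
        seed=21, lam=0.3, mu=0.2, origin=25, n_cap=1000,
        preservation=PreservationModel(kind=PreservationKind.HPP, q=4.0),
    )
    lin = conditioned_on_size(simulate_bd_lineages, scen, 40, 120)
    fossils, _ = simulate_preservation(lin, scen.preservation, seed=22)
    cfg = MCMCConfig(generations=20_000, sampling_freq=40, seed=5,
                     preservation_kind="hpp")
    return fossils, rjmcmc_run(fossils, cfg)


class TestRJMCMC:
    def test_sampled_times_respect_fossil_constraints(self, small_chain):
        fossils, chain = small_chain
        oldest = np.array([max(fossils[t]) for t in chain.taxa])
        youngest = np.array([min(fossils[t]) for t in chain.taxa])
        for s in chain.samples:
            assert np.all(s.ts >= oldest)
            assert np.all(s.te <= youngest)
            assert np.all(s.ts > s.te)

    def test_same_seed_reproduces_log_posteriors(self, small_chain):
        fossils, chain = small_chain
        again = rjmcmc_run(
            fossils,
            MCMCConfig(generations=20_000, sampling_freq=40, seed=5,
                       preservation_kind="hpp"),
        )
        assert [s.log_post for s in chain.samples] == [
            s.log_post for s in again.samples
        ]

    def test_chain_log_is_tabular(self, small_chain):
        _, chain = small_chain
        df = chain.to_frame()
        assert {"it", "posterior", "likelihood", "prior", "q", "k_l",
                "k_m"} <= set(df.columns)
        assert len(df) == len(chain.samples)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            rjmcmc_run({}, MCMCConfig(generations=100))

    def test_nonpositive_generations_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(generations=0)


class TestReplicatePooling:
    def test_pooled_count_excludes_burn_in(self, small_chain):
        _, chain = small_chain
        n_post = len(chain.post_burn_in())
        pooled = combine_replicates([chain, chain, chain])
        assert len(pooled) == 3 * n_post
        assert n_post == len(chain.samples) - int(0.2 * len(chain.samples))

    def test_single_chain_pools_to_itself(self, small_chain):
        _, chain = small_chain
        pooled = combine_replicates([chain])
        ref = chain.post_burn_in()
        assert len(pooled) == len(ref)
        assert all(a is b for a, b in zip(pooled, ref))

    def test_mismatched_taxon_sets_rejected(self, small_chain):
        _, chain = small_chain
        import copy

        other = copy.copy(chain)
        other.taxa = list(chain.taxa)[:-1] + ["Other species"]
        with pytest.raises(ValueError, match="taxon"):
            combine_replicates([chain, other])


def _const_sample(lam_val, mu_val, ts, te):
    return ChainSample(
        it=0, log_post=0.0, log_lik=0.0, log_prior=0.0, q=1.0,
        nhpp_shape=1.0, gamma_shape=float("nan"),
        lam=RateProfile(np.array([]), np.array([lam_val])),
        mu=RateProfile(np.array([]), np.array([mu_val])),
        ts=np.asarray(ts, float), te=np.asarray(te, float),
    )


class TestRTT:
    def test_single_sample_gives_flat_degenerate_band(self):
        s = _const_sample(0.2, 0.1, [10.0, 8.0], [5.0, 0.0])
        grid = np.arange(10.0, -0.01, -0.5)
        rtt = rates_through_time([s], grid)
        assert np.allclose(rtt.table["lam_mean"], 0.2)
        assert np.allclose(rtt.table["lam_lo"], rtt.table["lam_hi"])

    def test_two_samples_average_and_net_rate(self):
        s1 = _const_sample(0.2, 0.05, [10.0], [0.0])
        s2 = _const_sample(0.4, 0.15, [10.0], [0.0])
        grid = np.array([6.0, 3.0])
        rtt = rates_through_time([s1, s2], grid)
        assert np.allclose(rtt.table["lam_mean"], 0.3)
        # net diversification is the mean of per-sample lam - mu
        assert np.allclose(rtt.table["r_mean"], 0.3 - 0.1)

    def test_grid_beyond_span_rejected(self):
        s = _const_sample(0.2, 0.1, [10.0], [0.0])
        with pytest.raises(ValueError):
            rates_through_time([s], np.array([20.0, 5.0]))

    def test_ascending_grid_rejected(self):
        s = _const_sample(0.2, 0.1, [10.0], [0.0])
        with pytest.raises(ValueError):
            rates_through_time([s], np.array([1.0, 5.0]))


class TestDiversity:
    def test_interval_counts(self):
        s = _const_sample(0.2, 0.1, [10.0, 8.0], [5.0, 0.0])
        div = diversity_trajectory([s], np.array([9.0, 6.0]))
        assert list(div) == [1.0, 2.0]

    def test_age_equal_ts_counts_the_lineage(self):
        s = _const_sample(0.2, 0.1, [10.0, 8.0], [5.0, 0.0])
        assert diversity_trajectory([s], np.array([8.0]))[0] == 2.0

    def test_age_equal_te_does_not_count(self):
        s = _const_sample(0.2, 0.1, [10.0], [5.0])
        assert diversity_trajectory([s], np.array([5.0]))[0] == 0.0

    def test_no_lineages_gives_zero(self):
        div = diversity_trajectory([], np.array([5.0, 1.0]))
        assert np.all(div == 0)


class TestESS:
    def test_white_noise_ess_near_n(self):
        x = np.random.default_rng(3).normal(size=2000)
        assert effective_sample_size(x) == pytest.approx(2000, rel=0.2)

    def test_ar1_ess_matches_closed_form(self):
        rng = np.random.default_rng(7)
        n, rho = 10_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_sequence_flagged_degenerate(self):
        assert math.isnan(effective_sample_size(np.ones(500)))
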