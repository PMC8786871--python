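"""Joint Bayesian inference of lineage life spans and birth-death rates.

The observed fossil record of each species constrains its latent times of
speciation (``ts``) and extinction (``te``), in Ma before present.  Given
all life spans, speciation and extinction follow a piecewise-constant
birth-death process whose rate profiles (values plus shift times) are
sampled with reversible-jump MCMC, so the number of rate shifts is itself
a random variable.  The preservation process (see
:mod:`paleorates.preservation`) links the latent life spans to the fossil
ages and is sampled jointly (``q``, and the NHPP bell exponent when used).

Summaries: pooling of replicate chains, rate-through-time grids with 95%
highest-posterior-density bands, net diversification ``r = lambda - mu``,
diversity trajectories, and autocorrelation-based effective sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "LineageTimes",
    "RateProfile",
    "MCMCConfig",
    "ChainSample",
    "PosteriorChain",
    "RTTGrid",
    "bd_loglik",
    "rjmcmc_run",
    "combine_replicates",
    "rates_through_time",
    "diversity_trajectory",
    "ess_diagnostics",
]


@dataclass
class LineageTimes:
    """Per-species speciation/extinction times (Ma; ts > te >= 0)."""

    taxa: Sequence[str]
    ts: np.ndarray
    te: np.ndarray
    extant: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        if self.extant is None:
            self.extant = np.zeros(len(self.ts), dtype=bool)
        self.extant = np.asarray(self.extant, dtype=bool)
        if not (len(self.taxa) == len(self.ts) == len(self.te) == len(self.extant)):
            raise ValueError("taxa/ts/te/extant length mismatch")
        if np.any(self.te < 0) or np.any(self.ts <= self.te):
            raise ValueError("require ts > te >= 0 for every lineage")
        if np.any(self.te[self.extant] != 0.0):
            raise ValueError("extant lineages must have te = 0")

    def __len__(self) -> int:
        return len(self.ts)

    @property
    def durations(self) -> np.ndarray:
        return self.ts - self.te


@dataclass
class RateProfile:
    """Piecewise-constant rate: ``shift_times`` strictly descending (Ma),
    ``rates`` oldest-first with length ``len(shift_times) + 1``."""

    shift_times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.shift_times = np.asarray(self.shift_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != len(self.shift_times) + 1:
            raise ValueError("need len(rates) == len(shift_times) + 1")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be > 0")
        if len(self.shift_times) > 1 and np.any(np.diff(self.shift_times) >= 0):
            raise ValueError("shift_times must be strictly descending")

    @property
    def n_shifts(self) -> int:
        return len(self.shift_times)

    def rate_at(self, ages: Union[float, np.ndarray]) -> np.ndarray:
        """Rate applying at each age; an age equal to a shift time belongs
        to the older interval."""
        ages = np.asarray(ages, dtype=float)
        asc = self.shift_times[::-1]  # ascending
        n_le = np.searchsorted(asc, ages, side="right")
        idx = self.n_shifts - n_le  # oldest-first interval index
        return self.rates[idx]

    def integral(
        self, lo: Union[float, np.ndarray], hi: Union[float, np.ndarray]
    ) -> np.ndarray:
        """``\\int_lo^hi rate(u) du`` with lo <= hi (ages)."""
        asc = self.shift_times[::-1]
        r_young_first = self.rates[::-1]
        edges = np.concatenate(([0.0], asc))
        widths = np.diff(np.concatenate((edges, [np.inf])))
        cum = np.concatenate(
            ([0.0], np.cumsum(r_young_first[:-1] * widths[:-1]))
        ) if self.n_shifts else np.array([0.0])

        def cum_at(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            j = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, None)
            return cum[j] + r_young_first[j] * (t - edges[j])

        return cum_at(hi) - cum_at(lo)


def bd_loglik(
    lineages: LineageTimes, lam: RateProfile, mu: RateProfile
) -> float:
    """Piecewise-constant birth-death log likelihood of the life spans.

    ``sum_k [B_k ln lam_k + D_k ln mu_k - (lam_k + mu_k) T_k]`` where, per
    rate interval ``k``, ``B_k`` counts speciation events (all ts except the
    single oldest lineage's origin), ``D_k`` counts extinctions (te of
    extinct lineages), and ``T_k`` is the summed lineage time in the
    interval.
    """
    ts, te = lineages.ts, lineages.te
    oldest = int(np.argmax(ts))
    birth_mask = np.ones(len(ts), dtype=bool)
    birth_mask[oldest] = False
    death_mask = ~lineages.extant

    ll = float(np.sum(np.log(lam.rate_at(ts[birth_mask]))))
    ll += float(np.sum(np.log(mu.rate_at(te[death_mask]))))
    ll -= float(np.sum(lam.integral(te, ts)))
    ll -= float(np.sum(mu.integral(te, ts)))
    return ll


# ---------------------------------------------------------------------------
# MCMC machinery
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler settings.  The "paper" preset is generations=20_000_000,
    sampling_freq=5_000; the desk preset divides both by 100."""

    generations: int = 200_000
    sampling_freq: int = 50
    burn_in: float = 0.20
    seed: int = 0
    preservation_kind: str = "nhpp"  # "hpp" | "nhpp"
    nhpp_shape: float = 2.0
    sample_nhpp_shape: bool = True
    gamma_on: bool = False
    n_gamma_categories: int = 4
    fix_shifts: bool = False  # constrain both profiles to zero shifts
    max_shifts: int = 10
    poisson_shift_prior: float = 1.0
    rate_prior_shape: float = 1.1
    rate_prior_rate: float = 1.0
    window_ts: float = 1.0
    window_te: float = 1.0
    multiplier_width: float = 0.3

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if self.preservation_kind not in ("hpp", "nhpp"):
            raise ValueError(f"unknown preservation kind {self.preservation_kind!r}")


@dataclass
class ChainSample:
    it: int
    log_post: float
    log_lik: float
    log_prior: float
    q: float
    nhpp_shape: float
    gamma_shape: float
    lam: RateProfile
    mu: RateProfile
    ts: np.ndarray
    te: np.ndarray


@dataclass
class PosteriorChain:
    samples: list[ChainSample]
    config: MCMCConfig
    taxa: Sequence[str]
    burn_in: float = 0.20

    def post_burn_in(self) -> list[ChainSample]:
        cut = int(math.floor(self.burn_in * len(self.samples)))
        return self.samples[cut:]

    def to_frame(self) -> pd.DataFrame:
        """Scalar chain log (tab-separable); profiles serialised as
        comma-joined strings so rows are bit-stable given a seed."""
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "it": s.it,
                    "posterior": s.log_post,
                    "likelihood": s.log_lik,
                    "prior": s.log_prior,
                    "q": s.q,
                    "alpha_gamma": s.gamma_shape,
                    "k_l": s.lam.n_shifts,
                    "k_m": s.mu.n_shifts,
                    "lambda_rates": ",".join(f"{r:.6g}" for r in s.lam.rates),
                    "lambda_shifts": ",".join(
                        f"{t:.6g}" for t in s.lam.shift_times
                    ),
                    "mu_rates": ",".join(f"{r:.6g}" for r in s.mu.rates),
                    "mu_shifts": ",".join(f"{t:.6g}" for t in s.mu.shift_times),
                }
            )
        return pd.DataFrame(rows)


class _Data:
    """Preprocessed per-replicate fossil data (flat arrays for speed)."""

    def __init__(self, species_ages: dict[str, np.ndarray],
                 extant: Optional[set] = None) -> None:
        if not species_ages:
            raise ValueError("empty dataset")
        self.taxa = sorted(species_ages)
        self.n = len(self.taxa)
        self.k = np.array([len(species_ages[t]) for t in self.taxa])
        if np.any(self.k < 1):
            raise ValueError("every species needs >= 1 fossil age")
        self.oldest = np.array([max(species_ages[t]) for t in self.taxa])
        self.youngest = np.array([min(species_ages[t]) for t in self.taxa])
        self.fossil_age = np.concatenate(
            [np.asarray(species_ages[t], float) for t in self.taxa]
        )
        self.sp_idx = np.repeat(np.arange(self.n), self.k)
        self.offsets = np.concatenate(([0], np.cumsum(self.k)))
        extant = extant or set()
        self.extant = np.array([t in extant for t in self.taxa])
        if np.any(self.extant & (self.youngest < 0)):
            raise ValueError("invalid extant flags")
        self.span = float(self.oldest.max())

    def fossils_of(self, i: int) -> np.ndarray:
        return self.fossil_age[self.offsets[i]:self.offsets[i + 1]]


def _pres_loglik_terms(
    data: _Data, ts: np.ndarray, te: np.ndarray, q: float,
    kind: str, a: float,
) -> np.ndarray:
    """Per-species preservation log likelihood (vectorised)."""
    d = ts - te
    out = data.k * np.log(q) - q * d
    if kind == "nhpp":
        u = (ts[data.sp_idx] - data.fossil_age) / d[data.sp_idx]
        u = np.clip(u, 1e-12, 1 - 1e-12)
        logf = (a - 1.0) * (np.log(u) + np.log1p(-u)) - special.betaln(a, a)
        out = out + np.bincount(data.sp_idx, weights=logf, minlength=data.n)
    return out


def _pres_one(
    data: _Data, i: int, ts_i: float, te_i: float, q: float, kind: str,
    a: float, gamma_on: bool, gamma_shape: float, n_cat: int,
) -> float:
    """Preservation log likelihood of a single species (hot path of the
    per-species time updates)."""
    from .preservation import gamma_category_means

    d = ts_i - te_i
    shape_term = 0.0
    if kind == "nhpp":
        u = np.clip((ts_i - data.fossils_of(i)) / d, 1e-12, 1 - 1e-12)
        shape_term = float(
            np.sum((a - 1.0) * (np.log(u) + np.log1p(-u)))
        ) - data.k[i] * float(special.betaln(a, a))
    if not gamma_on:
        return data.k[i] * math.log(q) - q * d + shape_term
    means = gamma_category_means(gamma_shape, n_cat)
    terms = data.k[i] * np.log(q * means) - q * means * d + shape_term
    return float(special.logsumexp(terms) - math.log(n_cat))


def _pres_loglik_species(
    data: _Data, ts: np.ndarray, te: np.ndarray, q: float, kind: str,
    a: float, gamma_on: bool, gamma_shape: float, n_cat: int,
) -> np.ndarray:
    from .preservation import gamma_category_means

    if not gamma_on:
        return _pres_loglik_terms(data, ts, te, q, kind, a)
    means = gamma_category_means(gamma_shape, n_cat)
    mat = np.stack(
        [_pres_loglik_terms(data, ts, te, q * m, kind, a) for m in means]
    )
    return special.logsumexp(mat, axis=0) - np.log(n_cat)


def _log_prior(
    state: dict, cfg: MCMCConfig, span: float
) -> float:
    lp = 0.0
    for prof in (state["lam"], state["mu"]):
        k = prof.n_shifts
        lp += k * math.log(cfg.poisson_shift_prior) - cfg.poisson_shift_prior \
            - math.lgamma(k + 1)
        lp += float(
            np.sum(
                (cfg.rate_prior_shape - 1) * np.log(prof.rates)
                - cfg.rate_prior_rate * prof.rates
            )
        )
        lp += math.lgamma(k + 1) - k * math.log(span)  # ordered uniform times
    # q ~ Gamma(1.1, 1); nhpp shape, gamma shape ~ lognormal
    lp += 0.1 * math.log(state["q"]) - state["q"]
    if cfg.preservation_kind == "nhpp":
        la = math.log(state["a"])
        lp += -0.5 * (la - math.log(2.0)) ** 2 - la
    if cfg.gamma_on:
        lg = math.log(state["gamma_shape"])
        lp += -0.5 * lg**2 - lg
    return lp


def rjmcmc_run(
    replicate: Union[pd.DataFrame, dict],
    config: Optional[MCMCConfig] = None,
    extant: Optional[set] = None,
) -> PosteriorChain:
    """Sample the joint posterior of life spans, preservation parameters
    and rate profiles for one point-dated replicate dataset.

    ``replicate`` is either a DataFrame with columns ``taxon_key, age`` or a
    mapping taxon -> fossil-age array.  Deterministic given ``config.seed``.
    """
    cfg = config or MCMCConfig()
    if isinstance(replicate, pd.DataFrame):
        from .fossil_records import replicate_to_species_data

        species_ages = replicate_to_species_data(replicate)
    else:
        species_ages = {k: np.asarray(v, float) for k, v in replicate.items()}
    data = _Data(species_ages, extant)
    rng = np.random.default_rng(cfg.seed)

    # --- initial state: life spans just beyond the fossil ranges
    ts = data.oldest + 0.5 + rng.random(data.n)
    te = np.where(data.extant, 0.0, data.youngest * rng.random(data.n) * 0.5)
    state = {
        "ts": ts,
        "te": te,
        "q": max(0.5, float(np.sum(data.k) / np.sum(ts - te))),
        "a": cfg.nhpp_shape,
        "gamma_shape": 1.0,
        "lam": RateProfile(np.array([]), np.array([0.2])),
        "mu": RateProfile(np.array([]), np.array([0.1])),
    }

    kind = cfg.preservation_kind

    def pres_ll_vec(ts_, te_, q_, a_, g_) -> np.ndarray:
        return _pres_loglik_species(
            data, ts_, te_, q_, kind, a_, cfg.gamma_on, g_,
            cfg.n_gamma_categories,
        )

    def bd_ll(ts_, te_, lam_, mu_) -> float:
        lin = LineageTimes(data.taxa, ts_, te_, data.extant)
        return bd_loglik(lin, lam_, mu_)

    pres_vec = pres_ll_vec(ts, te, state["q"], state["a"], state["gamma_shape"])
    pres_total = float(pres_vec.sum())
    bd_total = bd_ll(ts, te, state["lam"], state["mu"])

    win_ts = cfg.window_ts
    win_te = cfg.window_te
    mult_w = cfg.multiplier_width
    acc = {"times": [0, 0], "mult": [0, 0]}
    burn_gen = int(cfg.burn_in * cfg.generations)

    move_p = np.array([0.45, 0.10, 0.05, 0.25, 0.10, 0.05])
    if kind != "nhpp" or not cfg.sample_nhpp_shape:
        move_p[2] = 0.0
    if cfg.fix_shifts:
        move_p[4] = 0.0
        move_p[5] = 0.0
    move_p = move_p / move_p.sum()

    samples: list[ChainSample] = []

    def record(it: int) -> None:
        lp_prior = _log_prior(state, cfg, data.span)
        ll = pres_total + bd_total
        samples.append(
            ChainSample(
                it=it,
                log_post=ll + lp_prior,
                log_lik=ll,
                log_prior=lp_prior,
                q=state["q"],
                nhpp_shape=state["a"],
                gamma_shape=state["gamma_shape"] if cfg.gamma_on else float("nan"),
                lam=RateProfile(
                    state["lam"].shift_times.copy(), state["lam"].rates.copy()
                ),
                mu=RateProfile(
                    state["mu"].shift_times.copy(), state["mu"].rates.copy()
                ),
                ts=state["ts"].copy(),
                te=state["te"].copy(),
            )
        )

    for it in range(1, cfg.generations + 1):
        move = rng.choice(6, p=move_p)
        if move == 0:  # single-species ts or te sliding window
            i = int(rng.integers(data.n))
            ts_, te_ = state["ts"], state["te"]
            do_ts = bool(rng.random() < 0.5) or data.extant[i]
            if do_ts:
                prop = ts_[i] + (rng.random() * 2 - 1) * win_ts
                valid = prop > max(data.oldest[i], te_[i])
            else:
                prop = te_[i] + (rng.random() * 2 - 1) * win_te
                valid = 0.0 <= prop < min(data.youngest[i], ts_[i])
            acc["times"][1] += 1
            if valid:
                new_ts_i = prop if do_ts else ts_[i]
                new_te_i = te_[i] if do_ts else prop
                new_pres_i = _pres_one(
                    data, i, new_ts_i, new_te_i, state["q"], kind,
                    state["a"], cfg.gamma_on, state["gamma_shape"],
                    cfg.n_gamma_categories,
                )
                new_ts = ts_.copy()
                new_te = te_.copy()
                (new_ts if do_ts else new_te)[i] = prop
                new_bd = bd_ll(new_ts, new_te, state["lam"], state["mu"])
                delta = (new_pres_i - pres_vec[i]) + (new_bd - bd_total)
                if math.log(rng.random()) < delta:
                    state["ts"], state["te"] = new_ts, new_te
                    pres_vec = pres_vec.copy()
                    pres_vec[i] = new_pres_i
                    pres_total = float(pres_vec.sum())
                    bd_total = new_bd
                    acc["times"][0] += 1
        elif move in (1, 2):  # q or NHPP shape multiplier
            key = "q" if move == 1 else "a"
            old = state[key]
            prop = old * math.exp((rng.random() * 2 - 1) * mult_w)
            new_pres = pres_ll_vec(
                state["ts"], state["te"],
                prop if key == "q" else state["q"],
                prop if key == "a" else state["a"],
                state["gamma_shape"],
            )
            old_prior = _log_prior(state, cfg, data.span)
            state[key] = prop
            new_prior = _log_prior(state, cfg, data.span)
            state[key] = old
            delta = (
                new_pres.sum() - pres_total + new_prior - old_prior
                + math.log(prop / old)  # multiplier Hastings term
            )
            acc["mult"][1] += 1
            if math.log(rng.random()) < delta:
                state[key] = prop
                pres_vec, pres_total = new_pres, float(new_pres.sum())
                acc["mult"][0] += 1
        elif move == 3:  # rate multiplier on one interval
            which = "lam" if rng.random() < 0.5 else "mu"
            prof: RateProfile = state[which]
            j = int(rng.integers(len(prof.rates)))
            old_r = prof.rates[j]
            new_r = old_r * math.exp((rng.random() * 2 - 1) * mult_w)
            new_rates = prof.rates.copy()
            new_rates[j] = new_r
            new_prof = RateProfile(prof.shift_times, new_rates)
            new_bd = bd_ll(state["ts"], state["te"],
                           new_prof if which == "lam" else state["lam"],
                           new_prof if which == "mu" else state["mu"])
            dprior = (
                (cfg.rate_prior_shape - 1) * math.log(new_r / old_r)
                - cfg.rate_prior_rate * (new_r - old_r)
            )
            delta = new_bd - bd_total + dprior + math.log(new_r / old_r)
            if math.log(rng.random()) < delta:
                state[which] = new_prof
                bd_total = new_bd
        elif move == 4:  # reversible jump: shift birth / death
            which = "lam" if rng.random() < 0.5 else "mu"
            prof = state[which]
            k = prof.n_shifts
            birth = rng.random() < 0.5 if 0 < k < cfg.max_shifts else (k == 0)
            lam_pois = cfg.poisson_shift_prior

            def p_birth(kk: int) -> float:
                return 1.0 if kk == 0 else (0.0 if kk >= cfg.max_shifts else 0.5)

            def p_death(kk: int) -> float:
                return 1.0 if kk >= cfg.max_shifts else (0.0 if kk == 0 else 0.5)

            if birth:
                t_new = rng.random() * data.span
                # the younger part of the split interval gets a prior draw
                r_new = float(
                    rng.gamma(cfg.rate_prior_shape, 1.0 / cfg.rate_prior_rate)
                )
                times = np.sort(np.append(prof.shift_times, t_new))[::-1]
                pos = int(np.where(times == t_new)[0][0])
                rates = np.insert(prof.rates, pos + 1, r_new)
                new_prof = RateProfile(times, rates)
                log_ratio_kp = math.log(lam_pois / (k + 1)) + math.log(
                    p_death(k + 1) / p_birth(k)
                )
            else:
                j = int(rng.integers(k))
                times = np.delete(prof.shift_times, j)
                rates = np.delete(prof.rates, j + 1)
                new_prof = RateProfile(times, rates)
                log_ratio_kp = math.log(k / lam_pois) + math.log(
                    p_birth(k - 1) / p_death(k)
                )
            new_bd = bd_ll(state["ts"], state["te"],
                           new_prof if which == "lam" else state["lam"],
                           new_prof if which == "mu" else state["mu"])
            # prior-draw proposal: rate prior and shift-time density cancel
            delta = new_bd - bd_total + log_ratio_kp
            if math.log(rng.random()) < delta:
                state[which] = new_prof
                bd_total = new_bd
        else:  # slide one shift time between its neighbours
            which = "lam" if rng.random() < 0.5 else "mu"
            prof = state[which]
            if prof.n_shifts:
                j = int(rng.integers(prof.n_shifts))
                hi = prof.shift_times[j - 1] if j > 0 else data.span
                lo = prof.shift_times[j + 1] if j < prof.n_shifts - 1 else 0.0
                t_new = lo + rng.random() * (hi - lo)
                times = prof.shift_times.copy()
                times[j] = t_new
                new_prof = RateProfile(times, prof.rates)
                new_bd = bd_ll(state["ts"], state["te"],
                               new_prof if which == "lam" else state["lam"],
                               new_prof if which == "mu" else state["mu"])
                if math.log(rng.random()) < new_bd - bd_total:
                    state[which] = new_prof
                    bd_total = new_bd

        # adapt proposal widths during burn-in only (frozen afterwards)
        if it <= burn_gen and it % 1000 == 0:
            if acc["times"][1] > 50:
                rate = acc["times"][0] / acc["times"][1]
                scale = math.exp(0.5 * (rate - 0.3))
                win_ts = min(10.0, max(0.01, win_ts * scale))
                win_te = min(10.0, max(0.01, win_te * scale))
                acc["times"] = [0, 0]
            if acc["mult"][1] > 50:
                rate = acc["mult"][0] / acc["mult"][1]
                mult_w = min(3.0, max(0.01, mult_w * math.exp(0.5 * (rate - 0.3))))
                acc["mult"] = [0, 0]

        if it % cfg.sampling_freq == 0:
            record(it)

    return PosteriorChain(
        samples=samples, config=cfg, taxa=data.taxa, burn_in=cfg.burn_in
    )


def combine_replicates(chains: Sequence[PosteriorChain]) -> list[ChainSample]:
    """Concatenate post-burn-in samples of replicate chains with equal
    per-replicate weight."""
    if not chains:
        raise ValueError("no chains supplied")
    ref = chains[0]
    for c in chains[1:]:
        if list(c.taxa) != list(ref.taxa):
            raise ValueError("chains have mismatched taxon sets")
        if c.config.preservation_kind != ref.config.preservation_kind:
            raise ValueError("chains have mismatched model configurations")
    pooled: list[ChainSample] = []
    for c in chains:
        pooled.extend(c.post_burn_in())
    if not pooled:
        raise ValueError("no post-burn-in samples")
    return pooled


@dataclass
class RTTGrid:
    """Rate-through-time summary on an age grid (descending)."""

    table: pd.DataFrame  # age, lam_mean/lo/hi, mu_..., r_..., div_mean


def _hpd(samples_2d: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """95% HPD bounds per column (arviz)."""
    import arviz as az

    if samples_2d.shape[0] < 2:
        v = samples_2d[0]
        return v.copy(), v.copy()
    hdi = az.hdi(samples_2d[None, :, :], hdi_prob=level)
    return np.asarray(hdi)[:, 0], np.asarray(hdi)[:, 1]


def rates_through_time(
    pooled: Sequence[ChainSample],
    grid: np.ndarray,
    level: float = 0.95,
) -> RTTGrid:
    """Evaluate each posterior sample's rate profiles on an age grid and
    summarise with means and HPD bands; ``r = lambda - mu`` per sample."""
    if not len(pooled):
        raise ValueError("empty posterior")
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("grid must be strictly descending")
    span = max(s.ts.max() for s in pooled)
    if grid.max() > span:
        raise ValueError("grid extends beyond the sampled time span")
    lam = np.stack([s.lam.rate_at(grid) for s in pooled])
    mu = np.stack([s.mu.rate_at(grid) for s in pooled])
    r = lam - mu
    div = np.stack(
        [np.sum((s.ts[:, None] >= grid) & (grid > s.te[:, None]), axis=0)
         for s in pooled]
    )
    cols = {"age": grid}
    for name, arr in (("lam", lam), ("mu", mu), ("r", r)):
        lo, hi = _hpd(arr, level)
        cols[f"{name}_mean"] = arr.mean(axis=0)
        cols[f"{name}_lo"] = lo
        cols[f"{name}_hi"] = hi
    cols["div_mean"] = div.mean(axis=0)
    return RTTGrid(table=pd.DataFrame(cols))


def diversity_trajectory(
    pooled: Sequence[ChainSample], grid: np.ndarray
) -> np.ndarray:
    """Mean number of lineages alive at each grid age; a lineage is alive
    on the half-open interval ``ts >= age > te``."""
    grid = np.asarray(grid, dtype=float)
    if not len(pooled):
        return np.zeros(len(grid))
    counts = np.stack(
        [np.sum((s.ts[:, None] >= grid) & (grid > s.te[:, None]), axis=0)
         for s in pooled]
    )
    return counts.mean(axis=0)


def ess_diagnostics(chain: PosteriorChain) -> dict[str, float]:
    """Autocorrelation-based effective sample sizes for scalar summaries
    (log posterior, mean rates, q) over the post-burn-in samples."""
    import arviz as az

    post = chain.post_burn_in()
    if len(post) < 10:
        raise ValueError("need >= 10 post-burn-in samples")
    series = {
        "log_post": np.array([s.log_post for s in post]),
        "mean_lambda": np.array([float(np.mean(s.lam.rates)) for s in post]),
        "mean_mu": np.array([float(np.mean(s.mu.rates)) for s in post]),
        "q": np.array([s.q for s in post]),
    }
    out = {}
    for name, x in series.items():
        if np.allclose(x, x[0]):
            out[name] = float("nan")  # degenerate, flagged as NaN
        else:
            out[name] = float(az.ess(x))
    return out


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a 1-D chain (arviz bulk ESS); NaN for a constant sequence."""
    import arviz as az

    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        return float("nan")
    return float(az.ess(x))
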