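"""Individual-based stochastic community simulators.

Three canonical two-species models with a fluctuating environment:

* discrete-time lottery (Chesson–Warner): per step of duration τ a
  fraction min(τ,1) of the N sites is vacated and refilled by a lottery
  weighted by fitness-weighted frequencies;
* its continuous-time Moran analogue: one site turns over per elementary
  event, time advances by 1/N generations per event;
* a Leslie–Gower tree/sapling model: adults survive yearly, saplings are
  recruited at environment-dependent rates and compete in a lottery for
  vacant adult sites.

The environment is piecewise constant: it keeps a value for one dwell
period of length τ and is then redrawn independently, so its
autocorrelation time is τ/2.

All simulators conserve the community/adult-site total N, are driven by
a :class:`numpy.random.Generator` (bit-for-bit reproducible given a
seed), and expose closed-form one-step moments where available so that
inference can be validated against exact conditional expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .series import AbundanceSeries

__all__ = [
    "EnvironmentProcess",
    "LotteryConfig",
    "LeslieGowerConfig",
    "simulate_lottery_discrete",
    "simulate_lottery_moran",
    "simulate_leslie_gower",
    "generate_recruitment_series",
    "sample_lottery_transitions",
    "sample_moran_transitions",
    "lottery_step_moments",
    "lottery_step_sample",
    "default_band",
]


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EnvironmentProcess:
    """Piecewise-constant environment: value held for τ, then redrawn.

    ``sigma`` scales unit-variance states η, so the invader log fitness is
    s_t = s0 + sigma·η_t. The default dichotomous states are η = ±1;
    "uniform" and "gaussian" states (also unit variance) are available.
    """

    tau: float
    sigma: float
    distribution: str = "dichotomous"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("dwell time tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.distribution not in ("dichotomous", "uniform", "gaussian"):
            raise ValueError(f"unknown environment distribution {self.distribution!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw `size` independent unit-variance environment states η."""
        if self.distribution == "dichotomous":
            return rng.integers(0, 2, size=size) * 2.0 - 1.0
        if self.distribution == "uniform":
            half = math.sqrt(3.0)
            return rng.uniform(-half, half, size=size)
        return rng.standard_normal(size)

    def discrete_states(self) -> list[tuple[float, float]]:
        """(η, weight) pairs; only defined for the dichotomous process."""
        if self.distribution != "dichotomous":
            raise NotImplementedError(
                "exact state enumeration requires a dichotomous environment"
            )
        if self.sigma == 0.0:
            return [(0.0, 1.0)]
        return [(1.0, 0.5), (-1.0, 0.5)]


@dataclass(frozen=True)
class LotteryConfig:
    """Lottery community: N sites, invader mean log-fitness advantage s0."""

    N: int
    s0: float
    env: EnvironmentProcess
    mode: str = "discrete"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("community size N must be at least 2")
        if self.mode not in ("discrete", "moran"):
            raise ValueError(f"unknown lottery mode {self.mode!r}")
        if self.mode == "discrete" and self.env.tau > 1.0:
            raise ValueError(
                "the discrete-time lottery requires tau <= 1 (the death "
                "fraction min(tau, 1) saturates); use the Moran mode"
            )


def _lottery_p(n, s, N):
    """Recruitment probability of the invader for a vacated site."""
    w = n * np.exp(s)
    return w / (w + (N - n))


def _discrete_step(n, s, N, tp, rng):
    """One dwell-time step of the discrete lottery, vectorised over chains.

    Deaths are a Binomial(N, tp) thinned independently per species (which
    is the same law as a hypergeometric split of the total death count);
    every vacated site is refilled by an invader with probability p.
    """
    d_inv = rng.binomial(n, tp)
    d_res = rng.binomial(N - n, tp)
    rec = rng.binomial(d_inv + d_res, _lottery_p(n, s, N))
    return n - d_inv + rec


def simulate_lottery_discrete(
    config: LotteryConfig,
    n0: int,
    horizon: float,
    record_interval: float | None = None,
    seed=None,
    rng=None,
) -> AbundanceSeries:
    """Simulate one discrete-time lottery trajectory.

    ``horizon`` is in generations; the invader abundance is recorded every
    ``record_interval`` generations (default: every dwell time τ, which is
    also the step duration). The environment is redrawn every step.
    """
    rng = _as_rng(seed, rng)
    tau = config.env.tau
    if not 0 <= n0 <= config.N:
        raise ValueError("n0 must lie in [0, N]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    record_interval = tau if record_interval is None else record_interval
    k = record_interval / tau
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("record_interval must be a positive multiple of the step tau")
    k = int(round(k))
    steps = int(round(horizon / tau))
    if steps < k:
        raise ValueError("horizon shorter than one record interval")
    tp = min(tau, 1.0)
    n = np.array([n0], dtype=np.int64)
    records = [n0]
    for step in range(1, steps + 1):
        s = config.s0 + config.env.sigma * config.env.sample(rng, 1)
        n = _discrete_step(n, s, config.N, tp, rng)
        if step % k == 0:
            records.append(int(n[0]))
    times = np.arange(len(records)) * (k * tau)
    return AbundanceSeries(times=times, counts=np.array(records, dtype=np.int64))


def default_band(N: int, nf: int) -> tuple[int, int]:
    """Default calibration band [1, band_max] for transition sampling.

    The upper edge must reach well past the demographic/environmental
    crossover so that the environmental variance is identifiable, while
    staying ≪ N to avoid density-dependent bias; band_max = N/50 clipped
    to [2·nf, 10·nf].
    """
    return 1, int(np.clip(N // 50, 2 * nf, 10 * nf))


def _band_homes(band: tuple[int, int], n_chains: int) -> np.ndarray:
    lo, hi = band
    if not (1 <= lo < hi):
        raise ValueError("band must satisfy 1 <= lo < hi")
    return np.rint(np.geomspace(lo, hi, n_chains)).astype(np.int64)


def sample_lottery_transitions(
    config: LotteryConfig,
    n_transitions: int,
    seed=None,
    rng=None,
    band: tuple[int, int] | None = None,
    n_chains: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (n, Δn) transition pairs of the discrete lottery over one τ.

    Runs ``n_chains`` independent chains homed at log-spaced abundances
    inside ``band``; a chain that leaves the band (absorption at 0 or
    overflow past the upper edge) is re-seeded at its home abundance.
    Every recorded pair is a genuine one-step draw of the kernel at its
    origin abundance — the re-seeding teleports are never recorded — so
    the band only shapes how visits are distributed over abundance.
    """
    rng = _as_rng(seed, rng)
    if band is None:
        band = default_band(config.N, max(50, config.N // 200))
    homes = _band_homes(band, n_chains)
    n = homes.copy()
    tp = min(config.env.tau, 1.0)
    steps = int(np.ceil(n_transitions / n_chains))
    orig = np.empty(steps * n_chains, dtype=np.int64)
    dest = np.empty(steps * n_chains, dtype=np.int64)
    for i in range(steps):
        s = config.s0 + config.env.sigma * config.env.sample(rng, n_chains)
        n_new = _discrete_step(n, s, config.N, tp, rng)
        orig[i * n_chains : (i + 1) * n_chains] = n
        dest[i * n_chains : (i + 1) * n_chains] = n_new
        out = (n_new == 0) | (n_new > band[1])
        n = np.where(out, homes, n_new)
    return orig[:n_transitions], (dest - orig)[:n_transitions]


# ---------------------------------------------------------------------------
# Moran (continuous-time) lottery
# ---------------------------------------------------------------------------

def _moran_rates(n, s, N):
    """Per-event probabilities of n -> n±1 under the current environment."""
    p = _lottery_p(n, s, N)
    frac = n / N
    up = p * (1.0 - frac)
    down = frac * (1.0 - p)
    return up, down


def _advance_dwell(N, n, s, n_events, rng):
    """Advance chains by ``n_events`` elementary Moran events in place.

    Uses geometric waiting times to the next abundance-changing event
    (most events replace a resident by a resident and change nothing),
    which is exact in distribution and avoids simulating every event.
    """
    rem = np.full(n.shape, n_events, dtype=np.int64)
    idx = np.flatnonzero(np.ones_like(n, dtype=bool))
    while idx.size:
        up, down = _moran_rates(n[idx], s[idx], N)
        q = up + down
        frozen = q <= 0.0  # n == 0 or n == N: nothing can happen
        skip = np.ones(idx.size, dtype=np.int64)
        live = ~frozen
        skip[live] = rng.geometric(q[live])
        move = live & (skip <= rem[idx])
        mv = idx[move]
        if mv.size:
            goes_up = rng.random(mv.size) * q[move] < up[move]
            n[mv] += np.where(goes_up, 1, -1)
            rem[mv] -= skip[move]
        idx = mv[rem[mv] > 0]
    return n


def _moran_events_per_dwell(config: LotteryConfig) -> int:
    return max(1, int(math.ceil(config.env.tau * config.N)))


def simulate_lottery_moran(
    config: LotteryConfig,
    n0: int,
    horizon: float,
    record_interval: float | None = None,
    seed=None,
    rng=None,
) -> AbundanceSeries:
    """Simulate one Moran-lottery trajectory, recorded every dwell time.

    Elementary events advance time by 1/N generations; the environment is
    redrawn every ⌈τN⌉ events. ``record_interval`` must be a multiple of
    the dwell time (default: one dwell time).
    """
    rng = _as_rng(seed, rng)
    if not 0 <= n0 <= config.N:
        raise ValueError("n0 must lie in [0, N]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    tau = config.env.tau
    record_interval = tau if record_interval is None else record_interval
    k = record_interval / tau
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("record_interval must be a positive multiple of tau")
    k = int(round(k))
    E = _moran_events_per_dwell(config)
    dwell_dt = E / config.N  # actual time per dwell after rounding up
    n_dwells = int(round(horizon / tau))
    if n_dwells < k:
        raise ValueError("horizon shorter than one record interval")
    n = np.array([n0], dtype=np.int64)
    records = [n0]
    for dwell in range(1, n_dwells + 1):
        s = config.s0 + config.env.sigma * config.env.sample(rng, 1)
        _advance_dwell(config.N, n, s, E, rng)
        if dwell % k == 0:
            records.append(int(n[0]))
    times = np.arange(len(records)) * (k * dwell_dt)
    return AbundanceSeries(times=times, counts=np.array(records, dtype=np.int64))


def sample_moran_transitions(
    config: LotteryConfig,
    n_transitions: int,
    seed=None,
    rng=None,
    band: tuple[int, int] | None = None,
    n_chains: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (n, Δn) pairs of the Moran lottery over one dwell time each.

    Same banded-chain scheme as :func:`sample_lottery_transitions`.
    """
    rng = _as_rng(seed, rng)
    if band is None:
        band = default_band(config.N, max(50, config.N // 200))
    homes = _band_homes(band, n_chains)
    n = homes.copy()
    E = _moran_events_per_dwell(config)
    steps = int(np.ceil(n_transitions / n_chains))
    orig = np.empty(steps * n_chains, dtype=np.int64)
    dest = np.empty(steps * n_chains, dtype=np.int64)
    for i in range(steps):
        s = config.s0 + config.env.sigma * config.env.sample(rng, n_chains)
        start = n.copy()
        _advance_dwell(config.N, n, s, E, rng)
        orig[i * n_chains : (i + 1) * n_chains] = start
        dest[i * n_chains : (i + 1) * n_chains] = n
        out = (n == 0) | (n > band[1])
        n = np.where(out, homes, n)
    return orig[:n_transitions], (dest - orig)[:n_transitions]


# ---------------------------------------------------------------------------
# Exact one-step moments and direct one-step sampling (discrete lottery)
# ---------------------------------------------------------------------------

def lottery_step_moments(config: LotteryConfig, n) -> tuple[np.ndarray, np.ndarray]:
    """Exact E[Δn] and Var[Δn] of one discrete-lottery step at abundance n.

    Derived from the sampling scheme: given environment state s, the
    invader death count is Bin(n, τ'), the resident death count
    Bin(N−n, τ'), and each vacancy is refilled by an invader with
    probability p = n e^s/(n e^s + N − n). Conditional moments:

        E[Δn | s]   = τ'(N p − n)
        Var[Δn | s] = N τ' p (1 − τ' p) + n τ'(1 − τ') − 2 p n τ'(1 − τ')

    (the covariance term comes from recruits and invader deaths sharing
    the total vacancy count). The environment is then averaged over its
    discrete states, adding the variance of the conditional mean.
    """
    n = np.asarray(n, dtype=float)
    N = config.N
    tp = min(config.env.tau, 1.0)
    mean = np.zeros_like(n)
    second = np.zeros_like(n)  # E[Var|s] + E[(E[Δn|s])²]
    for eta, w in config.env.discrete_states():
        s = config.s0 + config.env.sigma * eta
        p = _lottery_p(n, s, N)
        m_s = tp * (N * p - n)
        v_s = N * tp * p * (1 - tp * p) + n * tp * (1 - tp) - 2 * p * n * tp * (1 - tp)
        mean += w * m_s
        second += w * (v_s + m_s * m_s)
    return mean, second - mean * mean


def lottery_step_sample(
    config: LotteryConfig, n: int, size: int, rng=None, seed=None
) -> np.ndarray:
    """Draw ``size`` independent one-step destinations from abundance n."""
    rng = _as_rng(seed, rng)
    tp = min(config.env.tau, 1.0)
    s = config.s0 + config.env.sigma * config.env.sample(rng, size)
    d_inv = rng.binomial(n, tp, size=size)
    d_res = rng.binomial(config.N - n, tp, size=size)
    rec = rng.binomial(d_inv + d_res, _lottery_p(n, s, config.N))
    return n - d_inv + rec


# ---------------------------------------------------------------------------
# Leslie–Gower tree/sapling model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeslieGowerConfig:
    """Two-species Leslie–Gower forest model.

    N adult sites; adults survive each year with probability d; saplings
    survive with probability f; each species recruits
    Poisson(adults × rate_year) new saplings per year from its
    recruitment-rate series (cycled when shorter than the horizon); vacant
    adult sites are filled by a without-replacement lottery among the
    sapling pools.
    """

    N: int
    d: float
    f: float
    recruitment: np.ndarray = field(repr=False)  # shape (years, 2), rates > 0

    def __post_init__(self) -> None:
        rec = np.asarray(self.recruitment, dtype=float)
        object.__setattr__(self, "recruitment", rec)
        if self.N < 2:
            raise ValueError("number of adult sites N must be at least 2")
        if not 0 < self.d <= 1:
            raise ValueError("adult survival d must be in (0, 1]")
        if not 0 < self.f < 1:
            raise ValueError("sapling survival f must be in (0, 1)")
        if rec.ndim != 2 or rec.shape[1] != 2 or rec.shape[0] < 1:
            raise ValueError("recruitment must have shape (years, 2)")
        if np.any(rec <= 0):
            raise ValueError("recruitment rates must be positive")


def generate_recruitment_series(
    means,
    log_variance: float,
    correlation: float,
    years: int,
    seed=None,
    rng=None,
) -> np.ndarray:
    """Synthetic lognormal yearly recruitment rates for two species.

    Stand-in for empirical per-species recruitment series (such as the
    Barro Colorado *Spondias* estimates, which are not reproduced here):
    log-rates are bivariate normal with variance ``log_variance`` and
    cross-correlation ``correlation``; the arithmetic means match
    ``means`` exactly in expectation.
    """
    rng = _as_rng(seed, rng)
    means = np.asarray(means, dtype=float)
    if means.shape != (2,) or np.any(means <= 0):
        raise ValueError("means must be two positive values")
    if log_variance < 0:
        raise ValueError("log_variance must be nonnegative")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if years < 1:
        raise ValueError("years must be positive")
    mu = np.log(means) - log_variance / 2.0
    a = math.sqrt(log_variance)
    u = rng.standard_normal(years)
    v = rng.standard_normal(years)
    z1 = a * u
    z2 = a * (correlation * u + math.sqrt(1.0 - correlation**2) * v)
    return np.exp(np.column_stack([mu[0] + z1, mu[1] + z2]))


def _lg_year(a1, S1, S2, rates, config, rng):
    """One Leslie–Gower year, vectorised over replicates.

    Returns updated (a1, S1, S2). Recruitment uses start-of-year adults.
    If the sapling pools cannot fill every vacancy (rare, only at extreme
    parameters) the leftover sites are filled in proportion to surviving
    adults so that the N adult sites stay conserved.
    """
    N = config.N
    a2 = N - a1
    S1_new = rng.binomial(S1, config.f) + rng.poisson(a1 * rates[..., 0])
    S2_new = rng.binomial(S2, config.f) + rng.poisson(a2 * rates[..., 1])
    surv1 = rng.binomial(a1, config.d)
    surv2 = rng.binomial(a2, config.d)
    vac = N - surv1 - surv2
    pool = S1_new + S2_new
    take = np.minimum(vac, pool)
    win1 = np.where(take > 0, rng.hypergeometric(S1_new, S2_new, np.maximum(take, 1)), 0)
    win2 = take - win1
    leftover = vac - take
    surv_tot = surv1 + surv2
    frac1 = np.where(surv_tot > 0, surv1 / np.maximum(surv_tot, 1), 0.5)
    fill1 = np.where(leftover > 0, rng.binomial(np.maximum(leftover, 0), frac1), 0)
    a1 = surv1 + win1 + fill1
    return a1, S1_new - win1, S2_new - win2


def _lg_initial_saplings(config: LeslieGowerConfig, a1, rng):
    """Quasi-stationary sapling pools: recruits/(1 − f) per species."""
    rbar = config.recruitment.mean(axis=0)
    a2 = config.N - a1
    S1 = rng.poisson(a1 * rbar[0] / (1.0 - config.f))
    S2 = rng.poisson(a2 * rbar[1] / (1.0 - config.f))
    return S1, S2


def simulate_leslie_gower(
    config: LeslieGowerConfig,
    n0: int,
    horizon: int,
    record_interval: int = 1,
    seed=None,
    rng=None,
    phase: int | None = None,
) -> AbundanceSeries:
    """Simulate one Leslie–Gower trajectory of invader adult counts.

    ``horizon`` is in years; the recruitment series is cycled, starting
    at a random phase unless ``phase`` is given.
    """
    rng = _as_rng(seed, rng)
    if not 0 <= n0 <= config.N:
        raise ValueError("n0 must lie in [0, N]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if record_interval < 1 or int(record_interval) != record_interval:
        raise ValueError("record_interval must be a positive integer number of years")
    record_interval = int(record_interval)
    Y = config.recruitment.shape[0]
    phase = int(rng.integers(0, Y)) if phase is None else phase % Y
    a1 = np.array([n0], dtype=np.int64)
    S1, S2 = _lg_initial_saplings(config, a1, rng)
    records = [n0]
    for year in range(1, horizon + 1):
        rates = config.recruitment[(year - 1 + phase) % Y]
        a1, S1, S2 = _lg_year(a1, S1, S2, rates, config, rng)
        if year % record_interval == 0:
            records.append(int(a1[0]))
    times = np.arange(len(records)) * float(record_interval)
    return AbundanceSeries(times=times, counts=np.array(records, dtype=np.int64))
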