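"""Monte-Carlo estimation of the invasion probability Π(n0 → nf).

Each replicate starts the invader at n0 and runs until absorption at 0
or first passage at/above nf. Replicates that exhaust the elementary
event cap are counted and reported as censored, never silently dropped
(they still appear in the denominator, as failures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .simulate import (
    LeslieGowerConfig,
    LotteryConfig,
    _advance_dwell,
    _discrete_step,
    _lg_initial_saplings,
    _lg_year,
    _moran_events_per_dwell,
)

__all__ = ["InvasionEstimate", "estimate_invasion_mc"]


@dataclass(frozen=True)
class InvasionEstimate:
    """Monte-Carlo invasion probability with a Wilson 95% interval."""

    probability: float
    replicates: int
    successes: int
    ci: tuple[float, float]
    censored: int = 0
    method: str = "wilson"

    @property
    def standard_error(self) -> float:
        p = self.probability
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.replicates)


def _wilson_ci(successes: int, replicates: int) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, replicates, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _discrete_lottery_fp(config, n0, nf, size, rng, max_steps):
    tp = min(config.env.tau, 1.0)
    n = np.full(size, n0, dtype=np.int64)
    success = np.zeros(size, dtype=bool)
    censored = np.zeros(size, dtype=bool)
    active = np.flatnonzero(n < nf)
    success[n >= nf] = True
    for _ in range(max_steps):
        if not active.size:
            break
        s = config.s0 + config.env.sigma * config.env.sample(rng, active.size)
        n[active] = _discrete_step(n[active], s, config.N, tp, rng)
        na = n[active]
        won = na >= nf
        dead = na == 0
        success[active[won]] = True
        active = active[~(won | dead)]
    censored[active] = True
    return success, censored


def _moran_fp(config, n0, nf, size, rng, max_events):
    N = config.N
    E = _moran_events_per_dwell(config)
    max_dwells = max(1, int(math.ceil(max_events / E)))
    n = np.full(size, n0, dtype=np.int64)
    success = np.zeros(size, dtype=bool)
    censored = np.zeros(size, dtype=bool)
    success[n >= nf] = True
    active = np.flatnonzero(~success)
    for _ in range(max_dwells):
        if not active.size:
            break
        s = config.s0 + config.env.sigma * config.env.sample(rng, active.size)
        sub = n[active]
        _advance_dwell(N, sub, s, E, rng)
        n[active] = sub
        won = sub >= nf
        dead = sub == 0
        success[active[won]] = True
        active = active[~(won | dead)]
    censored[active] = True
    return success, censored


def _leslie_gower_fp(config, n0, nf, size, rng, max_years):
    Y = config.recruitment.shape[0]
    phase = rng.integers(0, Y, size=size)
    a1 = np.full(size, n0, dtype=np.int64)
    S1, S2 = _lg_initial_saplings(config, a1, rng)
    success = np.zeros(size, dtype=bool)
    censored = np.zeros(size, dtype=bool)
    success[a1 >= nf] = True
    active = np.flatnonzero(~success)
    for year in range(max_years):
        if not active.size:
            break
        rates = config.recruitment[(year + phase[active]) % Y]
        a_new, s1_new, s2_new = _lg_year(a1[active], S1[active], S2[active], rates, config, rng)
        a1[active], S1[active], S2[active] = a_new, s1_new, s2_new
        won = a_new >= nf
        dead = a_new == 0
        success[active[won]] = True
        active = active[~(won | dead)]
    censored[active] = True
    return success, censored


def estimate_invasion_mc(
    model,
    n0: int,
    nf: int,
    replicates: int,
    seed=None,
    rng=None,
    event_cap: float | None = None,
) -> InvasionEstimate:
    """Estimate Π(n0 → nf) by independent first-passage replicates.

    ``model`` is a :class:`LotteryConfig` (discrete or moran mode), a
    :class:`LeslieGowerConfig`, or a callable
    ``model(rng, n0, nf, size) -> (success_bool_array, censored_bool_array)``
    for custom dynamics. ``event_cap`` bounds the elementary events per
    replicate (default 10³·N·nf); replicates still unabsorbed at the cap
    are reported as censored.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    if not 0 < n0 <= nf:
        raise ValueError("need 0 < n0 <= nf")
    rng = np.random.default_rng(seed) if rng is None else rng

    if n0 == nf:
        return InvasionEstimate(1.0, replicates, replicates, (1.0, 1.0))

    if isinstance(model, LotteryConfig):
        if nf > model.N:
            raise ValueError("nf cannot exceed the community size N")
        cap = 1e3 * model.N * nf if event_cap is None else event_cap
        if model.mode == "moran":
            success, censored = _moran_fp(model, n0, nf, replicates, rng, cap)
        else:
            tp = min(model.env.tau, 1.0)
            max_steps = max(1, int(math.ceil(cap / (model.N * tp))))
            success, censored = _discrete_lottery_fp(
                model, n0, nf, replicates, rng, max_steps
            )
    elif isinstance(model, LeslieGowerConfig):
        if nf > model.N:
            raise ValueError("nf cannot exceed the number of adult sites N")
        cap = 1e3 * nf if event_cap is None else event_cap
        success, censored = _leslie_gower_fp(
            model, n0, nf, replicates, rng, int(math.ceil(cap))
        )
    elif callable(model):
        success, censored = model(rng, n0, nf, replicates)
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")

    k = int(np.count_nonzero(success))
    return InvasionEstimate(
        probability=k / replicates,
        replicates=replicates,
        successes=k,
        ci=_wilson_ci(k, replicates),
        censored=int(np.count_nonzero(censored)),
    )
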