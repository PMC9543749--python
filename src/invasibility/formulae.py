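"""Closed-form invasion probabilities.

Π(n → nf) is the chance that a population of initial abundance n grows to
a target abundance nf before going extinct, in a community whose dynamics
combine demographic stochasticity (variance ∝ n per dwell time) and
environmental stochasticity (variance ∝ n²).

Two approximations of the backward Kolmogorov problem are provided:

* :func:`pi_diffusion` — the diffusion approximation, valid for weak
  selection and weak fluctuations, parameterised in n-space,

      Π_DA = [1 − (1 + nℛ)^Q] / [1 − (1 + nf ℛ)^Q],
      ℛ = Ve_n/Vd_n,  Q = 1 − 2ℰ/Ve_n.

* :func:`pi_wkb` — a large-deviations (WKB) formula built on the
  two-destination reduction of the log-abundance jump process,
  parameterised in z-space,

      Π_WKB = [1 − (1 + nR)^q̄] / [1 − (1 + nf R)^q̄],

  with q̄ and R from :func:`wkb_outer`. It remains accurate for strong
  fluctuations and strong selection.

Both converge to the classical fixed-environment (Haldane/Kimura) result
:func:`pi_fixed_env` as the environmental variance vanishes, and to the
neutral ratio n/nf when the mean growth vanishes.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

from .params import InvasionQuery, NSpaceParams, WKBIntermediates, ZSpaceParams

__all__ = [
    "pi_diffusion",
    "pi_wkb",
    "pi_fixed_env",
    "pi_quenched",
    "wkb_outer",
    "q_interpolated",
    "extinction_threshold",
    "natural_target_abundance",
]

# Below this ratio of environmental to squared mean growth, the formulae
# switch to their fixed-environment branch. The WKB expression approaches
# the Kimura form only logarithmically in Ve/E0² (its exponent scale is
# q̄ ~ ln(E0²/Ve)/β), so the crossover must act well before α would
# under/overflow for the branches to agree to high relative accuracy.
_VE_CROSSOVER = 1e-5

# Floating-point dust tolerance: results outside [0,1] by more than this
# indicate misuse rather than rounding and raise.
_DUST = 1e-12


def _finish(p: float) -> float:
    """Clip floating-point dust around [0,1]; larger violations raise."""
    if -_DUST <= p <= 0.0:
        return 0.0
    if 1.0 <= p <= 1.0 + _DUST:
        return 1.0
    if p < 0.0 or p > 1.0:
        raise ArithmeticError(f"probability {p} outside [0,1] beyond rounding dust")
    return p


def _expm1_ratio(x: float, y: float) -> float:
    """expm1(x)/expm1(y) for same-signed x, y with |x| <= |y|, overflow-safe."""
    if y > 500.0:  # expm1 would overflow around 709
        # expm1(x)/expm1(y) = e^{x-y}·(1−e^{−x})/(1−e^{−y})
        return math.exp(x - y) * (-math.expm1(-x)) / (-math.expm1(-min(y, 700.0)))
    return math.expm1(x) / math.expm1(y)


def pi_fixed_env(query: InvasionQuery, growth: float, Vd: float) -> float:
    """Fixed-environment (Haldane/Kimura) invasion probability.

    Π = (1 − e^{−2·growth·n/Vd}) / (1 − e^{−2·growth·nf/Vd}); the neutral
    growth = 0 branch is the gambler's-ruin ratio n/nf.

    Parameters are per dwell time: ``growth`` the mean relative growth of
    the abundance and ``Vd`` the per-individual demographic variance.
    """
    if not Vd > 0:
        raise ValueError("fixed-environment formula requires Vd > 0")
    n, nf = query.n, query.nf
    if n == 0.0:
        return 0.0
    if n == nf:
        return 1.0
    if growth == 0.0:
        return _finish(n / nf)
    a = -2.0 * growth / Vd
    return _finish(_expm1_ratio(a * n, a * nf))


def pi_quenched(
    query: InvasionQuery,
    env_states: Sequence[tuple[float, float]],
    Vd: float,
) -> float:
    """Quenched-regime invasibility: weighted average of fixed environments.

    When the environmental dwell time exceeds the typical invasion time the
    environment is effectively frozen during each invasion attempt, and the
    overall invasibility is the expectation of the fixed-environment result
    over the environmental states, Σᵢ wᵢ·Π_fixed(growthᵢ).

    ``env_states`` is a sequence of (growth, weight) pairs with nonnegative
    weights summing to 1.
    """
    if len(env_states) == 0:
        raise ValueError("env_states must be nonempty")
    weights = [w for _, w in env_states]
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return _finish(
        sum(w * pi_fixed_env(query, g, Vd) for g, w in env_states)
    )


def pi_diffusion(query: InvasionQuery, p: NSpaceParams) -> float:
    """Diffusion-approximation invasion probability (n-space parameters).

    Limiting branches are taken analytically: ℰ=0 collapses to n/nf
    exactly; Ve→0 yields the fixed-environment formula; Q=0 yields the
    logarithmic ratio; Vd=0 (no demographic noise, only meaningful for
    n ≥ 1) yields the pure geometric-diffusion limit.
    """
    eps, Vd, Ve = p.eps, p.Vd_n, p.Ve_n
    if Vd == 0.0 and Ve == 0.0:
        raise ValueError("Vd_n + Ve_n must be positive")
    n, nf = query.n, query.nf
    if n == 0.0:
        return 0.0
    if n == nf:
        return 1.0

    if Vd == 0.0:
        if n < 1.0:
            raise ValueError(
                "Vd_n = 0 with n < 1 is rejected: without demographic noise "
                "there is no absorption at zero abundance"
            )
        # ℛ → ∞ limit of the general expression.
        Q = 1.0 - 2.0 * eps / Ve
        if Q <= 0.0:
            return 1.0
        return _finish((n / nf) ** Q)

    if Ve == 0.0 or Ve < _VE_CROSSOVER * eps * eps:
        return pi_fixed_env(query, eps, Vd)
    if eps == 0.0:
        return _finish(n / nf)

    ratio = Ve / Vd
    Q = 1.0 - 2.0 * eps / Ve
    if Q == 0.0:
        return _finish(math.log1p(n * ratio) / math.log1p(nf * ratio))
    return _finish(_expm1_ratio(Q * math.log1p(n * ratio), Q * math.log1p(nf * ratio)))


def wkb_outer(p: ZSpaceParams) -> WKBIntermediates:
    """Two-destination reduction in the outer (large-n) regime.

    The jump distribution of Δz over one dwell time is replaced by jumps
    of size ±β with forward probability α, preserving the first two
    moments: β = √E[Δz²] = √(Ve_z + E0²), α = ½ + E0/(2β). The nontrivial
    WKB exponent solving 1 = 2α·sinh(qβ) + e^{−qβ} is

        q̄ = ln((1−α)/α)/β,

    and the inner/outer interpolation scale is R = −2E0/(q̄·Vd_z).

    E0 = 0 returns the analytic q̄→0 limit (q̄=0, R = Ve_z/Vd_z). A
    numerically vanishing Ve_z returns ``degenerate=True``; the invasion
    formula must then use its fixed-environment branch.
    """
    E0, Vd, Ve = p.E0, p.Vd_z, p.Ve_z
    if Vd == 0.0:
        raise ValueError("Vd_z = 0 leaves the interpolation scale R undefined")
    if Ve == 0.0 or Ve < _VE_CROSSOVER * E0 * E0:
        if E0 == 0.0:
            raise ValueError("E0 = 0 with Ve_z = 0 has no stochastic dynamics")
        return WKBIntermediates(
            beta=abs(E0),
            alpha=1.0 if E0 > 0 else 0.0,
            q_bar=-math.inf if E0 > 0 else math.inf,
            R=0.0,
            degenerate=True,
        )
    if E0 == 0.0:
        return WKBIntermediates(
            beta=math.sqrt(Ve), alpha=0.5, q_bar=0.0, R=Ve / Vd
        )

    beta = math.sqrt(Ve + E0 * E0)
    alpha = 0.5 + E0 / (2.0 * beta)
    # (1−α)/α = Ve/(β+E0)² = (β−E0)²/Ve; pick the cancellation-free form.
    if E0 > 0:
        log_odds = math.log(Ve) - 2.0 * math.log(beta + E0)
    else:
        log_odds = 2.0 * math.log(beta - E0) - math.log(Ve)
    q_bar = log_odds / beta
    if q_bar == 0.0:  # |E0| so small that the log odds underflow
        return WKBIntermediates(
            beta=beta, alpha=alpha, q_bar=-2.0 * E0 / Ve, R=Ve / Vd
        )
    R = -2.0 * E0 / (q_bar * Vd)
    return WKBIntermediates(beta=beta, alpha=alpha, q_bar=q_bar, R=R)


def q_interpolated(n: float, E0: float, Vd_z: float, q_bar: float) -> float:
    """Interpolated WKB exponent q(n) = −2E0·n/(Vd_z − 2E0·n/q̄).

    Tends to the inner exponent −2E0·n/Vd_z as n→0 and to the outer
    constant q̄ as n→∞.
    """
    return -2.0 * E0 * n / (Vd_z - 2.0 * E0 * n / q_bar)


def pi_wkb(query: InvasionQuery, p: ZSpaceParams) -> float:
    """WKB (large-deviations) invasion probability (z-space parameters).

    Π = [1 − (1 + nR)^q̄] / [1 − (1 + nf R)^q̄] with q̄, R from
    :func:`wkb_outer`. Analytic branches: E0=0 gives the logarithmic
    q̄→0 limit ln(1+n·Ve_z/Vd_z)/ln(1+nf·Ve_z/Vd_z); a numerically
    vanishing Ve_z gives the fixed-environment formula with (E0, Vd_z);
    Vd_z=0 (only meaningful for n ≥ 1) gives the R→∞ limit.
    """
    E0, Vd, Ve = p.E0, p.Vd_z, p.Ve_z
    if Vd == 0.0 and Ve == 0.0:
        raise ValueError("Vd_z + Ve_z must be positive")
    n, nf = query.n, query.nf
    if n == 0.0:
        return 0.0
    if n == nf:
        return 1.0

    if Vd == 0.0:
        if n < 1.0:
            raise ValueError(
                "Vd_z = 0 with n < 1 is rejected: without demographic noise "
                "there is no absorption at zero abundance"
            )
        if Ve < _VE_CROSSOVER * E0 * E0:
            return 1.0 if E0 >= 0 else 0.0
        w = _outer_exponent_only(E0, Ve)
        if w <= 0.0:
            return 1.0
        return _finish((n / nf) ** w)

    if Ve == 0.0 or Ve < _VE_CROSSOVER * E0 * E0:
        return pi_fixed_env(query, E0, Vd)
    if E0 == 0.0:
        ratio = Ve / Vd
        return _finish(math.log1p(n * ratio) / math.log1p(nf * ratio))

    w = wkb_outer(p)
    x = w.q_bar * math.log1p(n * w.R)
    y = w.q_bar * math.log1p(nf * w.R)
    return _finish(_expm1_ratio(x, y))


def _outer_exponent_only(E0: float, Ve: float) -> float:
    """q̄ alone (no R), defined for any Vd; used by the Vd_z=0 limit."""
    beta = math.sqrt(Ve + E0 * E0)
    if E0 > 0:
        return (math.log(Ve) - 2.0 * math.log(beta + E0)) / beta
    if E0 < 0:
        return (2.0 * math.log(beta - E0) - math.log(Ve)) / beta
    return 0.0


def extinction_threshold(p: NSpaceParams) -> float:
    """Abundance nth = Vd_n/Ve_n at which demographic and environmental
    stochasticity are equally strong.

    Infinite-population models that neglect demographic noise become
    quantitatively usable once an absorbing boundary is placed at nth.
    """
    if p.Ve_n == 0.0:
        raise ValueError("no finite extinction threshold when Ve_n = 0")
    return p.Vd_n / p.Ve_n


def natural_target_abundance(w: WKBIntermediates) -> float:
    """Natural establishment target nf ~ e^{1/|q̄|}/R.

    Defined only for positive mean growth (q̄ < 0): the abundance above
    which the residual extinction risk is small, so "reaching nf" is a
    meaningful proxy for establishment.
    """
    if w.degenerate:
        raise ValueError("undefined for degenerate (Ve_z = 0) intermediates")
    if not w.q_bar < 0:
        raise ValueError("only defined for positive mean growth (q_bar < 0)")
    if not w.R > 0:
        raise ValueError("requires a positive interpolation scale R")
    return math.exp(-1.0 / w.q_bar) / w.R
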