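"""Exact backward-Kolmogorov solution on small state spaces.

The invasion probability obeys Π_n = Σ_Δn W(n→n+Δn) Π_{n+Δn} with
Π_0 = 0 and Π = 1 for every state at or above the target nf. On a small
state space this linear system can be solved exactly, providing an
independent oracle for both closed-form formulae and for the Monte-Carlo
estimator.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy import stats

from .simulate import LotteryConfig, _lottery_p

__all__ = ["solve_kolmogorov_exact", "lottery_transition_matrix"]


def solve_kolmogorov_exact(W: np.ndarray, nf: int) -> np.ndarray:
    """Solve Π = WΠ with Π_0 = 0 and all states ≥ nf absorbing successes.

    ``W`` is a row-stochastic transition matrix on states {0, …, nmax}
    with state 0 absorbing and nmax ≥ nf. States at or above nf are
    merged into a single success state. Returns the probability vector
    (Π_0, …, Π_{nf}) with Π_{nf} = 1 standing for the merged state.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    m = W.shape[0]
    if not 1 <= nf < m:
        raise ValueError("need 1 <= nf <= nmax")
    if np.any(np.abs(W.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows of W must sum to 1")
    if abs(W[0, 0] - 1.0) > 1e-12:
        raise ValueError("state 0 must be absorbing")
    interior = np.arange(1, nf)
    trapped = np.abs(np.diag(W)[interior] - 1.0) <= 1e-12
    if np.any(trapped):
        raise ValueError(
            f"interior state {int(interior[trapped][0])} is absorbing: no path "
            "to either boundary"
        )
    Q = W[np.ix_(interior, interior)]
    b = W[interior, nf:].sum(axis=1)
    try:
        pi_interior = scipy.linalg.solve(np.eye(len(interior)) - Q, b)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular system: no path to either boundary") from exc
    if not np.all(np.isfinite(pi_interior)):
        raise ValueError("singular system: no path to either boundary")
    return np.concatenate([[0.0], pi_interior, [1.0]])


def lottery_transition_matrix(config: LotteryConfig, nmax: int) -> np.ndarray:
    """Exact one-dwell-time kernel of the discrete lottery on {0, …, nmax}.

    For each abundance n and environment state, the invader death count
    d is Bin(n, τ'), the resident death count Bin(N−n, τ'), and recruits
    are Bin(d + d_res, p); the distribution of Δn = rec − d is obtained
    by convolving the recruit distribution with the death distribution
    over the total death count, then averaged over the (dichotomous)
    environment. Probability mass beyond nmax is lumped into nmax, so
    the matrix is row-stochastic; rows at and above a target nf ≤ nmax
    are treated as absorbing by :func:`solve_kolmogorov_exact`.
    """
    if config.mode != "discrete":
        raise ValueError("exact kernel is implemented for the discrete lottery")
    N = config.N
    if not 1 <= nmax <= N:
        raise ValueError("need 1 <= nmax <= N")
    tp = min(config.env.tau, 1.0)
    states = config.env.discrete_states()
    W = np.zeros((nmax + 1, nmax + 1))
    W[0, 0] = 1.0
    d_all = np.arange(N + 1)
    pmf_D = stats.binom.pmf(d_all, N, tp)  # total deaths
    keep = pmf_D > 1e-15
    for n in range(1, nmax + 1):
        row = np.zeros(N + n + 1)  # destination n' = n + rec − d in [0, n+D]
        for eta, w_env in states:
            s = config.s0 + config.env.sigma * eta
            p = float(_lottery_p(np.array(float(n)), s, N))
            for D in d_all[keep]:
                kmax = min(n, D)
                pmf_d = stats.hypergeom.pmf(np.arange(kmax + 1), N, n, D)
                pmf_rec = stats.binom.pmf(np.arange(D + 1), D, p)
                # distribution of rec − d, shifted so index 0 is rec−d = −kmax
                joint = np.convolve(pmf_rec, pmf_d[::-1])
                lo = n - kmax
                row[lo : lo + joint.size] += w_env * pmf_D[D] * joint
        W[n, :nmax] = row[:nmax]
        W[n, nmax] = row[nmax:].sum()
    return W
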