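"""Inferring invasion-formula parameters from abundance time series.

The series must be sampled at the environmental dwell time τ. Each pair
of adjacent samples yields one transition (n, Δn); transitions are
binned logarithmically in the origin abundance, and the per-bin mean and
variance of Δn (n-space) or Δz = Δln n (z-space) are regressed:

* n-space: E[Δn] = ℰ·n (slope through the origin gives ℰ);
  Var[Δn]/n = Vd + Ve·n (intercept Vd, slope Ve).
* z-space: E[Δz] = E0 − Vd/(2n) (intercept over 1/n gives E0);
  Var[Δz] = Ve + Vd/n (intercept Ve, slope Vd).

Transitions into the zero-abundance state cannot contribute a Δz (the
log diverges) and are filtered, which biases the small-n mean of Δz
upward; the E0 fit therefore excludes bins below a cutoff n_min, and the
variance-fit estimate of Vd is reported as primary.

All fits are weighted least squares with bin occupancies as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .params import NSpaceParams, ZSpaceParams
from .series import AbundanceSeries

__all__ = [
    "transitions",
    "BinningConfig",
    "BinnedMoments",
    "bin_moments",
    "infer_nspace",
    "infer_zspace",
    "estimate_dwell_time",
    "invasion_growth_rate",
    "InferenceReport",
]


def transitions(series) -> np.ndarray:
    """Extract (n, Δn) pairs from one series or an iterable of series.

    One pair per adjacent sample; pairs originating at n = 0 are dropped
    (nothing can be inferred from the extinction state). Returns an
    array of shape (T, 2); raises if no usable pair remains.
    """
    if isinstance(series, AbundanceSeries):
        series = [series]
    pairs = []
    for s in series:
        n = np.asarray(s.counts, dtype=np.int64)
        origin, dest = n[:-1], n[1:]
        keep = origin > 0
        pairs.append(np.column_stack([origin[keep], (dest - origin)[keep]]))
    if not pairs:
        raise ValueError("no series provided")
    return np.concatenate(pairs).reshape(-1, 2)


def _as_transitions(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept an AbundanceSeries, a list of them, an (origin, delta) pair
    of arrays, or a (T, 2) array; return origin and delta arrays."""
    if isinstance(data, AbundanceSeries):
        arr = transitions(data)
    elif isinstance(data, tuple) and len(data) == 2:
        origin = np.asarray(data[0], dtype=float)
        delta = np.asarray(data[1], dtype=float)
        keep = origin > 0
        return origin[keep], delta[keep]
    elif isinstance(data, np.ndarray):
        arr = np.asarray(data, dtype=float)
        keep = arr[:, 0] > 0
        arr = arr[keep]
    else:
        arr = transitions(data)
    return arr[:, 0].astype(float), arr[:, 1].astype(float)


@dataclass(frozen=True)
class BinningConfig:
    """Logarithmic binning of the origin abundance.

    bins_per_decade bins per factor of 10 in n; bins holding fewer than
    min_count transitions are discarded. ``n_min`` applies only to the
    z-space mean (E0) fit: "auto" places it at five times the abundance
    where the demographic term Vd/2n equals |E0| (estimated once and
    refitted once); a number fixes it; 0 disables it. ``var_n_min``
    excludes the smallest abundances from the z-space *variance* fit:
    below it the one-step relative change is no longer small, so the
    discreteness of Δn and the zero-destination filter distort Var[Δz]
    away from Ve + Vd/n.
    """

    bins_per_decade: int = 12
    min_count: int = 50
    n_min: float | str = "auto"
    var_n_min: float = 10.0

    def __post_init__(self) -> None:
        if self.bins_per_decade < 1:
            raise ValueError("bins_per_decade must be positive")
        if self.min_count < 2:
            raise ValueError("min_count must be at least 2")


@dataclass(frozen=True)
class BinnedMoments:
    """Per-bin occupancy and first two moments of the chosen increment."""

    centers: np.ndarray = field(repr=False)  # mean origin abundance per bin
    counts: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    var: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.centers)


def bin_moments(origin, values, config: BinningConfig) -> BinnedMoments:
    """Bin `values` by log-spaced origin abundance; drop sparse bins."""
    origin = np.asarray(origin, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = origin.min(), origin.max()
    span = np.log10(hi / lo) if hi > lo else 0.0
    n_edges = max(2, int(np.ceil(span * config.bins_per_decade)) + 1)
    edges = np.geomspace(lo, hi, n_edges)
    idx = np.clip(np.searchsorted(edges, origin, side="right") - 1, 0, n_edges - 2)
    centers, counts, means, variances = [], [], [], []
    for b in range(n_edges - 1):
        sel = idx == b
        c = int(np.count_nonzero(sel))
        if c < config.min_count:
            continue
        v = values[sel]
        centers.append(origin[sel].mean())
        counts.append(c)
        means.append(v.mean())
        variances.append(v.var(ddof=1))
    return BinnedMoments(
        centers=np.array(centers),
        counts=np.array(counts, dtype=np.int64),
        mean=np.array(means),
        var=np.array(variances),
    )


@dataclass
class InferenceReport:
    """Estimated parameters with the fit diagnostics that produced them."""

    params: NSpaceParams | ZSpaceParams
    bins: BinnedMoments
    diagnostics: dict
    flags: list[str] = field(default_factory=list)
    n_dropped_zero: int = 0


def _wls(y, X, w):
    res = sm.WLS(y, X, weights=w).fit()
    rms = float(np.sqrt(np.average(res.resid**2, weights=w)))
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.where(np.isfinite(res.bse), res.bse, 0.0)  # df_resid may be 0
    return res.params, bse, rms


def infer_nspace(data, config: BinningConfig | None = None) -> InferenceReport:
    """Estimate (ℰ, Vd_n, Ve_n) from transitions by the n-space regressions.

    ``data`` may be an :class:`AbundanceSeries` (sampled at τ), a list of
    them, or precomputed (origin, Δn) transition arrays.
    """
    config = config or BinningConfig()
    origin, delta = _as_transitions(data)
    if origin.size == 0:
        raise ValueError("no usable transitions (all origins are at zero abundance)")
    bins = bin_moments(origin, delta, config)
    if len(bins) < 2:
        raise ValueError("insufficient abundance range: fewer than 2 usable bins")
    flags: list[str] = []

    # E[Δn] = ℰ n: zero-intercept weighted fit.
    (eps,), (eps_se,), mean_rms = _wls(bins.mean, bins.centers[:, None], bins.counts)

    # Var[Δn]/n = Vd + Ve n.
    X = sm.add_constant(bins.centers)
    (vd, ve), (vd_se, ve_se), var_rms = _wls(bins.var / bins.centers, X, bins.counts)
    if vd < 0:
        flags.append("negative demographic variance truncated to 0")
        vd = 0.0
    if ve < 0:
        flags.append("negative environmental variance truncated to 0")
        ve = 0.0

    return InferenceReport(
        params=NSpaceParams(eps=float(eps), Vd_n=float(vd), Ve_n=float(ve)),
        bins=bins,
        diagnostics={
            "mean_fit": {
                "bins_used": len(bins),
                "weighted_rms_residual": mean_rms,
                "se": {"eps": float(eps_se)},
            },
            "variance_fit": {
                "bins_used": len(bins),
                "weighted_rms_residual": var_rms,
                "se": {"Vd_n": float(vd_se), "Ve_n": float(ve_se)},
            },
            "n_transitions": int(len(origin)),
        },
        flags=flags,
    )


def infer_zspace(
    data, config: BinningConfig | None = None, tau: float | None = None
) -> InferenceReport:
    """Estimate (E0, Vd_z, Ve_z) from transitions by the z-space regressions.

    Transitions into n = 0 are filtered (their count is reported): the
    log-increment is undefined there, and the filtering is what biases
    the small-n mean upward and motivates the n_min cutoff of the E0 fit.
    The variance-fit Vd is reported as primary; the mean-fit value is a
    diagnostic (``diagnostics["mean_fit"]["Vd_z"]``).
    """
    config = config or BinningConfig()
    origin, delta = _as_transitions(data)
    if origin.size == 0:
        raise ValueError("no usable transitions (all origins are at zero abundance)")
    if tau is None and isinstance(data, AbundanceSeries):
        tau = data.dt
    dest = origin + delta
    nonzero = dest > 0
    n_dropped = int(np.count_nonzero(~nonzero))
    origin, delta, dest = origin[nonzero], delta[nonzero], dest[nonzero]
    if origin.size == 0:
        raise ValueError("no transitions with nonzero destination")
    dz = np.log(dest / origin)
    bins = bin_moments(origin, dz, config)
    if len(bins) < 2:
        raise ValueError("insufficient abundance range: fewer than 2 usable bins")
    flags: list[str] = []
    inv_n = 1.0 / bins.centers

    # Var[Δz] = Ve + Vd/n — primary source for Vd; fitted only where the
    # log-increment moments are well described by that form.
    var_use = bins.centers >= config.var_n_min
    if np.count_nonzero(var_use) < 2:
        var_use = np.zeros(len(bins), dtype=bool)
        var_use[-2:] = True
    (ve, vd_var), (ve_se, vd_var_se), var_rms = _wls(
        bins.var[var_use], sm.add_constant(inv_n[var_use]), bins.counts[var_use]
    )
    if ve < 0:
        flags.append("negative environmental variance truncated to 0")
        ve = 0.0
    if vd_var < 0:
        flags.append("negative demographic variance truncated to 0")
        vd_var = 0.0

    # E[Δz] = E0 − Vd/(2n), fitted on bins with centers >= n_min.
    def mean_fit(n_min: float):
        use = bins.centers >= n_min
        if np.count_nonzero(use) < 2:
            use = np.zeros(len(bins), dtype=bool)
            use[-2:] = True  # fall back to the two largest-abundance bins
        (e0, slope), (e0_se, _), rms = _wls(
            bins.mean[use], sm.add_constant(inv_n[use]), bins.counts[use]
        )
        return float(e0), float(slope), float(e0_se), rms, int(np.count_nonzero(use))

    if config.n_min == "auto":
        e0_first, _, _, _, _ = mean_fit(0.0)
        if e0_first != 0.0 and vd_var > 0.0:
            n_min = 5.0 * vd_var / (2.0 * abs(e0_first))
            # keep at least the three largest bins in the fit
            n_min = min(n_min, bins.centers[max(len(bins) - 3, 0)])
        else:
            n_min = 0.0
    else:
        n_min = float(config.n_min)
    e0, slope, e0_se, mean_rms, bins_used = mean_fit(n_min)
    vd_mean = -2.0 * slope

    return InferenceReport(
        params=ZSpaceParams(E0=e0, Vd_z=float(vd_var), Ve_z=float(ve), tau=tau),
        bins=bins,
        diagnostics={
            "mean_fit": {
                "bins_used": bins_used,
                "n_min": float(n_min),
                "weighted_rms_residual": mean_rms,
                "Vd_z": float(vd_mean),
                "se": {"E0": float(e0_se)},
            },
            "variance_fit": {
                "bins_used": int(np.count_nonzero(var_use)),
                "var_n_min": float(config.var_n_min),
                "weighted_rms_residual": var_rms,
                "se": {"Vd_z": float(vd_var_se), "Ve_z": float(ve_se)},
            },
            "n_transitions": int(len(origin)),
        },
        flags=flags,
        n_dropped_zero=n_dropped,
    )


def estimate_dwell_time(signal, dt: float = 1.0) -> float:
    """Dwell time τ = 2 × integrated autocorrelation time of a signal.

    The signal may be the environmental state itself or, when that is
    unobserved, the large-n log-abundance increments. The integrated
    autocorrelation time is estimated as (½ + Σ ρ_k)·dt, summing the
    autocorrelation function from lag 1 until its first non-positive
    value. An uncorrelated signal therefore reports τ = dt exactly,
    flagging that the sampling cannot resolve a shorter dwell time.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("signal must be a 1-D array with at least 4 samples")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / len(x)
    if c0 == 0.0:
        raise ValueError("constant signal: autocorrelation undefined")
    acf_sum = 0.0
    for k in range(1, len(x) // 3):
        rho = float(np.dot(x[:-k], x[k:])) / (len(x) * c0)
        if rho <= 0.0:
            break
        acf_sum += rho
    return 2.0 * (0.5 + acf_sum) * dt


def invasion_growth_rate(p: ZSpaceParams) -> float:
    """Classical invasion growth rate Er = E0/τ."""
    if p.tau is None:
        raise ValueError("ZSpaceParams.tau is required to convert E0 to Er")
    return p.E0 / p.tau
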