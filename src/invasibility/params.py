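"""Parameter containers for the invasion-probability formulae.

Two distinct parameterisations are used, and they are *not*
interchangeable:

* **n-space** (:class:`NSpaceParams`): per-dwell-time moments of the raw
  abundance increment, ``E[Δn] = ℰ n`` and ``Var[Δn] = Vd_n n + Ve_n n²``.
  These feed the diffusion-approximation formula.
* **z-space** (:class:`ZSpaceParams`): per-dwell-time moments of the
  log-abundance increment ``Δz = Δln n``, with large-n mean ``E0``,
  environmental variance ``Ve_z`` and demographic coefficient ``Vd_z``
  (``Var[Δz] = Ve_z + Vd_z/n``). These feed the WKB formula.

Although the demographic/environmental coefficients agree to leading
order at large n, they are numerically different quantities; no automatic
conversion is provided on purpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class NSpaceParams:
    """Per-dwell-time moments of Δn: E[Δn]=eps·n, Var[Δn]=Vd_n·n+Ve_n·n²."""

    eps: float
    Vd_n: float
    Ve_n: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.eps, self.Vd_n, self.Ve_n)):
            raise ValueError("n-space parameters must be finite")
        if self.Vd_n < 0 or self.Ve_n < 0:
            raise ValueError("variance coefficients must be nonnegative")


@dataclass(frozen=True)
class ZSpaceParams:
    """Per-dwell-time moments of Δz=Δln n at large n, plus the dwell time.

    ``tau`` (generations) is only used for the conversion to the invasion
    growth rate, Er = E0/tau; it may be left as None when unknown.
    """

    E0: float
    Vd_z: float
    Ve_z: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.E0, self.Vd_z, self.Ve_z)):
            raise ValueError("z-space parameters must be finite")
        if self.Vd_z < 0 or self.Ve_z < 0:
            raise ValueError("variance coefficients must be nonnegative")
        if self.tau is not None and not self.tau > 0:
            raise ValueError("dwell time tau must be positive")


@dataclass(frozen=True)
class WKBIntermediates:
    """Quantities of the two-destination WKB reduction.

    beta
        jump size in z-space, √E[Δz²].
    alpha
        forward-jump probability, ½ + E[Δz]/(2β).
    q_bar
        outer WKB exponent, ln((1−α)/α)/β; sign(q_bar) = −sign(E0).
    R
        interpolation abundance scale, −2 E0/(q_bar·Vd_z); 1/R separates
        the demographically dominated inner regime from the outer one.
    degenerate
        True when Ve_z is (numerically) zero, in which case α∈{0,1},
        q_bar=∓∞ and the fixed-environment branch must be used instead.
    """

    beta: float
    alpha: float
    q_bar: float
    R: float
    degenerate: bool = False


@dataclass(frozen=True)
class InvasionQuery:
    """Initial abundance n and target abundance nf, as continuum reals."""

    n: float
    nf: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.n) and math.isfinite(self.nf)):
            raise ValueError("abundances must be finite")
        if self.n < 0:
            raise ValueError("initial abundance n must be nonnegative")
        if self.nf <= 0:
            raise ValueError("target abundance nf must be positive")
        if self.nf < self.n:
            raise ValueError("target abundance nf must satisfy nf >= n")
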