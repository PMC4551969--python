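"""Linear response of the gene network to acute stress.

A short toxic stress (trauma, radiation, misfolding agents) at age ``t0``
injects a defect increment ``F_s = (dF_p, dF_g)`` into the network state.
Projected on the eigenmodes, the perturbation splits into a fast
component that relaxes at rate ``E = c + delta`` and a slow component
that evolves at the instability rate ``lambda1 ~ Lambda``.  The excess
hazard after the stress is

    dM(t) = Omega1 s1 exp(lambda1 (t - t0)) + Omega2 s2 exp(lambda2 (t - t0))

with mode amplitudes ``s_i = a_i . F_s`` and mode-projected mortality
weights ``Omega_i = Omega . b_i``.  Two observables follow:

* the Mortality Index ``MI_T``, the fraction of stressed animals dying
  within an observation window ``T`` -- dominated by the fast mode for
  realistic stressors;
* the long-term IMR shift: for an unstable network the slow component
  never relaxes, so repeated trauma (``N`` strikes) raises the initial
  mortality rate by ``dM0 = chi * N`` and shortens lifespan accordingly,
  while a stable network recovers completely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .core import (
    EigenSystem,
    ModelParams,
    adiabatic_mortality,
    build_interaction_matrix,
    eigendecompose,
    stability,
)
from .demography import GompertzParams, LifespanResult, hazard, mean_lifespan

__all__ = [
    "StressEvent",
    "MortalityReadout",
    "StressSusceptibility",
    "MortalityIndexResult",
    "project_stress",
    "stressed_mortality",
    "mortality_index",
    "mortality_vs_strikes",
    "delta_M0",
    "lifespan_vs_strikes",
]


@dataclass(frozen=True)
class StressEvent:
    """An impulse stress: defect increments injected at age ``t0``.

    ``F_s`` are the counts of (expressome, genome) defects produced by
    the stress; for a repetitive protocol of ``N`` identical strikes the
    injected amplitude scales linearly with ``N``.
    """

    t0: float
    F_s: Sequence[float]
    N: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.F_s, dtype=float)
        if f.shape != (2,):
            raise ValueError("F_s must be a 2-vector of defect increments")
        if np.any(f < 0):
            raise ValueError("stress defect increments must be non-negative")
        if self.N < 0:
            raise ValueError("strike count must be non-negative")
        object.__setattr__(self, "F_s", f)

    def scaled(self, n_strikes: int) -> "StressEvent":
        """The same stress repeated ``n_strikes`` times (linear scaling)."""
        base = self.F_s / max(self.N, 1)
        return StressEvent(t0=self.t0, F_s=base * n_strikes, N=n_strikes)


@dataclass(frozen=True)
class MortalityReadout:
    """Per-defect mortality weights ``Omega = (Omega_p, Omega_g)``.

    The linearized hazard is ``M = Omega . x``; projections on the
    eigenmodes give the slow and fast mortality weights.
    """

    Omega: Sequence[float]

    def __post_init__(self) -> None:
        o = np.asarray(self.Omega, dtype=float)
        if o.shape != (2,):
            raise ValueError("Omega must be a 2-vector")
        if np.any(o < 0):
            raise ValueError("mortality weights must be non-negative")
        object.__setattr__(self, "Omega", o)

    def mode_weights(self, es: EigenSystem) -> tuple[float, float]:
        """(Omega1, Omega2) = (Omega.b1, Omega.b2)."""
        return float(self.Omega @ es.b1), float(self.Omega @ es.b2)


@dataclass(frozen=True)
class StressSusceptibility:
    """Per-strike IMR increment ``chi`` (per day per strike).

    An empirical composite absorbing the slow-mode mortality weight, the
    per-strike defect yield and the decay factor back to birth age; it is
    fitted, not derived.
    """

    chi: float

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be non-negative")


@dataclass(frozen=True)
class MortalityIndexResult:
    """Exact and linearized Mortality Index over a window ``T``."""

    mi: float
    mi_linearized: float
    slow_term: float
    fast_term: float


def project_stress(es: EigenSystem, ev: StressEvent) -> tuple[float, float]:
    """Mode amplitudes ``(s1, s2)`` of a stress impulse.

    ``s_i = a_i . F_s``; by biorthonormality ``s1 b1 + s2 b2`` rebuilds
    the injected increment exactly.
    """
    if es.degenerate:
        raise ValueError("degenerate eigensystem: mode projection is ill-defined")
    return float(es.a1 @ ev.F_s), float(es.a2 @ ev.F_s)


def stressed_mortality(
    params: ModelParams,
    readout: MortalityReadout,
    ev: StressEvent,
    t: Sequence[float] | float,
) -> np.ndarray | float:
    """Hazard of the stressed cohort at age ``t >= t0``.

    Background (unstressed) mortality from the adiabatic slow dynamics
    plus the two-mode linear response to the impulse.  Once
    ``t - t0 >> 1/E`` the fast term has died out and the survivors follow
    a Gompertz law with IMR shifted by ``Omega1 s1 exp(-lambda1 t0)``.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < ev.t0):
        raise ValueError("stressed mortality is defined for t >= t0 only")
    es = eigendecompose(build_interaction_matrix(params))
    s1, s2 = project_stress(es, ev)
    om1, om2 = readout.mode_weights(es)
    dt = tt - ev.t0
    out = (
        adiabatic_mortality(params, tt)
        + om1 * s1 * np.exp(es.lambda1 * dt)
        + om2 * s2 * np.exp(es.lambda2 * dt)
    )
    return out if np.ndim(t) else float(out)


def mortality_index(
    params: ModelParams,
    readout: MortalityReadout,
    ev: StressEvent,
    T: float,
) -> MortalityIndexResult:
    """Fraction of stressed animals dying within ``[t0, t0 + T]``.

    Exact: ``MI_T = 1 - exp(-int_{t0}^{t0+T} M(t) dt)`` with the stressed
    hazard.  Also returns the small-MI linearization

        MI ~ Omega1 s1 (e^{Lambda T} - 1)/Lambda + Omega2 s2 (1 - e^{-E T})/E

    which splits the index into slow-mode (aging-relevant) and fast-mode
    (transient) contributions; it is accurate only while MI << 1.
    """
    if T <= 0:
        raise ValueError("observation window T must be positive")
    integral, _ = quad(
        lambda u: stressed_mortality(params, readout, ev, u),
        ev.t0,
        ev.t0 + T,
        limit=200,
    )
    mi = 1.0 - np.exp(-integral)

    es = eigendecompose(build_interaction_matrix(params))
    s1, s2 = project_stress(es, ev)
    om1, om2 = readout.mode_weights(es)
    rep = stability(params)
    Lam, E = rep.Lambda, rep.E
    slow = om1 * s1 * (np.expm1(Lam * T) / Lam if Lam != 0 else T)
    fast = om2 * s2 * (1.0 - np.exp(-E * T)) / E
    return MortalityIndexResult(
        mi=float(mi),
        mi_linearized=float(slow + fast),
        slow_term=float(slow),
        fast_term=float(fast),
    )


def mortality_vs_strikes(
    gp: GompertzParams,
    chi: StressSusceptibility,
    N: int,
    t: Sequence[float] | float,
) -> np.ndarray | float:
    """Hazard of a cohort that received ``N`` strikes early in life.

    Past the fast transient, ``M(t, N) = (M0 + chi*N) e^{Lambda t}``: the
    IMR offset is linear in the strike count while the Gompertz slope is
    untouched.
    """
    if gp.model != "gompertz":
        raise ValueError("strike response is formulated for the Gompertz regime")
    if N < 0:
        raise ValueError("strike count must be non-negative")
    stressed = GompertzParams(M0=gp.M0 + chi.chi * N, Lambda=gp.Lambda)
    return hazard(stressed, t)


def delta_M0(chi: StressSusceptibility, N: int) -> float:
    """IMR excess over control after ``N`` strikes: ``dM0 = chi * N``."""
    if N < 0:
        raise ValueError("strike count must be non-negative")
    return chi.chi * N


def lifespan_vs_strikes(
    gp: GompertzParams, chi: StressSusceptibility, N: int
) -> LifespanResult:
    """Mean lifespan of the ``N``-strike cohort.

    Exact value for the shifted Gompertz hazard, plus the Gompertz-limit
    asymptotic ``~ Lambda^{-1} ln(Lambda / (M0 + chi N))``; strictly
    decreasing and convex in ``N``.
    """
    if gp.model != "gompertz":
        raise ValueError("strike response is formulated for the Gompertz regime")
    stressed = GompertzParams(M0=gp.M0 + chi.chi * N, Lambda=gp.Lambda)
    return mean_lifespan(stressed)
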