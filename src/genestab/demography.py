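"""Demographic consequences of network stability: hazards, survival, lifespan.

An unstable network yields the Gompertz hazard ``M(t) = M0 exp(Lambda t)``
with initial mortality rate (IMR) ``M0`` and Gompertz exponent ``Lambda``
(mortality-rate doubling time ``MRDT = ln 2 / Lambda``).  A stable network
yields a constant hazard ``Mbar`` and hence exponential (age-independent)
survival -- negligible senescence.  The dimensionless ratio
``gamma = M0 / Lambda`` controls the shape of the survival curve: the
"Gompertz limit" ``gamma << 1`` describes long-lived species whose mean
lifespan ``~ Lambda^{-1} ln(1/gamma)`` greatly exceeds the MRDT and is only
logarithmically sensitive to the ambient damage level.

From mortality data alone only ``(M0, Lambda)`` are identifiable, so this
module is parameterized by them directly; :func:`from_model_params` maps the
nine mechanistic constants onto the demographic surface for forward
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import exp1

from .core import ModelParams, combined_force, stability

__all__ = [
    "GompertzParams",
    "LifespanResult",
    "GompertzLimitReport",
    "hazard",
    "survival",
    "mean_lifespan",
    "gompertz_limit_diagnostics",
    "from_model_params",
]


@dataclass(frozen=True)
class GompertzParams:
    """Demographic parameter pair (hazard model).

    For ``model="gompertz"``: ``M0`` is the IMR (per day) and ``Lambda``
    the Gompertz exponent (per day), both positive.  For
    ``model="constant"``: ``M0`` holds the constant hazard ``Mbar`` and
    ``Lambda`` is ignored (kept at 0).
    """

    M0: float
    Lambda: float = 0.0
    model: str = "gompertz"

    def __post_init__(self) -> None:
        if self.model not in ("gompertz", "constant"):
            raise ValueError(f"unknown hazard model {self.model!r}")
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")
        if self.model == "gompertz" and self.Lambda <= 0:
            raise ValueError("Gompertz model requires Lambda > 0")

    @property
    def gamma(self) -> float:
        """Dimensionless IMR-to-exponent ratio ``M0/Lambda``."""
        if self.model != "gompertz":
            raise ValueError("gamma is defined for the Gompertz model only")
        return self.M0 / self.Lambda

    @property
    def mrdt(self) -> float:
        """Mortality-rate doubling time ``ln 2 / Lambda`` (days)."""
        if self.model != "gompertz":
            return float("inf")
        return float(np.log(2.0) / self.Lambda)


@dataclass(frozen=True)
class LifespanResult:
    """Mean lifespan: exact value and the Gompertz-limit asymptotic."""

    t_avg: float
    t_le_asymptotic: float


@dataclass(frozen=True)
class GompertzLimitReport:
    gamma: float
    mrdt: float
    t_avg: float
    ratio_tavg_mrdt: float
    in_gompertz_limit: bool


def _check_age(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")


def hazard(gp: GompertzParams, t: Sequence[float] | float) -> np.ndarray | float:
    """Instantaneous death rate ``M(t)`` at age ``t`` (per day)."""
    tt = np.asarray(t, dtype=float)
    _check_age(tt)
    if gp.model == "gompertz":
        out = gp.M0 * np.exp(gp.Lambda * tt)
    else:
        out = np.full_like(tt, gp.M0)
    return out if np.ndim(t) else float(out)


def survival(gp: GompertzParams, t: Sequence[float] | float) -> np.ndarray | float:
    """Survivorship ``S(t) = exp(-int_0^t M)``.

    Closed forms: ``exp(-gamma (e^{Lambda t} - 1))`` for Gompertz and
    ``exp(-Mbar t)`` for the constant hazard.
    """
    tt = np.asarray(t, dtype=float)
    _check_age(tt)
    if gp.model == "gompertz":
        # expm1 overflow at extreme ages is benign: S underflows to 0
        with np.errstate(over="ignore"):
            out = np.exp(-gp.gamma * np.expm1(gp.Lambda * tt))
    else:
        out = np.exp(-gp.M0 * tt)
    return out if np.ndim(t) else float(out)


def mean_lifespan(gp: GompertzParams) -> LifespanResult:
    """Mean lifespan ``t_avg = int_0^inf S(t) dt``.

    For the Gompertz hazard the integral has the closed form

        t_avg = Lambda^{-1} e^{gamma} E1(gamma)

    (substitute u = gamma e^{Lambda t}; E1 is the exponential integral),
    with the Gompertz-limit asymptotic ``t_le ~ Lambda^{-1} ln(1/gamma)``
    as gamma -> 0.  For the constant hazard ``t_avg = 1/Mbar``.
    """
    if gp.model == "constant":
        m = 1.0 / gp.M0
        return LifespanResult(t_avg=m, t_le_asymptotic=m)
    g = gp.gamma
    if g <= 0:
        raise ValueError("gamma must be positive for the Gompertz model")
    # e^g E1(g) evaluated stably: scipy's exp1 underflows to 0 for g > ~700,
    # where the asymptotic e^g E1(g) ~ 1/g takes over.
    if g < 700:
        core = float(np.exp(g) * exp1(g))
    else:
        core = float(1.0 / g - 1.0 / g**2 + 2.0 / g**3)
    t_avg = core / gp.Lambda
    t_le = float(np.log(1.0 / g) / gp.Lambda)
    return LifespanResult(t_avg=t_avg, t_le_asymptotic=t_le)


def gompertz_limit_diagnostics(
    gp: GompertzParams, gamma_threshold: float = 0.1
) -> GompertzLimitReport:
    """Is this demographic regime in the Gompertz limit (gamma small)?

    Reports gamma, the MRDT, the mean lifespan and its ratio to the MRDT;
    a species is flagged "in the Gompertz limit" when gamma falls below
    ``gamma_threshold`` (default 0.1), i.e. when lifespan comfortably
    exceeds the mortality-doubling time.
    """
    if gp.model != "gompertz":
        raise ValueError("diagnostics are defined for the Gompertz model only")
    ls = mean_lifespan(gp)
    return GompertzLimitReport(
        gamma=gp.gamma,
        mrdt=gp.mrdt,
        t_avg=ls.t_avg,
        ratio_tavg_mrdt=ls.t_avg / gp.mrdt,
        in_gompertz_limit=gp.gamma < gamma_threshold,
    )


def from_model_params(params: ModelParams) -> GompertzParams:
    """Project mechanistic parameters onto the demographic surface.

    Unstable network: Gompertz with ``M0 = omega*F_tot/Lambda`` (the
    saturated amplitude of the slow mode) and exponent ``Lambda``.
    Stable network: constant hazard ``Mbar = omega*F_tot/|Lambda|``, the
    plateau of :func:`genestab.core.adiabatic_mortality`.  On the
    separatrix the mortality grows linearly forever and no two-parameter
    demographic summary exists.
    """
    rep = stability(params)
    F = combined_force(params)
    if F <= 0:
        raise ValueError("damage forces are zero: the hazard vanishes identically")
    if rep.regime == "unstable":
        return GompertzParams(M0=params.omega * F / rep.Lambda, Lambda=rep.Lambda)
    if rep.regime == "stable":
        return GompertzParams(M0=params.omega * F / abs(rep.Lambda), model="constant")
    raise ValueError("critical networks have no Gompertz/constant demographic summary")
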