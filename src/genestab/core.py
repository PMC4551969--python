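"""Two-compartment linear defect dynamics for a gene regulatory network.

The model tracks two slowly varying defect counts in an organism: ``e_p``,
the number of mis-produced expressome copies (proteins, transcripts,
metabolites), and ``e_g``, the number of dysregulated genes.  Defective
gene products dysregulate further genes at a rate set by the translation
rate ``p``, the regulatory coupling ``beta`` and the network connectivity
``K``; repair machinery removes defects at rates ``c`` (expressome
turnover / protein quality control) and ``delta`` (DNA / epigenetic
repair).  Constant damage forces ``f_p`` and ``f_g`` model genotoxic and
proteotoxic stress.  In the linearized regime (``e_g << G``) the state
``x = (e_p, e_g)`` obeys

    de_p/dt = -c * e_p + p * e_g + f_p
    de_g/dt = beta*K*G * e_p - delta * e_g + G * f_g

i.e. ``dx/dt = I x + f`` with a 2x2 interaction matrix ``I``.  The sign of
the slow eigenvalue of ``I`` separates two demographic regimes: an
unstable network (``R0 = beta*p*G*K/(c*delta) > 1``) accumulates
regulatory errors exponentially at rate ``Lambda`` and produces Gompertz
mortality, while a stable network (``R0 < 1``) keeps the error burden --
and hence the death rate -- constant, the negligible-senescence
phenotype.

Time is measured in days throughout; all rates are per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "NetworkState",
    "InteractionMatrix",
    "EigenSystem",
    "StabilityReport",
    "LinearRegimeWarning",
    "build_interaction_matrix",
    "eigendecompose",
    "stability",
    "solve_dynamics",
    "adiabatic_mortality",
    "combined_force",
]

#: fraction of dysregulated genes above which the linearization is suspect
LINEAR_REGIME_THRESHOLD = 0.1


class LinearRegimeWarning(UserWarning):
    """Raised when e_g/G leaves the small-defect regime the model assumes."""


@dataclass(frozen=True)
class ModelParams:
    """Mechanistic rate constants of the gene-network model.

    Parameters
    ----------
    beta
        Coupling rate of expressome defects onto gene regulation
        (per day per defect).
    p
        Defective-translation rate (per day): rate at which a dysregulated
        gene emits defective product copies.
    G
        Genome size (number of genes, >= 1).
    K
        Mean number of genes regulated per protein; the network
        connectivity (dimensionless, >= 0).
    c
        Expressome turnover / protein quality-control rate (per day).
    delta
        Genome (DNA/epigenetic) repair rate (per day).
    f_p
        Proteome damage force (defects per day).
    f_g
        Per-gene genome damage force (defects per gene per day).
    omega
        Essential-gene mortality scale (per day): the hazard is
        ``omega * e_g / G``, so ``omega`` is roughly the fraction of
        essential genes times a lethality rate.
    coupling_includes_G
        If True (default) the feedback gain onto the genome is
        ``beta*K*G``; set False for a ``beta*K`` convention.

    The defaults describe a fly-like unstable network: loop gain
    ``beta*p*G*K = 6.5/day`` against repair ``c*delta = 6/day^2``
    (``R0 ~ 1.08``) gives the Gompertz exponent ``Lambda = 0.1/day``
    (MRDT ~ 7 days), and with the default damage forces and ``omega`` the
    initial mortality rate is ``~0.005/day``, i.e. ``gamma ~ 0.05`` --
    the values a fruit-fly lifetable implies.
    """

    beta: float = 0.0065
    p: float = 1.0
    G: float = 1000.0
    K: float = 1.0
    c: float = 3.0
    delta: float = 2.0
    f_p: float = 0.05
    f_g: float = 5.0e-4
    omega: float = 1.37
    coupling_includes_G: bool = True

    def __post_init__(self) -> None:
        for name in ("beta", "p", "K", "c", "delta", "f_p", "f_g", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if self.c + self.delta <= 0:
            raise ValueError("c + delta must be positive (some repair is required)")

    @property
    def coupling(self) -> float:
        """Feedback gain of expressome defects onto the genome (per day)."""
        return self.beta * self.K * (self.G if self.coupling_includes_G else 1.0)

    @property
    def loop_gain(self) -> float:
        """Error-proliferation rate ``beta*p*G*K`` of the regulatory loop."""
        return self.p * self.coupling

    @property
    def repair_gain(self) -> float:
        """Combined repair rate product ``c*delta``."""
        return self.c * self.delta

    @property
    def E(self) -> float:
        """Fast relaxation rate ``c + delta`` (per day)."""
        return self.c + self.delta


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous defect burden of a network: ``(e_p, e_g)`` at age t."""

    e_p: float
    e_g: float
    t: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.e_p, self.e_g], dtype=float)


@dataclass(frozen=True)
class InteractionMatrix:
    """2x2 linear operator ``I`` and constant force of ``dx/dt = I x + f``."""

    matrix: np.ndarray
    force: np.ndarray
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if m.shape != (2, 2) or f.shape != (2,):
            raise ValueError("matrix must be 2x2 and force a 2-vector")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "force", f)
        if m[0, 1] < 0 or m[1, 0] < 0:
            raise ValueError("off-diagonal (coupling) entries must be non-negative")
        if m[0, 0] > 0 or m[1, 1] > 0:
            raise ValueError("diagonal (relaxation) entries must be non-positive")

    @property
    def trace(self) -> float:
        return float(self.matrix[0, 0] + self.matrix[1, 1])

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))


@dataclass(frozen=True)
class EigenSystem:
    """Eigen-structure of the interaction matrix.

    ``lambda1 >= lambda2`` and the left/right eigenvectors satisfy the
    biorthonormality ``a_i . b_k = delta_ik``, so that any state
    decomposes as ``x = (a1.x) b1 + (a2.x) b2``.  The slow mode ``b1``
    carries aging; the fast mode ``b2`` carries transient stress
    responses.
    """

    lambda1: float
    lambda2: float
    b1: np.ndarray
    b2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    degenerate: bool = False

    @property
    def right_matrix(self) -> np.ndarray:
        """Columns are the right eigenvectors (b1, b2)."""
        return np.column_stack([self.b1, self.b2])

    @property
    def left_matrix(self) -> np.ndarray:
        """Rows are the left eigenvectors (a1, a2)."""
        return np.vstack([self.a1, self.a2])


@dataclass(frozen=True)
class StabilityReport:
    """Stability verdict for one parameter set (one point of the phase plane).

    ``R0`` is the dimensionless stability ratio ``beta*p*G*K/(c*delta)``;
    the separatrix ``R0 = 1`` divides Gompertzian aging (``R0 > 1``) from
    negligible senescence (``R0 < 1``).  ``Lambda`` is the near-separatrix
    instability rate ``(beta*p*G*K - c*delta)/(c + delta)``, the Gompertz
    exponent; ``lambda1_exact`` is the exact slow eigenvalue, which always
    shares its sign.  ``mrdt`` is the mortality-rate doubling time
    ``ln 2 / Lambda`` (NaN unless unstable).
    """

    R0: float
    Lambda: float
    lambda1_exact: float
    E: float
    regime: str
    mrdt: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "Lambda": self.Lambda,
            "lambda1_exact": self.lambda1_exact,
            "E": self.E,
            "regime": self.regime,
            "mrdt": self.mrdt,
        }


def build_interaction_matrix(params: ModelParams) -> InteractionMatrix:
    """Assemble ``dx/dt = I x + f`` for the state ``x = (e_p, e_g)``.

    ``I = [[-c, p], [beta*K*G, -delta]]`` and ``f = (f_p, G*f_g)``.
    """
    m = np.array(
        [
            [-params.c, params.p],
            [params.coupling, -params.delta],
        ]
    )
    f = np.array([params.f_p, params.G * params.f_g])
    return InteractionMatrix(matrix=m, force=f, params=params)


def eigendecompose(I: InteractionMatrix, degeneracy_tol: float = 1e-12) -> EigenSystem:
    """Eigenvalues and biorthonormal left/right eigenvectors of ``I``.

    For the model matrix the eigenvalues are the real roots

        lambda_{1,2} = ( -(c+delta) +- sqrt((c-delta)^2 + 4 p beta K G) ) / 2

    (the discriminant is a sum of squares of real quantities plus a
    non-negative product, hence never negative).  If the discriminant
    vanishes the two modes merge; the returned system is then flagged
    ``degenerate`` and carries the standard basis as a fallback so that
    callers can detect the (measure-zero) case and switch to numerical
    integration.
    """
    m = I.matrix
    tr = m[0, 0] + m[1, 1]
    disc = (m[0, 0] - m[1, 1]) ** 2 + 4.0 * m[0, 1] * m[1, 0]
    if disc < 0:  # impossible for non-negative couplings; guard anyway
        raise ValueError("complex eigenvalues: matrix is not of the model form")
    root = np.sqrt(disc)
    lam1 = (tr + root) / 2.0
    lam2 = (tr - root) / 2.0

    scale = max(abs(m).max(), 1.0)
    if root <= degeneracy_tol * scale:
        return EigenSystem(
            lambda1=lam1,
            lambda2=lam2,
            b1=np.array([1.0, 0.0]),
            b2=np.array([0.0, 1.0]),
            a1=np.array([1.0, 0.0]),
            a2=np.array([0.0, 1.0]),
            degenerate=True,
        )

    def right_vec(lam: float) -> np.ndarray:
        # (I - lam) v = 0; pick the better-conditioned row.
        r1 = np.array([m[0, 1], lam - m[0, 0]])
        r2 = np.array([lam - m[1, 1], m[1, 0]])
        v = r1 if np.linalg.norm(r1) >= np.linalg.norm(r2) else r2
        return v / np.linalg.norm(v)

    b1 = right_vec(lam1)
    b2 = right_vec(lam2)
    B = np.column_stack([b1, b2])
    A = np.linalg.inv(B)  # rows are left eigenvectors with a_i.b_k = delta_ik
    return EigenSystem(lambda1=lam1, lambda2=lam2, b1=b1, b2=b2, a1=A[0], a2=A[1])


def stability(params: ModelParams, rel_tol: float = 1e-9) -> StabilityReport:
    """Classify a parameter set as stable / unstable / critical.

    The regime is decided by the sign of ``loop_gain - repair_gain``
    (equivalently ``R0 - 1``), which provably agrees with the sign of the
    exact slow eigenvalue and of the near-separatrix rate ``Lambda``.
    """
    if params.c == 0 and params.delta == 0:
        raise ValueError("c = delta = 0: no repair at all, the model has no fast scale")
    loop, repair = params.loop_gain, params.repair_gain
    R0 = loop / repair if repair > 0 else float("inf")
    Lambda = (loop - repair) / params.E
    es = eigendecompose(build_interaction_matrix(params))
    margin = loop - repair
    if abs(margin) <= rel_tol * max(loop, repair, 1e-300):
        regime = "critical"
    elif margin > 0:
        regime = "unstable"
    else:
        regime = "stable"
    mrdt = np.log(2.0) / Lambda if regime == "unstable" else float("nan")
    return StabilityReport(
        R0=R0,
        Lambda=Lambda,
        lambda1_exact=es.lambda1,
        E=params.E,
        regime=regime,
        mrdt=mrdt,
    )


def _fixed_point(I: InteractionMatrix) -> np.ndarray | None:
    """Stationary state ``x* = -I^{-1} f``, or None near the separatrix."""
    m = I.matrix
    scale = np.linalg.norm(m) ** 2
    if abs(I.det) < 1e-12 * max(scale, 1e-300):
        return None
    return -np.linalg.solve(m, I.force)


def _check_linear_regime(e_g: np.ndarray, G: float, threshold: float) -> None:
    frac = np.max(np.abs(e_g)) / G
    if frac > threshold:
        warnings.warn(
            f"e_g/G reached {frac:.3g} > {threshold}: the linearized model "
            "is leaving its domain of validity",
            LinearRegimeWarning,
            stacklevel=3,
        )


def solve_dynamics(
    params: ModelParams,
    x0: NetworkState | Sequence[float] = (0.0, 0.0),
    t_grid: Sequence[float] = (0.0,),
    linear_threshold: float = LINEAR_REGIME_THRESHOLD,
) -> "np.ndarray":
    """Trajectory of ``dx/dt = I x + f`` on ``t_grid``.

    Uses the closed-form modal solution

        x(t) = x* + sum_i (a_i . (x0 - x*)) b_i exp(lambda_i (t - t0))

    with ``x* = -I^{-1} f`` whenever the matrix is comfortably
    non-singular and non-degenerate; on (or numerically near) the
    separatrix, where ``det I -> 0`` and the fixed point escapes to
    infinity, it falls back to adaptive numerical integration.

    Returns a structured array with fields ``t, e_p, e_g, M`` where
    ``M = omega * e_g / G`` is the instantaneous hazard readout.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    if isinstance(x0, NetworkState):
        x0_vec = x0.as_vector()
        t0 = x0.t
    else:
        x0_vec = np.asarray(x0, dtype=float)
        t0 = t[0]
    if t[0] < t0:
        raise ValueError("t_grid must start at or after the initial-state age")

    I = build_interaction_matrix(params)
    es = eigendecompose(I)
    xstar = _fixed_point(I)
    force_free = not np.any(I.force)

    if es.degenerate or (xstar is None and not force_free):
        sol = solve_ivp(
            lambda _t, x: I.matrix @ x + I.force,
            (t0, t[-1]),
            x0_vec,
            t_eval=t,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"numerical integration failed: {sol.message}")
        xs = sol.y.T
    else:
        if xstar is None:
            xstar = np.zeros(2)
        c1 = es.a1 @ (x0_vec - xstar)
        c2 = es.a2 @ (x0_vec - xstar)
        dt = t - t0
        xs = (
            xstar[None, :]
            + c1 * np.exp(es.lambda1 * dt)[:, None] * es.b1[None, :]
            + c2 * np.exp(es.lambda2 * dt)[:, None] * es.b2[None, :]
        )

    _check_linear_regime(xs[:, 1], params.G, linear_threshold)
    out = np.zeros(t.size, dtype=[("t", float), ("e_p", float), ("e_g", float), ("M", float)])
    out["t"] = t
    out["e_p"] = xs[:, 0]
    out["e_g"] = xs[:, 1]
    out["M"] = params.omega * xs[:, 1] / params.G
    return out


def combined_force(params: ModelParams) -> float:
    """Effective per-gene damage rate driving the slow mode.

    Adiabatic elimination of the fast expressome variable reduces the
    2-D system to ``de/dt = Lambda e + G*F_tot`` for the dysregulated
    gene count, with

        F_tot = (beta*K*f_p + c*f_g) / (c + delta)

    the combined measure of genotoxic stress (damage forces divided by
    the fast relaxation rate).
    """
    bk = params.coupling / params.G if params.coupling_includes_G else params.coupling
    return (bk * params.f_p + params.c * params.f_g) / params.E


def adiabatic_mortality(
    params: ModelParams,
    t: Sequence[float] | float,
    warn_ratio: float = 10.0,
    rate: str = "exact",
) -> np.ndarray | float:
    """Hazard from the one-mode (adiabatic) reduction, ``M(t) = omega*e(t)/G``.

    Eliminating the fast mode reduces the 2-D system to a single slow
    equation; with ``e(0) = 0`` it integrates to

        M(t) = (omega * F_slow / lam) * (exp(lam*t) - 1)   (lam != 0)
        M(t) = omega * F_slow * t                          (lam == 0)

    With ``rate="exact"`` (default) the slow rate is the exact eigenvalue
    ``lambda1`` and ``F_slow = (a1 . f) b1_g / G`` is the exact slow-mode
    force projection, so the only neglected piece is the fast transient.
    With ``rate="near_separatrix"`` the first-order pair
    ``(Lambda, F_tot)`` of :func:`combined_force` is used instead -- the
    textbook reduction, identical to first order in ``Lambda/E``.

    For a stable network (``lam < 0``) the hazard plateaus at the
    constant mortality ``Mbar = omega*F_slow/|lam|`` -- the
    negligible-senescence regime.  Valid when the fast scale dominates,
    ``c + delta >> |Lambda|``; a warning is emitted when the separation
    drops below ``warn_ratio``.
    """
    rep = stability(params)
    if rep.Lambda != 0 and params.E < warn_ratio * abs(rep.Lambda):
        warnings.warn(
            f"timescale separation E/|Lambda| = {params.E / abs(rep.Lambda):.2f} "
            "is weak; the adiabatic reduction may be inaccurate",
            UserWarning,
            stacklevel=2,
        )
    tt = np.asarray(t, dtype=float)
    if rate == "exact":
        I = build_interaction_matrix(params)
        es = eigendecompose(I)
        lam = es.lambda1
        F = float(es.a1 @ I.force) * float(es.b1[1]) / params.G
    elif rate == "near_separatrix":
        lam = rep.Lambda
        F = combined_force(params)
    else:
        raise ValueError("rate must be 'exact' or 'near_separatrix'")
    if lam == 0:
        M = params.omega * F * tt
    else:
        M = params.omega * F * np.expm1(lam * tt) / lam
    return M if np.ndim(t) else float(M)
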