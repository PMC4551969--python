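"""Maximum-likelihood recovery of demographic parameters from event times.

Individual ages at death (optionally right-censored) are fitted under the
Gompertz hazard ``M(t) = M0 e^{Lambda t}`` or the constant hazard ``Mbar``.
For the Gompertz model the log-likelihood

    l(M0, Lambda) = sum_deaths [ln M0 + Lambda t_i]
                    - sum_all (M0/Lambda) (e^{Lambda t_i} - 1)

is maximized by profiling ``M0`` in closed form given ``Lambda``,

    M0^(Lambda) = n_deaths * Lambda / sum_all (e^{Lambda t_i} - 1),

followed by a one-dimensional search over ``log Lambda``.  Censored rows
contribute only the cumulative-hazard (survival) term.  AIC comparison of
the two hazard models classifies a cohort as "senescent" (Gompertz wins)
or "negligible-senescence-consistent" (constant hazard wins).

Multi-cohort trauma experiments (strike counts ``N`` per cohort) are
fitted jointly with a shared slope and the linear IMR constraint
``M0(N) = M0 + chi N``, giving the stress susceptibility ``chi``.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``age`` (float, > 0), ``censored`` (bool), ``cohort`` (str) and ``N``
(int); :func:`read_events` / :func:`write_events` move them through
delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

__all__ = [
    "EVENT_COLUMNS",
    "FitResult",
    "RegimeReport",
    "make_event_table",
    "validate_event_table",
    "read_events",
    "write_events",
    "lifetable_to_events",
    "gompertz_loglik",
    "fit_gompertz",
    "fit_constant",
    "compare_regimes",
    "fit_stress_susceptibility",
    "bootstrap_ci",
]

EVENT_COLUMNS = ("age", "censored", "cohort", "N")

LAMBDA_BOUNDS = (1e-6, 10.0)  # per day, log-scaled 1-D search bracket
MIN_EVENTS = 10
LOW_POWER_FLOOR = 100


@dataclass
class FitResult:
    """Point estimates, log-likelihood and bookkeeping for one fit."""

    model: str
    estimates: dict
    loglik: float
    n_events: int
    n_total: int
    converged: bool = True
    flags: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_events": self.n_events,
            "n_total": self.n_total,
            "converged": self.converged,
            "flags": self.flags,
            "ci": self.ci,
            "diagnostics": self.diagnostics,
        }


@dataclass
class RegimeReport:
    """AIC verdict on the aging regime of a cohort."""

    label: str
    aic_gompertz: float
    aic_constant: float
    aic_margin: float
    low_power: bool
    fit_gompertz: FitResult
    fit_constant: FitResult

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "aic_gompertz": self.aic_gompertz,
            "aic_constant": self.aic_constant,
            "aic_margin": self.aic_margin,
            "low_power": self.low_power,
        }


def make_event_table(
    ages: Iterable[float],
    censored: Iterable[bool] | None = None,
    cohort: str | Iterable[str] = "cohort",
    N: int | Iterable[int] = 0,
) -> pd.DataFrame:
    """Assemble a validated event table from column data."""
    ages = np.asarray(list(ages), dtype=float)
    n = ages.size
    df = pd.DataFrame(
        {
            "age": ages,
            "censored": np.zeros(n, bool) if censored is None else np.asarray(list(censored), bool),
            "cohort": [cohort] * n if isinstance(cohort, str) else list(cohort),
            "N": np.full(n, N, int) if np.isscalar(N) else np.asarray(list(N), int),
        }
    )
    validate_event_table(df)
    return df


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    if np.any(df["age"].to_numpy(float) <= 0):
        raise ValueError("all ages must be positive")
    if np.any(df["N"].to_numpy(int) < 0):
        raise ValueError("strike counts must be non-negative")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["censored"] = df["censored"].astype(bool)
    return validate_event_table(df)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    validate_event_table(df)
    df.to_csv(path, index=False)


def lifetable_to_events(
    lifetable: pd.DataFrame, cohort: str = "lifetable", N: int = 0
) -> pd.DataFrame:
    """Expand a binned lifetable into individual event rows.

    Expects columns ``age_start``, ``deaths`` and ``at_risk`` with rows in
    increasing age order.  Deaths are spread uniformly within each bin
    (bin width taken from consecutive starts; the last bin reuses the
    previous width); survivors of the last bin become censored rows at
    its upper edge.  A documented approximation -- individual times are
    always preferable.
    """
    for col in ("age_start", "deaths", "at_risk"):
        if col not in lifetable.columns:
            raise ValueError(f"lifetable is missing column {col!r}")
    starts = lifetable["age_start"].to_numpy(float)
    deaths = lifetable["deaths"].to_numpy(int)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("age bins must be strictly increasing")
    widths = np.diff(starts)
    widths = np.append(widths, widths[-1] if widths.size else 1.0)
    ages, cens = [], []
    for s, w, d in zip(starts, widths, deaths):
        if d > 0:
            # uniform spread: midpoints of d equal slices of the bin
            ages.extend(s + w * (np.arange(d) + 0.5) / d)
            cens.extend([False] * d)
    survivors = int(lifetable["at_risk"].iloc[-1] - deaths[-1])
    if survivors > 0:
        ages.extend([starts[-1] + widths[-1]] * survivors)
        cens.extend([True] * survivors)
    return make_event_table(ages, cens, cohort=cohort, N=N)


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(e^x - 1) for x > 0, stable for both tails."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-8
    out = np.where(small, np.log(np.maximum(x, 1e-300)) + x / 2.0, 0.0)
    xb = np.where(small, 1.0, x)
    return np.where(small, out, xb + np.log1p(-np.exp(-xb)))


def gompertz_loglik(df: pd.DataFrame, M0: float, Lambda: float) -> float:
    """Exact Gompertz log-likelihood of an event table (censoring aware)."""
    validate_event_table(df)
    t_all = df["age"].to_numpy(float)
    t_dead = df.loc[~df["censored"], "age"].to_numpy(float)
    cum = (M0 / Lambda) * np.sum(np.expm1(Lambda * t_all))
    return float(t_dead.size * np.log(M0) + Lambda * np.sum(t_dead) - cum)


def _profile_M0(t_all: np.ndarray, n_dead: int, lam: float) -> tuple[float, float]:
    """Closed-form profile maximizer M0^(lam) and its log, computed in logs."""
    log_sum = logsumexp(_log_expm1(lam * t_all))
    log_m0 = np.log(n_dead) + np.log(lam) - log_sum
    return float(np.exp(log_m0)), float(log_m0)


def _profile_loglik(t_all: np.ndarray, t_dead: np.ndarray, lam: float) -> float:
    d = t_dead.size
    _, log_m0 = _profile_M0(t_all, d, lam)
    return d * log_m0 + lam * float(np.sum(t_dead)) - d


def fit_gompertz(
    df: pd.DataFrame,
    lambda_bounds: tuple[float, float] = LAMBDA_BOUNDS,
    min_events: int = MIN_EVENTS,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> FitResult:
    """MLE of (M0, Lambda) under the Gompertz hazard.

    ``M0`` is profiled out in closed form; ``Lambda`` is found by Brent
    search on a log grid over ``lambda_bounds``.  An estimate pinned to a
    bracket edge (e.g. ``Lambda -> 0`` on exponential data) is returned
    with ``converged=False`` and an explanatory flag, never silently.
    """
    validate_event_table(df)
    dead = ~df["censored"].to_numpy(bool)
    t_all = df["age"].to_numpy(float)
    t_dead = t_all[dead]
    if t_dead.size == 0:
        raise ValueError("all rows are censored: nothing to fit")
    if t_dead.size < min_events:
        raise ValueError(
            f"need at least {min_events} uncensored events, got {t_dead.size}"
        )

    lo, hi = lambda_bounds
    res = minimize_scalar(
        lambda u: -_profile_loglik(t_all, t_dead, np.exp(u)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    m0, _ = _profile_M0(t_all, t_dead.size, lam)
    ll = gompertz_loglik(df, m0, lam)

    flags: list[str] = []
    converged = bool(res.success)
    # bracket-edge detection on the log scale
    span = np.log(hi) - np.log(lo)
    if res.x - np.log(lo) < 1e-3 * span:
        flags.append("Lambda at lower search bound: data look age-independent")
        converged = False
    elif np.log(hi) - res.x < 1e-3 * span:
        flags.append("Lambda at upper search bound")
        converged = False

    out = FitResult(
        model="gompertz",
        estimates={"M0": m0, "Lambda": lam},
        loglik=ll,
        n_events=int(t_dead.size),
        n_total=int(t_all.size),
        converged=converged,
        flags=flags,
    )
    if n_bootstrap > 0:
        out.ci = bootstrap_ci(
            df, lambda d: fit_gompertz(d, lambda_bounds, min_events).estimates,
            n_bootstrap, seed,
        )
    return out


def fit_constant(
    df: pd.DataFrame,
    min_events: int = MIN_EVENTS,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> FitResult:
    """MLE of the constant hazard: ``Mbar = n_deaths / total exposure``.

    Censored rows contribute exposure time but no death.
    """
    validate_event_table(df)
    dead = ~df["censored"].to_numpy(bool)
    t_all = df["age"].to_numpy(float)
    n_dead = int(dead.sum())
    if n_dead == 0:
        raise ValueError("all rows are censored: nothing to fit")
    if n_dead < min_events:
        raise ValueError(f"need at least {min_events} uncensored events, got {n_dead}")
    exposure = float(np.sum(t_all))
    mbar = n_dead / exposure
    ll = n_dead * np.log(mbar) - mbar * exposure
    out = FitResult(
        model="constant",
        estimates={"Mbar": mbar},
        loglik=float(ll),
        n_events=n_dead,
        n_total=int(t_all.size),
    )
    if n_bootstrap > 0:
        out.ci = bootstrap_ci(
            df, lambda d: fit_constant(d, min_events).estimates, n_bootstrap, seed
        )
    return out


def compare_regimes(
    df: pd.DataFrame,
    low_power_floor: int = LOW_POWER_FLOOR,
    **fit_kwargs,
) -> RegimeReport:
    """Classify a cohort's aging regime by AIC.

    Gompertz (2 parameters) against constant hazard (1 parameter):
    senescent if the Gompertz AIC is lower, otherwise
    negligible-senescence-consistent.  Cohorts with fewer than
    ``low_power_floor`` deaths keep their verdict but are flagged
    ``low_power``.
    """
    fg = fit_gompertz(df, **fit_kwargs)
    fc = fit_constant(df)
    margin = fc.aic - fg.aic
    label = "senescent" if margin > 0 else "negligible-senescence-consistent"
    return RegimeReport(
        label=label,
        aic_gompertz=fg.aic,
        aic_constant=fc.aic,
        aic_margin=float(margin),
        low_power=fg.n_events < low_power_floor,
        fit_gompertz=fg,
        fit_constant=fc,
    )


def _joint_negloglik(theta: np.ndarray, groups: list[tuple[int, np.ndarray, np.ndarray]]) -> float:
    log_m0, log_lam, chi = theta
    m0, lam = np.exp(log_m0), np.exp(log_lam)
    total = 0.0
    for n_strikes, t_all, t_dead in groups:
        imr = m0 + chi * n_strikes
        if imr <= 0:
            return np.inf
        cum = (imr / lam) * np.sum(np.expm1(lam * t_all))
        total += t_dead.size * np.log(imr) + lam * np.sum(t_dead) - cum
    return -float(total)


def fit_stress_susceptibility(
    df: pd.DataFrame,
    lambda_bounds: tuple[float, float] = LAMBDA_BOUNDS,
    min_events: int = MIN_EVENTS,
) -> FitResult:
    """Joint MLE of (M0, Lambda, chi) across multi-strike cohorts.

    All cohorts share the Gompertz slope ``Lambda``; the IMR of the
    cohort with strike count ``N`` is constrained to ``M0 + chi N``.
    Requires at least two distinct ``N`` values including an unstressed
    control (``N = 0``); otherwise ``chi`` is unidentifiable.

    Diagnostics mirror the classic two-panel trauma analysis: per-cohort
    unconstrained IMR estimates at the shared slope, their least-squares
    line in ``N`` (slope, intercept, R^2), and per-cohort mean lifespans.
    """
    validate_event_table(df)
    n_values = np.sort(df["N"].unique())
    if n_values.size < 2:
        raise ValueError("chi unidentifiable: need at least two distinct strike counts")
    if 0 not in n_values:
        raise ValueError("chi fit requires an unstressed control cohort (N = 0)")

    groups = []
    for n_strikes, sub in df.groupby("N"):
        dead = ~sub["censored"].to_numpy(bool)
        t_all = sub["age"].to_numpy(float)
        groups.append((int(n_strikes), t_all, t_all[dead]))

    # initialize from the control fit and the naive per-cohort IMR slope
    control = df[df["N"] == 0]
    f0 = fit_gompertz(control, lambda_bounds, min_events)
    lam0, m00 = f0.estimates["Lambda"], f0.estimates["M0"]
    per_m0 = {}
    for n_strikes, t_all, t_dead in groups:
        per_m0[n_strikes], _ = _profile_M0(t_all, t_dead.size, lam0)
    ns = np.array(sorted(per_m0))
    m0s = np.array([per_m0[n] for n in ns])
    chi0 = max(float(np.polyfit(ns, m0s, 1)[0]), 1e-8) if ns.size > 1 else 1e-8

    res = minimize(
        _joint_negloglik,
        x0=np.array([np.log(m00), np.log(lam0), chi0]),
        args=(groups,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000},
    )
    log_m0, log_lam, chi = res.x
    m0_hat, lam_hat, chi_hat = float(np.exp(log_m0)), float(np.exp(log_lam)), float(chi)

    # diagnostics at the fitted shared slope
    per_cohort = {}
    for n_strikes, t_all, t_dead in groups:
        per_cohort[n_strikes] = _profile_M0(t_all, t_dead.size, lam_hat)[0]
    ns = np.array(sorted(per_cohort), dtype=float)
    m0s = np.array([per_cohort[int(n)] for n in ns])
    slope, intercept = np.polyfit(ns, m0s, 1)
    resid = m0s - (slope * ns + intercept)
    ss_tot = float(np.sum((m0s - m0s.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    mean_ls = df[~df["censored"]].groupby("N")["age"].mean().to_dict()

    return FitResult(
        model="gompertz-strikes",
        estimates={"M0": m0_hat, "Lambda": lam_hat, "chi": chi_hat},
        loglik=float(-res.fun),
        n_events=int((~df["censored"]).sum()),
        n_total=int(len(df)),
        converged=bool(res.success),
        flags=[] if res.success else ["joint optimizer did not converge"],
        diagnostics={
            "per_cohort_M0": {int(k): float(v) for k, v in per_cohort.items()},
            "imr_vs_N_slope": float(slope),
            "imr_vs_N_intercept": float(intercept),
            "imr_vs_N_r2": r2,
            "mean_lifespan_by_N": {int(k): float(v) for k, v in mean_ls.items()},
        },
    )


def bootstrap_ci(
    df: pd.DataFrame,
    estimator,
    n_reps: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> dict:
    """Nonparametric bootstrap percentile intervals (resampling animals)."""
    rng = np.random.default_rng(seed)
    n = len(df)
    draws: dict[str, list[float]] = {}
    for _ in range(n_reps):
        sample = df.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        try:
            est = estimator(sample)
        except ValueError:
            continue
        for k, v in est.items():
            draws.setdefault(k, []).append(v)
    alpha = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for k, v in draws.items()
        if v
    }
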