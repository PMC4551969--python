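"""Seeded generators for synthetic cohorts and expressome panels.

Three emulations stand in for experimental fly data:

* Gompertz or constant-hazard lifespans drawn by inverse-CDF sampling --
  the input to the demographic fitters;
* multi-strike trauma cohorts whose initial mortality rate is offset
  linearly in the strike count ``N``;
* expressome snapshot panels with one slowly drifting unstable mode plus
  fast mean-reverting fluctuations, reproducing the structure seen in
  principal-component plots of aging transcriptomes: a unidirectional
  age drift along the slow axis with rapid noise orthogonal to it.

Everything is bit-reproducible given a seed.  The expression panel is a
structural stand-in only: read-outs are linear-Gaussian, with no attempt
at count-distribution realism (no negative binomial, no library-size
effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ModelParams,
    NetworkState,
    build_interaction_matrix,
    eigendecompose,
    solve_dynamics,
    stability,
)
from .demography import GompertzParams
from .inference import make_event_table
from .stress import StressSusceptibility

__all__ = [
    "ExpressomePanel",
    "simulate_lifespans",
    "simulate_tbi_experiment",
    "simulate_expressome",
    "expressome_pca_summary",
    "DEFAULT_AGES",
]

#: six sampling ages (days), young adulthood to late life for a ~26-day
#: mean-lifespan cohort
DEFAULT_AGES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass
class ExpressomePanel:
    """Synthetic expression snapshot panel.

    ``matrix`` is samples x genes; ``ages`` and ``groups`` label the
    rows; ``loading`` is the genes x 2 map from the latent defect state
    ``(e_p, e_g)`` to read-outs; ``sigma`` is the additive noise scale.
    """

    matrix: np.ndarray
    ages: np.ndarray
    groups: list
    loading: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        a = np.asarray(self.ages, dtype=float)
        if m.shape[0] != a.size or m.shape[0] != len(self.groups):
            raise ValueError("matrix rows, ages and groups must align")
        if np.any(a < 0):
            raise ValueError("ages must be non-negative")
        if self.loading.shape != (m.shape[1], 2):
            raise ValueError("loading must be genes x 2")

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [f"s{i:04d}" for i in range(self.matrix.shape[0])],
                "age": self.ages,
                "group": self.groups,
            }
        )


def _draw_gompertz(gp: GompertzParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws: S(t) = U  =>  t = ln(1 - ln U / gamma)/Lambda."""
    u = rng.uniform(size=n)
    if gp.model == "gompertz":
        return np.log1p(-np.log(u) / gp.gamma) / gp.Lambda
    return -np.log(u) / gp.M0


def simulate_lifespans(
    gp: GompertzParams,
    n: int,
    seed: int | np.random.Generator,
    cohort: str = "cohort0",
    N: int = 0,
    censor_time: float | None = None,
) -> pd.DataFrame:
    """Draw ``n`` i.i.d. ages at death from a hazard model.

    Returns an event table; with ``censor_time`` set, deaths beyond it
    are recorded as censored at that age (off by default -- fly cohorts
    are followed to extinction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = _draw_gompertz(gp, n, rng)
    censored = np.zeros(n, bool)
    if censor_time is not None:
        censored = ages > censor_time
        ages = np.minimum(ages, censor_time)
    return make_event_table(ages, censored, cohort=cohort, N=N)


def simulate_tbi_experiment(
    gp: GompertzParams,
    chi: StressSusceptibility,
    N_list: list[int],
    n_per_group: int,
    t0: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Multi-strike trauma cohorts: group ``N`` has hazard ``(M0+chi N)e^{Lambda t}``.

    ``t0`` (the age at which strikes are applied) is bookkeeping only:
    the linear-response prediction for survivors past the fast transient
    is a pure IMR offset, which is what is simulated.
    """
    if not N_list:
        raise ValueError("N_list must not be empty")
    if 0 not in N_list:
        raise ValueError("include an unstressed control group (N = 0)")
    if gp.model != "gompertz":
        raise ValueError("trauma cohorts are simulated in the Gompertz regime")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = []
    for n_strikes in N_list:
        stressed = GompertzParams(M0=gp.M0 + chi.chi * n_strikes, Lambda=gp.Lambda)
        tab = simulate_lifespans(
            stressed, n_per_group, rng, cohort=f"N={n_strikes}", N=n_strikes
        )
        tab["age"] += t0
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def simulate_expressome(
    params: ModelParams,
    ages: tuple[float, ...] = DEFAULT_AGES,
    n_genes: int = 200,
    n_replicates: int = 2,
    sigma: float = 0.05,
    seed: int | np.random.Generator = 0,
    kick_rate: float = 1.0,
    kick_size: float | None = None,
) -> ExpressomePanel:
    """Expression panel from the latent two-mode defect dynamics.

    Each replicate (group) follows the deterministic trajectory of the
    defect state from a pristine start, perturbed by Poisson-timed
    impulse "kicks" along the fast eigenmode (rate ``kick_rate`` per day)
    that relax at rate ``|lambda2|`` -- the model's own impulse-stress
    formalism used as the noise process.  Read-outs are ``y = L x + eps``
    with a fixed Gaussian loading ``L`` (genes x 2) drawn once per seed
    and i.i.d. noise of scale ``sigma``.

    ``kick_size`` defaults to 1% of the slow-state norm at the middle
    sampling age, keeping fast fluctuations visibly smaller than the
    age drift (chosen for qualitative agreement with transcriptome PC
    plots; unanchored by any quantitative measurement).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    es = eigendecompose(build_interaction_matrix(params))
    # pristine state at birth (t = 0), sampled at the given ages
    traj = solve_dynamics(params, NetworkState(0.0, 0.0, t=0.0), ages)
    x_det = np.column_stack([traj["e_p"], traj["e_g"]])

    if kick_size is None:
        mid = x_det[len(ages) // 2]
        kick_size = 0.01 * max(float(np.linalg.norm(mid)), 1.0)

    L = rng.normal(size=(n_genes, 2))
    rows, row_ages, row_groups = [], [], []
    t_max = float(ages[-1])
    for r in range(n_replicates):
        x_rep = x_det.copy()
        if kick_rate > 0:
            n_kicks = rng.poisson(kick_rate * t_max)
            t_kicks = np.sort(rng.uniform(0.0, t_max, n_kicks))
            amps = rng.normal(scale=kick_size, size=n_kicks)
            for tk, amp in zip(t_kicks, amps):
                later = ages >= tk
                decay = np.exp(es.lambda2 * (ages[later] - tk))
                x_rep[later] += amp * decay[:, None] * es.b2[None, :]
        y = x_rep @ L.T + rng.normal(scale=sigma, size=(len(ages), n_genes))
        rows.append(y)
        row_ages.append(ages)
        row_groups.extend([f"group{r}"] * len(ages))

    return ExpressomePanel(
        matrix=np.vstack(rows),
        ages=np.concatenate(row_ages),
        groups=row_groups,
        loading=L,
        sigma=float(sigma),
    )


def expressome_pca_summary(panel: ExpressomePanel, params: ModelParams) -> dict:
    """Principal-axis diagnostics of a panel against the slow-mode read-out.

    Computes the leading principal axis of the age-pooled, mean-centred
    panel, its |cosine| with the theoretical slow-mode direction
    ``L b1``, the mean PC1 score per age, and the least-squares slope of
    score against age with a normal-theory confidence interval.
    """
    X = panel.matrix - panel.matrix.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    axis = vt[0]
    es = eigendecompose(build_interaction_matrix(params))
    slow_dir = panel.loading @ es.b1
    slow_dir = slow_dir / np.linalg.norm(slow_dir)
    cosine = float(axis @ slow_dir)
    scores = X @ axis * np.sign(cosine)  # orient PC1 along the slow mode

    ages = panel.ages
    uniq = np.unique(ages)
    mean_by_age = np.array([scores[ages == a].mean() for a in uniq])

    # OLS slope of score on age with 95% CI
    A = np.column_stack([np.ones_like(ages), ages])
    coef, res_ss, *_ = np.linalg.lstsq(A, scores, rcond=None)
    n = len(ages)
    dof = max(n - 2, 1)
    s2 = float(res_ss[0]) / dof if res_ss.size else float(np.var(scores - A @ coef) * n / dof)
    cov = s2 * np.linalg.inv(A.T @ A)
    se = float(np.sqrt(cov[1, 1]))
    slope = float(coef[1])
    return {
        "pc1_axis": axis,
        "cosine_with_slow_mode": abs(cosine),
        "ages": uniq,
        "mean_score_by_age": mean_by_age,
        "score_age_slope": slope,
        "score_age_slope_ci": (slope - 1.96 * se, slope + 1.96 * se),
        "regime": stability(params).regime,
    }
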