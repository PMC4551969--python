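# Methods

## Model

The package tracks regulatory defects in a two-compartment linear system.
The state `x = (e_p, e_g)` — defective expressome copies and dysregulated
genes — evolves as `dx/dt = I·x + f` with

```
I = [ −c    p  ]        f = ( f_p )
    [ βKG  −δ  ]            ( G·f_g )
```

Assumptions: the organism starts near a healthy fixed point with few
defects (`e_g ≪ G`), interactions are linear in the defect counts,
defects do not disable the repair machinery itself (no error catastrophe
nonlinearity), and damage forces are constant once averaged over times
long compared with molecular turnover but short compared with the
lifespan. Mortality is read out linearly from the dysregulated-gene
fraction, `M(t) = ω·e_g/G`, interpreting `ω` as the essential-gene
fraction times a lethality rate.

`trace I = −(c+δ)` and `det I = cδ − βpGK`, so the two eigenvalues

```
λ₁,₂ = [ −(c+δ) ± sqrt((c−δ)² + 4pβKG) ] / 2
```

are always real (the discriminant is a sum of non-negative terms). The
slow eigenvalue changes sign exactly on the separatrix `βpGK = cδ`
(`R₀ = βpGK/cδ = 1`), which is also exactly where the near-separatrix
rate `Λ = (βpGK − cδ)/(c+δ)` changes sign: `λ₁λ₂ = det I` and
`λ₂ < 0` always, so `sign λ₁ = sign(βpGK − cδ)` with no tolerance. The
test suite asserts this sign identity over randomized sweeps rather than
treating it as approximate.

## Trajectories and the adiabatic reduction

`solve_dynamics` uses the closed-form modal solution
`x(t) = x* + Σᵢ (aᵢ·(x₀−x*)) bᵢ e^{λᵢt}` with `x* = −I⁻¹f`, where
`aᵢ, bᵢ` are biorthonormal left/right eigenvectors (`aᵢ·b_k = δ_ik`,
enforced to 1e−10). Two degenerate situations fall back to adaptive
numerical integration (LSODA, rtol 1e−10): repeated eigenvalues
(flagged, measure-zero) and a near-singular matrix
(`|det I| < 1e−12·‖I‖²`, i.e. on the separatrix, where `x*` diverges and
the closed form cancels catastrophically). Correctness is checked against
an independent high-order integrator (DOP853, rtol 1e−11) at 1e−6
sup-norm relative error.

`adiabatic_mortality` eliminates the fast mode and solves the remaining
scalar equation from a pristine start, `M(t) = (ωF₁/λ₁)(e^{λ₁t} − 1)`.
By default the slow rate is the **exact** eigenvalue `λ₁` and
`F₁ = (a₁·f)·b₁_g/G` the exact slow-mode force projection; the
`rate="near_separatrix"` option instead uses the textbook first-order
pair `Λ` and `F_tot = (βK f_p + c f_g)/(c+δ)`, identical to first order
in `Λ/(c+δ)`. The exact-rate default was chosen because the first-order
exponent error compounds over the five e-foldings of a lifespan: at
`(c+δ) = 100|Λ|` the `Λ`-form deviates by ~5% in sup-norm while the
exact-rate form stays at ~3e−5 (unstable) / 0.5% (stable). Accuracy is
measured as `max_t|ΔM| / max_t|M|` over the window `[0, 5/|Λ|]`, because
any one-mode reduction with a matched initial condition has an O(1)
pointwise error during the initial fast transient of duration
`~1/(c+δ)`; the sup-norm metric reflects what the reduction is for —
reproducing the hazard trajectory at demographic time scales. A warning
fires when `(c+δ) < 10|Λ|`.

## Demography

Only `(M₀, Λ)` are identifiable from mortality data, so the demographic
layer is parameterized by them directly; `from_model_params` provides the
forward map `M₀ = ωF_tot/Λ` (the model fixes `M₀` only up to an order-one
factor, hence it is free in fits). The hazard is taken literally as
`M(t) = M₀e^{Λt}` for demography and fitting, while the mechanistic
zero-initial-error form `∝ (e^{Λt} − 1)` lives in the core module; the
two coincide after the fast transient.

Closed forms: `S(t) = exp(−γ(e^{Λt}−1))` with `γ = M₀/Λ`; mean lifespan
`t_avg = Λ⁻¹e^γE₁(γ)` via the exponential integral (`scipy.special.exp1`;
for `γ > 700`, where `exp1` underflows, the asymptotic series
`1/γ − 1/γ² + 2/γ³` replaces it), with the Gompertz-limit approximation
`t_le ≈ Λ⁻¹ln(1/γ)` reported alongside. As `γ → 0`,
`Λ·t_avg + ln γ → −γ_EM` (Euler–Mascheroni), which the tests verify by
quadrature. A species is flagged "in the Gompertz limit" when
`γ < 0.1` (configurable); fruit flies sit at `γ ≈ 0.05`.

## Stress response

A short stress is an impulse: an instantaneous state increment `F_s` at
age `t₀` (a finite exposure of duration `τ` maps to `F_s ≈ f_s·τ`).
Projected amplitudes `sᵢ = aᵢ·F_s` evolve independently, giving the
stressed hazard `M(t) = M_ctrl(t) + Ω₁s₁e^{λ₁(t−t₀)} + Ω₂s₂e^{λ₂(t−t₀)}`
with mode mortality weights `Ωᵢ = Ω·bᵢ`. The Mortality Index over a
window `T` is computed exactly as `1 − exp(−∫M)` (adaptive quadrature) —
guaranteed to stay in [0, 1] for strong stresses — with the small-MI
split `Ω₁s₁(e^{ΛT}−1)/Λ + Ω₂s₂(1−e^{−ET})/E`, `E = c+δ`, reported
alongside for interpretation (fast- vs slow-mode shares).

For repeated trauma the package does not attempt to decompose the
per-strike susceptibility mechanistically: `χ` is an empirical composite
absorbing `Ω₁`, the per-strike defect yield, and the decay factor back to
birth age. The observables are `M(t,N) = (M₀+χN)e^{Λt}` and the mean
lifespan of the shifted Gompertz law.

## Inference

Individual event times are fitted by maximum likelihood rather than least
squares on binned log-hazards (binning noise dominates at fly-cohort
sizes; the binned per-cohort IMR diagnostic is still reported for
plotting). The Gompertz log-likelihood with right censoring is

```
ℓ(M₀,Λ) = Σ_deaths [ln M₀ + Λtᵢ] − Σ_all (M₀/Λ)(e^{Λtᵢ} − 1)
```

`M₀` has the closed-form profile maximizer
`M̂₀(Λ) = n_deaths·Λ/Σ(e^{Λtᵢ}−1)`, evaluated in log space
(`log-sum-exp` over `log(expm1)`) to survive `Λt` up to ~10³; the
remaining 1-D problem is solved by bounded Brent search on
`ln Λ ∈ [ln 1e−6, ln 10]` (per day, configurable). An estimate pinned to
a bracket edge — e.g. `Λ → 0⁺` on exponential data — is returned flagged
and non-converged, never silently. The constant-hazard MLE is
`M̄ = deaths/exposure`. Nonparametric bootstrap (resampling animals,
default 200 reps, seeded) supplies confidence intervals.

Regime classification compares AIC of the two hazard models; fewer than
100 deaths flags the verdict low-power. Because the Gompertz family nests
the constant hazard at the `Λ → 0` boundary, exponential data can favor
the constant model by at most ~2 AIC units (the one-parameter penalty),
while Gompertz data reject the constant model by margins that grow with
`n` (≈2200 at n=2000 under fly parameters); a decisive margin is
therefore only expected in the senescent direction.

The multi-cohort trauma fit shares `Λ` across cohorts and constrains the
cohort IMR to `M₀ + χN` (Nelder-Mead on `(ln M₀, ln Λ, χ)`, initialized
from the control fit and the naive per-cohort IMR slope). It requires a
control cohort (`N = 0`) and at least two strike levels — `χ` is
unidentifiable otherwise. Lifetables can be expanded to pseudo-individual
times by uniform spreading within bins (a documented approximation;
survivors of the last bin become censored rows).

## Synthetic data

The generators define the study conditions used throughout the tests:

* **Lifespans** — inverse-CDF draws `t = Λ⁻¹ln(1 − ln U/γ)` (Gompertz) or
  `−ln U/M̄` (constant), bit-reproducible per seed. Default demographic
  truth `(M₀, Λ) = (0.005, 0.1)/day` — the fly-like values implied by the
  default mechanistic parameters.
* **Trauma cohorts** — strike counts `{0,1,2,4,8}`, hazard
  `(M₀+χN)e^{Λt}` with `χ = 0.002/day/strike` in the reference
  experiments; cohort sizes of 2000/group give ~5% estimator spread.
* **Expressome panels** — the latent trajectory from a pristine start,
  sampled at six ages (5–30 days, mirroring a six-timepoint design with
  two groups), plus Poisson-timed impulse kicks along the fast mode
  (rate 1/day; size 1% of the mid-life slow-state norm) standing in for
  fast biological noise in the model's own impulse formalism, then a
  fixed Gaussian gene loading `L` (genes × 2) and i.i.d. read-out noise
  (`σ = 0.05`). The kick and noise scales are chosen for qualitative
  agreement with published PC plots of aging transcriptomes and are not
  anchored to any measured variance ratio.

What passing tests do and do not show: the panels are structural
stand-ins — linear-Gaussian read-outs with no count statistics, library
sizes, batch effects or gene-gene correlation beyond the two latent
modes — so the principal-axis results demonstrate the model's two-time-
scale geometry, not RNA-seq realism. Likewise the cohort generators draw
i.i.d. lifetimes from the exact model law; recovery rates measure
estimator behavior under the model, not robustness to heterogeneity,
frailty or measurement error, none of which are modelled.

## Problem sizes and numerical defaults

Randomized eigen-sweeps use 1000 draws (rates log-uniform over
`10^±[−2,1]`, `G ≤ 2000`); trajectory cross-checks use 100 random
instances over `t ≤ min(10, 5/|λ₁|)` days; recovery experiments use 100
replicates of n=5000 cohorts; classification checks use n=2000 cohorts.
These sizes give decisive margins (small binomial noise on a 95% pass
rate, AIC margins ≫ 10) while keeping the full suite in seconds.
Linearized-regime warnings fire when `e_g/G > 0.1` (configurable); the
warning threshold is advisory — values are never clamped.

## Known limitations

* No nonlinear defect-repair coupling, hormesis, or frailty: phenomena
  that are intrinsically nonlinear in the defect burden are out of scope.
* One expressome compartment; tissue-resolved or multi-omics extensions
  change the eigenstructure dimension but not the slow/fast dichotomy.
* `M₀` is only order-of-magnitude linked to the mechanistic forces; the
  mechanistic nine-parameter set is not identifiable from survival data
  and the package deliberately refuses to fit it.
* On the separatrix itself no two-parameter demographic summary exists
  (mortality grows linearly forever); `from_model_params` raises there.
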