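# genestab

Stability analysis of a minimal gene-regulatory-network model of aging,
linking network instability to the Gompertz mortality law, stress
resistance, and negligible senescence.

`genestab` is for quantitative biologists and biodemographers who want a
mechanistic, fit-able bridge between molecular damage dynamics and cohort
survival data: it simulates the model, derives its demographic
consequences, and recovers the identifiable parameters from event-time
tables by maximum likelihood.

## The model

An organism is reduced to two slowly varying defect counts: `e_p`, the
number of mis-produced expressome copies (proteins, transcripts,
metabolites), and `e_g`, the number of dysregulated genes out of a genome
of `G`. In the linearized regime (`e_g ≪ G`) the state `x = (e_p, e_g)`
obeys

```
de_p/dt = −c·e_p + p·e_g + f_p
de_g/dt = βKG·e_p − δ·e_g + G·f_g
```

where `p` is the (defective-)translation rate, `β` the regulatory
coupling, `K` the network connectivity (genes regulated per protein), `c`
the expressome turnover/repair rate, `δ` the DNA/epigenetic repair rate,
and `f_p`, `f_g` constant damage forces. All rates are per day. Mortality
is a linear readout of the dysregulated-gene fraction, `M(t) = ω·e_g/G`.

The 2×2 interaction matrix always has two real eigenvalues: a fast one,
`λ₂ ≈ −(c+δ)`, and a slow one whose sign is set by the **stability ratio**

```
R₀ = βpGK / (cδ)
```

* `R₀ > 1` — the network is unstable: regulatory errors compound at the
  rate `Λ = (βpGK − cδ)/(c+δ)`, the hazard grows as `M(t) = M₀e^{Λt}`
  (the Gompertz law, with mortality-rate doubling time `MRDT = ln2/Λ`),
  and the mean lifespan is `Λ⁻¹·e^γ·E₁(γ)` with `γ = M₀/Λ`
  (`≈ Λ⁻¹ln(1/γ)` in the Gompertz limit `γ ≪ 1`).
* `R₀ < 1` — the network is stable: the error burden and the hazard
  plateau at constant values, survival is exponential and
  age-independent — the negligible-senescence phenotype of naked mole
  rats, ocean quahogs and some turtles.

Acute stress (e.g. repeated traumatic strikes, `N` of them) injects a
defect impulse that splits across the two eigenmodes: the fast component
drives the short-term Mortality Index, while in an unstable network the
slow component never relaxes and permanently raises the initial mortality
rate by `ΔM₀ = χN`, shortening lifespan; a stable network recovers
completely.

## Worked example

```python
import genestab as gs

params = gs.ModelParams()          # fly-like defaults
rep = gs.stability(params)
print(f"regime: {rep.regime}   R0 = {rep.R0:.3f}   Lambda = {rep.Lambda:.3f}/day   MRDT = {rep.mrdt:.2f} d")

gp = gs.from_model_params(params)
ls = gs.mean_lifespan(gp)
print(f"M0 = {gp.M0:.4f}/day   gamma = {gp.gamma:.4f}   mean lifespan = {ls.t_avg:.1f} d")

tab = gs.simulate_lifespans(gp, n=5000, seed=1)
fit = gs.fit_gompertz(tab)
print(f"fit on n=5000 simulated deaths: M0_hat = {fit.estimates['M0']:.4f}"
      f"   Lambda_hat = {fit.estimates['Lambda']:.4f}")

chi = gs.StressSusceptibility(0.002)
tbi = gs.simulate_tbi_experiment(gp, chi, [0, 1, 2, 4, 8], 2000, seed=1)
res = gs.fit_stress_susceptibility(tbi)
print(f"trauma cohorts: chi_hat = {res.estimates['chi']:.5f}/day/strike"
      f"   IMR-vs-N R^2 = {res.diagnostics['imr_vs_N_r2']:.4f}")
```

prints

```
regime: unstable   R0 = 1.083   Lambda = 0.100/day   MRDT = 6.93 d
M0 = 0.0050/day   gamma = 0.0500   mean lifespan = 25.9 d
fit on n=5000 simulated deaths: M0_hat = 0.0048   Lambda_hat = 0.1011
trauma cohorts: chi_hat = 0.00202/day/strike   IMR-vs-N R^2 = 0.9986
```

The default parameter set sits just below the separatrix (`R₀ ≈ 1.08`),
giving the Gompertz exponent (`Λ = 0.1/day`), initial mortality
(`M₀ = 0.005/day`, so `γ = 0.05` — the fruit-fly value) and a ~26-day
mean lifespan. Simulating a 5000-fly cohort and refitting recovers both
demographic parameters to a few percent; the multi-strike trauma
simulation recovers the per-strike susceptibility `χ` and shows the
predicted linear rise of initial mortality with strike count.

The same pipeline is available from the shell (`genestab stability`,
`simulate-cohort`, `simulate-tbi`, `fit`, `tbi-analysis`,
`simulate-dynamics`, `expressome-demo`); see `genestab --help`.

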