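# jointvisit

Joint modelling of a Gaussian longitudinal marker, an **informative
visiting/observation process**, and **informative competing risks**, by full
marginal maximum likelihood.

## The problem

In electronic-health-record cohorts the times at which a marker (say CD4
count in people with HIV) is measured are not fixed by design: sicker
patients may visit more or less often, and death or disengagement from care
ends observation altogether.  Standard mixed-model analyses assume the
visit times carry no information about the marker; when visiting depends on
the *latent* marker trajectory (visiting not at random) or events are
informative (missing not at random), marker estimates from such analyses
are biased.

`jointvisit` fits a shared-parameter model for all three processes at once:

* **marker** — `Y_i(t) = X_i(t)'β + Z_i(t)'b_i + ε_i(t)`,
  `b_i ~ N(0, D)`, `ε ~ N(0, σ²)`, with latent value
  `m_i(t) = X_i(t)'β + Z_i(t)'b_i` and slope `m_i'(t)`;
* **visiting process** — proportional hazards for the gap time since the
  most recent visit, or a proportional intensity on calendar time:
  `h_v = h_v0(·) exp[γ_v'X̄_v + φ_v'g_v{Ȳ} + α_v1 m_i(0) + α_v2 m_i'(·)]`,
  optionally multiplied by a gamma frailty `w_i ~ Γ(1/η, 1/η)`;
* **competing risks** — cause-specific hazards
  `h_k = h_k0(t) exp[γ_k'X̄_k + φ_k'g_k{Ȳ} + α_k1 m_i(0) + α_k2 m_i'(t)]`.

The submodels condition on the *observed* marker and visit histories as
well as the shared random effects, so conditional independence between the
processes is not assumed.  Baselines are cubic B-spline log-hazards; the
random effects are integrated out by pseudo-adaptive Gauss–Hermite
quadrature using `b_i | Y_i` as importance density; estimation is BFGS with
an analytic score, inverse-Hessian standard errors, and matrix-log /
log-scale parametrisation of the variance components.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate from the gap-time study design (scenario I: visiting depends on
the last observed value, the time trend, the previous gap, and the latent
baseline value and slope), fit the correctly specified joint model, and
look at the association parameters and the derived population marker
value:

```python
import jointvisit as jv

scn = jv.scenario_I()                 # truths incl. beta = (17.20, 4.83, -2.80)
data = jv.simulate_dataset(scn, 200, seed=1)

model = jv.build_model(jv.scenario_model_config(scn, quad_nodes=5), data)
fit = model.fit(data)
tab = fit.summary_table().set_index("name")
for name in ("visit:phi(last_y)", "visit:alpha1(m0)", "visit:alpha2(slope)",
             "cause2:alpha2(slope)"):
    row = tab.loc[name]
    print(f"{name:22s} {row['estimate']:7.3f} (SE {row['se']:.3f})")
est, se = jv.derived_mean_marker(fit, model.marker_basis, 10.0)
print(f"mean marker at 10y     {est:7.2f} (SE {se:.2f})   truth 25.98")
print(f"loglik {fit.loglik:.1f}  AIC {fit.aic:.1f}  converged {fit.converged}")
```

Output from this exact script:

```
visit:phi(last_y)        0.021 (SE 0.008)
visit:alpha1(m0)         0.020 (SE 0.010)
visit:alpha2(slope)      0.245 (SE 0.026)
cause2:alpha2(slope)    -0.284 (SE 0.627)
mean marker at 10y       25.32 (SE 0.77)   truth 25.98
loglik -5556.3  AIC 11194.5  converged True
```

The fit recovers the generating associations — a one-unit higher latent
slope multiplies the visiting hazard by about `e^0.245 ≈ 1.28` (truth
`e^0.20`), i.e. the visiting process is correctly detected as informative
— and the derived 10-year population marker value covers the truth within
one standard error.  On any single dataset the ignore-the-visiting-process
comparison is noisy; its systematic upward bias (about +1 marker unit at
10 years under these truths) is a repeated-sampling statement, reproduced
by the simulation harness (`jointvisit simstudy`, and at reduced scale in
`tests/test_acceptance.py`).

## Command line

```bash
jointvisit simulate --scenario I --n 1000 --seed 7 --out data/
jointvisit fit --marker data/marker.csv --subjects data/subjects.csv \
               --config model.yaml --out fit.json
jointvisit simstudy --scenario I --model correct --reps 50 --n 300 --out study/
```

Scenario presets `I`, `II`, `I-frailty`, `II-frailty` and
`I-strong-marker` ship the study truths; `--model` chooses `correct`,
`ignore-visits`, `ignore-marker`, `no-frailty` or `enriched`.  Every
output embeds the resolved configuration and seed.

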