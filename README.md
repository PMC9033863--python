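# fedcox

One-shot, privacy-preserving inference for the **stratified Cox
proportional-hazards model** across multiple clinical sites, for
biostatisticians and clinical-research-network analysts who cannot pool
patient-level data.

## The problem and the method

Multi-center time-to-event studies (electronic health records, claims)
usually cannot share patient-level data. The standard workaround —
fitting a Cox model at each site and taking the inverse-variance weighted
average of the estimates (meta-analysis) — breaks down when events are
rare or sites are small: site-level estimates are unstable and the
weighted average becomes biased.

`fedcox` implements a one-shot distributed alternative (the ODACH
surrogate-likelihood approach) for the stratified Cox model, in which
site *j* has its own unspecified baseline hazard λⱼ(t) but the log hazard
ratios β are shared:

    λ(t | x_ij) = λ_j(t) · exp(β'x_ij)

The stratified log partial likelihood is the size-weighted average of
site likelihoods, L(β) = (1/N) Σⱼ nⱼ Lⱼ(β). The federated protocol has
exactly two communication rounds:

1. **Initialize** — each site sends its local estimate β̂ⱼ and variance
   V̂ⱼ; the coordinator forms the anchor
   β̄ = (Σ V̂ⱼ⁻¹)⁻¹ Σ V̂ⱼ⁻¹ β̂ⱼ (also the meta-analysis estimator).
2. **Derive** — each site sends ∇Lⱼ(β̄) and ∇²Lⱼ(β̄); the global
   derivatives are ∇ʳL(β̄) = (1/N) Σⱼ nⱼ ∇ʳLⱼ(β̄).
3. **Estimate** — a lead site, keeping its own patient-level data,
   maximises the surrogate likelihood

       L̃(β) = L₁(β) + ⟨∇L(β̄) − ∇L₁(β̄), β⟩
               + ½ (β − β̄)' [∇²L(β̄) − ∇²L₁(β̄)] (β − β̄)

   whose gradient and Hessian at β̄ equal the pooled stratified ones
   *exactly*. The maximiser β̃ tracks the pooled estimate far better than
   meta-analysis, especially at low event rates.

Only O(p²) aggregates ever cross a site boundary; message schemas are
closed so subject-level fields cannot be serialized.

The package also provides the pooled stratified fitter (the gold
standard, exact Newton–Raphson with Breslow ties), the meta-analysis
comparator, multi-lead synthesis, a heterogeneous Weibull multi-site
simulator with calibrated censoring, and a file-based CLI so the protocol
can be replayed as separate per-site invocations.

## Worked example

Simulate a 10-site federation (500 subjects/site, Weibull baselines with
scales 100–280 and shapes 20–0.5, true β = (−1, 1), 20% event rate), then
compare the three estimators:

```python
import numpy as np
import fedcox as fc

cfg = fc.SimulationConfig(event_rate_target=0.20, seed=7)
sites = fc.generate_multisite(cfg)

pooled = fc.fit_pooled_stratified(sites)          # gold standard
est, beta_bar, meta_vcov = fc.run_odach(sites)    # two-round protocol

print("pooled  beta_hat  :", pooled.beta_hat)
print("meta    beta_bar  :", beta_bar)
print("odach   beta_tilde:", est.beta_tilde, "lead:", est.lead_site_id)
```

Output:

```
pooled  beta_hat  : [-0.9758  1.1437]
meta    beta_bar  : [-0.9737  1.1387]
odach   beta_tilde: [-0.9758  1.1437] lead: site09
```

The surrogate estimate agrees with the pooled patient-level fit to four
decimals, although it never saw nine of the ten sites' data; the
meta-analysis anchor is close here because at a 20% event rate every
local fit is stable. Rerun with `event_rate_target=0.01` (≈5 events per
site) and the meta estimate drifts by around −15% relative to the pooled
one while the surrogate stays on top of it — the rare-event contrast the
benchmark quantifies.

The same protocol runs file-by-file from a shell (each command sees only
one site's CSV or aggregate JSON messages):

```sh
fedcox simulate --out-dir sim --n-sites 3 --n-per-site 200 --seed 2
fedcox fit-local sim/site01.csv init_site01.json          # at each site
fedcox combine init_*.json --out control.json             # coordinator
fedcox derive sim/site01.csv control.json deriv_site01.json
fedcox estimate sim/site01.csv control.json deriv_*.json --out est.json
```

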