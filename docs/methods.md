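# Methods

## Model and estimators

Site *j* (j = 1..K, nⱼ subjects, N = Σnⱼ) observes {Tᵢⱼ, δᵢⱼ, xᵢⱼ}:
follow-up time, event indicator and p covariates. The stratified Cox
model gives each site its own baseline hazard λⱼ(t) with shared log
hazard ratios β. The site log partial likelihood (normalised by nⱼ) is

    L_j(β) = (1/nⱼ) Σᵢ δᵢⱼ [β'xᵢⱼ − log Σ_{s∈Rⱼ(Tᵢⱼ)} exp(β'x_sⱼ)],

with risk set Rⱼ(t) = {s : T_sⱼ ≥ t} (a subject enters its own risk set;
a subject censored exactly at an event time is at risk). The pooled
(gold-standard) estimator maximises L(β) = (1/N) Σⱼ nⱼLⱼ(β); risk sets
never cross sites.

Three estimators are implemented:

- **Pooled**: Newton–Raphson on L(β) with patient-level data from all
  sites.
- **Meta-analysis**: β̄ = (Σ V̂ⱼ⁻¹)⁻¹ Σ V̂ⱼ⁻¹ β̂ⱼ over sites whose local
  fit converged, with combined variance (Σ V̂ⱼ⁻¹)⁻¹.
- **Surrogate (ODACH)**: the lead site maximises
  L̃(β) = L₁(β) + ⟨∇L(β̄) − ∇L₁(β̄), β⟩ + ½(β−β̄)'[∇²L(β̄) − ∇²L₁(β̄)](β−β̄),
  where the global derivatives are assembled distributively as
  ∇ʳL(β̄) = (1/N) Σⱼ nⱼ∇ʳLⱼ(β̄). By construction ∇L̃(β̄) and ∇²L̃(β̄)
  equal the pooled score and Hessian exactly (tested to machine
  precision), so the surrogate is a second-order-correct proxy of the
  pooled likelihood anchored at β̄.

## Numerical choices

- **Ties**: Breslow convention. The denominator at a tied event time
  includes all tied subjects; each event contributes its own term. The
  simulator draws continuous times, so ties occur with probability zero
  there; the convention matters only for real data.
- **Risk-set evaluation**: one ascending sort per likelihood call plus
  cumulative sums; S(t) = total − prefix(T < t) via `searchsorted`, which
  handles ties without special cases. Linear predictors are clipped at
  ±700 before exponentiation so line-search excursions cannot overflow.
- **Optimizer**: damped Newton–Raphson, initial step 1, halved up to 20
  times until the concave objective is non-decreasing; default tolerance
  1e−8 on the score max-norm, max 100 iterations, zero initial vector
  (the surrogate fit starts from β̄). Convergence additionally requires
  the Newton increment max-norm ≤ √tol: under monotone likelihood
  (separation) the gradient decays to zero along the divergence path
  while the increment stays O(1), and the increment check is what
  distinguishes a flat maximum from a runaway one. Such fits are
  reported `converged=False` with no variance and are excluded from the
  inverse-variance combination (they would enter a standard software fit
  with an enormous variance and near-zero weight; excluding them is the
  same limit).
- **Variance scales**: Lⱼ is normalised by 1/nⱼ, so the local observed
  information is −nⱼ∇²Lⱼ(β̂ⱼ) and V̂ⱼ = [−nⱼ∇²Lⱼ(β̂ⱼ)]⁻¹, matching a
  standard Cox fit. The surrogate variance is [−N·∇²L̃(β̃)]⁻¹, treating
  the surrogate as the full-data likelihood; this is approximate (it
  ignores the variability of β̄ and of the transmitted derivatives) and
  is flagged as such. Wald 95% intervals use ±1.96·se.
- **Lead site**: default is the largest site *among sites with at least
  one event* (a lead without events has a degenerate L₁); ties are
  broken by event count, then input order. Any site can be forced by
  flag, and per-lead estimates can be synthesised by inverse-variance
  weighting (`multi_lead_synthesize`) — the same weighting as the
  anchor, chosen for symmetry since no canonical rule exists.
- **Degenerate sites**: a site with zero events contributes Lⱼ ≡ 0; it
  cannot be fit locally but still sends (zero) derivative messages and
  its nⱼ still enters the weights, so it participates in the protocol
  without special-casing.
- **Staleness guard**: derivative messages echo the anchor they were
  evaluated at; aggregation and the estimate command refuse mixed
  anchors rather than silently combining inconsistent rounds.

## The simulator

The generator draws, per site, covariates xᵢⱼ ~ i.i.d. Uniform(0,1)² and
event times from the Weibull proportional-hazards inverse CDF
T = scale·(−log U/exp(β'x))^(1/shape), with site parameters interpolated
across sites: scales linearly from 100 to 280, shapes geometrically from
20 to 0.5. The defaults are the benchmark's study conditions: K = 10
sites × 500 subjects, β = (−1, 1), 200 replications, event rates 20%, 2%
or 1%.

- **Covariate law**: "uniform" pins neither support nor scale; the
  package uses the conventional Uniform(0,1). This choice matters — see
  the caveat below.
- **Censoring**: per-site exponential C ~ Exp(θⱼ). θⱼ is calibrated by a
  bracketed root finder on the closed-form Monte-Carlo objective
  E[exp(−θT)] = target (10⁵ fixed draws per site, tolerance 0.002); the
  objective is strictly decreasing in θ, from 1 at θ = 0. Per-site
  calibration keeps the event rate balanced across sites, so at 1% every
  site sits in the ~5-event regime that destabilises local fits. A
  per-site administrative cutoff (fixed follow-up time at the target
  quantile) is available as a config switch.
- **RNG discipline**: one master `SeedSequence` spawns per-replication
  children, which spawn per-site streams; adding replications or sites
  never perturbs existing draws, and fixed seeds make the whole
  benchmark bit-reproducible.
- **Benchmark**: per replication, the pooled fit, the meta combination of
  local fits, and the full two-round protocol (largest site as lead) are
  computed; relative bias is (estimate − pooled)/pooled × 100 per
  component, following the convention that the pooled fit is the gold
  standard. Replications with a failed pooled fit are dropped and
  counted (none occur at the default settings).

What the generator does *not* emulate: site-specific covariate
distributions or effect sizes, dependent censoring, discrete/tied event
times, missing data. Passing benchmarks therefore demonstrate the
protocol's accuracy under clean proportional hazards with heterogeneous
baselines, not robustness to those real-data features.

## Benchmark behaviour and a known caveat

At a 20% event rate all three estimators agree closely and the pooled
fit recovers β = (−1, 1) within Monte-Carlo error. As events become rare
the meta-analysis estimator drifts below the pooled one (site-level
estimates are unstable and inverse-variance weights correlate with
them), while the surrogate estimator stays on top of the pooled fit: at
1% the mean absolute gap |meta − pooled| is ~0.15 on a true effect of 1,
versus ~0.005 for the surrogate, and the surrogate's relative-bias IQR
is one to two orders of magnitude smaller than meta's at every rate.

Caveat: with Uniform(0,1) covariates, a 1% event rate leaves ~50 events
in N = 5000, so the pooled β̂₂ has Monte-Carlo sd ≈ 0.6 and occasionally
lands near zero. The *mean* relative bias — a ratio with that estimate
in the denominator — is therefore heavy-tailed and unstable across
seeds, while the median and IQR are stable (meta median ≈ −14 to −17%).
A more dispersed covariate law would concentrate the denominator and
stabilise the mean; since the exact law behind the reference design is
unspecified, the package keeps the conventional choice and reports both
mean and median.
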