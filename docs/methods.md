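# Methods

## Model

Activated rhodopsin (R\*) is modelled as a continuous-time Markov chain on
active states 1…n+1 (state k holds k−1 phosphates) plus an absorbing
arrestin-bound state n+2. Thermal decay of R\* to opsin is excluded: it acts
on a far longer time scale than the ≤3 s horizon simulated here, so genotypes
that cannot reach the arrestin-binding threshold (0P–2P, arrestin knockout)
simply remain active to the horizon and their paths are reported as censored.

The chain is a pure birth process with killing, so all its first-passage
statistics have product closed forms, which the analytic layer uses directly
rather than deriving them from the ODE solution:

- branch probabilities qₖ = λₖ/(λₖ+μₖ) (phosphorylation) and
  pₖ = μₖ/(λₖ+μₖ) (capture); states with zero exit rate get qₖ = pₖ = 0;
- visit probabilities Pr(visit k) = ∏_{j<k} qⱼ;
- step law P(M=m) = Pr(visit m)·p_m, with the *deficit* 1 − ΣP(M=m) the
  probability of never shutting off (exactly 1 for 0P–2P and arrestin KO);
- expected lifetime T = Σₖ Pr(visit k)·τ̄ₖ with τ̄ₖ = 1/(λₖ+μₖ). Infinite
  sojourns are represented by `inf`, never a large float, so downstream code
  must branch explicitly.

The closed-form CV of the total integrated activity,
CV = sqrt(Σ(νₖτ̄ₖ)²)/Σνₖτ̄ₖ, is evaluated over **all active states** by
default; a fixed-step-count variant (sum truncated at m states) is available
for comparison against fixed-step ensembles. The all-states form is the one
that reproduces the reference theoretical values 0.56/0.54/0.52/0.51 for
3P–6P under the slow preset, and is only defined when shutoff is certain
(≥3 sites with arrestin present); anything else raises `NoShutoffError`.

## Parameters

| symbol | meaning | slow | fast | units |
|---|---|---|---|---|
| ω | base per-site phosphorylation rate | 10.5 | 19 | 1/s |
| μ | saturated arrestin rate | 60 | 120 | 1/s |
| ν₁ | activity of unphosphorylated R\* | 330 | 500 | eff./s |
| k_ν | activity decay per phosphate | 0.5 | 0.5 | – |
| τ_R | effective WT lifetime target | 75 | 41 | ms |

The two presets correspond to the two experimental estimates of the WT R\*
lifetime; the fast-preset ν₁ = 500 s⁻¹ encodes transducin activation every
2 ms. The arrestin threshold (3 attached phosphates) is hard-wired as the
default but exposed as `mu_threshold` for sensitivity exploration. The
`calibration` module reproduces the derivations: k_ν = ln(10)/6 ≈ 0.384 from
the saturated-depletion datum (the presets adopt 0.5, the value retained
after wider consistency analysis of the photoresponse data); μ from ω via a
bracketed root-solve of the expected-lifetime formula (the expected lifetime
falls monotonically in μ from ∞ to the 3-phosphorylation floor Σ_{k≤3}1/λₖ);
and the arrestin-KO plateau/peak fraction as a consistency check on the
terminal activity ν₇ = ν₁e⁻³.

## Numerics

- **Master equation.** Default propagation is by the matrix exponential of
  the constant generator (n ≤ 8 states), exact up to floating point and
  probability-conserving to machine precision; repeated grid steps reuse the
  cached exponential. A stiff ODE route (LSODA, rtol 1e-8) is kept as an
  independent cross-check and is validated against the exponential in tests.
- **Mean effector.** dĒ/dt = Σνₖ Pₖ(t) − k_E Ē is integrated with an exact
  exponential step for a drive linearly interpolated between grid points;
  it therefore needs the drive sampled on a fine grid (1 ms is the reporting
  default) to be accurate.
- **Per-path effector.** Between jumps the drive is constant, so E\*(t) is
  evaluated from the piecewise-exponential closed form; no quadrature.
- **Photocurrent.** Fixed-step RK4 with sub-steps capped at 0.25 ms,
  vectorized across trials; the integrator raises with a parameter echo if
  the state diverges. ΔJ/J is clipped only through the channel Hill term
  (cG floored at 0); in practice the state stays strictly positive.
- **Sampling.** Trial i of an ensemble uses
  `SeedSequence(seed, spawn_key=(i,))`, so ensembles are bit-reproducible
  and independent of execution order. "Integer closest to the mean" for the
  fixed-step regime rounds half away from zero; none of the shipped N values
  (4.45, 4.41, 4.30, 4.15, 4) sits on a tie.
- **CV reporting.** CV is set to exactly 0 when the SD is below a 1e-9
  relative floor (deterministic functionals); the Monte-Carlo SE of each CV
  is a 1000-resample nonparametric bootstrap.

## Randomness regimes

- **Case 1** — step count fixed at round(N), sojourns exponential.
- **Case 2** — sojourns fixed at τ̄ₖ, step count drawn from P(M=m).
- **Case 3** — both random (the biologically realistic regime).

For genotypes that never shut off, Cases 1 and 2 are defined as full
traversal of all available states (random or fixed sojourns respectively)
with no binding event — the only reading under which those genotypes have
well-defined fixed-step ensembles. An exact enumeration oracle
(`case2_cv_exact`) gives the Case-2 CV of the total integrated activity in
closed form and pins the Monte-Carlo estimate in tests.

## The downstream surrogate and what it can and cannot show

The reference transduction stage is a 3-D spatio-temporal diffusion model;
this package deliberately replaces it with a well-mixed ODE surrogate:
hydrolysis β_d + β_e·E\* acting on cGMP, a Ca²⁺-inhibited cyclase
(Hill m_cyc around K_ca), current ∝ cG^n_ch, Ca²⁺ influx proportional to the
current with first-order clearance, and dark-state consistency enforced by
construction. Geometry enters through the relative outer-segment volume:
shortening the segment at fixed channel count scales the effector coupling
by inverse volume, which is what makes the shortened-segment 0P\* response
exceed the full-length 0P response.

The surrogate's constants are not taken from the reference parameter table
(not available in the extracted source); they were chosen once against the
documented calibration constraints — wild-type peak suppression ≈5 % in the
0.1–0.2 s range and an arrestin-KO plateau near half its peak — and frozen:
k_E = 3.5 s⁻¹, β_d = 4.1 s⁻¹, β_e = 0.0364 s⁻¹ per effector unit,
cG_dark = 6 µM, Ca_dark = 0.25 µM, Ca_min = 0.023 µM, K_ca = 0.135 µM,
m_cyc = 1.5, n_ch = 2, γ_Ca = 25 s⁻¹. With these defaults the WT slow
response peaks at 5.0 % at 172 ms and the arrestin-KO plateau sits at 0.44
of its peak.

Consequences: absolute current amplitudes, areas and current-level CV values
are surrogate-dependent and are asserted only as orderings and inequalities
(peak, time-to-peak and area monotone in the number of sites; knockout
partial recovery to a sustained plateau; current-level CVs below their
effector-level counterparts). One inequality deserves a caveat: the CV of
the *per-trial peak amplitude* is not suppressed below the pointwise
effector CV by a well-mixed stage — spatial diffusion, which the surrogate
omits, is the published suppressor for that functional. The suppression
inequalities are therefore asserted for the corresponding pairs
(ΔJ/J at t̄ vs E\*(t̄); SPR area vs total integrated activity), which hold
robustly here.

The expected average activity over a lifetime (the expectation of the ratio
Σνₖ Tₖ / ΣTₖ) has no simple closed form; it is shipped as a seeded
vectorized Monte-Carlo estimate with standard error, with the ratio-of-means
first-moment approximation available as an option.

## Problem sizes

Default ensembles use 5000 trials over a 3 s horizon (the canonical
configuration of the CV table). Oracle-equivalence tests use 2×10⁴–5×10⁴
paths, current-level CV comparisons 400 trials, and the average-activity
Monte-Carlo 10⁵–10⁶ paths; these sizes put every 3-SE comparison comfortably
inside its tolerance while keeping the full suite around a minute.

## Known limitations

- No thermal decay of R\*, no site identity or ordered phosphorylation
  (sites are exchangeable by construction), no time-inhomogeneous rates.
- The downstream stage is deterministic given the R\* path: channel noise
  and diffusional fluctuations are not modelled.
- Censored functionals (0P–2P, arrestin KO) depend on the horizon by
  construction; CVs for those genotypes reflect only pre-horizon randomness.
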