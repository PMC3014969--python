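# Methods

## Model and assumptions

The package describes the two effectors of an allosteric, product-activated
enzyme (the motivating system is yeast phosphofructokinase, substrate ATP,
product/activator ADP) in dimensionless form: substrate α = ATP/K_M,
product γ = ADP/K_P, time in units of the product consumption rate 1/k_d,
length in units of the activator diffusion length √(D_ADP/k_d).  The local
kinetics is substrate supply at rate ν, conversion at rate σφ(α, γ) and
linear product removal; diffusion enters only through the ratio
δ = D_ATP/D_ADP (diagonal diffusion matrix — cross-diffusion and
concentration-dependent diffusivities are out of scope).  The unified rate
law

    φ = α(ε + γ)ⁿ / (L + (1 + α)(ε + γ)ⁿ)

covers the sequential MWC mechanism (ε = 1, allosteric constant L > 1,
with n + 1 partially liganded active states whose binomial weights produce
the (1 + γ)ⁿ factor) and the Hill/Sel'kov mechanism (ε = 0, L = 1, the
infinite-affinity limit in which only the fully liganded state is
populated).  A state-enumeration implementation of the MWC fractional
saturation (explicit binomial sums over the R_lm states) is kept as an
exact cross-check of the closed form.  Substrate binding is hyperbolic
(no substrate cooperativity, no ATP inhibition of the enzyme), which is
what makes the two mechanisms directly comparable.

Interpolation between mechanisms rescales the product-binding affinity,
K_P → εK_P.  The rate law of the interpolated model carries the effective
allosteric constant L_eff = ε(L − 1) + 1 in its L slot (the true allosteric
constant of the underlying MWC scheme is L_eff/εⁿ, which diverges as
ε → 0).  ε = 0 with L ≠ 1 is rejected: the Hill model is the *limit* of
the family, approached uniformly on compact concentration boxes only once
ε ≪ 1/(L − 1).

The low-glycolytic-flux variant (φ ≈ α(ε + γ)ⁿ/L, valid when γ_sⁿ ≪ 1 for
Hill or (1 + γ_s)ⁿ ≪ L for MWC) is a first-class model (`flux_mode`), with
the 1/L factor absorbed into a rescaled maximal rate σ̄ = σ/L.  It is a
user choice, never switched automatically: no quantitative validity
threshold for the approximation is imposed, and keeping it explicit lets
the closed-form amplitude-equation coefficients be tested as exact
identities on the model they belong to.

## Steady state and linear stability

γ_s = νq always; α_s = ν/(σ − ν)·(1 + L/(ε + νq)ⁿ) (full) or
ν/(σ̄(ε + νq)ⁿ) (low flux), requiring σ > ν.  Stability of (α_s, γ_s)
against exp(ikx + λt) perturbations reduces to
λ² + a₁(k)λ + a₀(k) = 0 with

    a₁ = k²(1 + δ) + 1 − qB + A,
    a₀ = δk⁴ + k²(δ(1 − qB) + A) + A,

where A = −∂f_α/∂α and B = −∂f_α/∂γ at the steady state.  In closed form,
with the saturation ratio Λ = L/(ε + νq)ⁿ,

    A = (σ − ν)²/(σ(1 + Λ)),
    B = (σ − ν)ν/σ · nΛ/((ε + νq)(1 + Λ)).

Λ is deliberately named differently from L_eff above — both play the role
of an "effective" allosteric constant in different contexts but are
different quantities.

The Hopf condition a₁(0) = 0 is quadratic in σ, σ² − 2rσ + s = 0 with

    r = ν + ½(Λ[((n−1)νq − ε)/(ε + νq)] − 1),   s = ν²(1 + Λnq/(ε + νq)),

giving an oscillatory window (σ_lo, σ_hi); the Hopf frequency is
ω_H = √A.  All amplitude-equation expansions and phase diagrams use the
*upper* root, which is the one the reference simulation σ values sit just
below; the lower root is retained as the lower window edge.  In low-flux
mode the condition is linear in σ̄ (single threshold,
ω_H² = (νq(n−1) − ε)/(νq + ε)); a monomer (n = 1) never oscillates.

The Turing locus is T = [δ(qB − 1) − A]² − 4δA = 0 with critical
wavenumber k_c² = [δ(qB − 1) − A]/(2δ).  At σ_hi the identity qB − 1 = A
collapses the two conditions into the codimension-2 closed form
δ_TH = (A + 2 + 2√(A + 1))/A, monotone decreasing in A: higher
cooperativity needs less diffusive scale separation (δ_TH ≈ 2.1 for the
Hill octamer, ≈ 4.2–4.3 for the MWC octamer).  Every closed form here is
paired in the test suite with a blind numerical oracle (bisection on
a₁(0), two-dimensional root solving in (σ, δ)) at 1e-8 relative tolerance.
Degenerate inputs (σ ≤ ν, no Hopf) raise explicit errors rather than
returning NaN.

## Amplitude-equation reduction

Near the supercritical Hopf point the dynamics maps to the CGLE
∂tA = (1 + ic₁)∇²A + A − (1 + ic₃)|A|²A.  The Jacobian at σ_hi is
J = [[−A, −(1+A)/q], [qA, A]]; the eigenvector gauge is fixed to

    u0 = ((−1 + i/ω)/q, 1),    u0* = ½(−iqω, 1 − iω),

which satisfies J·u0 = iω·u0, u0*·J = iω·u0*, u0*·u0 = 1 exactly and
reproduces the closed form c₁ = ω(δ−1)/(δ+1) from the defining ratio
c₁ = Im(u0*Du0)/Re(u0*Du0), D = diag(δ, 1).  Both c₁ and c₃ are ratios and
therefore gauge independent (property-tested with random complex gauge
factors).

c₃ = Im(g)/Re(g) is assembled from explicit small-tensor contractions
(numpy einsum over 2 species components and ≤ 3 concentration indices) of
the second- and third-order partials of (f_α, f_γ): M = ½∂², N = ⅙∂³,

    g = −2 u0*·M(u0, V0) − 2 u0*·M(ū0, V+) − 3 u0*·N(u0, u0, ū0),
    V0 = −2 J⁻¹ M(u0, ū0),    V+ = −(J − 2iω I)⁻¹ M(u0, u0).

(J − 2iωI) is never singular since the eigenvalues of J are ±iω.  The
partials are hand-derived closed forms of the rational φ (chain rule
through u = (ε+γ)ⁿ), verified once symbolically during development and
continuously against central finite differences in the tests; runtime
never differentiates numerically or symbolically, because c₃ needs
third-order accuracy.  In the low-flux regime c₃ collapses to the
polynomial form

    c₃ = [P₂(νq)² + εP₁(νq) + ε²P₀] / [P₃(νq + ε)ω_H],
    P₀ = 9n−3, P₁ = −9n²+13n−6, P₂ = 2n³−5n²+6n−3,
    P₃ = 3(n−1)²νq − 3ε(n−3),

which the tensor reduction matches to ~1e-15 across (n, ε, νq); for ε = 0
both coefficients are independent of νq.  The full model at L = 10⁶
agrees with the low-flux form to ~0.02%.

Regime classification: Turing preemption (δ ≥ δ_TH) takes precedence, then
Benjamin–Feir instability (1 + c₁c₃ < 0), then wave direction by the sign
of c₁ − c₃ (inward if positive) with a 1e-9 absolute boundary band —
callers needing wider bands should inspect the raw coefficients.  The
sign convention of the (c₁, c₃) pair is anchored by the fixed gauge; its
correctness is arbitrated by the simulated wave directions of the
reference panels (outward spirals for the MWC model at δ = 1, inward at
δ = 3).

## Phase diagrams

Curves are traced by bisection in δ (tolerance 1e-8, default bracket
[0.25, 16] expanded on demand) of the defining functions δ − δ_TH (TH),
c₁(δ) − c₃ (AS) and 1 + c₁(δ)c₃ (BF), with σ re-solved to the upper Hopf
root at every sweep point.  Sweep axes: ε ∈ [0, 1] in low-flux mode
(mechanism interpolation at fixed ν, q, n — the n = 8, ν = 0.5, q = 1
configuration shared with the simulation panels) and γ_s = νq via ν in
full mode (fixed q, L, n).  Points without a Hopf root or without a sign
change are omitted and logged, never interpolated.  Grid default is 101
points per axis.  The resulting structure: for ε = 1 the AS curve lies
below TH (inward waves observable in the oscillatory regime); by ε ≤ 0.1
it has crossed above TH (inward waves preempted by stationary patterns);
BF exists only for small ε at δ < 1.  The Hill overlay evaluates n_H and
its analytic derivative on the γ_s grid and locates the interior maximum
by bounded scalar maximization; the anti-spiral region falls on the rising
flank (dn_H/dγ_s > 0), a structure that is robust under L ∈ {10², 10⁴} and
q ∈ {0.1, 10}.

## Simulation

Method of lines on an N × N grid: five-point Laplacian with cell-centered
mirror (no-flux) boundaries and classical fixed-step RK4.  The mirror
(edge-duplicating) ghost cells make the discrete operator exactly mass
conserving; its 1D eigenmodes are cos(πm(j+½)/N) with decay rate
(2/dx²)(1 − cos(πm/N)), which the tests verify against pure-diffusion
integration.  A conservative stability guard dt ≤ 0.2dx²/(4 max(δ,1)) can
be overridden because the reference integrator settings are authoritative
for the presets.  Negative or non-finite concentrations abort the run: the
exact dynamics preserves positivity, so a violation indicates an unstable
step, and clipping would silently change the model.

Initial conditions: per-cell uniform multiplicative noise
field·(1 + a(2r−1)) with a = 0.05 (seeded, reproducible), or crossed
linear gradients α ∝ (1 + κ(2x/N − 1)), γ ∝ (1 + κ(2y/N − 1)) that seed a
single phase defect (spiral core); κ = 1/70 for the spiral panels, 2/3 for
the large-amplitude Hill spiral panel.  The recorded space-time slice
defaults to the horizontal mid-row; snapshots are taken at a fixed
cadence.  The dimensionless domain side is l_s = dx·N/√δ.

### Diagnostics

Classification uses the space-time slice.  Spectral and phase metrics use
the second half of the record; the stationary-versus-oscillatory decision
uses the final quarter, because a Turing mode can coexist with a weakly
unstable Hopf mode and outgrow it only late in the run (the δ = 5 MWC
panel).  A run is *stationary* when the residual temporal amplitude falls
below 0.15 of the spatial pattern amplitude of the final snapshot.
Otherwise the per-cell Fourier amplitude at the dominant shared frequency
defines a spatial phase field; waves are *coherent* when the local
phase-gradient alignment |Σ Z_{x+1}Z̄_x|/Σ|Z_{x+1}Z̄_x| ≥ 0.85, else
*irregular*.  Propagation direction comes from the traveling-wave identity
v = −⟨s_t s_x⟩/⟨s_x²⟩ evaluated relative to the core (the minimum of the
smoothed oscillation-amplitude profile, where a spiral's phase singularity
pins the amplitude), energy-weighted and with the core and 5% edges
excluded; positive means outward.  The dominant wavelength is the peak of
the radially binned 2D power spectrum of the final snapshot; for the
stationary panels it agrees with the linear prediction 2π/k_c within 30%.
The thresholds (0.15, 0.85) were chosen to separate the reference-panel
phenotypes with margin and are package constants, not physical claims.

### Presets, scaled runs and known limitations

The registry `fig3A`–`fig3F` carries the reference panel conditions
(δ, σ, dx, dt, t_end, IC; N = 176).  Tests and the scaled acceptance runs
use N = 88 at the same dx (half the domain), which preserves all panel
phenotypes that are locally determined; grid refinement (dx/2, dt/4,
N doubled) leaves the anti-spiral panel's classification unchanged.

Two limitations are inherent to the Hill-mechanism panels at σ = 1770 and
are reported rather than glossed over:

* **Stiffness.**  Once the relaxation amplitude develops, local reaction
  rates reach ~1.7·10³ per time unit and the reference dt = 0.05 violates
  positivity within a few time units.  Panels A and B therefore run at
  dt = 10⁻³ (the largest RK4-stable step, exposed via
  `preset(..., stable_dt=True)`); this is a numerical-accuracy choice, not
  a change of the study conditions.
* **Basin escape.**  The Hopf bifurcation at σ_hi ≈ 1791 is supercritical
  but its limit cycle at σ = 1770 is small, and the panel-A/B initial
  amplitudes (5% noise; κ = 2/3 gradients) exceed its basin.  The ensuing
  relaxation excursion locally quenches γ (the γⁿ activation shuts the
  reaction off) while α loads at rate ν; at dx = 3 activator diffusion
  lengths the quenched cells are diffusively decoupled, and the accurate
  solution freezes into pinned localized spikes instead of sustained
  spatio-temporal chaos (A) or an outward spiral (B).  On a resolved grid
  (dx = 1) the same conditions instead relax to a nearly homogeneous
  coherent oscillation.  The two panels' simulated phenotypes are
  accordingly classified *stationary* by the diagnostics, and the
  corresponding phenotype assertions in the acceptance tests fail by
  design rather than being weakened; the amplitude-equation route
  (c₁ − c₃ < 0: outward) is unaffected and passes.  The synthetic panels
  exercise the integrator and classifier on idealized ICs and cannot
  establish what a physical extract with intrinsic noise and unresolved
  microscale mixing would do in this regime.

All randomness flows through a single recorded integer seed
(numpy `default_rng`); reruns with the same configuration are bitwise
reproducible, and the CLI writes a config digest alongside every
simulation archive.
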