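# Methods

## Models

`epibim` simulates two Itô SDE systems from mathematical epidemiology on
bounded, biologically admissible domains.

**Stochastic SIR with disease deaths.** With contact rate β, recovery rate α,
disease death rate γ, natural birth/death rate μ and carrying capacity K,

    dS = (−βSI + μ(K−S)) dt − SI·F1(S,I,R) dW1
    dI = (βSI − (α+γ+μ)I) dt + SI·F1(S,I,R) dW1 − I·F2(S,I,R) dW2
    dR = (αI − μR) dt + I·F2(S,I,R) dW2

on the prism D = {S > 0, I ≥ 0, R > 0, S+I+R ≤ K} ⊂ R³.

**Stochastic SIS** (recovered return to the susceptible class):

    dS = (−βSI + μ(K−S) + αI) dt − SI·F1 dW1 + I·F2 dW2
    dI = (βSI − (α+γ+μ)I) dt + SI·F1 dW1 − I·F2 dW2

on the triangle D = {S > 0, I ≥ 0, S+I ≤ K} ⊂ R².

The diffusion rate functions F1 (transmission channel) and F2 (recovery
channel) are arbitrary locally Lipschitz state functions — the "variable
contact diffusion rate" generality.  The noise structure is conservative:
each noise column moves mass between two compartments, so the total
population N obeys the ODE N' = μ(K−N) − γI in both models and the noise
cancels in N exactly.

Key derived quantities: the basic reproduction number R0 = βK/(α+γ+μ); the
disease-free equilibrium (K, 0[, 0]); and, for R0 > 1, the endemic
equilibria (K/R0, μK/(γ+μ)(1−1/R0)) for SIS and
(K/R0, μ/β(R0−1), α/β(R0−1)) for SIR.

## The balanced implicit method

Standard explicit schemes (Euler–Maruyama, Milstein) do not keep discrete
trajectories inside D: a single large increment can drive I negative or the
total above K.  The balanced implicit method (BIM) adds a scalar diagonal
damping term c(Yₙ)(Yₙ − Yₙ₊₁) with c(Yₙ) = Aₙ·Id and weight

    Aₙ = (α+γ+μ+βIₙ)Δₙ + K·|F1(Yₙ)ΔWₙ¹| + (K/Rₙ)·|F2(Yₙ)ΔWₙ²|     (SIR)

(SIS replaces K/Rₙ by K/Sₙ).  Solving the implicit relation gives the closed
form actually iterated:

    Yₙ₊₁ = Yₙ + (f(Yₙ)Δₙ + g(Yₙ)ΔWₙ) / (1 + Aₙ).

The weight is engineered so that each updated coordinate is a sum of
manifestly nonnegative terms: the update is invariant with respect to D for
*every* step size and *every* increment realization, with no clipping,
projection or noise truncation anywhere.  I = 0 is exactly absorbing for the
I coordinate (every I-increment carries a factor Iₙ), and the total obeys
the damped renewal identity Nₙ₊₁ = Nₙ + Δₙ(μ(K−Nₙ) − γIₙ)/(1+Aₙ).

Theoretical guarantees computed/verified by the package: V-stability with
V(y) = 1+‖y‖² and constant K1 = L3 + (L3²+L4²)/2; mean-square contractivity
of the exact flow with constant K2 = 2|L1| + L2²; mean consistency of local
order 1.5 and mean-square consistency of local order 1.0; mean-square Hölder
continuity with exponent 0.5; and global strong (L²) convergence of order
0.5.  The Lipschitz/growth constants L1..L4 and the derived constants a, b,
c3, K4, K5 are evaluated from the printed closed forms in
`stability_constants_sir`.  These bounds are *loose* by construction; the
empirical tests assert one-sided inequalities against them, never equality.

Two bookkeeping notes. The contractivity constant is stored in the theorem
form 2|L1|+L2², although the Gronwall exponent in the underlying derivation
reads 2L1²+L2²; the discrepancy is inherited and recorded, not resolved.
The constants c3, K4, K5 contain exp(3(L3²+L4²)) and relatives; for
realistic epidemic magnitudes (K in the hundreds) these are mathematically
finite but overflow double precision and are reported as `inf`.  Tests of
these constants use small synthetic parameter sets where everything is
representable.

## Numerical choices

* **No solver.**  The implicit relation is never solved iteratively; the
  closed form is exact.  `implicit_residual_*` exists only as a verification
  oracle (residual ≤ 1e−10 relative at random states, step sizes and
  increments).
* **Domain boundary.**  The membership test accepts the closed boundary
  (S, R ≥ 0) so the disease-free equilibrium is a member; strict positivity
  of the divisor coordinate (R for SIR, S for SIS) is enforced where the
  weight needs it.  The cap N ≤ K carries a 1e−12 relative roundoff
  tolerance; all other comparisons are exact.
* **Update grouping.**  Each coordinate update is computed as
  `x + (numerator)·damping` with the noise transfers n1 = SI·F1·ΔW1 and
  n2 = I·F2·ΔW2 computed once and reused with opposite signs, so the noise
  cancels *exactly* in floating point in the population identity.
* **Indicator rates.**  The indicator-gated fixtures (1{S>I}, 1{S>0.01},
  1{R>0.01}) are evaluated exactly, never smoothed; their discontinuity sets
  have measure zero and the gates are what keep |F2|/R (resp. |F2|/S)
  bounded.
* **Step sizes above one year** are allowed (invariance is unconditional)
  but emit a warning, since the stability and consistency estimates assume
  Δ ≤ 1.
* **Suprema are metadata.**  Each built-in rate fixture carries analytically
  derived bounds sup|F1| and sup(|F2|/R); nothing is numerically maximized.
  The constant fixture is the one genuine exception: |F2|/R is unbounded as
  R→0, so its stored ratio bound is valid on {R ≥ r_floor} only (documented
  on the fixture; tests that use it do not rely on its suprema).

## Monte Carlo machinery

Wiener increments are drawn once on the finest grid; coarser grids are exact
k-wise sums, so simulations at different step sizes share Brownian paths and
strong errors are measured path-wise.  Path i draws from the substream
`SeedSequence(seed, spawn_key=(i,))`, making path i's increments independent
of the requested ensemble size (stable regression tests).  Ensemble
variances use the unbiased M−1 denominator.

**Strong order.**  No closed-form solutions exist for variable F_j, so the
finest-grid BIM path on shared increments is the reference — standard
practice in strong-order studies.  The order is the least-squares slope of
log terminal L² error vs log Δ.  The two levels nearest the reference are
excluded from the fit (bias guard: error against a numerical reference is
biased downward near the reference resolution).  Terminal-time error defines
the curve; a max-over-grid-times mode is available as an option.

**Local consistency.**  One-step errors are measured against a proxy exact
solution: the BIM sub-stepped 64× on the same Brownian path (sub-increments
generated at the fine grid from the start and summed exactly — no Brownian
bridge needed).  The mean error fits the order-1.5 claim, the RMS error the
order-1.0 claim.

## Study configurations and problem sizes

The built-in fixtures are the parameter sets of the simulation studies:

| study | model | α | β | γ | μ | K | rates | R0 |
|---|---|---|---|---|---|---|---|---|
| sub-threshold SIS | sis | 13 | 0.02 | 13 | 0.013 | 200 | sis-linear / sin-indicator | 0.15 |
| endemic SIS | sis | 52 | 0.03 | 13 | 0.013 | 3000 | sis-linear | 1.38 |
| α/β sweeps | sis | var | var | 26 | 0.013 | 450 | sis-linear | var |
| disease-free SIR | sir | 52 | 0.05 | 52 | 0.013 | 1000 | sir-linear-indicator | βK/γ=0.96 |
| endemic SIR | sir | 13 | 0.1 | 26 | 0.013 | 1000 | sir-linear-indicator | 2.56 |

The equilibrium-seeking fixtures are centered at the equilibrium *formulas*
evaluated unconditionally — in the sub-threshold regime the centering point
(S2, I2) = (1300.7, −16.5) lies outside the domain, which makes F2 large
(≈ 10 at (190, 10)) and the scheme heavily damped at coarse steps.  Two
consequences documented here because they shape the tests: (i) strong-error
curves for that fixture saturate at step sizes ≥ 2⁻⁶ (the balanced weight is
O(1) per step) and only enter the Δ^0.5 regime at much finer resolution, so
the strong-order study uses the endemic SIR configuration, where the fitted
slope is 0.51; (ii) local consistency rates are measured at Δ ∈ [1e−5, 1e−3]
for the same reason.

The package's verification runs are scaled relative to the original
10000-path studies: ensembles use M = 2000 (stability diagnostics) and
M = 200–500 (order estimates), which keeps Monte-Carlo noise on fitted
slopes below ±0.1 while the whole suite runs in well under a minute of
compute for these pieces.  Horizons: T = 2 y for the sub-threshold SIS run;
T = 20 y for the endemic SIS run, about one relaxation time
1/(μ+βI2) ≈ 26 y of its slow susceptible mode, by which the ensemble mean
has entered the 2%-of-K neighbourhood of the endemic equilibrium; T = 1 y
for order studies.

## What the synthetic experiments do and do not show

All data are generated by the package itself; there is no observational
input.  Passing tests show that the *scheme* has the advertised properties
(domain invariance without step-size restriction, the damped-renewal
population identity, strong order ≥ 0.5 against a coupled fine grid,
one-step consistency rates, settling at the predicted equilibria) under the
study parameter sets.  They do not validate the SIR/SIS models against real
epidemic data, do not explore parameter regions beyond the study sets, and
say nothing about inference.  Two further honest caveats: the strong-order
reference is itself a BIM path (self-convergence, justified by the
convergence theory, but not an exact solution); and the sub-threshold mean
at short horizons is governed by slow natural turnover (S(2) ≈ 194.3, not
200) — the scheme reproduces this exactly, so diagnostics that expect the
mean *at* the disease-free point after two years are testing the model's
timescales, not the integrator.

## Known limitations

* Exactly two noise channels; no time-dependent coefficients; diagonal
  scalar weights only (non-diagonal weight matrices are out of scope).
* Drift-implicit variants (Θ ≠ 0) are not implemented; the forward
  Euler–Maruyama map exists purely as a comparator.
* Stability constants are computed, not analyzed; several overflow for
  realistic magnitudes (see above).
* The mean-consistency slope estimate is Monte-Carlo limited: the mean error
  signal is O(Δ^1.5) while its estimation noise is O(Δ·M^−1/2), so at
  moderate M the fitted mean rate is biased toward 1; the mean-square rate
  does not suffer from this and is the one asserted.
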