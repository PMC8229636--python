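# Methods

## Model class and coordinates

The toolkit treats lifetime laws whose density and reliability function are
both of exponential form,

    f(x; θ) = exp{Σᵢ αᵢ(θ) cᵢ(x) − ψ(θ)},
    R(x; θ) = 1 − F(x; θ) = exp{Σᵢ βᵢ(θ) dᵢ(x) − ϕ(θ)},

on a support [0, ∞). Under a progressive Type-II censoring scheme
(n, m, R₁…R_m) the joint density of the censored order statistics is

    L = c(R) Π_r f(x_r) R(x_r)^{R_r}
      = c(R) exp{ Σ_r Σᵢ θᵢ eᵢ(x_r, R_r) + offset − m φ(θ) },

with natural statistics eᵢ(x, R) = cᵢ(x) + R dᵢ(x) per free coordinate,
data-only offset terms (e.g. ln x for the Rayleigh law), and censored
cumulant

    φ(θ) = ψ(θ) + ((n − m)/m) ϕ(θ),

the unique definition for which m·φ equals the total normalizer
m·ψ + (n−m)·ϕ of the joint law. For the built-in one-parameter laws ϕ ≡ 0
and φ is scheme-independent.

Coordinates follow the lifetime-analysis convention: the rate parameter λ
itself is the coordinate (an affine image of the canonical natural
parameter), so all printed closed forms hold literally and the e-connection
still vanishes. Built-ins:

| model | coordinate(s) | ψ | natural statistic e(x, R) |
|---|---|---|---|
| Rayleigh `2λxe^{−λx²}` | λ > 0 | −ln 2λ | −(1+R)x² |
| exponential `λe^{−λx}` | λ > 0 | −ln λ | −(1+R)x |
| Gamma (rate b, shape a) | (b, a−1) | ln Γ(a) − a ln b | (−x, ln x), complete samples only |

The Gamma reliability has no exponential closed form, so the Gamma model
deliberately refuses schemes with removals; it exists to exercise the k = 2
tensor machinery (symmetry, dual flatness) on complete ordered samples.

Additive constants in ψ (e.g. −ln λ vs −ln 2λ for the Rayleigh law) are
irrelevant to every derivative-based quantity; the normalization-correct
ψ = −ln 2λ is used so densities integrate to one.

## Scheme algebra

Risk-set sizes are γ_s = Σ_{j≥s}(R_j + 1) = n − s + 1 − Σ_{r<s}R_r, which
reproduces the joint normalizer c(R) = Πγ_s = n(n−R₁−1)(n−R₁−R₂−2)…
identically (checked exhaustively over all 255 schemes with n ≤ 8). A sign
variant of the γ_s formula that circulates in the literature (with
+Σ_{r<s}R_r) is inconsistent with c(R) — it would give risk sets exceeding
n — and is treated as an erratum. Scheme arithmetic is exact: γ and c(R) in
Python integers, the marginal-density coefficients
c_{r−1} = Π_{s≤r}γ_s and a_{s,r} = Π_{k≠s}1/(γ_k−γ_s) in `fractions.Fraction`
with a float view for numerics. The coefficients alternate in sign and are
ill-conditioned for large r; floating-point mixture sums are accumulated in
extended (long double) precision.

## Sampling and marginals

Censored samples are generated by the exact uniform-transformation
construction: V_i = U_i^{1/(i + R_m + … + R_{m−i+1})},
W_i = 1 − Π_{j≥m−i+1}V_j, x_i = F^{−1}(W_i). It is loop-free, O(m), and a
seed plus scheme fully determines the output. The r-th order statistic has
the mixture marginal f_r = c_{r−1}Σ_s a_{s,r} f (1−F)^{γ_s−1}, with the
closed-form mixture CDF used for Kolmogorov–Smirnov validation of the
sampler. Rayleigh marginal raw moments use
E[x_r^q] = c_{r−1}Σ_s a_{s,r} λ Γ(q/2+1)/(λγ_s)^{q/2+1} (q > −2; smaller q
diverges and is rejected).

## Geometry

With the joint likelihood linear in the natural statistics, the score is
Σ_r e(x_r, R_r) − m∂φ and the higher log-likelihood derivatives are
data-free, giving g = m∂²φ, T = m∂³φ, Γ = 0, Γ^α = ((1−α)/2)T. Torsion
vanishes by i↔j symmetry; the Riemann–Christoffel curvature of Γ^α is
evaluated with central finite differences of the mixed connection and
vanishes for k = 1 and at α = ±1 (dual flatness), while α strictly between
the dual pair is genuinely curved for k = 2.

A *marginal-informed* variant forms h_{i,r} = E[eᵢ(x_{r:m:n}, R_r)] by
adaptive quadrature (relative tolerance 1e−9) against each exact marginal
and assembles modified tensors Γ̃_ijk = g_ij(m∂ₖφ − h_k),
T̃_ijk = Π_l(h_l − m∂_lφ). Because the marginals are the true ones, the
totals satisfy h = m∂φ — for the Rayleigh law this is the exact rational
identity Σ_rΣ_s(1+R_r)c_{r−1}a_{s,r}γ_s^{−2} = m, verified exhaustively for
n ≤ 8 — so Γ̃ and T̃ vanish identically. A construction of these tensors
from an independence approximation to the order statistics would not
collapse; the package computes both the assembled tensors and their
ingredients so the collapse is observable rather than assumed.

## Bayesian machinery

Exact posteriors and predictives (k = 1) are computed by adaptive
quadrature of the likelihood against the prior, after recentring the
integrand at the MLE in log scale for stability. The Rayleigh model is
conjugate: with a Jeffreys prior π_J ∝ 1/λ the posterior is
Gamma(m, rate S), S = Σ(1+R_r)x_r², with predictive
2mxS^m/(S+x²)^{m+1}; with a uniform(0, b) prior the posterior is a
truncated Gamma(m+1, S) and the predictive has a closed form in regularized
incomplete gamma functions. These closed forms serve as independent oracles
for the quadrature path (agreement to ~1e−15) and as the fast path in the
simulation study.

The Jeffreys prior's log-gradient uses the identity
∂ᵢ log π_J = ½ g^{jk}∂ᵢg_jk = ½ Tᵢ, so the cancellation
∂log π − T/2 = 0 in the predictive expansion is exact, not numerical.

### Posterior expansion

The Laplace expansion around the MLE is implemented with the cubic term
−T_ijk θ̃ⁱθ̃ʲθ̃ᵏ/6 and the prefactor det g(θ̂): differentiating the
log-likelihood three times gives ∂³l = −T, which fixes the minus sign, and
the expansion then matches the third-order Taylor coefficients of the exact
conjugate Gamma posterior (a sign-flipped variant fails that check). Its
sup-norm error against the exact posterior decreases monotonically in m.

### Predictive expansion

Two modes are exposed:

* **corrected** (default) — the Laplace form
  f(x;θ̂) + ½g^{ij}∂ᵢ∂ⱼf + bⁱ∂ᵢf with bⁱ = g^{ij}(∂ⱼlog π − Tⱼ/2), density
  derivatives taken in closed form from the natural decomposition
  (∂ᵢf = f(cᵢ − ∂ᵢψ)). All sample-size dependence is carried inside the
  censored-information metric, g^{ij} = O(1/m); no bare 1/n appears, since
  the information content of a censored sample scales with m. For
  Rayleigh–Jeffreys this reduces to f(x;λ̂)[1 + (u²/2 − u)/m], u = λ̂x²: the
  correction integrates to exactly zero (E[U²/2 − U] = 0 for U ~ Exp(1)),
  and the sup-norm error against the exact predictive decays as m⁻²
  (empirical ratio ≈ 3.9 when m doubles).
* **paper** — a fidelity mode reproducing a historical printed reduction
  for the Rayleigh–Jeffreys case: f(x;λ̂) + 1/(4mn), plus a
  marginal-informed variant whose extra term is proportional to
  (Σ_rΣ_s(1+R_r)c_{r−1}a_{s,r}γ_s^{−2} − m) and therefore vanishes by the
  collapse identity. The additive constant is not integrable, so this mode
  is regression-locked for reference, restricted to Rayleigh + Jeffreys,
  and never the default.

## Simulation study

The study draws censored Rayleigh samples at a true rate, evaluates each
prediction rule at a point x₀, and accumulates bias and MSE against the
true density, with Monte Carlo standard errors; a base seed plus the
configuration determines every number. Methods: plug-in (PP), Jeffreys
Bayes via the corrected expansion (BP-J), and uniform-prior Bayes via the
exact truncated-Gamma form (BP-U). Since every method is a function of the
sufficient statistic S, and λS ~ Gamma(m, 1) exactly, each cell also has a
sampler-independent semi-analytic check by one-dimensional quadrature over
the pivot density (`pivot_moments`), which the tests use as the oracle.

The default profile is λ_true = 0.125 with x₀ = 2.5 — i.e. Rayleigh scale
σ = 2, which puts x₀ near the density mode so that predicted-density errors
are on a meaningful scale (the rate-reading λ = 2 makes the true density at
x₀ about 3.7e−5 and every method trivially accurate; that profile remains
available via configuration). Default cells are (m, n) = (10,30), (10,35),
(15,40), (20,40) with scheme families R1/R2/R3 and 10,000 replications;
the committed tests and the acceptance script use 2,000 replications on an
(m, n = 2m) ladder, which resolves every oracle comparison well inside
3 Monte Carlo standard errors.

What the generator does *not* emulate: real lifetime data with ties,
rounding, inspection-time grouping, random (rather than prefixed) removals,
or model misspecification. Passing tests certify the internal consistency
of the machinery under a correctly specified continuous model, not
robustness to those features.

## Numerical choices

* Finite differences: central stencils with one Richardson level, step
  max(1e−4·|θᵢ|, 1e−6); third-derivative tensors use a direct 4-point
  stencil (step 0.01·|θᵢ|, Richardson) for pure entries (~1e−8 relative)
  and nested second-order stencils for mixed entries (~1e−5, matching the
  curvature tolerance); a guard raises when θ is too close to the domain
  boundary for the stencil. Closed-form suppliers bypass FD for all
  built-ins.
* Quadrature: `scipy.integrate.quad`, relative tolerance 1e−9 (marginal
  expectations) / 1e−10 (posterior normalizers), integrands recentred at
  the MLE in log scale; improper upper limits handled by the library's
  semi-infinite transformation.
* Degenerate inputs: schemes are validated eagerly with errors naming the
  violated constraint; samples with Σ(1+R)x² = 0 are rejected; ties in
  input samples are permitted and stably ordered (they occur with
  probability zero under the continuous models).
* MLE: closed form for Rayleigh/exponential; L-BFGS-B with the analytic
  score otherwise, gradient norm ≤ 1e−6 enforced at the reported optimum.

## Known limitations

* Exact quadrature posteriors/predictives are implemented for k = 1;
  multi-parameter models get the expansion path only (the Einstein-summed
  forms are fully general, exercised at k = 2 through the Gamma model's
  geometry).
* The Gamma model excludes censoring (no exponential-form reliability).
* The study harness is Rayleigh-specific, leaning on the sufficient
  statistic for speed and for its pivot oracle.
* No Type-I/hybrid/adaptive censoring, random removals, covariates, or
  MCMC; the scope is the exponential-family/progressive-Type-II geometry
  and its Laplace-expansion consequences.
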