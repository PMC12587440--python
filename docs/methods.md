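# Methods

This note documents the model, the numerical choices, and the limits of
what the package's synthetic-data experiments can show.

## Equation of state

The residual Helmholtz energy per molecule, reduced by kT, is the sum of
three contributions, `a_res = a_hc + a_disp + a_assoc`.

**Hard chain.**  Segments interact as hard spheres with a
temperature-dependent diameter `d_i(T) = σ_i [1 − 0.12 exp(−3 u_i/k_B T)]`.
The mixture hard-sphere term is the Boublík–Mansoori form in the packing
fractions ζ_0..ζ_3; chain connectivity subtracts
`Σ x_i (m_i − 1) ln g_ii(d_ii)` with g the hard-sphere contact value.  A
single segment (m = 1) with no attractions reduces exactly to the
Carnahan–Starling fluid, which the tests pin to 1e−8.

**Dispersion.**  Second-order perturbation theory with the standard 7×3
universal coefficient arrays for the two power-series integrals I₁(η, m̄)
and I₂(η, m̄); a checksum test pins the arrays.  Combining rules are
Lorentz for σ (arithmetic) and Berthelot for u (geometric) with the
correction `u_ij = √(u_i u_j)(1 − k_ij)`.

**Association.**  Wertheim first-order theory with molecules carrying two
site *types* — donors and acceptors with integer multiplicities — where
donors bind only acceptors.  Polymers with thousands of sites (e.g.
Soluplus, 2 486 + 2 486) are handled through the multiplicities; sites are
never enumerated.  Cross-association uses the Wolbach–Sandler rules
(arithmetic ε, geometric κ with a σ-ratio correction).  This is what makes
"induced association" work: the packaged polymers carry ε = 0 (no
self-association, Δ_polymer–polymer = 0 because exp(0) − 1 = 0) but κ = 0.02
and nonzero site counts, so they cross-associate with a hydrogen-bonding
drug at strength governed by ε_cross = ε_drug/2.  Site fractions are solved
by damped successive substitution (damping 0.5, residual < 1e−12, ≤ 500
sweeps) followed by one exact substitution pass so the mass-action equations
hold to the tolerance.

**Derived quantities.**  Residual chemical potentials are analytic
mole-number derivatives of the total residual Helmholtz energy at fixed
(T, V); the association part uses the stationarity of the Wertheim
functional, so only the explicit density dependence of the association
strengths (through the contact values) contributes.  The compressibility
factor follows from the Euler identity `Z = 1 + Σ x_i μ_i/kT − a_res`, which
makes pressure and fugacity coefficients exactly consistent by
construction; an independent finite-difference oracle in the tests confirms
both routes to better than 1e−6 relative.  `ln φ_i = μ_i/kT − ln Z`, and
`γ_i = exp(ln φ_i(mixture) − ln φ_i(pure liquid i))`.

The kernel is compiled with numba; the first call in a fresh process takes
a few seconds of JIT time.

**Density solver.**  P(η) = P_target is bracketed on a descending η grid
from 0.72 (liquid hint; ascending from 1e−12 for vapor) and polished by
Brent to machine tolerance, giving |ΔP|/P < 1e−9.  The liquid branch is
defined as the largest root; with no phase hint all roots are compared by
the residual Gibbs criterion ln ρ + a_res + Z.  SLE work always uses the
liquid hint and warm-starts from the previous η, since successive calls
move the composition only slightly.

**Pressure.**  All condensed-phase evaluations run at 1.01325×10⁵ Pa;
liquid-phase fugacities are insensitive to pressure at these conditions and
the experiments being emulated are ambient-pressure DSC.

**Units.**  σ in Å, energies as temperatures (K), number densities in Å⁻³
internally; pressures in Pa; temperatures converted from °C to K at the I/O
boundary (T/K = t/°C + 273.15).  Linear Δ_fus C_p coefficients are
interpreted with T in kelvin (the loader accepts an explicit a/b column
pair or an expression string, so the Celsius interpretation can be encoded
by the caller if ever needed).

## Solubility condition

`fusion_exponent` evaluates the melting-term bracket with closed-form
integrals for Δ_fus C_p(T) = a + bT:
`∫ C_p dT = a(T−T_m) + b/2 (T²−T_m²)` and
`∫ C_p/T dT = a ln(T/T_m) + b(T−T_m)`; quadrature cross-checks agree to
1e−10.  The solubility equation `x γ(x) = exp(K)` is solved by damped
successive substitution (damping 0.5, start at the ideal solubility).  That
iteration converges for mildly non-ideal systems but oscillates wherever γ
varies steeply with composition — strongly cross-associating pairs can have
γ of order 1e−3 at mid-composition, making the map x → exp(K)/γ(x)
violently expanding.  When the iteration fails to contract (25 iterations
without progress, or budget exhausted), the solver switches to a bracketed
Brent root solve of ln(x γ(x)) − K, scanning from the drug-rich side; the
topmost sign change is the branch that connects continuously to x = 1 at
T_m.  Every returned point satisfies |x γ − exp(K)| < 1e−9; curve solving
flags failed temperatures instead of dropping them.  The polymer is treated
as a single molecule of its stated M_w for mole-fraction bookkeeping, and
mole/weight conversion is exact (round trip to 1e−14).

## Parameter regression

The objective is RMSRD (%) between calculated and experimental weight
fractions, plus a quadratic penalty `1e4 · Σ ((violation)/(bound width))²`
for parameters outside their bounds; the penalty is normalized by the bound
width so that K-scale (u/k_B, ε) and Å-scale (σ) violations are comparable.
Any candidate for which the EOS or the solubility condition is unsolvable
contributes a large finite value (1e6) instead of raising, which keeps the
simplex moving through infeasible pockets.

Default bounds (user-overridable) span the ranges of the published drug and
polymer parameters: A = m/M_w^API ∈ [0.015, 0.060] mol/g, B = σ^API ∈
[2.5, 4.5] Å, C = u/k_B^API ∈ [150, 500] K, D = ε^assoc/k_B ∈ [0, 2500] K,
E = κ^assoc ∈ [0.001, 0.10], F = m/M_w^poly ∈ [0.030, 0.060] mol/g,
G = σ^poly ∈ [2.5, 3.2] Å, H = u/k_B^poly ∈ [180, 280] K.  Association-site
counts and molar masses are fixed inputs (a `SystemTemplate`), not fit
parameters; the API default is 2 donors + 2 acceptors.

The two-step pipeline is: 20 uniform random draws inside the bounds
(seeded generator; argmin retained, ties broken by draw order), then
Nelder–Mead refinement capped at 5 iterations, then 50 further iterations,
all at k_ij = 0.  Nelder–Mead runs in bound-normalized coordinates so all
eight parameters move on the unit scale.  The stage-1 initial simplex is
built from the nine best-ranked screening draws — the screen has already
paid for that ranking, and it orients the simplex along the directions the
landscape rewards; stage 2 continues from stage 1's final simplex rather
than rebuilding.  The result is a pure function of (dataset, bounds, seed):
reruns are bit-identical.

With this budget — 20 draws and 55 simplex iterations in an 8-dimensional
space — roughly half of the random screening seeds land in basins that the
refinement can descend to RMSRD ≲ 1 %; the rest terminate at 2–6 %.  The
non-uniqueness of PC-SAFT parameter sets means the successful fits
reproduce the generating *curve*, not the generating parameters.  Extending
the second stage to a few hundred iterations brings essentially every seed
below 0.1 % on noise-free data; `scripts/acceptance.py` computes both the
standard-budget pass count and one extended-budget endpoint so the gap is
visible in every run.

`fit_kij` minimizes the plain RMSRD (no bound penalty — the pure-component
parameters are frozen and may legitimately sit outside the screening
bounds) over k_ij ∈ [−0.2, 0.2] with a 41-point grid pre-scan followed by
bounded Brent polish around the best grid point; the grid contains 0, so
the result never exceeds the k_ij = 0 misfit.  `average_parameters` takes
arithmetic means of the fitted polymer (F–H) or API (A–E) subsets across
systems, reporting the fixed polymer association constants alongside.

## Synthetic data

`generate_dataset` emulates DSC stepwise-dissolution datasets: N = 6 evenly
spaced temperatures on [0.80 T_m, 0.98 T_m] (the sparse, drug-rich,
sub-melting region such measurements cover), solved from a known parameter
set, with multiplicative Gaussian noise on w (default 3 % relative —
typical of stepwise-dissolution scatter; the sources of the emulated
datasets do not quantify their uncertainty, so this is a package choice).
The ground-truth sidecar (parameters, k_ij, noise-free curve, seed) is
sufficient to regenerate the clean curve bit-identically.

What the generator does *not* emulate: temperature-dependent or correlated
measurement error, the melting-point-depression protocol's distinct error
structure, kinetic artifacts (incomplete dissolution, degradation near
T_m), or model misspecification — the data are generated by the same
equation of state that is fitted, so recovery experiments demonstrate the
optimizer and the identifiability of the curve, not the physical adequacy
of PC-SAFT for any real drug–polymer pair.

## Known limitations

* No polar/quadrupolar PC-SAFT terms, no copolymer extension, and binary
  mixtures only.
* Parameters are fitted to solubility data alone; they are not constrained
  by vapor pressure or density data and should not be expected to predict
  those properties.
* Fitted parameter sets are non-unique and transfer poorly between
  chemically dissimilar polymers; k_ij retuning is expected whenever a
  parameter set is moved to a new system.
* The Nelder–Mead trajectories are deterministic but chaotic: numerically
  equivalent reformulations of the objective can land different seeds in
  different basins at the standard iteration budget.
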