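# Methods

This note records the model as implemented, the numerical choices, and the
limits of what the tests demonstrate. Everything is in Hartree atomic units
(ħ = e = mₑ = k_e = 1) unless stated; conversions (1 hartree = 27211.386
meV = 315775.02 K, 1 bohr = 0.52917721 Å, 1 hartree = 627.5095 kcal/mol)
are applied only at I/O boundaries.

## The pair potential

Each atom is a quantum Drude oscillator: a drudon of charge −q and mass μ
harmonically bound with frequency ω, so that α₁ = q²/μω², C₆ = (3/4)ωα₁²,
C₈ = 5C₆/μω, C₁₀ = (245/8)C₆/(μω)². The drudon ground state is an isotropic
Gaussian of width (μω)^(−1/2); the contact-normalized overlap of two such
densities at separation R is S(R) = exp(−μωR²/2), which also equals the
squared wave-function overlap. Exchange repulsion is modelled as an
effective Heitler–London exchange integral with a 1/R envelope,

    E_ex(R) = A k_e q² S(R)/R ,

whose dipole-limit form is k_e q² S/(2R) (obtained by evaluating the
dipole–dipole coupling between the symmetrized product states; only the
z-components survive, giving the factor 1/2). The total potential is

    V(R) = A k_e q² S(R)/R − Σₙ₌₃,₄,₅ fₙ(R) C₂ₙ/R²ⁿ .

The damping function is fₙ(z) = 1 − e^(−z) Σₖ₌₀ⁿ zᵏ/k! with z = μωR²/2 —
an incomplete-gamma (Tang–Toennies-like) form whose variable is the overlap
exponent itself rather than a Born–Mayer bR, so each damped term contains
only even powers of R up to R²ⁿ and vanishes like R² at contact. It is
evaluated as the regularized incomplete gamma P(n+1, z) to avoid small-z
cancellation. `damping_argument` isolates the definition of z in a single
function.

## Parameterization from {α₁, C₆}

1. ω = 4C₆/3α₁² (inverting the C₆ closed form).
2. R_e = 2Φα₁^(1/7), Φ = α_fsc^(−4/21), evaluated from the CODATA
   fine-structure constant at import (numerically 2.55280 bohr); the
   coefficient is never hard-coded.
3. μω solves the dipole force balance at R_e,
   d/dR [k_e q² S/(2R) − f₃C₆/R⁶] = 0, with q² = α₁(μω)ω substituted so μω
   is the only unknown (f₃ ≡ 1 in the undamped variant).
4. μ = μω/ω and q = √(α₁μ)·ω.
5. A closes the full force balance dV/dR(R_e) = 0 including C₈, C₁₀ (and
   the damping derivatives in the damped variant), so V(R_e) = −D_e exactly.

Eliminating A from −V(R_e) gives the closed-form well depth

    D_e = Σₙ C₂ₙ/R_e²ⁿ · [fₙ·(γ²+1−2n) + 2z e^(−z) zⁿ/n!] / (γ²+1) ,

with γ² = μωR_e² and z = γ²/2. The two-term truncation used as the
noble-gas well-depth scaling law keeps the dipole-model depth plus the
leading C₈ correction:

    D_e ≈ (C₆/R_e⁶)(γ² + 5/γ²)/(γ²+1) .

This needs only {α₁, C₆} and reproduces the reference well depths of the
He–Xe homodimers to better than 1 meV (radon, whose reference data are
less certain, is underbound by ≈4.5 meV).

### Root selection

The dipole balance residual rises from negative values at μω → 0 (a drudon
far more diffuse than the dimer exerts almost no exchange force), crosses
zero, peaks, and decays through a second zero as the overlap collapses.
Only the **descending** crossing corresponds to a localized oscillator
whose exchange wall decays with distance; the ascending crossing is a
spurious diffuse-oscillator artifact (for Ne it sits at μω ≈ 0.003 with
S(R_e) ≈ 0.95, i.e. near-total overlap at equilibrium — unphysical).
`solve_mu_omega` brackets on a geometric grid (64 points/decade over
[1e−4, 1e2]), refines with Brent to relative 1e−14, keeps descending
crossings only, and raises if none or several remain. This supersedes a
blanket "any multiple bracket is an error" rule, which would reject every
noble-gas solve.

### Validated range

The undamped dispersion series diverges at contact; the undamped potential
is validated for R ≳ 0.7R_e and evaluation below 0.5R_e logs a warning.
For the heaviest noble gas (Rn, smallest γ²) the divergence already pulls
V below zero at ≈0.705R_e; the damped variant has the correct R → 0
behaviour (exchange wall → +∞, damped dispersion → 0) everywhere.

## Corresponding states

Dividing V by D_e and R by R_e gives a dimensionless family shape

    U*(x) = A* e^(−γ*²x²/2)/x − Σₙ fₙ*(γ*²x²/2) C₂ₙ*/x²ⁿ ,

with A* = A k_e q²/(R_e D_e), γ* = R_e√(μω), C₂ₙ* = C₂ₙ/(D_e R_e²ⁿ). The
noble-gas shape is computed once from undamped Ne₂ and cross-checked at
build time against its published starred values within 0.1%; the group-II
shape comes from damped Sr₂ at the reference R_e = 8.88 bohr. The starred
set is normalized by the **model's own** closed-form well depth — the only
convention under which U*(1) = −1 holds identically. (For Sr₂ the model
depth is 106.2 meV versus the 129.7 meV ab initio reference; normalizing by
the reference would rescale C₆* from 1.62 to 1.33 and break U*(1) = −1.)

Rescaling: noble-gas dimers take R_e from the α^(1/7) law and D_e from the
two-term scaling law; group-II dimers take both from the packaged reference
table, because their bonding is not purely vdW and the scaling laws are
deliberately never used as a fallback. Be₂ violates corresponding states
(anomalous long-range shape) and is rejected with an explanatory error.
Conformal dispersion coefficients follow as C₂ₙ = C₂ₙ*·D_e·R_e²ⁿ; the
conformal C₆ overestimates the references homogeneously by 12–13%, while
C₁₀ (and C₈ for Ne–Rn) underestimate them — He's C₈ is the one mild
exception (+9%).

## Mixing and damping conventions

C₆ mixes by the London two-parameter rule. Polarizability mixes as the
geometric mean α₁^AB = √(α_A α_B), chosen as the heteronuclear form of the
radius law (R_vdW^AB = Φ(α_Aα_B)^(1/14), the geometric mean of the two
homonuclear radii); it is symmetric, idempotent, and places every mixed R_e
strictly between the homonuclear ones. The heteronuclear dimer is then two
*identical* effective oscillators, so the homonuclear exchange formalism
applies unchanged. Lorentz–Berthelot mixing is provided for benchmarking
only.

For noble gases, damping is nearly neutral in the well and tail: the fully
damped re-parameterization of Ne₂ tracks the undamped curve within 2% of
D_e over [0.95R_e, 2R_e] and shifts D_e by under 1%. On the steep exchange
wall below ≈0.9R_e any damping convention produces deviations of order D_e
(a tiny horizontal shift of a near-vertical wall), so "agreement" is
quantified from just inside the minimum outward. The 2% figure and the
window are recorded as tunable test constants.

## Molecular mode

Hirshfeld volume ratios v_i are input data (sidecar TSV keyed by atom
index) — computing them needs electronic-structure calculations, which are
out of scope. Each atom's free-atom {α₁, C₆} is scaled (α₁ → vα₁,
C₆ → v²C₆), each cross pair is mixed and parameterized with the damped
variant, and the pairwise sum runs over intermolecular pairs only. Totals
use exactly-rounded summation (`math.fsum`) so the result is independent of
pair order (swapping the molecules is bitwise neutral). The exchange and
dispersion parts are exposed separately; the SAPT-corrected combiner adds a
user-supplied per-separation first-order SAPT energy to the dispersion part
alone (no interpolation between tabulated separations — a missing
separation is an error). Molecular energies are reported in kcal/mol.

The synthetic fixture generator builds compact C/H clusters (minimum
intra-cluster spacing 2 bohr, rejection sampling) with ratios drawn
uniformly from [0.7, 1.1], reproducibly from a seed. It emulates the
*plumbing* of real molecular input — geometry, per-atom ratios, pair
enumeration — not the physics of real molecules: passing tests demonstrate
correctness of the pairwise machinery (invariances, asymptotics, forces),
not chemical accuracy, which would require reference Hirshfeld volumes and
correlated-wavefunction benchmarks.

## Comparison metric

Δ_S = 100% · ∫|V_test − V_ref| dR / ∫|V_ref| dR over [0.8R_e, 2.0R_e],
by adaptive quadrature to relative 1e−8 (the difference integral gets an
absolute floor of 1e−10 of the reference area so near-identical curves do
not ask the quadrature to resolve rounding noise). The ratio form makes
Δ_S invariant under common rescaling of both curves; a doubled reference
gives exactly 100%. Tabulated reference curves are interpolated with a
cubic spline strictly inside the window. Long-range quality is judged via
dispersion coefficients instead, so the window stops at 2R_e. The 12-6
Lennard-Jones form V = D_e[(R_e/r)¹² − 2(R_e/r)⁶] is the stock comparison
potential; no published LJ parameter sets are shipped.

## Data

The packaged TSV carries {α₁, C₆} for He–Rn and Mg–Hg with per-row
provenance tags (Rn's dispersion coefficients come from a different source
than the other noble gases, which the tag records), reference (R_e, D_e)
for all dimers, reference C₈/C₁₀ for noble gases, and free-atom H and C
rows (α₁ = 4.50/12.0, C₆ = 6.50/46.6 a.u., the standard reference values
used by Tkatchenko–Scheffler scaling) for molecular mode. Additional
elements can be supplied through a user TSV with the same columns.

## Known limitations

* No electrostatics or polarization: the model covers exchange repulsion
  and dispersion only; polar systems need an additional term.
* Pairwise additivity: many-body dispersion and many-body exchange are
  absent; molecular-mode exchange walls deviate from first-order SAPT.
* Group-II dimers require reference (R_e, D_e); heteronuclear group-II
  pairs are unsupported for lack of tabulated references. Be₂ is excluded.
* Rn inherits the uncertainty of its reference data; the undamped Rn₂
  potential is usable only above ≈0.71R_e (use the damped variant below).
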