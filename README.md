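# vdwqdo

Universal pairwise van der Waals (vdW) potentials built from the quantum
Drude oscillator (QDO) model.

Classical force fields describe nonbonded repulsion and dispersion with
Lennard-Jones-type potentials whose two parameters (R_e, D_e) must be known
per pair and whose shape is notoriously inflexible. `vdwqdo` implements an
alternative: a quantum-mechanically derived pair potential that is fully
parameterized by **two free-atom properties** — the static dipole
polarizability α₁ and the dipole–dipole dispersion coefficient C₆ — both
available ab initio across the periodic table. It targets force-field
developers and molecular-modelling practitioners who need transferable
nonbonded potentials without per-dimer fitting.

## The model

An atom is coarse-grained into a Drude oscillator: a charged quasi-particle
(charge −q, mass μ) bound harmonically (frequency ω) to a pseudo-nucleus,
with α₁ = q²/μω². In atomic units the pair potential is

    V(R) = A k_e q² S(R)/R − Σₙ₌₃,₄,₅ fₙ(R) C₂ₙ / R²ⁿ

* **Exchange wall** — S(R) = exp(−μωR²/2) is the contact-normalized overlap
  of the two drudon ground-state densities; the 1/R prefactor gives the
  correct infinite repulsion at contact.
* **Dispersion** — C₈ = 5C₆/μω and C₁₀ = (245/8)C₆/(μω)² follow in closed
  form; fₙ is an incomplete-gamma damping function of z = μωR²/2 (fₙ ≡ 1 in
  the undamped variant used for noble gases).
* **Parameterization** — ω = 4C₆/3α₁²; the equilibrium distance follows the
  scaling law R_e = 2Φα₁^(1/7) with Φ = α_fsc^(−4/21) ≈ 2.5528 bohr; μω
  solves a transcendental dipole force balance at R_e; A closes the full
  force balance dV/dR(R_e) = 0. No adjustable parameters remain.
* **Corresponding states** — scaled by (R_e, D_e), the family potentials
  collapse onto dimensionless shapes U*(x) (one for noble gases, built from
  Ne₂; one for group II, built from damped Sr₂), so any family member needs
  only R_e and D_e — both predicted from {α₁, C₆} for noble gases.
* **Molecules** — free-atom properties are rescaled per atom by Hirshfeld
  volume ratios (Tkatchenko–Scheffler: α₁ → vα₁, C₆ → v²C₆) and the damped
  potential is summed over intermolecular atom pairs.

Heteronuclear pairs mix by the London rule for C₆ and a geometric-mean
polarizability rule consistent with the radius scaling law. A 12-6
Lennard-Jones reference and a normalized area-difference metric
Δ_S = ∫|V − V_ref|dR / ∫|V_ref|dR (over [0.8R_e, 2R_e]) are included for
benchmarking.

## Worked example

```sh
$ vdwqdo parameterize Ne
# element = Ne (damped = False)
q        = 1.18865 a.u.
mu       = 0.371642 a.u.
omega    = 1.19326 a.u.
mu*omega = 0.443467 a.u.
C6       = 6.38 a.u.
C8       = 71.9331 a.u.
C10      = 993.513 a.u.
R_e      = 5.87457 bohr
A        = 0.826763 (dimensionless)
D_e      = 3.58591 meV
```

From just α₁ = 2.67 and C₆ = 6.38 a.u., the chain predicts the full
oscillator triple, the higher dispersion coefficients, an equilibrium
distance of 5.87 bohr and a well depth of 3.59 meV for the neon dimer —
all without touching any reference binding curve. The same library calls
are available in Python:

```python
import vdwqdo

table = vdwqdo.load_element_table()
params = vdwqdo.qdo_parameters(table["Ne"])
v_at_7_bohr = vdwqdo.potential(params, 7.0)   # hartree
```

Other subcommands: `curve` (sampled potential, any element pair, TSV),
`dimer-table` (R_e/D_e/C₂ₙ for a whole family), `molecular` (XYZ +
Hirshfeld-ratio sidecar → intermolecular energy in kcal/mol, optionally
SAPT-corrected), and `delta-s` (curve comparison metric).

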