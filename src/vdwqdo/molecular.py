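"""Atom-in-molecule (AIM) pairwise intermolecular vdW energies.

Free-atom properties are rescaled per atom by Hirshfeld volume ratios
v_i = V_i^AIM / V_i^free following the Tkatchenko-Scheffler prescription
(alpha1 -> v alpha1, C6 -> v^2 C6).  Every cross pair (i in A, j in B) is
then mixed, parameterized as a damped effective oscillator, and evaluated
at its separation; the intermolecular energy is the pairwise sum over
cross pairs only.  Hirshfeld ratios come from electronic-structure
calculations and are consumed as input data (a sidecar table), never
computed here.

Energies are reported in kcal/mol at the interface; atomic units inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL
from . import core
from .core import AtomProperties, qdo_parameters
from .mixing import pair_properties

__all__ = [
    "MolecularSystem",
    "PairContribution",
    "InteractionResult",
    "aim_scale",
    "intermolecular_energy",
    "sapt_corrected_energy",
    "generate_fixture_dimer",
    "read_xyz",
    "read_hirshfeld_ratios",
    "read_sapt_table",
    "sapt_energy_at",
]

_MIN_PAIR_DISTANCE = 0.1  # bohr; closer atoms are treated as overlapping


@dataclass(frozen=True)
class MolecularSystem:
    """Atoms of one molecule: element labels, Cartesian coordinates (bohr)
    and per-atom Hirshfeld volume ratios."""

    labels: Tuple[str, ...]
    coordinates: np.ndarray  # (n, 3), bohr
    hirshfeld_ratios: np.ndarray  # (n,), dimensionless in (0, 2]

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        ratios = np.asarray(self.hirshfeld_ratios, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "hirshfeld_ratios", ratios)
        n = len(self.labels)
        if n == 0:
            raise ValueError("a molecular system needs at least one atom")
        if coords.shape != (n, 3):
            raise ValueError(f"coordinates must have shape ({n}, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if ratios.shape != (n,):
            raise ValueError(f"hirshfeld_ratios must have shape ({n},)")
        if np.any(~np.isfinite(ratios)) or np.any(ratios <= 0) or np.any(ratios > 2):
            raise ValueError("Hirshfeld volume ratios must lie in (0, 2]")

    def __len__(self) -> int:
        return len(self.labels)

    def translated(self, shift) -> "MolecularSystem":
        return MolecularSystem(self.labels, self.coordinates + np.asarray(shift, float),
                               self.hirshfeld_ratios)

    def rotated(self, rotation_matrix, about=(0.0, 0.0, 0.0)) -> "MolecularSystem":
        rot = np.asarray(rotation_matrix, float)
        about = np.asarray(about, float)
        coords = (self.coordinates - about) @ rot.T + about
        return MolecularSystem(self.labels, coords, self.hirshfeld_ratios)


@dataclass(frozen=True)
class PairContribution:
    """One cross pair's contribution: indices, distance (bohr) and the
    exchange / dispersion split (kcal/mol)."""

    i: int
    j: int
    distance: float
    exchange: float
    dispersion: float

    @property
    def total(self) -> float:
        return self.exchange + self.dispersion


@dataclass(frozen=True)
class InteractionResult:
    """Pairwise intermolecular interaction energy (kcal/mol)."""

    total: float
    exchange: float
    dispersion: float
    per_pair: List[PairContribution] = field(repr=False, default_factory=list)


def aim_scale(atom: AtomProperties, ratio: float) -> AtomProperties:
    """Tkatchenko-Scheffler AIM rescaling: alpha1 scales linearly and C6
    quadratically with the Hirshfeld volume ratio."""
    return atom.scaled(ratio)


def _pair_parameterization(atom_i: AtomProperties, v_i: float,
                           atom_j: AtomProperties, v_j: float):
    scaled_i = aim_scale(atom_i, v_i)
    scaled_j = aim_scale(atom_j, v_j)
    mixed = pair_properties(scaled_i, scaled_j)
    return qdo_parameters(mixed, damped=True)


def intermolecular_energy(mol_a: MolecularSystem, mol_b: MolecularSystem,
                          table) -> InteractionResult:
    """Damped vdW-QDO interaction energy between two molecules, kcal/mol.

    For each cross pair the two atoms are AIM-scaled, mixed, parameterized
    as a damped effective oscillator (R_e from the alpha^(1/7) law of the
    mixed polarizability) and the damped potential is evaluated at the
    interatomic distance.  Intramolecular pairs never contribute.

    ``table`` maps element labels to free-atom :class:`AtomProperties`
    (e.g. ``vdwqdo.load_element_table()``).
    """
    for mol in (mol_a, mol_b):
        for label in mol.labels:
            if label not in table:
                raise KeyError(f"element {label!r} is not in the property table")

    per_pair: List[PairContribution] = []
    cache = {}
    for i, (lab_i, x_i) in enumerate(zip(mol_a.labels, mol_a.coordinates)):
        v_i = float(mol_a.hirshfeld_ratios[i])
        for j, (lab_j, x_j) in enumerate(zip(mol_b.labels, mol_b.coordinates)):
            v_j = float(mol_b.hirshfeld_ratios[j])
            r_ij = float(np.linalg.norm(x_i - x_j))
            if r_ij < _MIN_PAIR_DISTANCE:
                raise ValueError(
                    f"atoms A[{i}] and B[{j}] overlap (R = {r_ij:.4f} bohr "
                    f"< {_MIN_PAIR_DISTANCE} bohr)"
                )
            key = (lab_i, v_i, lab_j, v_j) if lab_i <= lab_j else (lab_j, v_j, lab_i, v_i)
            params = cache.get(key)
            if params is None:
                params = _pair_parameterization(table[key[0]], key[1], table[key[2]], key[3])
                cache[key] = params
            ex = core.exchange_energy(params, r_ij) * HARTREE_TO_KCALMOL
            disp = core.dispersion_energy(params, r_ij) * HARTREE_TO_KCALMOL
            per_pair.append(PairContribution(i, j, r_ij, ex, disp))
    # fsum is exactly rounded, so the totals do not depend on pair order
    # (swapping the two molecules is bitwise neutral).
    exchange_total = math.fsum(p.exchange for p in per_pair)
    dispersion_total = math.fsum(p.dispersion for p in per_pair)
    return InteractionResult(
        total=exchange_total + dispersion_total,
        exchange=exchange_total,
        dispersion=dispersion_total,
        per_pair=per_pair,
    )


def separation_force(mol_a: MolecularSystem, mol_b: MolecularSystem, table,
                     axis=(0.0, 0.0, 1.0)) -> float:
    """Analytic derivative of the interaction energy with respect to a rigid
    displacement of molecule B along ``axis`` (kcal/mol per bohr)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    total = 0.0
    cache = {}
    for i, (lab_i, x_i) in enumerate(zip(mol_a.labels, mol_a.coordinates)):
        v_i = float(mol_a.hirshfeld_ratios[i])
        for j, (lab_j, x_j) in enumerate(zip(mol_b.labels, mol_b.coordinates)):
            v_j = float(mol_b.hirshfeld_ratios[j])
            d = x_j - x_i
            r_ij = float(np.linalg.norm(d))
            key = (lab_i, v_i, lab_j, v_j) if lab_i <= lab_j else (lab_j, v_j, lab_i, v_i)
            params = cache.get(key)
            if params is None:
                params = _pair_parameterization(table[key[0]], key[1], table[key[2]], key[3])
                cache[key] = params
            dv_dr = core.potential_derivative(params, r_ij)
            total += dv_dr * float(d @ axis) / r_ij
    return total * HARTREE_TO_KCALMOL


def sapt_corrected_energy(dispersion_only: float, sapt_first_order: float) -> float:
    """Corrected interaction energy: the vdW-QDO *dispersion* energy plus a
    user-supplied first-order SAPT energy (electrostatics + exchange), both
    in the same units.  A plain sum -- the first-order term replaces the
    model's own exchange wall."""
    for name, value in (("dispersion_only", dispersion_only),
                        ("sapt_first_order", sapt_first_order)):
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")
    return dispersion_only + sapt_first_order


def sapt_energy_at(sapt_table, separation: float, atol: float = 1e-9) -> float:
    """Look up the first-order SAPT energy at an exact tabulated separation.
    No interpolation: a missing separation is an error."""
    seps = np.asarray([row[0] for row in sapt_table], float)
    match = np.nonzero(np.abs(seps - separation) <= atol)[0]
    if len(match) == 0:
        raise KeyError(
            f"no SAPT energy tabulated at separation {separation!r} "
            f"(available: {sorted(seps.tolist())}); interpolation is not done"
        )
    return float(sapt_table[int(match[0])][1])


# ---------------------------------------------------------------------------
# plain-text I/O


def read_xyz(path) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Read a standard XYZ file (coordinates in angstrom); returns labels
    and coordinates in bohr."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: first line of an XYZ file must be the atom count")
    body = lines[2:2 + n]
    if len(body) < n:
        raise ValueError(f"{path}: expected {n} atom lines, found {len(body)}")
    labels, coords = [], []
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {k + 3}: {line!r}")
        labels.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return tuple(labels), np.asarray(coords) / BOHR_TO_ANGSTROM


def read_hirshfeld_ratios(path, n_atoms: int) -> np.ndarray:
    """Read a sidecar TSV ``index<TAB>ratio`` (0-based indices) into an
    array aligned with the XYZ atom order."""
    ratios = np.full(n_atoms, np.nan)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'index<TAB>ratio', got {raw!r}")
            idx, ratio = int(parts[0]), float(parts[1])
            if not 0 <= idx < n_atoms:
                raise ValueError(f"{path}:{lineno}: atom index {idx} out of range")
            ratios[idx] = ratio
    if np.any(np.isnan(ratios)):
        missing = np.nonzero(np.isnan(ratios))[0].tolist()
        raise ValueError(f"{path}: missing Hirshfeld ratios for atoms {missing}")
    return ratios


def read_sapt_table(path) -> List[Tuple[float, float]]:
    """Read an optional SAPT TSV ``separation<TAB>E1_kcalmol``."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'separation<TAB>energy', got {raw!r}")
            rows.append((float(parts[0]), float(parts[1])))
    return rows


def load_system(xyz_path, ratios_path) -> MolecularSystem:
    """Build a :class:`MolecularSystem` from an XYZ file and its ratio
    sidecar."""
    labels, coords = read_xyz(xyz_path)
    ratios = read_hirshfeld_ratios(ratios_path, len(labels))
    return MolecularSystem(labels, coords, ratios)


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_fixture_dimer(n_atoms_a: int, n_atoms_b: int, separation: float,
                           seed: int) -> Tuple[MolecularSystem, MolecularSystem]:
    """Deterministic synthetic pair of compact C/H clusters for testing.

    Atoms are placed by rejection sampling inside a compact blob with a
    minimum intra-cluster distance of 2 bohr; Hirshfeld ratios are drawn
    uniformly from [0.7, 1.1].  The second cluster is shifted by
    ``separation`` (bohr) along z.  Reproducible from ``seed``.
    """
    if n_atoms_a < 1 or n_atoms_b < 1:
        raise ValueError("both clusters need at least one atom")
    if separation <= _MIN_PAIR_DISTANCE:
        raise ValueError(f"separation must exceed {_MIN_PAIR_DISTANCE} bohr")
    rng = np.random.default_rng(seed)

    def cluster(n, offset):
        coords = np.zeros((n, 3))
        spread = 1.2 * max(1.0, n ** (1.0 / 3.0))
        for k in range(1, n):
            for _ in range(2000):
                trial = rng.normal(scale=spread, size=3)
                if np.min(np.linalg.norm(coords[:k] - trial, axis=1)) >= 2.0:
                    coords[k] = trial
                    break
            else:  # pragma: no cover - would need a pathological spread
                raise RuntimeError("could not place atoms without overlap")
        labels = tuple(rng.choice(["C", "H"]) for _ in range(n))
        ratios = rng.uniform(0.7, 1.1, size=n)
        return MolecularSystem(labels, coords + offset, ratios)

    mol_a = cluster(n_atoms_a, np.zeros(3))
    mol_b = cluster(n_atoms_b, np.array([0.0, 0.0, separation]))
    # guard against infeasible geometries (clusters bleeding into each other)
    min_cross = min(
        float(np.linalg.norm(xa - xb))
        for xa in mol_a.coordinates for xb in mol_b.coordinates
    )
    if min_cross < 1.0:
        raise ValueError(
            f"infeasible geometry: clusters overlap (closest cross pair "
            f"{min_cross:.2f} bohr); increase the separation"
        )
    return mol_a, mol_b
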