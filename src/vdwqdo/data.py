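"""Packaged element data, run configuration, and curve file I/O.

The packaged table carries the free-atom {alpha1, C6} values (atomic
units) together with reference dimer well parameters where available, one
provenance tag per row so data lineage can be audited (including the Rn
dispersion coefficients that come from a different source than the rest).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Optional

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_MEV, energy_from_hartree, length_from_bohr
from .core import AtomProperties

__all__ = [
    "ElementTable",
    "RunConfig",
    "PotentialCurve",
    "load_element_table",
    "write_curve",
    "read_curve",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("element", "alpha1_au", "c6_au", "re_ref_bohr", "de_ref_mev", "source")


@dataclass(frozen=True)
class ElementTable:
    """Mapping element symbol -> :class:`AtomProperties`, plus reference
    dispersion coefficients where tabulated."""

    atoms: Dict[str, AtomProperties]
    reference_c8: Dict[str, float] = field(default_factory=dict)
    reference_c10: Dict[str, float] = field(default_factory=dict)
    families: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, element: str) -> AtomProperties:
        try:
            return self.atoms[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not in the property table "
                f"(available: {', '.join(sorted(self.atoms))})"
            )

    def __contains__(self, element: str) -> bool:
        return element in self.atoms

    def __iter__(self) -> Iterator[str]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


def _builtin_table_text() -> str:
    return resources.files("vdwqdo").joinpath("data/elements.tsv").read_text()


def load_element_table(path: Optional[str] = None) -> ElementTable:
    """Load the packaged element table, or a user TSV with the same columns.

    Duplicate elements resolve last-wins with a warning; a malformed row is
    an error naming its line number; a missing column is an error naming
    the column.
    """
    if path is None:
        text, origin = _builtin_table_text(), "<builtin>"
    else:
        text, origin = Path(path).read_text(), str(path)
    frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).rename(columns=str.strip)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"{origin}: missing required column {column!r}")

    atoms: Dict[str, AtomProperties] = {}
    c8_ref: Dict[str, float] = {}
    c10_ref: Dict[str, float] = {}
    families: Dict[str, str] = {}
    for row_index, row in frame.iterrows():
        lineno = int(row_index) + 2  # header is line 1
        element = str(row["element"]).strip()
        try:
            alpha1 = float(row["alpha1_au"])
            c6 = float(row["c6_au"])
            re_ref = _optional_float(row["re_ref_bohr"])
            de_ref_mev = _optional_float(row["de_ref_mev"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{origin}: malformed row at line {lineno}: {exc}") from exc
        if element in atoms:
            warnings.warn(
                f"{origin}: duplicate element {element!r} at line {lineno}; "
                "last occurrence wins",
                stacklevel=2,
            )
        atoms[element] = AtomProperties(
            label=element,
            alpha1=alpha1,
            c6=c6,
            re_ref=re_ref,
            de_ref=None if de_ref_mev is None else de_ref_mev / HARTREE_TO_MEV,
            source=str(row.get("source", "") or ""),
        )
        families[element] = str(row.get("family", "") or "").strip()
        c8 = _optional_float(row.get("c8_ref_au"))
        c10 = _optional_float(row.get("c10_ref_au"))
        if c8 is not None:
            c8_ref[element] = c8
        if c10 is not None:
            c10_ref[element] = c10
    return ElementTable(atoms=atoms, reference_c8=c8_ref, reference_c10=c10_ref,
                        families=families)


def _optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    return float(text)


@dataclass
class RunConfig:
    """Run-wide configuration, serialized into every output header."""

    length_unit: str = "bohr"
    energy_unit: str = "hartree"
    damped: bool = False
    mixing: str = "qdo"  # 'qdo' (London C6 + alpha mixing) or 'lorentz-berthelot'
    grid_rmin: float = 0.8
    grid_rmax: float = 3.0
    grid_n: int = 200
    verbosity: str = "warning"
    seed: int = 0

    def __post_init__(self):
        from .constants import ENERGY_UNITS, LENGTH_UNITS

        if self.length_unit.lower() not in LENGTH_UNITS:
            raise ValueError(f"unknown length unit {self.length_unit!r}")
        if self.energy_unit.lower() not in ENERGY_UNITS:
            raise ValueError(f"unknown energy unit {self.energy_unit!r}")
        if self.mixing not in ("qdo", "lorentz-berthelot"):
            raise ValueError(f"unknown mixing rule {self.mixing!r}")
        if not (0 < self.grid_rmin < self.grid_rmax):
            raise ValueError("grid bounds must satisfy 0 < rmin < rmax")
        if self.grid_n < 2:
            raise ValueError("grid needs at least two points")

    def header_items(self):
        return {
            "length_unit": self.length_unit,
            "energy_unit": self.energy_unit,
            "damped": self.damped,
            "mixing": self.mixing,
            "grid": f"{self.grid_rmin}:{self.grid_rmax}:{self.grid_n}",
            "seed": self.seed,
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a simple key=value configuration file."""
        values = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs = {}
        for f_name, f_type in (("length_unit", str), ("energy_unit", str),
                               ("mixing", str), ("verbosity", str),
                               ("grid_rmin", float), ("grid_rmax", float),
                               ("grid_n", int), ("seed", int)):
            if f_name in values:
                kwargs[f_name] = f_type(values.pop(f_name))
        if "damped" in values:
            kwargs["damped"] = values.pop("damped").lower() in ("1", "true", "yes", "on")
        if values:
            raise ValueError(f"{path}: unknown configuration keys {sorted(values)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class PotentialCurve:
    """A sampled potential curve; r in bohr, v in hartree internally."""

    r: np.ndarray
    v: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "v", v)
        if r.size == 0:
            raise ValueError("a potential curve needs at least one sample")
        if r.shape != v.shape:
            raise ValueError("r and v must have the same shape")


def write_curve(curve: PotentialCurve, path, fmt: str = "tsv",
                length_unit: str = "bohr", energy_unit: str = "hartree") -> None:
    """Write a curve as TSV/CSV with a provenance header and 12 significant
    digits; units converted at this boundary only."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    r = length_from_bohr(curve.r, length_unit)
    v = energy_from_hartree(curve.v, energy_unit)
    try:
        with open(path, "w") as fh:
            for key, value in curve.meta.items():
                fh.write(f"# {key} = {value}\n")
            fh.write(f"# units = r:{length_unit} v:{energy_unit}\n")
            fh.write(f"r{sep}v\n")
            for ri, vi in zip(r, v):
                fh.write(f"{ri:.12g}{sep}{vi:.12g}\n")
    except OSError as exc:
        raise OSError(f"cannot write curve to {path}: {exc}") from exc


def read_curve(path) -> PotentialCurve:
    """Read a curve written by :func:`write_curve` back into bohr/hartree."""
    meta: Dict[str, object] = {}
    rows = []
    length_unit, energy_unit = "bohr", "hartree"
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                key, value = key.strip(), value.strip()
                if key == "units":
                    for part in value.split():
                        axis, _, unit = part.partition(":")
                        if axis == "r":
                            length_unit = unit
                        elif axis == "v":
                            energy_unit = unit
                elif key:
                    meta[key] = value
                continue
            if line[0].isalpha():  # column header
                continue
            sep = "," if "," in line else None
            rows.append([float(x) for x in line.split(sep)])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    r = arr[:, 0] / length_from_bohr(1.0, length_unit)
    v = arr[:, 1] / energy_from_hartree(1.0, energy_unit)
    return PotentialCurve(r=r, v=v, meta=meta)
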