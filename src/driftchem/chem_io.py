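"""Candidate-structure ensembles: types, validation and file I/O.

A candidate structure is one protomer/conformer of a (multiply) protonated
molecule: Cartesian coordinates, electrostatic-potential-fitted partial
charges, the charge state z, the protonation-site label, and gas/solution
Gibbs energies from quantum chemistry.  Ensembles are stored in an
extended-XYZ dialect::

    <n_atoms>
    molecule=<s> id=<s> z=<int> site=<a|b|c|other|none> g_gas=<f> g_aq=<f>
    <El> <x> <y> <z> <q>
    ...

g_gas/g_aq (kJ/mol) are optional; blocks repeat for multi-structure files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .constants import ATOMIC_MASSES

SITE_LABELS = ("a", "b", "c", "other", "none")

__all__ = [
    "Atom",
    "CandidateStructure",
    "Ensemble",
    "EnsembleValidationError",
    "ParseError",
    "default_lj_table",
    "load_lj_table",
    "read_ensemble",
    "write_ensemble",
]


class ParseError(ValueError):
    """Malformed ensemble file; message names the offending line."""


class EnsembleValidationError(ValueError):
    """Physically inconsistent structure; message names the structure id."""


@dataclass(frozen=True)
class Atom:
    """One atom: element, position (Å), partial charge (e), LJ parameters."""

    element: str
    position: tuple[float, float, float]
    partial_charge: float
    lj_epsilon: float  # kJ/mol
    lj_sigma: float    # Å
    mass: float = 0.0  # u; filled from the element table when 0

    def __post_init__(self):
        if self.element not in ATOMIC_MASSES:
            raise EnsembleValidationError(
                f"unrecognized element symbol {self.element!r}"
            )
        if self.mass == 0.0:
            object.__setattr__(self, "mass", ATOMIC_MASSES[self.element])
        if self.mass <= 0:
            raise EnsembleValidationError(f"non-positive mass for {self.element}")
        if self.lj_epsilon < 0:
            raise EnsembleValidationError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise EnsembleValidationError("lj_sigma must be > 0")


@dataclass
class CandidateStructure:
    """A single protomer/conformer candidate with its thermochemistry."""

    id: str
    molecule: str
    charge_state: int
    site_label: str
    atoms: list[Atom]
    g_gas: float | None = None   # kJ/mol
    g_aq: float | None = None    # kJ/mol
    ccs_calc: float | None = None         # Å², cached engine output
    ccs_calc_stderr: float | None = None  # Å²

    def __post_init__(self):
        if self.charge_state < 0:
            raise EnsembleValidationError(
                f"structure {self.id!r}: charge state must be >= 0"
            )
        if self.site_label not in SITE_LABELS:
            raise EnsembleValidationError(
                f"structure {self.id!r}: unknown site label {self.site_label!r}"
            )
        if not self.atoms:
            raise EnsembleValidationError(f"structure {self.id!r}: no atoms")

    @property
    def charge_sum(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def mass(self) -> float:
        """Total mass in u."""
        return float(sum(a.mass for a in self.atoms))

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def validate(self, charge_tolerance: float = 0.01) -> None:
        """Check the partial charges sum to the declared charge state."""
        dev = abs(self.charge_sum - self.charge_state)
        if dev > charge_tolerance:
            raise EnsembleValidationError(
                f"structure {self.id!r}: partial charges sum to "
                f"{self.charge_sum:.4f} but z={self.charge_state} "
                f"(tolerance {charge_tolerance})"
            )

    def with_ccs(self, ccs: float, stderr: float | None = None) -> "CandidateStructure":
        return replace(self, ccs_calc=ccs, ccs_calc_stderr=stderr)


@dataclass
class Ensemble:
    """All candidate structures considered for one molecule."""

    molecule: str
    candidates: list[CandidateStructure] = field(default_factory=list)
    temperature: float = 298.15  # K

    def __post_init__(self):
        for c in self.candidates:
            if c.molecule != self.molecule:
                raise EnsembleValidationError(
                    f"candidate {c.id!r} belongs to molecule {c.molecule!r}, "
                    f"not {self.molecule!r}"
                )
        ids = [c.id for c in self.candidates]
        if len(ids) != len(set(ids)):
            raise EnsembleValidationError("duplicate candidate ids in ensemble")

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)

    def get(self, cid: str) -> CandidateStructure:
        for c in self.candidates:
            if c.id == cid:
                return c
        raise KeyError(cid)


def default_lj_table() -> dict[str, tuple[float, float]]:
    """Built-in element → (ε kJ/mol, σ Å) map (UFF-derived defaults)."""
    text = resources.files("driftchem.data").joinpath("lj_params.yaml").read_text()
    raw = yaml.safe_load(text)
    return {el: (v["epsilon_kJmol"], v["sigma_A"]) for el, v in raw.items()}


def load_lj_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Load a user LJ table (YAML, same schema as the built-in one)."""
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for el, v in raw.items():
        try:
            out[el] = (float(v["epsilon_kJmol"]), float(v["sigma_A"]))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"LJ table entry for {el!r} malformed: {exc}") from exc
    return out


def _parse_comment(line: str, lineno: int) -> dict[str, str]:
    fields = {}
    for tok in line.split():
        if "=" not in tok:
            raise ParseError(f"line {lineno}: expected key=value tokens, got {tok!r}")
        k, v = tok.split("=", 1)
        fields[k] = v
    return fields


def read_ensemble(
    path: str | Path,
    lj_table: Mapping[str, tuple[float, float]] | None = None,
    charge_tolerance: float = 0.01,
) -> Ensemble:
    """Read an ensemble file in the extended-XYZ dialect.

    Parameters
    ----------
    path:
        File to read (one or more structure blocks).
    lj_table:
        element → (ε, σ) map; defaults to the built-in table.  A missing
        element raises a configuration error naming the element.
    charge_tolerance:
        Allowed |Σq − z| per structure (e).
    """
    lj = dict(lj_table) if lj_table is not None else default_lj_table()
    lines = Path(path).read_text().splitlines()
    candidates: list[CandidateStructure] = []
    molecule = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 2}: missing comment line")
        meta = _parse_comment(lines[i + 1], i + 2)
        for key in ("molecule", "id", "z", "site"):
            if key not in meta:
                raise ParseError(f"line {i + 2}: missing required key {key!r}")
        atoms = []
        for j in range(n_atoms):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ParseError(f"line {ln + 1}: unexpected end of file")
            parts = lines[ln].split()
            if len(parts) != 5:
                raise ParseError(
                    f"line {ln + 1}: expected 'El x y z q', got {lines[ln]!r}"
                )
            el = parts[0]
            try:
                x, y, z, q = (float(p) for p in parts[1:])
            except ValueError:
                raise ParseError(f"line {ln + 1}: non-numeric atom fields")
            if el not in lj:
                raise KeyError(
                    f"no Lennard-Jones parameters configured for element {el!r} "
                    f"(line {ln + 1}); add it to the LJ table"
                )
            eps, sig = lj[el]
            atoms.append(Atom(el, (x, y, z), q, eps, sig))
        cand = CandidateStructure(
            id=meta["id"],
            molecule=meta["molecule"],
            charge_state=int(meta["z"]),
            site_label=meta["site"],
            atoms=atoms,
            g_gas=float(meta["g_gas"]) if "g_gas" in meta else None,
            g_aq=float(meta["g_aq"]) if "g_aq" in meta else None,
            ccs_calc=float(meta["ccs_calc"]) if "ccs_calc" in meta else None,
        )
        cand.validate(charge_tolerance)
        if molecule is None:
            molecule = cand.molecule
        candidates.append(cand)
        i += 2 + n_atoms
    if not candidates:
        raise ParseError(f"{path}: no structures found")
    return Ensemble(molecule=molecule, candidates=candidates)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble in the extended-XYZ dialect (lossless round trip)."""
    if not ensemble.candidates:
        raise ValueError("refusing to write an empty ensemble")
    out = []
    for c in ensemble.candidates:
        meta = [
            f"molecule={c.molecule}",
            f"id={c.id}",
            f"z={c.charge_state}",
            f"site={c.site_label}",
        ]
        if c.g_gas is not None:
            meta.append(f"g_gas={c.g_gas:.6f}")
        if c.g_aq is not None:
            meta.append(f"g_aq={c.g_aq:.6f}")
        if c.ccs_calc is not None:
            meta.append(f"ccs_calc={c.ccs_calc:.6f}")
        out.append(str(len(c.atoms)))
        out.append(" ".join(meta))
        for a in c.atoms:
            x, y, z = a.position
            out.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f} {a.partial_charge:.6f}")
    Path(path).write_text("\n".join(out) + "\n")
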