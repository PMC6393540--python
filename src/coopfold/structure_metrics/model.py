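"""Structure model, PDB reading/writing and atom selections.

Author residue numbering is used everywhere; ranges are inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "Selection",
    "read_structure",
    "write_pdb",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "ATOM_SETS",
]

#: Bondi van der Waals radii (Angstrom); fallback handled by callers.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}

#: Named atom sets accepted in selection strings.
ATOM_SETS: dict[str, frozenset[str] | None] = {
    "backbone": frozenset({"N", "CA", "C", "O"}),
    "ca": frozenset({"CA"}),
    "heavy": None,  # all non-hydrogen atoms
    "all": None,
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """One atom record (author numbering, Angstrom coordinates)."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass(frozen=True)
class Selection:
    """Chains + inclusive residue ranges + atom-name set.

    ``atom_names=None`` selects every atom of the residues.  String syntax
    (``Selection.parse``): ``chain[,chain...][:start-end[,start-end...][:atomset]]``
    e.g. ``A:4-99:backbone`` or ``A,B``.
    """

    chains: frozenset[str]
    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] | None = None
    exclude_hydrogens: bool = False

    @classmethod
    def parse(cls, text: str) -> "Selection":
        parts = text.strip().split(":")
        if not parts or not parts[0]:
            raise ValueError(f"selection needs a chain id: {text!r}")
        chains = frozenset(c.strip() for c in parts[0].split(",") if c.strip())
        ranges: tuple[tuple[int, int], ...] = ()
        atom_names: frozenset[str] | None = None
        exclude_h = False
        if len(parts) >= 2 and parts[1]:
            out = []
            for chunk in parts[1].split(","):
                if "-" in chunk:
                    lo, _, hi = chunk.partition("-")
                    out.append((int(lo), int(hi)))
                else:
                    v = int(chunk)
                    out.append((v, v))
            ranges = tuple(out)
        if len(parts) >= 3 and parts[2]:
            key = parts[2].strip().lower()
            if key in ATOM_SETS:
                atom_names = ATOM_SETS[key]
                exclude_h = key == "heavy"
            else:
                atom_names = frozenset(
                    a.strip().upper() for a in parts[2].split("+") if a.strip()
                )
        if len(parts) > 3:
            raise ValueError(f"malformed selection: {text!r}")
        return cls(chains=chains, residue_ranges=ranges, atom_names=atom_names,
                   exclude_hydrogens=exclude_h)

    def matches(self, atom: Atom) -> bool:
        if atom.chain not in self.chains:
            return False
        if self.residue_ranges and not any(
            lo <= atom.resnum <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.exclude_hydrogens and atom.element == "H":
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


@dataclass(frozen=True)
class StructureModel:
    """An ordered collection of atoms from one model of one structure."""

    atoms: tuple[Atom, ...]
    label: str = ""

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        for a in atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates on atom {a}")
        seen: set[tuple] = set()
        for a in atoms:
            key = (a.chain, a.resnum, a.icode, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc filtering: {key}")
            seen.add(key)
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    def select(self, selection: Selection | str) -> "StructureModel":
        if isinstance(selection, str):
            selection = Selection.parse(selection)
        picked = tuple(a for a in self.atoms if selection.matches(a))
        if not picked:
            raise ValueError(f"selection matches no atoms: {selection}")
        return StructureModel(atoms=picked, label=self.label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """New model with coordinates x -> R x + t."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_coords = self.coords @ rot.T + t
        atoms = tuple(
            Atom(a.chain, a.resnum, a.icode, a.resname, a.name, a.element,
                 float(c[0]), float(c[1]), float(c[2]), a.occupancy, a.hetero)
            for a, c in zip(self.atoms, new_coords)
        )
        return StructureModel(atoms=atoms, label=self.label)

    def masses(self, fallback: float = 12.011) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(a.element.upper(), fallback) for a in self.atoms]
        )

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out


def _guess_element(atom_name: str, resname: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if name[:2].upper() in VDW_RADII and len(name) >= 2 and name[:2].isalpha():
        # Two-letter elements only when the PDB name starts in column 13,
        # which we cannot see here; default to the first letter for organics.
        pass
    return name[0].upper()


def read_structure(
    path: str | Path,
    model_index: int = 1,
    altloc: str = "A",
    include_hetero: bool = False,
) -> StructureModel:
    """Read one model from a PDB file into a StructureModel.

    Keeps atoms whose altloc is blank or equal to ``altloc``; HETATM
    records are excluded unless ``include_hetero``; waters are always
    excluded.  ``model_index`` is 1-based over the MODEL records.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")
    if not 1 <= model_index <= len(models):
        raise ValueError(
            f"model_index {model_index} out of range (file has {len(models)})"
        )
    model = models[model_index - 1]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.get_id()
            is_water = hetflag == "W" or residue.get_resname().strip() in _WATER_NAMES
            if is_water:
                continue
            is_het = hetflag.strip() != ""
            if is_het and not include_hetero:
                continue
            for atom in residue.get_unpacked_list():
                alt = atom.get_altloc().strip()
                if alt not in ("", altloc):
                    continue
                element = (atom.element or "").strip().upper()
                if not element:
                    element = _guess_element(atom.get_name(), residue.get_resname())
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(
                    Atom(
                        chain=chain.get_id(),
                        resnum=int(resnum),
                        icode=icode.strip(),
                        resname=residue.get_resname().strip(),
                        name=atom.get_name().strip(),
                        element=element,
                        x=x, y=y, z=z,
                        occupancy=float(atom.get_occupancy() or 1.0),
                        hetero=is_het,
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms retained from {path}")
    return StructureModel(atoms=tuple(atoms), label=path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a minimal PDB file."""
    path = Path(path)
    lines = []
    for serial, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{serial:5d} {name:<4.4s} {a.resname:<3.3s} "
            f"{a.chain:1.1s}{a.resnum:4d}{a.icode or ' ':1.1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
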