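"""Reading PDB structures and building active-site templates.

A *template* is an ordered set of atoms taken from an annotated enzyme
active site.  Each source residue carries one of four role annotations that
decide which of its atoms enter the template:

* ``catalytic_site`` and ``modified`` residues contribute sidechain atoms,
* ``cofactor_binding_site`` residues contribute all atoms,
* ``mainchain_catalytic`` residues contribute mainchain atoms (N, CA, C, O).

The atom order of a template is fixed at construction time and persisted:
it defines the feature ordering used by every downstream measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ProteinStructure",
    "ResidueRole",
    "Template",
    "read_pdb",
    "write_pdb",
    "build_template",
    "write_template",
    "read_template",
    "sidechain_atom_names",
    "mainchain_atom_names",
    "StructureFormatError",
    "EmptyStructureError",
    "MissingResidueError",
    "DegenerateTemplateError",
]


class StructureFormatError(ValueError):
    """Input file is not parseable in the expected format."""


class EmptyStructureError(StructureFormatError):
    """PDB file contains no atom records."""


class MissingResidueError(KeyError):
    """A residue spec does not resolve to any residue in the structure."""


class DegenerateTemplateError(ValueError):
    """Template would hold fewer than two atoms."""


MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

# Heavy atoms of the 20 standard amino acids in PDB v3 standard order.
# Sidechain = heavy atoms minus {N, CA, C, O, OXT}.
STANDARD_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}


def mainchain_atom_names(residue_name: str) -> tuple[str, ...]:
    return MAINCHAIN_ATOMS


def sidechain_atom_names(residue_name: str) -> tuple[str, ...]:
    """Heavy sidechain atom names of a standard residue (may be empty: GLY)."""
    heavy = STANDARD_HEAVY_ATOMS.get(residue_name.upper())
    if heavy is None:
        raise KeyError(f"unknown residue name {residue_name!r}")
    excluded = set(MAINCHAIN_ATOMS) | {"OXT"}
    return tuple(a for a in heavy if a not in excluded)


class ResidueRole(Enum):
    CATALYTIC_SITE = "catalytic_site"
    COFACTOR_BINDING_SITE = "cofactor_binding_site"
    MODIFIED = "modified"
    MAINCHAIN_CATALYTIC = "mainchain_catalytic"


@dataclass(frozen=True)
class Atom:
    """A single atom record: name, residue identity and coordinates in Å."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: tuple[float, float, float]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.icode,
                self.residue_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class ProteinStructure:
    structure_id: str
    atoms: list[Atom]

    @property
    def residues(self) -> dict[tuple[str, int, str, str], list[Atom]]:
        """Atoms grouped by (chain, residue number, insertion code, name)."""
        groups: dict[tuple[str, int, str, str], list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_key, []).append(atom)
        return groups

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Template:
    """Ordered atom set used as a structural query (m >= 2 atoms)."""

    template_id: str
    atoms: list[Atom]
    roles: list[ResidueRole]  # one role per atom, from its source residue
    function_label: str

    def __post_init__(self) -> None:
        if len(self.atoms) < 2:
            raise DegenerateTemplateError(
                f"template {self.template_id!r} has {len(self.atoms)} atoms; "
                "at least 2 required")
        if len(self.roles) != len(self.atoms):
            raise ValueError("one role per atom required")

    @property
    def m(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_groups(self) -> list[tuple[tuple[str, int, str, str],
                                           list[int]]]:
        """Source residues in first-appearance order with atom indices."""
        order: list[tuple[str, int, str, str]] = []
        groups: dict[tuple[str, int, str, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        return [(key, groups[key]) for key in order]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, structure_id: str | None = None
             ) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first model is read.  Alternate locations other than blank or
    'A' are dropped.  Insertion codes are preserved as part of residue
    identity.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                for at in res:
                    if at.altloc not in ("", "\0", "A"):
                        continue
                    atoms.append(Atom(
                        atom_name=at.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        icode=(res.seqid.icode or "").strip(),
                    ))
    if not atoms:
        raise EmptyStructureError(f"{path} contains no atom records")
    sid = structure_id if structure_id is not None else (st.name or path.stem)
    return ProteinStructure(structure_id=sid.lower(), atoms=atoms)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write minimal fixed-width ATOM records (heavy atoms, single model)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name
        # PDB atom-name column convention: element right-justified in 14-15
        padded = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {padded:<4s} {a.residue_name:>3s} {a.chain_id:1s}"
            f"{a.residue_number:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{name[0]:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def _canonical_sort_key(residue_name: str):
    heavy = STANDARD_HEAVY_ATOMS.get(residue_name.upper(), ())
    index = {name: i for i, name in enumerate(heavy)}

    def key(atom: Atom):
        return (index.get(atom.atom_name, len(heavy)), atom.atom_name)

    return key


def _select_atoms(residue_atoms: list[Atom], role: ResidueRole) -> list[Atom]:
    resname = residue_atoms[0].residue_name
    if role is ResidueRole.COFACTOR_BINDING_SITE:
        wanted = None  # all atoms
    elif role is ResidueRole.MAINCHAIN_CATALYTIC:
        wanted = set(MAINCHAIN_ATOMS)
    else:  # catalytic_site or modified: sidechain only
        try:
            side = sidechain_atom_names(resname)
        except KeyError:
            side = ()
        if not side:
            # Glycine (and other sidechain-less cases) cannot contribute
            # sidechain atoms; fall back to the mainchain.
            warnings.warn(
                f"residue {resname} has no sidechain; using mainchain atoms",
                stacklevel=3)
            wanted = set(MAINCHAIN_ATOMS)
        else:
            wanted = set(side)
    selected = [a for a in residue_atoms
                if wanted is None or a.atom_name in wanted]
    return sorted(selected, key=_canonical_sort_key(resname))


def build_template(structure: ProteinStructure,
                   residue_specs: list[tuple[str, int, ResidueRole]],
                   template_id: str | None = None,
                   function_label: str = "") -> Template:
    """Build a template from role-annotated residues of a structure.

    ``residue_specs`` is an ordered list of (chain_id, residue_number, role);
    atom selection per role follows the four-way convention documented in
    the module docstring.  Atoms are ordered by the listed residue order,
    then by the canonical PDB atom-name order within each residue.
    """
    residues = structure.residues
    atoms: list[Atom] = []
    roles: list[ResidueRole] = []
    for chain_id, resnum, role in residue_specs:
        matches = [key for key in residues
                   if key[0] == chain_id and key[1] == resnum]
        if not matches:
            raise MissingResidueError(
                f"no residue {chain_id}/{resnum} in {structure.structure_id}")
        key = sorted(matches)[0]
        selected = _select_atoms(residues[key], role)
        atoms.extend(selected)
        roles.extend([role] * len(selected))
    if len(atoms) < 2:
        raise DegenerateTemplateError(
            f"selection yields {len(atoms)} atoms; at least 2 required")
    tid = template_id or structure.structure_id
    return Template(template_id=tid, atoms=atoms, roles=roles,
                    function_label=function_label)


# ---------------------------------------------------------------------------
# Template serialization (small line-oriented text format)
# ---------------------------------------------------------------------------

_TEMPLATE_MAGIC = "# actsite template v1"


def write_template(template: Template, path: str | Path) -> None:
    lines = [_TEMPLATE_MAGIC,
             f"template_id\t{template.template_id}",
             f"function_label\t{template.function_label}"]
    for atom, role in zip(template.atoms, template.roles):
        x, y, z = atom.coords
        lines.append("atom\t" + "\t".join([
            atom.chain_id, str(atom.residue_number), atom.icode or "-",
            atom.residue_name, atom.atom_name, role.value,
            f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_template(path: str | Path) -> Template:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _TEMPLATE_MAGIC:
        raise StructureFormatError(f"{path}: not an actsite template file")
    template_id = ""
    function_label = ""
    atoms: list[Atom] = []
    roles: list[ResidueRole] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "template_id":
            template_id = fields[1]
        elif fields[0] == "function_label":
            function_label = fields[1] if len(fields) > 1 else ""
        elif fields[0] == "atom":
            if len(fields) != 10:
                raise StructureFormatError(f"{path}: malformed atom line")
            (_, chain, resnum, icode, resname, atomname, role_token,
             x, y, z) = fields
            try:
                role = ResidueRole(role_token)
            except ValueError as exc:
                raise StructureFormatError(
                    f"{path}: unknown role {role_token!r}") from exc
            atoms.append(Atom(
                atom_name=atomname, residue_name=resname,
                residue_number=int(resnum), chain_id=chain,
                coords=(float(x), float(y), float(z)),
                icode="" if icode == "-" else icode))
            roles.append(role)
        else:
            raise StructureFormatError(
                f"{path}: unknown record {fields[0]!r}")
    if len(atoms) < 2:
        raise DegenerateTemplateError(
            f"{path}: template holds {len(atoms)} atoms; at least 2 required")
    return Template(template_id=template_id, atoms=atoms, roles=roles,
                    function_label=function_label)
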