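"""Local site search: enumerate candidate sites matching a template.

Given a template and a protein structure, the search returns every *local
site*: an ordered atom set drawn from distinct protein residues whose
residue names match the template's source residues and which contains all
required atom names, with RMSD to the template (after optimal superposition)
no larger than a cutoff (4.0 Å by default).

Candidates are enumerated by backtracking over residue assignments, pruned
by pairwise-distance compatibility before any superposition: if the site's
RMSD is within the cutoff c, every inter-atom distance can differ from the
template's by at most 2·c·√m, so that bound is a sound pre-filter.

Chemically equivalent sidechain atoms (e.g. ASP OD1/OD2) admit more than one
atom-level correspondence; all admissible mappings are generated and the
lowest-RMSD one is kept per residue combination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import umd
from .structures_io import Atom, ProteinStructure, Template

__all__ = ["LocalSite", "search", "label_sites", "distance_slack",
           "write_sites_tsv", "read_sites_tsv"]

# Swap groups of chemically indistinguishable heavy atoms.  Each group is a
# tuple of (name_a, name_b) pairs that are exchanged together.
EQUIVALENT_ATOM_SWAPS: dict[str, list[tuple[tuple[str, str], ...]]] = {
    "ASP": [(("OD1", "OD2"),)],
    "GLU": [(("OE1", "OE2"),)],
    "ARG": [(("NH1", "NH2"),)],
    "LEU": [(("CD1", "CD2"),)],
    "VAL": [(("CG1", "CG2"),)],
    "PHE": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "TYR": [(("CD1", "CD2"), ("CE1", "CE2"))],
}

ResidueKey = tuple[str, int, str, str]


@dataclass
class LocalSite:
    """Atoms of a candidate site, ordered by template correspondence."""

    structure_id: str
    atoms: list[Atom]
    template_id: str
    label: int = 0  # +1 positive, -1 negative, 0 unknown

    @property
    def m(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_keys(self) -> tuple[ResidueKey, ...]:
        seen: list[ResidueKey] = []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.append(a.residue_key)
        return tuple(seen)

    def residue_label(self) -> str:
        return ", ".join(f"{k[3]} {k[1]}{k[2]} {k[0]}"
                         for k in self.residue_keys)


def distance_slack(rmsd_cutoff: float, m: int) -> float:
    """Sound pairwise-distance pruning bound: 2·cutoff·√m."""
    return 2.0 * rmsd_cutoff * np.sqrt(m)


def _atom_mappings(residue_atoms: list[Atom], resname: str,
                   required_names: list[str]) -> list[list[Atom]]:
    """All admissible orderings of the residue's atoms matching the
    template's required atom names, including equivalent-atom swaps."""
    by_name = {}
    for a in residue_atoms:
        by_name.setdefault(a.atom_name, a)
    mappings: list[list[Atom]] = []
    swap_groups = EQUIVALENT_ATOM_SWAPS.get(resname, [])
    # Each swap group is independently applied or not.
    for flags in itertools.product([False, True], repeat=len(swap_groups)):
        rename: dict[str, str] = {}
        for applied, group in zip(flags, swap_groups):
            if applied:
                for a_name, b_name in group:
                    rename[a_name] = b_name
                    rename[b_name] = a_name
        selected = []
        ok = True
        for name in required_names:
            actual = rename.get(name, name)
            atom = by_name.get(actual)
            if atom is None:
                ok = False
                break
            selected.append(atom)
        if ok and selected not in mappings:
            mappings.append(selected)
    return mappings


def _compatible(new_coords: np.ndarray, placed_coords: list[np.ndarray],
                template_coords: np.ndarray, placed_idx: list[np.ndarray],
                new_idx: np.ndarray, slack: float) -> bool:
    """Check template-vs-site distance agreement between the new residue's
    atoms and every already-placed residue's atoms."""
    for coords, idx in zip(placed_coords, placed_idx):
        d_site = np.linalg.norm(
            new_coords[:, None, :] - coords[None, :, :], axis=2)
        d_tmpl = np.linalg.norm(
            template_coords[new_idx][:, None, :]
            - template_coords[idx][None, :, :], axis=2)
        if np.any(np.abs(d_site - d_tmpl) > slack):
            return False
    return True


def search(protein: ProteinStructure, template: Template,
           rmsd_cutoff: float = 4.0) -> list[LocalSite]:
    """Enumerate all local sites of the protein matching the template.

    Returns sites in canonical order (by chain/residue identity); an empty
    list is a valid result.
    """
    groups = template.residue_groups()
    t_coords = template.coords
    m = template.m
    slack = distance_slack(rmsd_cutoff, m)

    # Candidate (protein residue, atom mapping) units per template residue.
    candidates: list[list[tuple[ResidueKey, list[Atom], np.ndarray]]] = []
    residues = protein.residues
    for key, atom_idx in groups:
        resname = key[3]
        required = [template.atoms[i].atom_name for i in atom_idx]
        units = []
        for pkey, patoms in residues.items():
            if pkey[3] != resname:
                continue
            for mapping in _atom_mappings(patoms, resname, required):
                units.append((pkey, mapping,
                              np.array([a.coords for a in mapping])))
        if not units:
            return []
        candidates.append(units)

    idx_arrays = [np.asarray(atom_idx) for _, atom_idx in groups]
    found: dict[tuple[ResidueKey, ...], tuple[float, LocalSite]] = {}

    def backtrack(level: int, used: set[ResidueKey],
                  placed_atoms: list[list[Atom]],
                  placed_coords: list[np.ndarray]) -> None:
        if level == len(groups):
            atoms = [a for group in placed_atoms for a in group]
            site = LocalSite(structure_id=protein.structure_id, atoms=atoms,
                             template_id=template.template_id)
            dev = umd(site.coords, t_coords)
            if dev <= rmsd_cutoff ** 2 + 1e-12:
                rkey = tuple(g[0].residue_key for g in placed_atoms)
                prev = found.get(rkey)
                if prev is None or dev < prev[0]:
                    found[rkey] = (dev, site)
            return
        for pkey, mapping, coords in candidates[level]:
            if pkey in used:
                continue
            if not _compatible(coords, placed_coords, t_coords,
                               idx_arrays[:level], idx_arrays[level], slack):
                continue
            backtrack(level + 1, used | {pkey}, placed_atoms + [mapping],
                      placed_coords + [coords])

    backtrack(0, set(), [], [])

    def sort_key(item):
        rkey = item[0]
        return tuple((k[0], k[1], k[2]) for k in rkey)

    return [site for _, (dev, site) in sorted(found.items(), key=sort_key)]


def label_sites(sites: list[LocalSite],
                annotations: dict[str, list[tuple[frozenset, str]]],
                template: Template) -> list[LocalSite]:
    """Attach ±1 labels to searched sites.

    ``annotations`` maps structure_id to the list of annotated active sites,
    each a (frozenset of (chain, resnum, icode) residue keys, function label)
    pair.  A site is positive iff its residue set matches an annotated site
    whose function label equals the template's; negative otherwise.  Sites
    from structures absent from the annotation map keep an unknown label.
    """
    labeled = []
    for site in sites:
        if site.structure_id not in annotations:
            labeled.append(site)
            continue
        site_res = frozenset((k[0], k[1], k[2]) for k in site.residue_keys)
        label = -1
        for ann_res, function_label in annotations[site.structure_id]:
            if ann_res == site_res and \
                    function_label == template.function_label:
                label = 1
                break
        labeled.append(LocalSite(structure_id=site.structure_id,
                                 atoms=site.atoms,
                                 template_id=site.template_id, label=label))
    return labeled


# ---------------------------------------------------------------------------
# Site table serialization (TSV, one row per atom)
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ("site_index", "structure_id", "template_id", "label",
                 "chain", "resnum", "icode", "resname", "atomname",
                 "x", "y", "z")


def write_sites_tsv(sites: list[LocalSite], path) -> None:
    lines = ["\t".join(_SITE_COLUMNS)]
    for j, site in enumerate(sites):
        for a in site.atoms:
            x, y, z = a.coords
            lines.append("\t".join([
                str(j), site.structure_id, site.template_id, str(site.label),
                a.chain_id, str(a.residue_number), a.icode or "-",
                a.residue_name, a.atom_name,
                f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]))
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites_tsv(path) -> list[LocalSite]:
    from pathlib import Path
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_SITE_COLUMNS):
        raise ValueError(f"{path}: not a site table")
    sites: dict[int, LocalSite] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        (j, sid, tid, label, chain, resnum, icode, resname, atomname,
         x, y, z) = line.split("\t")
        atom = Atom(atom_name=atomname, residue_name=resname,
                    residue_number=int(resnum), chain_id=chain,
                    coords=(float(x), float(y), float(z)),
                    icode="" if icode == "-" else icode)
        j = int(j)
        if j not in sites:
            sites[j] = LocalSite(structure_id=sid, atoms=[],
                                 template_id=tid, label=int(label))
        sites[j].atoms.append(atom)
    return [sites[j] for j in sorted(sites)]
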