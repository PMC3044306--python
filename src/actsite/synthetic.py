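"""Synthetic fixtures: templates, labeled sites and PDB-format proteins.

The generator emulates the statistical structure the learning algorithms
assume: an active-site template whose atoms are conserved to different
degrees.  Positive sites are rigid-transformed copies of the template with
per-atom Gaussian displacement (conserved atoms get small sigma, variable
atoms larger sigma); negative (decoy) sites are the same construction with a
uniformly large sigma, so they share the template's residue composition and
pass the search composition filter but deviate more.

The default *heterogeneous-noise benchmark* is: m = 6 atoms, 2 conserved at
sigma 0.05 Å, 4 variable at sigma 0.8 Å, decoys at sigma 1.5 Å, 50 positives
and 500 negatives (1:10 class skew).  Under it the unweighted deviation is
informative but imperfect, leaving measurable headroom for the learned
measurements.

All generation is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lss import LocalSite
from .structures_io import Atom, ProteinStructure, ResidueRole, Template

__all__ = [
    "NoiseProfile",
    "heterogeneous_noise_profile",
    "make_template",
    "make_sites",
    "make_protein_fixture",
    "GenerationError",
    "BENCHMARK_N_POS",
    "BENCHMARK_N_NEG",
]

# One-atom catalytic residue pool used to name template atoms.
ATOM_POOL: tuple[tuple[str, str], ...] = (
    ("SER", "OG"), ("HIS", "NE2"), ("ASP", "OD1"), ("LYS", "NZ"),
    ("TYR", "OH"), ("HIS", "ND1"), ("ASP", "OD2"), ("GLU", "OE1"),
)

BENCHMARK_N_POS = 50
BENCHMARK_N_NEG = 500


class GenerationError(RuntimeError):
    """Constraint-satisfying generation failed."""


@dataclass
class NoiseProfile:
    """Per-atom Gaussian displacement model of site variability (Å)."""

    per_atom_sigma: np.ndarray
    decoy_sigma: float
    n_conserved: int

    def __post_init__(self) -> None:
        self.per_atom_sigma = np.asarray(self.per_atom_sigma, dtype=float)
        if np.any(self.per_atom_sigma < 0) or self.decoy_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_conserved > self.per_atom_sigma.size:
            raise ValueError("n_conserved exceeds atom count")


def heterogeneous_noise_profile(m: int = 6, n_conserved: int = 2,
                                conserved_sigma: float = 0.05,
                                variable_sigma: float = 0.8,
                                decoy_sigma: float = 1.5) -> NoiseProfile:
    """The default benchmark noise profile (conserved + variable atoms)."""
    sigma = np.full(m, variable_sigma)
    sigma[:n_conserved] = conserved_sigma
    return NoiseProfile(per_atom_sigma=sigma, decoy_sigma=decoy_sigma,
                        n_conserved=n_conserved)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_template(m: int, span: float = 10.0, seed: int = 0,
                  function_label: str = "synthetic-reaction",
                  template_id: str | None = None,
                  min_distance: float = 2.0,
                  max_tries: int = 10_000) -> Template:
    """Generate an m-atom template with pairwise distances in [2, span] Å.

    Atoms are assigned residue and atom names from a catalytic-residue pool,
    one residue per atom.
    """
    if m < 3:
        raise ValueError("at least 3 atoms required")
    rng = np.random.default_rng(seed)
    side = span / np.sqrt(3.0)  # cube diagonal = span bounds all pairs
    for _ in range(max_tries):
        coords = rng.uniform(0.0, side, size=(m, 3))
        diffs = coords[:, None, :] - coords[None, :, :]
        dists = np.linalg.norm(diffs, axis=2)
        iu = np.triu_indices(m, k=1)
        if np.all(dists[iu] >= min_distance) and np.all(dists[iu] <= span):
            break
    else:
        raise GenerationError(
            f"cannot place {m} atoms with pair distances in "
            f"[{min_distance}, {span}] Å")
    atoms = []
    for i in range(m):
        resname, atomname = ATOM_POOL[i % len(ATOM_POOL)]
        atoms.append(Atom(atom_name=atomname, residue_name=resname,
                          residue_number=i + 1, chain_id="A",
                          coords=tuple(coords[i])))
    tid = template_id or f"synth-t{seed}"
    return Template(template_id=tid, atoms=atoms,
                    roles=[ResidueRole.CATALYTIC_SITE] * m,
                    function_label=function_label)


def _perturbed_copy(template: Template, sigma: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    coords = template.coords
    A = _random_rotation(rng)
    b = rng.uniform(-50.0, 50.0, size=3)
    return coords @ A.T + b + rng.standard_normal(coords.shape) \
        * sigma[:, None]


def _site_from_coords(template: Template, coords: np.ndarray,
                      structure_id: str, label: int) -> LocalSite:
    atoms = [Atom(atom_name=a.atom_name, residue_name=a.residue_name,
                  residue_number=a.residue_number, chain_id=a.chain_id,
                  coords=tuple(xyz), icode=a.icode)
             for a, xyz in zip(template.atoms, coords)]
    return LocalSite(structure_id=structure_id, atoms=atoms,
                     template_id=template.template_id, label=label)


def make_sites(template: Template, n_pos: int, n_neg: int,
               profile: NoiseProfile | None = None, seed: int = 0,
               n_structures: int | None = None,
               decoy_mode: str = "noise") -> list[LocalSite]:
    """Generate labeled positive and decoy sites for one template.

    Positives are rigid-transformed template copies with per-atom Gaussian
    noise; negatives use the (larger) decoy sigma on all atoms, or a
    distance-matrix shuffle (``decoy_mode="shuffle"``: atom order permuted
    before the noise, destroying the geometry while keeping composition).
    If ``n_structures`` is given, sites are assigned round-robin to that many
    pseudo-structure ids (several sites per structure, as in a real protein);
    otherwise each site gets its own structure id.
    """
    if n_pos < 1 or n_neg < 1:
        raise GenerationError("need at least one site of each class")
    if profile is None:
        profile = heterogeneous_noise_profile(template.m)
    if profile.per_atom_sigma.size != template.m:
        raise ValueError("noise profile does not match template size")
    rng = np.random.default_rng(seed)
    sites: list[LocalSite] = []

    def sid(index: int) -> str:
        if n_structures is None:
            return f"synth{index:05d}"
        return f"synth{index % n_structures:05d}"

    for i in range(n_pos):
        coords = _perturbed_copy(template, profile.per_atom_sigma, rng)
        sites.append(_site_from_coords(template, coords, sid(i), +1))
    decoy_sigma = np.full(template.m, profile.decoy_sigma)
    for i in range(n_neg):
        coords = _perturbed_copy(template, decoy_sigma, rng)
        if decoy_mode == "shuffle":
            coords = coords[rng.permutation(template.m)]
        sites.append(_site_from_coords(template, coords,
                                       sid(n_pos + i), -1))
    return sites


def make_protein_fixture(template: Template, planted: bool = True,
                         n_decoy_residues: int = 10, seed: int = 0,
                         noise_sigma: float = 0.2,
                         structure_id: str | None = None,
                         box: float = 60.0,
                         ) -> tuple[ProteinStructure, dict]:
    """Build a PDB-writable protein containing decoys and, optionally, one
    planted noisy copy of the template.

    Decoy residues reuse the template's residue types so the search
    composition filter cannot dismiss them trivially.  Returns the structure
    and its ground-truth annotation record
    ``{structure_id: [(residue-key frozenset, function_label), ...]}``.
    """
    if n_decoy_residues < 0:
        raise ValueError("n_decoy_residues must be non-negative")
    rng = np.random.default_rng(seed)
    sid = structure_id or f"fixture{seed:04d}"
    atoms: list[Atom] = []
    taken: list[np.ndarray] = []
    annotated: list[tuple[frozenset, str]] = []
    resnum = 0
    if planted:
        sigma = np.full(template.m, noise_sigma)
        coords = _perturbed_copy(template, sigma, rng)
        # Recenter the planted copy inside the box.
        coords = coords - coords.mean(axis=0) + box / 2.0
        keys = []
        for a, xyz in zip(template.atoms, coords):
            resnum += 1
            atoms.append(Atom(atom_name=a.atom_name,
                              residue_name=a.residue_name,
                              residue_number=resnum, chain_id="A",
                              coords=tuple(xyz)))
            keys.append(("A", resnum, ""))
            taken.append(xyz)
        annotated.append((frozenset(keys), template.function_label))
    for i in range(n_decoy_residues):
        resname, atomname = ATOM_POOL[i % len(ATOM_POOL)]
        for _ in range(10_000):
            xyz = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(xyz - t) >= 2.5 for t in taken):
                break
        else:
            raise GenerationError("cannot place decoy residue")
        resnum += 1
        atoms.append(Atom(atom_name=atomname, residue_name=resname,
                          residue_number=resnum, chain_id="A",
                          coords=tuple(xyz)))
        taken.append(xyz)
    structure = ProteinStructure(structure_id=sid, atoms=atoms)
    return structure, {sid: annotated}
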