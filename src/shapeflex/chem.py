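"""Molecular data model, SDF I/O, conformer generation and MMFF94 contract.

`Molecule3D` is a plain 3D molecular graph: elements, formal charges,
explicit-hydrogen coordinates and a kekulized bond list. RDKit does the
heavy lifting (SDF parsing, ETKDG embedding, MMFF94) behind this surface;
everything downstream of this module manipulates `Molecule3D` and numpy
arrays only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

_BOND_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


class ParameterizationError(RuntimeError):
    """MMFF94 parameters could not be assigned to the molecule."""


class SDFParseError(ValueError):
    """A record in an SDF file could not be parsed."""


@dataclass
class Molecule3D:
    """A 3D molecular graph with explicit hydrogens.

    Attributes
    ----------
    elements : list of element symbols, one per atom.
    charges : list of integer formal charges, one per atom.
    coords : (N, 3) float array, Angstrom.
    bonds : list of (i, j, order) with i < j and kekulized integer order.
    name : text identifier.
    """

    elements: list[str]
    charges: list[int]
    coords: np.ndarray
    bonds: list[tuple[int, int, int]]
    name: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.charges) != len(self.elements):
            raise ValueError("charges/elements length mismatch")
        n = len(self.elements)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int, int]] = []
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], int(order)))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Molecule3D":
        return replace(
            self,
            coords=np.array(coords, dtype=float),
            name=self.name if name is None else name,
            properties=dict(self.properties),
        )

    def bond_graph_key(self) -> tuple:
        """Hashable (elements, bonds) key for graph-identity checks."""
        return (tuple(self.elements), tuple(sorted(self.bonds)))

    # ---- RDKit bridge -------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = 0, name: str | None = None) -> "Molecule3D":
        if mol.GetNumConformers() == 0:
            raise ValueError("RDKit molecule has no conformer")
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        conf = kek.GetConformer(conf_id)
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in kek.GetAtoms()]
        charges = [a.GetFormalCharge() for a in kek.GetAtoms()]
        bonds = []
        for b in kek.GetBonds():
            order = int(round(b.GetBondTypeAsDouble()))
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(order, 1)))
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        return cls(elements, charges, coords, bonds, name=name, properties=props)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for el, q in zip(self.elements, self.charges):
            atom = Chem.Atom(el)
            atom.SetFormalCharge(int(q))
            atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _BOND_TO_RDKIT.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
        if sanitize:
            Chem.SanitizeMol(mol)
        mol.SetProp("_Name", self.name)
        for k, v in self.properties.items():
            mol.SetProp(k, str(v))
        return mol


@dataclass
class ConformerEnsemble:
    """A molecule template plus one coordinate set per conformer."""

    molecule: Molecule3D
    coordinate_sets: list[np.ndarray]
    energies: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.coordinate_sets) < 1:
            raise ValueError("ensemble must contain at least one conformer")
        for k, cs in enumerate(self.coordinate_sets):
            cs = np.asarray(cs, dtype=float)
            if cs.shape != (self.molecule.n_atoms, 3):
                raise ValueError(f"conformer {k} has shape {cs.shape}")
            self.coordinate_sets[k] = cs
        if self.energies is not None and len(self.energies) != len(self.coordinate_sets):
            raise ValueError("energies length mismatch")

    def __len__(self) -> int:
        return len(self.coordinate_sets)

    def conformer(self, k: int) -> Molecule3D:
        name = f"{self.molecule.name}_conf{k}" if self.molecule.name else f"conf{k}"
        return self.molecule.with_coords(self.coordinate_sets[k], name=name)


# ---- SDF I/O ---------------------------------------------------------


def read_sdf(path: str) -> list[Molecule3D]:
    """Read all records of a V2000/V3000 SDF file, hydrogens kept as stored."""
    with open(path) as fh:
        if not fh.read().strip():
            return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out: list[Molecule3D] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SDFParseError(f"could not parse SDF record {idx} in {path}")
        out.append(Molecule3D.from_rdkit(mol))
    return out


def write_sdf(mols: list[Molecule3D], path: str) -> None:
    """Write molecules as a multi-record V2000 SDF file."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for m in mols:
            writer.write(m.to_rdkit())
    finally:
        writer.close()


# ---- MMFF94 ----------------------------------------------------------


def _mmff_forcefield(mol: Chem.Mol):
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94")
    if props is None:
        bad = [
            f"{a.GetSymbol()}{a.GetIdx()}"
            for a in mol.GetAtoms()
            if a.GetAtomicNum() not in (1, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53)
        ]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else "<unnamed>"
        raise ParameterizationError(
            f"MMFF94 parameters unassignable for {name}"
            + (f" (suspect atoms: {bad})" if bad else "")
        )
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    if ff is None:
        raise ParameterizationError("MMFF94 force field construction failed")
    return ff


def mmff94_energy(mol: Molecule3D) -> float:
    """MMFF94 energy (kcal/mol) of the molecule's current geometry."""
    rd = mol.to_rdkit()
    return float(_mmff_forcefield(rd).CalcEnergy())


def mmff94_minimize(mol: Molecule3D, max_cycles: int = 500) -> tuple[Molecule3D, float]:
    """Minimize with MMFF94; returns (minimized molecule, final energy).

    The bond graph is untouched; only coordinates move. Energy never
    increases relative to the input geometry.
    """
    rd = mol.to_rdkit()
    ff = _mmff_forcefield(rd)
    e_in = float(ff.CalcEnergy())
    ff.Minimize(maxIts=int(max_cycles))
    e_out = float(ff.CalcEnergy())
    if e_out > e_in:  # minimizer never reports uphill moves, but be strict
        return mol.with_coords(mol.coords), e_in
    coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
    return mol.with_coords(coords), e_out


def mmff94_minimize_restrained(
    mol: Molecule3D,
    restrain_atoms: list[int],
    max_cycles: int = 500,
    max_displacement: float = 0.3,
    force_constant: float = 100.0,
) -> tuple[Molecule3D, float]:
    """MMFF94 minimization with flat-bottom position restraints.

    Restrained atoms pay no penalty within `max_displacement` (A) of their
    input position and a harmonic penalty (`force_constant`,
    kcal/mol/A^2) beyond it. Used to repair bond geometry after rigid
    fragment moves without letting the minimizer undo the moves. The
    returned energy is the plain MMFF94 energy of the final geometry
    (restraint terms excluded).
    """
    rd = mol.to_rdkit()
    ff = _mmff_forcefield(rd)
    for i in restrain_atoms:
        ff.MMFFAddPositionConstraint(int(i), float(max_displacement), float(force_constant))
    ff.Minimize(maxIts=int(max_cycles))
    coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
    out = mol.with_coords(coords)
    return out, mmff94_energy(out)


# ---- conformer generation -------------------------------------------


def generate_conformers(
    mol: Molecule3D,
    n: int,
    prune_rms: float = 1.0,
    seed: int = 0,
    max_cycles: int = 500,
) -> ConformerEnsemble:
    """ETKDG conformer ensemble, MMFF94-optimized and RMSD-pruned.

    Embedding uses the experimental-torsion knowledge distance geometry
    method; duplicates closer than `prune_rms` (symmetry-aware heavy-atom
    best-fit RMSD) are removed both at embedding time and again after
    force-field optimization, so the returned ensemble satisfies the
    pairwise-diversity guarantee on its final coordinates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from rdkit.Chem import rdMolAlign

    rd = mol.to_rdkit()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = float(prune_rms)
    params.useRandomCoords = False
    conf_ids = list(AllChem.EmbedMultipleConfs(rd, numConfs=int(n), params=params))
    if not conf_ids:
        params.useRandomCoords = True
        conf_ids = list(AllChem.EmbedMultipleConfs(rd, numConfs=int(n), params=params))
    if not conf_ids:
        raise RuntimeError(f"conformer embedding failed for molecule '{mol.name}'")

    results = AllChem.MMFFOptimizeMoleculeConfs(rd, maxIters=int(max_cycles), mmffVariant="MMFF94")
    energies = {cid: res[1] for cid, res in zip(conf_ids, results)}

    noh = Chem.RemoveHs(Chem.Mol(rd))
    kept: list[int] = []
    for cid in conf_ids:
        duplicate = False
        for kc in kept:
            probe = Chem.Mol(noh)
            rms = rdMolAlign.GetBestRMS(probe, noh, prbId=cid, refId=kc)
            if rms < prune_rms:
                duplicate = True
                break
        if not duplicate:
            kept.append(cid)

    coord_sets = [np.array(rd.GetConformer(cid).GetPositions(), dtype=float) for cid in kept]
    return ConformerEnsemble(
        molecule=mol,
        coordinate_sets=coord_sets,
        energies=[float(energies[cid]) for cid in kept],
    )
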