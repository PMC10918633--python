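"""Synthetic benchmark fixtures: drug-like references and torsion decoys.

The bundled SMILES list spans the structural variety the alignment pipeline
has to cope with — 1 to 9 fragments per molecule, rotatable-bond counts
from 0 to ~12, halogens and H-bond donors/acceptors so all four
pharmacophoric point classes occur. Every fixture is generated on the fly
(ETKDG embedding + MMFF94 minimization); nothing is downloaded.

A `FixtureCase` pairs a minimized reference conformer with decoys obtained
by rotating 1–3 randomly chosen rotatable bonds by 60–180 degrees and then
re-minimizing with the perturbed torsions restrained, emulating the
experimental-vs-generated conformer gap of a self-alignment benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .chem import ConformerEnsemble, Molecule3D
from .config import RunConfig, derive_seed

# name, SMILES — order is part of the fixture contract (seeded selection)
BUNDLED_SMILES: list[tuple[str, str]] = [
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
    ("bromobenzene", "Brc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("diphenylmethane", "c1ccccc1Cc1ccccc1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("procainamide", "CCN(CC)CCNC(=O)c1ccc(N)cc1"),
    ("sulfamethoxazole", "Cc1cc(no1)NS(=O)(=O)c1ccc(N)cc1"),
    ("diphenhydramine", "CN(C)CCOC(c1ccccc1)c1ccccc1"),
    ("fluoxetine", "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1"),
    ("haloperidol", "OC1(CCN(CC1)CCCC(=O)c1ccc(F)cc1)c1ccc(Cl)cc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("promazine", "CN(C)CCCN1c2ccccc2Sc2ccccc21"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("melatonin", "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"),
    ("trimethoprim", "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
]


@dataclass
class FixtureCase:
    """A reference conformer with torsion-perturbed decoy conformers."""

    reference: Molecule3D
    decoys: ConformerEnsemble
    perturbed_torsions: list[list[tuple[tuple[int, int], float]]] = field(default_factory=list)
    expected_fragment_count: int = 0


def embed_smiles(smiles: str, name: str = "", seed: int = 0) -> Molecule3D:
    """Deterministic 3D structure from SMILES: ETKDG embed + MMFF94 minimize."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"bad SMILES for {name!r}: {smiles}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(rd, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise RuntimeError(f"embedding failed for {name!r}")
    AllChem.MMFFOptimizeMolecule(rd, maxIters=500, mmffVariant="MMFF94")
    return Molecule3D.from_rdkit(rd, name=name)


def _rotatable_torsions(rd: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Heavy-atom dihedrals (a,b,c,d) around strictly rotatable bonds b-c."""
    patt = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")
    torsions = []
    for b, c in rd.GetSubstructMatches(patt):
        nb = [
            a.GetIdx()
            for a in rd.GetAtomWithIdx(b).GetNeighbors()
            if a.GetIdx() != c and a.GetAtomicNum() > 1
        ]
        nc = [
            a.GetIdx()
            for a in rd.GetAtomWithIdx(c).GetNeighbors()
            if a.GetIdx() != b and a.GetAtomicNum() > 1
        ]
        if nb and nc:
            torsions.append((min(nb), b, c, min(nc)))
    return torsions


def make_decoy(
    reference: Molecule3D, seed: int, max_torsions: int = 3
) -> tuple[Molecule3D, list[tuple[tuple[int, int], float]]]:
    """Rotate 1–3 rotatable torsions by 60–180 deg, re-minimize restrained.

    Returns the decoy (graph-identical to the reference) and the list of
    ((b, c) bond, applied angle in degrees) perturbations; rigid molecules
    yield an unperturbed minimized copy.
    """
    rng = np.random.default_rng(int(seed) % (2**31 - 1))
    rd = reference.to_rdkit()
    torsions = _rotatable_torsions(rd)
    if not torsions:
        return reference.with_coords(reference.coords, name=reference.name + "_decoy"), []
    k = int(rng.integers(1, min(max_torsions, len(torsions)) + 1))
    chosen = rng.choice(len(torsions), size=k, replace=False)
    conf = rd.GetConformer()
    applied: list[tuple[tuple[int, int], float]] = []
    for ti in chosen:
        a, b, c, d = torsions[int(ti)]
        delta = float(rng.uniform(60.0, 180.0)) * (1.0 if rng.random() < 0.5 else -1.0)
        cur = rdMolTransforms.GetDihedralDeg(conf, a, b, c, d)
        rdMolTransforms.SetDihedralDeg(conf, a, b, c, d, cur + delta)
        applied.append(((b, c), delta))

    props = AllChem.MMFFGetMoleculeProperties(rd, mmffVariant="MMFF94")
    if props is not None:
        ff = AllChem.MMFFGetMoleculeForceField(rd, props)
        if ff is not None:
            for ti in chosen:
                a, b, c, d = torsions[int(ti)]
                ang = rdMolTransforms.GetDihedralDeg(conf, a, b, c, d)
                ff.MMFFAddTorsionConstraint(a, b, c, d, False, ang - 5.0, ang + 5.0, 100.0)
            ff.Minimize(maxIts=200)
    coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
    decoy = reference.with_coords(coords, name=reference.name + "_decoy")
    return decoy, applied


def make_fixture_set(
    n_cases: int,
    seed: int = 0,
    n_decoys: int = 3,
    config: RunConfig | None = None,
) -> list[FixtureCase]:
    """Deterministic fixture cases drawn from the bundled SMILES list."""
    from .flex import fragment_molecule

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cfg = config or RunConfig()
    cases: list[FixtureCase] = []
    for i in range(n_cases):
        name, smiles = BUNDLED_SMILES[i % len(BUNDLED_SMILES)]
        ref = embed_smiles(smiles, name=name, seed=derive_seed(seed, "ref", i))
        decoys = []
        perturbations = []
        for j in range(n_decoys):
            decoy, applied = make_decoy(ref, seed=derive_seed(seed, "decoy", i, j))
            decoys.append(decoy.coords)
            perturbations.append(applied)
        cases.append(
            FixtureCase(
                reference=ref,
                decoys=ConformerEnsemble(molecule=ref, coordinate_sets=decoys),
                perturbed_torsions=perturbations,
                expected_fragment_count=len(fragment_molecule(ref, cfg)),
            )
        )
    return cases
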